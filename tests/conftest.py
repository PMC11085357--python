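"""Shared fixtures.

Heavy artefacts (the desk-scale datasets and trained models) are
session-scoped so the recovery, Grad-CAM and prediction tests share one
training run per seed instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenonet import model as mod
from phenonet import synthetic_data as syn

DESK_INPUT = 48
DESK_ITERATIONS = 500
DESK_BATCH = 16


@pytest.fixture(scope="session")
def tiny_growth_spec():
    """A very small time-series spec for fast plumbing tests."""
    return syn.GrowthSeriesSpec(
        plants_per_accession={a.name: 2 for a in syn.make_default_accessions()},
        n_days=6,
        image_size=64,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_growth_spec, tmp_path_factory):
    root = tmp_path_factory.mktemp("tiny_plants")
    manifest = syn.generate_phenotype_dataset(tiny_growth_spec, root)
    return manifest, root


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """Desk-preset rosette dataset (4 accessions x 5 plants x 22 days, 96 px)."""
    root = tmp_path_factory.mktemp("desk_plants")
    manifest = syn.generate_phenotype_dataset(syn.desk_growth_spec(seed=1), root)
    return manifest, root


def train_desk_model(manifest, root, seed: int):
    split = mod.stratified_split(manifest, seed=seed)
    net = mod.build_multioutput_net(
        mod.NetworkSpec(input_size=DESK_INPUT), seed=seed
    )
    cfg = mod.TrainConfig(iterations=DESK_ITERATIONS, batch_size=DESK_BATCH,
                          seed=seed)
    net, history = mod.train(net, split, cfg, images_root=root)
    return net, history


@pytest.fixture(scope="session")
def trained_desk_models(desk_dataset):
    """Multi-output models trained on the desk preset for seeds 1..3.

    Each seed re-generates its own dataset only for the split/batching
    randomness; the underlying images are the seed-1 desk dataset, so the
    three runs differ in initialisation, split and batch order.
    """
    manifest, root = desk_dataset
    out = {}
    for seed in (1, 2, 3):
        out[seed] = train_desk_model(manifest, root, seed)
    return out


@pytest.fixture(scope="session")
def desk_model(trained_desk_models):
    """The seed-1 trained multi-output model."""
    return trained_desk_models[1][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
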