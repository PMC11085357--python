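"""Network construction, loss, splitting, training and prediction."""

import math

import numpy as np
import pytest

from phenonet import model as mod
from phenonet import synthetic_data as syn


# ---------------------------------------------------------------------------
# specs and construction


def test_spec_validation():
    with pytest.raises(ValueError):
        mod.NetworkSpec(stem_kernel=4)
    with pytest.raises(ValueError):
        mod.NetworkSpec(n_classes=1)
    with pytest.raises(ValueError):
        mod.TrainConfig(learning_rate=0)
    with pytest.raises(ValueError):
        mod.TrainConfig(iterations=0)


def test_build_requires_matching_head_flag():
    with pytest.raises(ValueError):
        mod.build_multioutput_net(mod.NetworkSpec(regression_head=False))
    with pytest.raises(ValueError):
        mod.build_classifier_net(mod.NetworkSpec(regression_head=True))


def test_forward_at_reference_input_size():
    """Default spec: a 150x150x3 input yields 4 class probabilities and a
    non-negative day prediction."""
    net = mod.build_multioutput_net(mod.NetworkSpec(), seed=0)
    x = np.random.default_rng(0).random((1, 150, 150, 3), dtype=np.float32)
    logits, day = net.forward(x, train=False)
    assert logits.shape == (1, 4)
    assert day.shape == (1,) and day[0] >= 0.0


def test_forward_shape_error():
    net = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=0)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 48, 48, 3), dtype=np.float32))


def test_same_seed_builds_identical_networks():
    a = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=5)
    b = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=5)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)
    c = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=6)
    assert any(
        not np.array_equal(pa.value, pc.value)
        for pa, pc in zip(a.params(), c.params())
    )


def test_classifier_variant_shares_trunk_and_drops_head():
    multi = mod.build_multioutput_net(
        mod.NetworkSpec(input_size=32, n_classes=3), seed=0
    )
    single = mod.build_classifier_net(
        mod.NetworkSpec(input_size=32, n_classes=3, regression_head=False), seed=0
    )
    assert single.trunk_n_params() == multi.trunk_n_params()
    assert single.n_params() < multi.n_params()
    x = np.random.default_rng(1).random((2, 32, 32, 3), dtype=np.float32)
    logits, day = single.forward(x, train=False)
    assert day is None
    probs = mod.predict(single, x).class_probs
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert mod.predict(single, x).pred_day is None


# ---------------------------------------------------------------------------
# loss


def test_multitask_loss_perfect_is_zero():
    probs = np.eye(3)[[0, 1, 2]]
    days = np.array([3.0, 7.0, 20.0])
    assert mod.multitask_loss(probs, [0, 1, 2], days, days, lam=1.0) < 1e-9


def test_multitask_loss_lambda_zero_is_cross_entropy():
    probs = np.array([[0.7, 0.3], [0.4, 0.6]])
    ce = -np.mean([math.log(0.7), math.log(0.6)])
    got = mod.multitask_loss(probs, [0, 1], np.array([5.0]), np.array([1.0]),
                             lam=0.0)
    assert abs(got - ce) < 1e-12


def test_multitask_loss_uniform_probs_give_ln4():
    probs = np.full((6, 4), 0.25)
    days = np.linspace(1, 22, 6)
    got = mod.multitask_loss(probs, [0, 1, 2, 3, 0, 1], days, days, lam=1.0)
    assert abs(got - math.log(4)) < 1e-12


def test_multitask_loss_monotone_in_lambda():
    probs = np.array([[0.9, 0.1]])
    pred = np.array([10.0])
    true = np.array([12.0])
    losses = [mod.multitask_loss(probs, [0], pred, true, lam) for lam in (0, 1, 2)]
    assert losses[0] < losses[1] < losses[2]


def test_multitask_loss_length_mismatch():
    with pytest.raises(ValueError):
        mod.multitask_loss(np.full((2, 2), 0.5), [0], None, None, 0.0)
    with pytest.raises(ValueError):
        mod.multitask_loss(np.full((2, 2), 0.5), [0, 1], np.zeros(2),
                           np.zeros(3), 1.0)


# ---------------------------------------------------------------------------
# stratified split


def _label_manifest(counts):
    import pandas as pd

    rows = []
    for label, n in counts.items():
        for i in range(n):
            rows.append({"path": f"{label}_{i}.png", "label": label,
                         "day": 1, "split": "unassigned"})
    df = pd.DataFrame(rows)
    df["day"] = df["day"].astype("Int64")
    return df


@pytest.mark.parametrize("total,n_train,n_val", [
    (550, 385, 165),   # Cvi-sized class
    (572, 400, 172),   # Ler-1-sized class
    (528, 370, 158),   # Col-0-sized class
    (484, 339, 145),   # Sf-2-sized class
    (300, 210, 90),    # organelle class
    (10, 7, 3),
])
def test_stratified_split_counts(total, n_train, n_val):
    df = mod.stratified_split(_label_manifest({"x": total, "y": 40}), seed=0)
    sub = df[df["label"] == "x"]
    assert (sub["split"] == "train").sum() == n_train
    assert (sub["split"] == "validation").sum() == n_val


def test_stratified_split_no_overlap_and_deterministic():
    df = _label_manifest({"a": 30, "b": 20})
    s1 = mod.stratified_split(df, seed=3)
    s2 = mod.stratified_split(df, seed=3)
    assert list(s1["split"]) == list(s2["split"])
    tr = set(s1.loc[s1["split"] == "train", "path"])
    va = set(s1.loc[s1["split"] == "validation", "path"])
    assert not (tr & va)
    assert len(tr) + len(va) == len(df)


def test_stratified_split_empty_manifest_raises():
    import pandas as pd

    with pytest.raises(ValueError):
        mod.stratified_split(pd.DataFrame({"label": [], "path": [], "split": []}))


# ---------------------------------------------------------------------------
# training and prediction (tiny, fast)


@pytest.fixture(scope="module")
def tiny_trained(tiny_dataset_module):
    manifest, root = tiny_dataset_module
    split = mod.stratified_split(manifest, seed=0)
    net = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=0)
    cfg = mod.TrainConfig(iterations=50, batch_size=16, seed=0)
    net, history = mod.train(net, split, cfg, images_root=root)
    return net, history, split, root


@pytest.fixture(scope="module")
def tiny_dataset_module(tmp_path_factory):
    spec = syn.GrowthSeriesSpec(
        plants_per_accession={a.name: 2 for a in syn.make_default_accessions()},
        n_days=6, image_size=64, seed=11,
    )
    root = tmp_path_factory.mktemp("model_tiny")
    return syn.generate_phenotype_dataset(spec, root), root


def test_training_reduces_loss(tiny_trained):
    _, history, _, _ = tiny_trained
    assert len(history.loss) == 50 and len(history.accuracy) == 50
    assert history.loss[-1] < history.loss[0]


def test_training_is_reproducible(tiny_dataset_module):
    manifest, root = tiny_dataset_module
    split = mod.stratified_split(manifest, seed=0)
    runs = []
    for _ in range(2):
        net = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=0)
        cfg = mod.TrainConfig(iterations=10, batch_size=8, seed=0)
        _, history = mod.train(net, split, cfg, images_root=root)
        runs.append(history)
    assert runs[0].loss == runs[1].loss
    assert runs[0].val_metrics == runs[1].val_metrics


def test_training_empty_split_raises(tiny_dataset_module):
    manifest, root = tiny_dataset_module
    bad = manifest.copy()
    bad["split"] = "validation"
    net = mod.build_multioutput_net(mod.NetworkSpec(input_size=32), seed=0)
    with pytest.raises(ValueError):
        mod.train(net, bad, mod.TrainConfig(iterations=1), images_root=root)


def test_predictions_are_probabilities_with_nonnegative_days(tiny_trained):
    net, _, split, root = tiny_trained
    from phenonet import preprocessing as P

    va = split[split["split"] == "validation"]
    x, labels, days = P.load_manifest_arrays(
        va, root, P.SegmentationConfig(input_size=32)
    )
    batch = mod.predict(net, x)
    assert batch.class_probs.shape == (len(va), 4)
    assert np.allclose(batch.class_probs.sum(axis=1), 1.0, atol=1e-6)
    assert (batch.pred_day >= 0).all()


def test_converged_model_fits_training_data(trained_desk_models, desk_dataset):
    """A converged desk-scale model classifies (a sample of) its own
    training data almost perfectly."""
    from phenonet import preprocessing as P

    net, _ = trained_desk_models[1]
    manifest, root = desk_dataset
    split = mod.stratified_split(manifest, seed=1)
    tr = split[split["split"] == "train"].sample(n=100, random_state=0)
    x, labels, _ = P.load_manifest_arrays(
        tr, root, P.SegmentationConfig(input_size=net.spec.input_size)
    )
    batch = mod.predict(net, x)
    names = net.class_names
    pred = [names[i] for i in batch.class_probs.argmax(axis=1)]
    acc = np.mean([p == l for p, l in zip(pred, labels)])
    assert acc >= 0.95


def test_checkpoint_round_trip(tiny_trained, tmp_path):
    net, _, split, root = tiny_trained
    from phenonet import preprocessing as P

    path = tmp_path / "model.npz"
    mod.save_checkpoint(net, path)
    again = mod.load_checkpoint(path)
    va = split[split["split"] == "validation"]
    x, _, _ = P.load_manifest_arrays(va, root, P.SegmentationConfig(input_size=32))
    a = mod.predict(net, x)
    b = mod.predict(again, x)
    assert np.allclose(a.class_probs, b.class_probs, atol=1e-6)
    assert np.allclose(a.pred_day, b.pred_day, atol=1e-5)
    assert again.class_names == net.class_names
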