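"""End-to-end experiment harness.

Three experiments, each runnable at desk scale on synthetic data:

* **background** — train the multi-output network twice with identical
  seeds, once on raw images and once with the background segmented away,
  and compare classification/regression performance.  The synthetic soil
  darkens with the growth day, so background pixels carry day information;
  the with-background arm can therefore legitimately win on day RMSE.
* **interval** — thin each plant's 22-day series to every (k+1)-th day
  starting at day 1 ("k skipped days"), for k = 1..5, and retrain per
  interval; dataset size (and training time) shrink with k.
* **organelle** — train the single-task classifier variant on the
  three-class organelle dataset.

Reports carry per-arm classification and regression summaries, wall-clock
training time and the config snapshot; they serialise to JSON.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from . import model as mod
from . import preprocessing as P
from . import synthetic_data as syn
from .manifest import (  # re-exported: the manifest is the harness's lingua franca
    ManifestError,
    ManifestRecord,
    is_timeseries,
    read_manifest,
    write_manifest,
)

__all__ = [
    "ManifestRecord",
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "subsample_interval",
    "ExperimentConfig",
    "ArmReport",
    "ExperimentReport",
    "evaluate",
    "run_background_experiment",
    "run_interval_experiment",
    "run_organelle_experiment",
]


def subsample_interval(manifest: pd.DataFrame, interval_days: int) -> pd.DataFrame:
    """Keep days {1, 1+(k+1), 1+2(k+1), ...} of every plant (k skipped days).

    ``interval_days=0`` is the identity.  Raises on organelle manifests
    (no day labels).
    """
    if interval_days < 0:
        raise ValueError("interval_days must be >= 0")
    if not is_timeseries(manifest):
        raise ValueError("interval subsampling requires day labels on every row")
    step = interval_days + 1
    keep = ((manifest["day"].astype(int) - 1) % step) == 0
    return manifest[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration and reports


@dataclass
class ExperimentConfig:
    """Shared knobs of the desk-scale experiments."""

    workdir: Path
    seed: int = 0
    input_size: int = 48
    iterations: int = 500
    batch_size: int = 16
    learning_rate: float = 1e-3
    loss_weight_lambda: float = 1.0
    train_frac: float = 0.7
    growth_spec: Optional[syn.GrowthSeriesSpec] = None
    organelle_spec: Optional[syn.OrganelleSpec] = None

    def train_config(self, iterations: Optional[int] = None) -> mod.TrainConfig:
        return mod.TrainConfig(
            iterations=iterations or self.iterations,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            loss_weight_lambda=self.loss_weight_lambda,
            seed=self.seed,
        )

    def snapshot(self) -> dict:
        d = {k: v for k, v in vars(self).items()
             if k not in ("growth_spec", "organelle_spec")}
        d["workdir"] = str(d["workdir"])
        return d


@dataclass
class ArmReport:
    name: str
    seed: int
    classification: M.ClassificationReport
    regression: Optional[M.RegressionReport]
    train_time_s: float
    n_train: int
    n_val: int
    final_train_loss: float
    final_train_accuracy: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "classification": self.classification.to_dict(),
            "regression": None if self.regression is None else self.regression.to_dict(),
            "train_time_s": self.train_time_s,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "final_train_loss": self.final_train_loss,
            "final_train_accuracy": self.final_train_accuracy,
        }


@dataclass
class ExperimentReport:
    experiment: str
    config: dict
    arms: List[ArmReport] = field(default_factory=list)
    extras: Dict[str, float] = field(default_factory=dict)
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "experiment": self.experiment,
            "config": self.config,
            "arms": [a.to_dict() for a in self.arms],
            "extras": self.extras,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# evaluation


def evaluate(net: mod.MultiOutputNet, manifest: pd.DataFrame, images_root,
             seg_config: Optional[P.SegmentationConfig] = None,
             remove_background: bool = False):
    """Classification (and regression, if applicable) reports on a manifest."""
    seg = seg_config or P.SegmentationConfig(input_size=net.spec.input_size)
    x, labels, days = P.load_manifest_arrays(manifest, images_root, seg,
                                             remove_background)
    batch = mod.predict(net, x)
    names = net.class_names or [str(i) for i in range(net.spec.n_classes)]
    pred_labels = [names[i] for i in batch.class_probs.argmax(axis=1)]
    cm = M.confusion_matrix(list(labels), pred_labels, names)
    cls_report = M.macro_report(cm)
    reg_report = None
    if batch.pred_day is not None and not np.isnan(days).any() and np.ptp(days) > 0:
        reg_report = M.regression_report(days, batch.pred_day)
    return cls_report, reg_report


# ---------------------------------------------------------------------------
# experiment arms


def _train_arm(name: str, manifest: pd.DataFrame, images_root,
               config: ExperimentConfig, *, n_classes: int,
               regression_head: bool, remove_background: bool = False,
               iterations: Optional[int] = None) -> ArmReport:
    spec = mod.NetworkSpec(input_size=config.input_size, n_classes=n_classes,
                           regression_head=regression_head)
    build = mod.build_multioutput_net if regression_head else mod.build_classifier_net
    net = build(spec, seed=config.seed)
    seg = P.SegmentationConfig(input_size=config.input_size)
    t0 = time.perf_counter()
    net, history = mod.train(net, manifest, config.train_config(iterations),
                             images_root=images_root, seg_config=seg,
                             remove_background=remove_background)
    elapsed = time.perf_counter() - t0
    val = manifest[manifest["split"] == "validation"]
    cls_report, reg_report = evaluate(net, val, images_root, seg,
                                      remove_background=remove_background)
    return ArmReport(
        name=name,
        seed=config.seed,
        classification=cls_report,
        regression=reg_report,
        train_time_s=elapsed,
        n_train=int((manifest["split"] == "train").sum()),
        n_val=len(val),
        final_train_loss=history.loss[-1],
        final_train_accuracy=history.accuracy[-1],
    )


def _growth_dataset(config: ExperimentConfig):
    spec = config.growth_spec or syn.desk_growth_spec(seed=config.seed)
    out = Path(config.workdir) / "plant_images"
    manifest = syn.generate_phenotype_dataset(spec, out)
    manifest = mod.stratified_split(manifest, config.train_frac, seed=config.seed)
    return manifest, out


def run_background_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Raw-image arm vs background-removed arm, identical seeds."""
    manifest, root = _growth_dataset(config)
    report = ExperimentReport("background", config.snapshot())
    for name, remove in (("with_background", False), ("background_removed", True)):
        report.arms.append(
            _train_arm(name, manifest, root, config, n_classes=4,
                       regression_head=True, remove_background=remove)
        )
    with_bg, no_bg = report.arms
    if with_bg.regression and no_bg.regression:
        report.extras["rmse_with_background"] = with_bg.regression.rmse
        report.extras["rmse_background_removed"] = no_bg.regression.rmse
        report.extras["rmse_delta"] = no_bg.regression.rmse - with_bg.regression.rmse
    report.extras["accuracy_delta"] = (
        with_bg.classification.overall_accuracy
        - no_bg.classification.overall_accuracy
    )
    return report


def run_interval_experiment(config: ExperimentConfig,
                            intervals: Sequence[int] = (1, 2, 3, 4, 5)
                            ) -> List[ExperimentReport]:
    """One retraining per day-interval; dataset size decreases with k."""
    manifest, root = _growth_dataset(config)
    reports = []
    for k in intervals:
        sub = subsample_interval(manifest, k)
        report = ExperimentReport(f"interval_{k}", config.snapshot())
        report.extras["interval_days"] = k
        report.extras["n_images"] = len(sub)
        report.extras["days_per_plant"] = int(sub["day"].nunique())
        report.arms.append(
            _train_arm(f"interval_{k}", sub, root, config, n_classes=4,
                       regression_head=True)
        )
        reports.append(report)
    return reports


def run_organelle_experiment(config: ExperimentConfig,
                             iterations: Optional[int] = None) -> ExperimentReport:
    """Single-task classifier on the three organelle classes."""
    spec = config.organelle_spec or syn.desk_organelle_spec(seed=config.seed)
    root = Path(config.workdir) / "organelle_images"
    manifest = syn.generate_organelle_dataset(spec, root)
    manifest = mod.stratified_split(manifest, config.train_frac, seed=config.seed)
    # feed organelle frames at native resolution so blob shape statistics
    # (the only class signal) survive
    config = replace(config, input_size=min(spec.image_size, 64))
    report = ExperimentReport("organelle", config.snapshot())
    report.arms.append(
        _train_arm("organelle", manifest, root, config, n_classes=3,
                   regression_head=False, iterations=iterations)
    )
    return report
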