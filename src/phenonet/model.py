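"""The multi-output phenotyping network and its training loop.

Architecture (shared trunk, two heads):

    input (S, S, 3)
      -> Conv(16, 5x5) - BN - ReLU                        (stem)
      -> Conv(32, 3x3) - BN - ReLU - Conv(32, 3x3) - BN   (main branch)
         + Conv(32, 1x1) - BN - ReLU                      (skip branch)
      -> addition -> ReLU                                  (trunk output)
      -> global average pool -> FC(64) - ReLU              (shared features)
      -> head A: FC(K) - softmax            (genotype / organelle class)
      -> head B: FC(16) - ReLU - FC(1) - ReLU (growth day, non-negative)

The single-task classifier variant keeps the identical trunk and simply
omits head B.  Training minimises

    L = cross_entropy(class) + lambda * MSE(day / day_scale)

with Adam; day labels are divided by ``day_scale`` (default 22, the length
of the observation window) so both loss terms are O(1).  "Iterations" are
mini-batch updates.  Everything is seeded: weight init, batch sampling and
the stratified split are reproducible bit-for-bit on one machine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from . import preprocessing as P
from .nn import (Adam, BatchNorm, Conv2D, Dense, GlobalAvgMaxPool,
                 GlobalAvgPool, ReLU, softmax, zero_grads)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "PredictionBatch",
    "TrainHistory",
    "MultiOutputNet",
    "build_multioutput_net",
    "build_classifier_net",
    "multitask_loss",
    "stratified_split",
    "train",
    "fit_arrays",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    input_size: int = 150
    stem_filters: int = 16
    stem_kernel: int = 5
    res_filters: int = 32
    res_kernel: int = 3
    skip_kernel: int = 1
    n_classes: int = 4
    regression_head: bool = True
    fc_width: int = 64
    reg_hidden: int = 16
    pooling: str = "avgmax"  # "avgmax" | "avg"

    def __post_init__(self):
        for k in (self.stem_kernel, self.res_kernel, self.skip_kernel):
            if k % 2 != 1:
                raise ValueError("kernel sizes must be odd")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.pooling not in ("avgmax", "avg"):
            raise ValueError("pooling must be 'avgmax' or 'avg'")


@dataclass
class TrainConfig:
    iterations: int = 500
    batch_size: int = 128
    learning_rate: float = 1e-3
    loss_weight_lambda: float = 1.0
    seed: int = 0
    day_scale: float = 22.0

    def __post_init__(self):
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_weight_lambda < 0:
            raise ValueError("loss_weight_lambda must be >= 0")


@dataclass
class PredictionBatch:
    class_probs: np.ndarray            # (n, K), rows on the simplex
    pred_day: Optional[np.ndarray]     # (n,) days, >= 0; None without head B


@dataclass
class TrainHistory:
    loss: List[float] = field(default_factory=list)
    accuracy: List[float] = field(default_factory=list)
    val_metrics: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# network


class MultiOutputNet:
    """Shared-trunk CNN with a softmax class head and optional day head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.class_names: Optional[List[str]] = None
        self.day_scale: float = 22.0
        f = spec
        self.stem = [Conv2D(3, f.stem_filters, f.stem_kernel, rng),
                     BatchNorm(f.stem_filters), ReLU()]
        self.main = [Conv2D(f.stem_filters, f.res_filters, f.res_kernel, rng),
                     BatchNorm(f.res_filters), ReLU(),
                     Conv2D(f.res_filters, f.res_filters, f.res_kernel, rng),
                     BatchNorm(f.res_filters)]
        self.skip = [Conv2D(f.stem_filters, f.res_filters, f.skip_kernel, rng),
                     BatchNorm(f.res_filters), ReLU()]
        self.post_relu = ReLU()
        if f.pooling == "avgmax":
            self.pool = GlobalAvgMaxPool()
            pooled = 2 * f.res_filters
        else:
            self.pool = GlobalAvgPool()
            pooled = f.res_filters
        self.shared = [Dense(pooled, f.fc_width, rng), ReLU()]
        self.cls_head = Dense(f.fc_width, f.n_classes, rng)
        if f.regression_head:
            self.reg_head = [Dense(f.fc_width, f.reg_hidden, rng), ReLU(),
                             Dense(f.reg_hidden, 1, rng), ReLU()]
            # start the day output small and near the middle of the
            # normalised target range: a large initial output would be
            # slammed below zero by the first updates, permanently killing
            # the output ReLU
            self.reg_head[2].W.value *= 0.05
            self.reg_head[2].b.value[:] = 0.5
        else:
            self.reg_head = None
        self.trunk_activation: Optional[np.ndarray] = None

    # -- parameter plumbing --------------------------------------------------

    def _layers(self):
        layers = self.stem + self.main + self.skip + self.shared + [self.cls_head]
        if self.reg_head is not None:
            layers += self.reg_head
        return layers

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def trunk_n_params(self) -> int:
        out = 0
        for layer in self.stem + self.main + self.skip:
            out += sum(p.value.size for p in layer.params)
        return out

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True):
        """Returns ``(logits, day_norm)``; ``day_norm`` is None without head B."""
        x = np.asarray(x, dtype=np.float32)
        s = self.spec.input_size
        if x.ndim != 4 or x.shape[1] != s or x.shape[2] != s or x.shape[3] != 3:
            raise ValueError(f"expected input (N, {s}, {s}, 3), got {x.shape}")
        h = x
        for layer in self.stem:
            h = layer.forward(h, train)
        m = h
        for layer in self.main:
            m = layer.forward(m, train)
        sk = h
        for layer in self.skip:
            sk = layer.forward(sk, train)
        a = self.post_relu.forward(m + sk, train)
        self.trunk_activation = a
        g = self.pool.forward(a, train)
        for layer in self.shared:
            g = layer.forward(g, train)
        logits = self.cls_head.forward(g, train)
        day = None
        if self.reg_head is not None:
            d = g
            for layer in self.reg_head:
                d = layer.forward(d, train)
            day = d[:, 0]
        return logits, day

    def backward(self, dlogits: np.ndarray, dday: Optional[np.ndarray] = None,
                 to_trunk: bool = False):
        """Backpropagate head gradients; uses the caches of the last forward.

        With ``to_trunk=True`` stops at (and returns) the gradient with
        respect to the trunk activation map — what Grad-CAM needs.
        Otherwise propagates all the way to the input and accumulates
        parameter gradients.
        """
        dg = self.cls_head.backward(np.asarray(dlogits, dtype=np.float32))
        if self.reg_head is not None and dday is not None:
            dd = np.asarray(dday, dtype=np.float32)[:, None]
            for layer in reversed(self.reg_head):
                dd = layer.backward(dd)
            dg = dg + dd
        for layer in reversed(self.shared):
            dg = layer.backward(dg)
        da = self.pool.backward(dg)
        if to_trunk:
            return da
        da = self.post_relu.backward(da)
        dm = da
        for layer in reversed(self.main):
            dm = layer.backward(dm)
        dsk = da
        for layer in reversed(self.skip):
            dsk = layer.backward(dsk)
        dh = dm + dsk
        for layer in reversed(self.stem):
            dh = layer.backward(dh)
        return dh

    # -- inference -----------------------------------------------------------

    def predict_arrays(self, x: np.ndarray, batch: int = 64):
        """Eval-mode forward in minibatches; returns (probs, day_norm|None)."""
        probs, days = [], []
        for i in range(0, len(x), batch):
            logits, day = self.forward(x[i : i + batch], train=False)
            probs.append(softmax(logits))
            if day is not None:
                days.append(day)
        return (
            np.concatenate(probs) if probs else np.zeros((0, self.spec.n_classes)),
            np.concatenate(days) if days else None,
        )


def build_multioutput_net(spec: NetworkSpec, seed: int = 0) -> MultiOutputNet:
    """The two-headed network (classification + day regression)."""
    if not spec.regression_head:
        raise ValueError("spec.regression_head must be True; "
                         "use build_classifier_net for the single-task variant")
    return MultiOutputNet(spec, seed=seed)


def build_classifier_net(spec: NetworkSpec, seed: int = 0) -> MultiOutputNet:
    """Single-task variant: identical trunk, classification head only."""
    if spec.regression_head:
        raise ValueError("spec.regression_head must be False for the classifier")
    return MultiOutputNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# loss


def multitask_loss(class_probs: np.ndarray, class_true: np.ndarray,
                   pred_day: Optional[np.ndarray], day_true: Optional[np.ndarray],
                   lam: float, day_scale: float = 22.0) -> float:
    """Joint loss: cross-entropy + lambda * MSE on day-scale-normalised days.

    ``class_true`` holds integer class indices.  With ``lam == 0`` (or no
    regression head) this is exactly the mean cross-entropy.
    """
    probs = np.asarray(class_probs, dtype=float)
    idx = np.asarray(class_true)
    if probs.shape[0] != idx.shape[0]:
        raise ValueError("batch lengths differ")
    ce = float(-np.mean(np.log(np.clip(probs[np.arange(len(idx)), idx], 1e-12, None))))
    if lam == 0 or pred_day is None or day_true is None:
        return ce
    pred_day = np.asarray(pred_day, dtype=float)
    day_true = np.asarray(day_true, dtype=float)
    if pred_day.shape != day_true.shape:
        raise ValueError("day batch lengths differ")
    mse = float(np.mean(((pred_day - day_true) / day_scale) ** 2))
    return ce + lam * mse


# ---------------------------------------------------------------------------
# splitting


def stratified_split(manifest: pd.DataFrame, train_frac: float = 0.7,
                     seed: int = 0) -> pd.DataFrame:
    """Per-class random split into train/validation.

    Each class contributes ``round(train_frac * class_total)`` training
    rows; the remainder goes to validation.  Returns a copy with the
    ``split`` column assigned.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "validation"
    for label in sorted(out["label"].unique()):
        idx = np.flatnonzero((out["label"] == label).to_numpy())
        if idx.size == 0:
            raise ValueError(f"empty class {label!r}")
        n_train = int(math.floor(train_frac * idx.size + 0.5))
        chosen = rng.permutation(idx)[:n_train]
        out.iloc[chosen, out.columns.get_loc("split")] = "train"
    return out


# ---------------------------------------------------------------------------
# training


def fit_arrays(net: MultiOutputNet, x_train: np.ndarray, y_train: np.ndarray,
               day_train: Optional[np.ndarray], config: TrainConfig,
               x_val: Optional[np.ndarray] = None,
               y_val: Optional[np.ndarray] = None,
               day_val: Optional[np.ndarray] = None) -> TrainHistory:
    """Run ``config.iterations`` Adam minibatch updates on in-memory arrays.

    ``y_train`` holds integer class indices; ``day_train`` raw day labels
    (or None for the single-task classifier).  Validation metrics, when
    validation data is given, are stored in ``history.val_metrics``.
    """
    n = len(x_train)
    if n == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    params = net.params()
    opt = Adam(params, lr=config.learning_rate)
    lam = config.loss_weight_lambda
    scale = config.day_scale
    net.day_scale = scale
    use_reg = net.reg_head is not None and day_train is not None
    bs = min(config.batch_size, n)
    history = TrainHistory()

    for _ in range(config.iterations):
        idx = rng.choice(n, size=bs, replace=False)
        xb = x_train[idx]
        yb = y_train[idx]
        logits, day_norm = net.forward(xb, train=True)
        probs = softmax(logits)
        dlogits = probs.copy()
        dlogits[np.arange(bs), yb] -= 1.0
        dlogits /= bs
        dday = None
        day_b = None
        if use_reg:
            day_b = day_train[idx]
            dday = lam * 2.0 * (day_norm - day_b / scale) / bs
        zero_grads(params)
        net.backward(dlogits.astype(np.float32),
                     None if dday is None else dday.astype(np.float32))
        opt.step()
        loss = multitask_loss(probs, yb,
                              None if day_norm is None else day_norm * scale,
                              day_b, lam if use_reg else 0.0, scale)
        history.loss.append(loss)
        history.accuracy.append(float(np.mean(probs.argmax(axis=1) == yb)))

    if x_val is not None and len(x_val):
        probs, day_norm = net.predict_arrays(x_val)
        pred = probs.argmax(axis=1)
        history.val_metrics["accuracy"] = float(np.mean(pred == y_val))
        names = net.class_names or [str(i) for i in range(net.spec.n_classes)]
        cm = M.confusion_matrix([names[i] for i in y_val],
                                [names[i] for i in pred], names)
        history.val_metrics["macro_f1"] = M.macro_report(cm).macro_f1
        if use_reg and day_val is not None and day_norm is not None:
            pred_day = day_norm * scale
            history.val_metrics["rmse"] = M.rmse(day_val, pred_day)
            if np.ptp(day_val) > 0:
                history.val_metrics["r2"] = M.r_squared(day_val, pred_day)
                history.val_metrics["rpd"] = M.rpd(day_val, pred_day)
    return history


def _encode_labels(labels: np.ndarray, class_names: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    return np.array([index[l] for l in labels], dtype=np.int64)


def train(net: MultiOutputNet, manifest: pd.DataFrame, config: TrainConfig, *,
          images_root, seg_config: Optional[P.SegmentationConfig] = None,
          remove_background: bool = False):
    """Train from a split manifest; loads and preprocesses images itself.

    Returns ``(net, TrainHistory)``.  The manifest must already carry a
    train/validation split (see :func:`stratified_split`).
    """
    seg = seg_config or P.SegmentationConfig(input_size=net.spec.input_size)
    if seg.input_size != net.spec.input_size:
        raise ValueError("seg_config.input_size must match the network input size")
    tr = manifest[manifest["split"] == "train"]
    va = manifest[manifest["split"] == "validation"]
    if len(tr) == 0:
        raise ValueError("empty training split")
    class_names = sorted(manifest["label"].unique())
    if len(class_names) != net.spec.n_classes:
        raise ValueError(
            f"manifest has {len(class_names)} classes, network expects "
            f"{net.spec.n_classes}"
        )
    net.class_names = class_names
    xt, lt, dt = P.load_manifest_arrays(tr, images_root, seg, remove_background)
    xv, lv, dv = P.load_manifest_arrays(va, images_root, seg, remove_background)
    yt = _encode_labels(lt, class_names)
    yv = _encode_labels(lv, class_names)
    has_days = not np.isnan(dt).any()
    history = fit_arrays(
        net, xt, yt, dt if has_days else None, config,
        x_val=xv, y_val=yv, day_val=dv if has_days else None,
    )
    return net, history


def predict(net: MultiOutputNet, images: np.ndarray) -> PredictionBatch:
    """Predict class probabilities (and days, rescaled) for a batch of images.

    ``images`` may be uint8 in [0, 255] or float already scaled to [0, 1].
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / np.float32(255.0)
    probs, day_norm = net.predict_arrays(np.asarray(x, dtype=np.float32))
    return PredictionBatch(
        class_probs=probs,
        pred_day=None if day_norm is None else day_norm * net.day_scale,
    )


def save_history_csv(history: TrainHistory, path) -> None:
    """Training log: one row per iteration (iteration, loss, accuracy)."""
    pd.DataFrame({
        "iteration": np.arange(1, len(history.loss) + 1),
        "loss": history.loss,
        "accuracy": history.accuracy,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(net: MultiOutputNet, path) -> None:
    """Single-file checkpoint: weights + BN statistics + spec header."""
    arrays = {}
    for i, p in enumerate(net.params()):
        arrays[f"param_{i:03d}"] = p.value
    bn_state = []
    for layer in net._layers():
        if isinstance(layer, BatchNorm):
            bn_state.extend([layer.running_mean, layer.running_var])
    for i, a in enumerate(bn_state):
        arrays[f"bn_{i:03d}"] = a
    header = {
        "spec": asdict(net.spec),
        "class_names": net.class_names,
        "day_scale": net.day_scale,
    }
    np.savez_compressed(path, header=yaml.safe_dump(header), **arrays)


def load_checkpoint(path) -> MultiOutputNet:
    with np.load(path, allow_pickle=False) as z:
        header = yaml.safe_load(str(z["header"]))
        net = MultiOutputNet(NetworkSpec(**header["spec"]))
        net.class_names = header["class_names"]
        net.day_scale = float(header["day_scale"])
        for i, p in enumerate(net.params()):
            p.value[...] = z[f"param_{i:03d}"]
        i = 0
        for layer in net._layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean = z[f"bn_{i:03d}"]
                layer.running_var = z[f"bn_{i + 1:03d}"]
                i += 2
    return net
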