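"""Bone age regressors: base training and same-domain transfer learning.

One regressor per (sex, segment) with segment in {fullhand, shortbones,
carpals, wrist}.  The default backbone is a small CNN (three conv blocks,
global average pooling, linear head) so the whole pipeline trains on one CPU
in minutes; a heavier backbone can be substituted by swapping
``build_backbone``.

Transfer protocol for a shifted target cohort: freeze every layer of the
source-trained model except the final linear head, re-fit that head on
target-cohort crops, and keep normalizing inputs with the SOURCE training
statistics (mean/sd of source images) so the frozen features see the
distribution they were trained on.  The head re-fit is a ridge-regularized
least-squares solve on the frozen pooled features — deterministic, exact, and
byte-preserving for every non-head parameter.

Predictions are continuous months, clamped to [0, 300] for physical
plausibility; snapping to GP classes happens later, at fusion/evaluation time.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .errors import DataError, InvalidInputError
from .segmentation import resize_image

__all__ = [
    "LabeledImage", "TrainConfig", "RegressorState", "train_base",
    "fine_tune_head", "predict_age", "average_raters",
    "save_regressor", "load_regressor",
]

TARGETS = ("fullhand", "shortbones", "carpals", "wrist")
AGE_CLAMP = (0.0, 300.0)


@dataclass(frozen=True)
class LabeledImage:
    """A training example: grayscale image, age label in months, subject sex."""

    image: np.ndarray
    label: float
    sex: str


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    lr: float = 1e-2
    input_size: int = 64
    seed: int = 0
    loss: str = "L1"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0 or self.input_size < 8:
            raise InvalidInputError("invalid TrainConfig values")
        if self.loss not in ("L1", "L2"):
            raise InvalidInputError("loss must be 'L1' or 'L2'")


@dataclass
class RegressorState:
    backbone: str
    net: nn.Sequential
    norm_mean: float            # input normalization (source-image statistics)
    norm_sd: float
    label_mean: float           # internal label standardization (months)
    label_sd: float
    segment: str
    sex: str
    config: TrainConfig
    fine_tuned: bool = False
    loss_trajectory: list[float] = field(default_factory=list)


def build_backbone(rng: np.random.Generator) -> nn.Sequential:
    """Small CNN: 3x(Conv-BN-ReLU-pool) -> GAP -> linear head (last layer)."""
    return nn.Sequential(
        nn.Conv2d(1, 8, 3, rng), nn.BatchNorm2d(8), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(8, 16, 3, rng), nn.BatchNorm2d(16), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2d(16, 32, 3, rng), nn.BatchNorm2d(32), nn.ReLU(), nn.MaxPool2(),
        nn.GlobalAvgPool(),
        nn.Linear(32, 1, rng),
    )


def average_raters(rater_a: Sequence[float], rater_b: Sequence[float]) -> np.ndarray:
    """Training labels from two independent raters: their arithmetic mean."""
    a, b = np.asarray(rater_a, float), np.asarray(rater_b, float)
    if a.shape != b.shape:
        raise InvalidInputError("rater columns must have equal length")
    return (a + b) / 2.0


def _check_single_sex(data: Sequence[LabeledImage], expected: str | None = None) -> str:
    if len(data) == 0:
        raise DataError("empty training set")
    sexes = {d.sex for d in data}
    if len(sexes) > 1:
        raise DataError(f"training set mixes sexes {sorted(sexes)}; train per sex")
    sex = sexes.pop()
    if expected is not None and sex != expected:
        raise DataError(f"training set is {sex!r} but model is {expected!r}")
    return sex


def _prepare(data: Sequence[LabeledImage], size: int,
             mean: float | None = None, sd: float | None = None):
    x = np.stack([resize_image(d.image, size) for d in data])[:, None]
    y = np.array([d.label for d in data], dtype=float)
    if mean is None:
        mean = float(x.mean())
        sd = float(x.std())
        if sd <= 0:
            raise DataError("training images have zero intensity variance")
    return ((x - mean) / sd).astype(nn.F32), y, mean, sd


def train_base(data: Sequence[LabeledImage], cfg: TrainConfig = TrainConfig(),
               segment: str = "fullhand") -> RegressorState:
    """Train a regressor from scratch on source-domain images.

    Normalization statistics (mean/sd of the training images after resizing)
    are computed here and stored with the model; they follow the model through
    any later transfer step.
    """
    if segment not in TARGETS:
        raise InvalidInputError(f"segment must be one of {TARGETS}")
    sex = _check_single_sex(data)
    rng = np.random.default_rng(cfg.seed)
    net = build_backbone(rng)
    x, y, mean, sd = _prepare(data, cfg.input_size)
    # the net regresses standardized labels (z-scores); months are restored at
    # prediction time.  Keeps head weights O(1) and training well-conditioned.
    label_mean = float(y.mean())
    label_sd = float(y.std()) or 1.0
    ys = (y - label_mean) / label_sd
    loss_fn = nn.l1_loss if cfg.loss == "L1" else nn.l2_loss
    opt = nn.Adam(net.parameters(), net.gradients(), lr=cfg.lr)
    n = len(data)
    traj = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = net.forward(x[idx], "train")[:, 0]
            loss, dpred = loss_fn(pred, ys[idx])
            net.backward(dpred[:, None])
            opt.step()
            epoch_loss += loss * len(idx)
        # trajectory reported in months for interpretability
        traj.append(epoch_loss / n * (label_sd if cfg.loss == "L1" else label_sd**2))
    _calibrate(net, x, ys)
    return RegressorState(backbone="small_cnn", net=net, norm_mean=mean,
                          norm_sd=sd, label_mean=label_mean, label_sd=label_sd,
                          segment=segment, sex=sex, config=cfg,
                          loss_trajectory=traj)


def _calibrate(net: nn.Sequential, x: np.ndarray, ys: np.ndarray,
               ridge: float = 1e-3) -> None:
    """Align inference with training after SGD.

    Mini-batch batch-norm statistics drift from the full-data statistics, so
    running buffers are re-estimated with one full-data pass; the linear head
    is then re-solved in closed form on the eval-mode pooled features (the
    exact optimum of the squared loss the head sees at inference).
    """
    for layer in net.layers:
        if isinstance(layer, nn.BatchNorm2d):
            saved = layer.momentum
            layer.momentum = 1.0
    net.forward(x, "train")
    for layer in net.layers:
        if isinstance(layer, nn.BatchNorm2d):
            layer.momentum = saved
    h = x
    for layer in net.layers[:-1]:
        h = layer.forward(h, "eval")
    feats = h.astype(float)
    n, k = feats.shape
    design = np.hstack([feats, np.ones((n, 1))])
    reg = ridge * np.eye(k + 1)
    reg[-1, -1] = 0.0
    coef = np.linalg.solve(design.T @ design + reg, design.T @ ys)
    head = net.layers[-1]
    head.weight[...] = coef[:k][None, :].astype(nn.F32)
    head.bias[...] = np.float32(coef[k])


def _features(state: RegressorState, x: np.ndarray) -> np.ndarray:
    """Pooled features just before the linear head, eval-mode normalization."""
    h = x
    for layer in state.net.layers[:-1]:
        h = layer.forward(h, "eval")
    return h


def fine_tune_head(base: RegressorState, data: Sequence[LabeledImage],
                   ridge: float = 1e-3) -> RegressorState:
    """Same-domain transfer: re-fit only the final linear head on target data.

    All non-head parameters and buffers of the returned model are
    byte-identical to the base model; inputs are normalized with the base
    model's stored source statistics.
    """
    if base.norm_sd is None or base.norm_sd <= 0:
        raise DataError("base model is missing normalization statistics")
    _check_single_sex(data, expected=base.sex)
    x, y, _, _ = _prepare(data, base.config.input_size,
                          mean=base.norm_mean, sd=base.norm_sd)
    ys = (y - base.label_mean) / base.label_sd          # base model's label scale
    feats = _features(base, x).astype(float)           # (n, 32)
    n, k = feats.shape
    design = np.hstack([feats, np.ones((n, 1))])
    reg = ridge * np.eye(k + 1)
    reg[-1, -1] = 0.0                                   # do not shrink the intercept
    coef = np.linalg.solve(design.T @ design + reg, design.T @ ys)
    tuned = copy.deepcopy(base)
    head = tuned.net.layers[-1]
    head.weight[...] = coef[:k][None, :].astype(nn.F32)
    head.bias[...] = np.float32(coef[k])
    tuned.fine_tuned = True
    tuned.loss_trajectory = []
    return tuned


def predict_age(state: RegressorState, image: np.ndarray) -> float:
    """Deterministic eval-mode age prediction in months, clamped to [0, 300]."""
    img = np.asarray(image, dtype=float)
    size = state.config.input_size
    if img.shape != (size, size):
        raise InvalidInputError(
            f"image shape {img.shape} does not match model input size {size}")
    x = ((img - state.norm_mean) / state.norm_sd)[None, None].astype(nn.F32)
    z = float(state.net.forward(x, "eval")[0, 0])
    return float(np.clip(z * state.label_sd + state.label_mean, *AGE_CLAMP))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_regressor(state: RegressorState, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **nn.state_dict(state.net))
    sidecar = {
        "backbone": state.backbone,
        "segment": state.segment,
        "sex": state.sex,
        "norm_mean": state.norm_mean,
        "norm_sd": state.norm_sd,
        "label_mean": state.label_mean,
        "label_sd": state.label_sd,
        "fine_tuned": state.fine_tuned,
        "config": asdict(state.config),
        "loss_trajectory": state.loss_trajectory,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_regressor(path: str | Path) -> RegressorState:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = TrainConfig(**sidecar["config"])
    net = build_backbone(np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        nn.load_state_dict(net, dict(data))
    return RegressorState(
        backbone=sidecar["backbone"], net=net, norm_mean=sidecar["norm_mean"],
        norm_sd=sidecar["norm_sd"], label_mean=sidecar["label_mean"],
        label_sd=sidecar["label_sd"], segment=sidecar["segment"],
        sex=sidecar["sex"], config=cfg, fine_tuned=sidecar["fine_tuned"],
        loss_trajectory=list(sidecar["loss_trajectory"]))
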