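"""Segmental Greulich-Pyle (SGP) fusion.

A full-hand regressor captures global skeletal maturity; three segment
regressors (short bones, carpals, wrist) capture local, possibly asynchronous
maturity.  The SGP estimate blends the segment average with the full-hand
prediction through a convex combination

    C_i = alpha * Seg_Avg_i + (1 - alpha) * fh_i,

snaps C_i to the closest discrete GP class C~_i, and picks the per-sex weight
alpha* minimizing the squared error sum(C~_i - y_i)^2 over a sweep of the
interval [0, 1].  Inference then reports SGP_i = snap(alpha* * Seg_Avg_i +
(1 - alpha*) * fh_i), always a member of the GP grid.

Because the loss is evaluated after snapping it is piecewise constant in
alpha; minima are plateaus and ties are resolved toward the smallest alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, InvalidInputError
from .gp_scale import GPScale, snap_array

__all__ = [
    "PredictionRecord", "FusionModel", "combine", "fusion_sse",
    "fit_alpha", "sgp_predict", "save_fusion_model", "load_fusion_model",
]


@dataclass
class PredictionRecord:
    """One image's predictions: full-hand fh, three segments, ground truth y."""

    id: str
    sex: str
    fh: float
    seg_shortbones: float
    seg_carpals: float
    seg_wrist: float
    y: float
    seg_avg: float = field(default=None)  # type: ignore[assignment]
    extra: dict = field(default_factory=dict)   # unknown table columns, preserved

    def __post_init__(self):
        mean = (self.seg_shortbones + self.seg_carpals + self.seg_wrist) / 3.0
        if self.seg_avg is None:
            self.seg_avg = mean
        elif abs(self.seg_avg - mean) > 1e-6:
            raise DataError(
                f"record {self.id}: seg_avg={self.seg_avg} is not the mean of the "
                f"segment predictions ({mean})")


@dataclass
class FusionModel:
    """Fitted per-sex SGP weight with its sweep grid and loss landscape."""

    sex: str
    alpha_star: float
    grid_step: float
    scale: GPScale
    loss_curve: list[tuple[float, float]]   # (alpha, summed squared error)


def combine(fh: float, seg_avg: float, alpha: float) -> float:
    """Convex combination alpha*seg_avg + (1-alpha)*fh; lies between the two."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidInputError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * seg_avg + (1.0 - alpha) * fh


def _extract(records: list[PredictionRecord], scale: GPScale):
    if len(records) == 0:
        raise DataError("no prediction records")
    sexes = {r.sex for r in records}
    if len(sexes) > 1:
        raise DataError(f"records mix sexes {sorted(sexes)}; fit per sex")
    if sexes != {scale.sex}:
        raise DataError(f"records are {sexes.pop()!r} but scale is {scale.sex!r}")
    fh = np.array([r.fh for r in records])
    sa = np.array([r.seg_avg for r in records])
    y = np.array([r.y for r in records])
    grid = np.asarray(scale.classes)
    off_grid = ~np.isclose(y[:, None], grid[None, :], rtol=0, atol=1e-6).any(axis=1)
    if off_grid.any():
        bad = records[int(np.nonzero(off_grid)[0][0])]
        raise DataError(f"record {bad.id}: y={bad.y} is not a class of the GP scale")
    return fh, sa, y


def fusion_sse(records: list[PredictionRecord], scale: GPScale,
               alphas: np.ndarray) -> np.ndarray:
    """Snapped squared-error sum of the convex combination at each alpha."""
    fh, sa, y = _extract(records, scale)
    a = np.asarray(alphas, dtype=float)[:, None]
    snapped = snap_array(a * sa[None, :] + (1.0 - a) * fh[None, :], scale)
    return ((snapped - y[None, :]) ** 2).sum(axis=1)


def fit_alpha(records: list[PredictionRecord], scale: GPScale,
              grid_step: float = 0.01) -> FusionModel:
    """Sweep alpha over [0, 1] and keep the loss-minimizing weight.

    Ties (the snapped loss is piecewise constant, so minima are plateaus) go
    to the smallest alpha on the grid.
    """
    if not 0.0 < grid_step <= 1.0:
        raise InvalidInputError("grid_step must lie in (0, 1]")
    n_steps = int(round(1.0 / grid_step))
    alphas = np.linspace(0.0, 1.0, n_steps + 1)
    sse = fusion_sse(records, scale, alphas)
    best = int(np.argmin(sse))  # first minimum = smallest alpha
    return FusionModel(
        sex=scale.sex, alpha_star=float(alphas[best]), grid_step=grid_step,
        scale=scale, loss_curve=[(float(a), float(s)) for a, s in zip(alphas, sse)])


def sgp_predict(records: list[PredictionRecord], model: FusionModel) -> np.ndarray:
    """SGP ages (months, members of the GP grid) for each record."""
    fh, sa, _ = _extract(records, model.scale)
    return snap_array(model.alpha_star * sa + (1.0 - model.alpha_star) * fh,
                      model.scale)


def save_fusion_model(model: FusionModel, path: str | Path) -> None:
    payload = {
        "sex": model.sex,
        "alpha_star": model.alpha_star,
        "grid_step": model.grid_step,
        "scale_name": model.scale.name,
        "scale_classes": list(model.scale.classes),
        "loss_curve": model.loss_curve,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_fusion_model(path: str | Path) -> FusionModel:
    payload = json.loads(Path(path).read_text())
    scale = GPScale(sex=payload["sex"], classes=tuple(payload["scale_classes"]),
                    name=payload["scale_name"])
    return FusionModel(
        sex=payload["sex"], alpha_star=payload["alpha_star"],
        grid_step=payload["grid_step"], scale=scale,
        loss_curve=[(a, s) for a, s in payload["loss_curve"]])
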