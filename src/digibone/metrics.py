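"""Agreement statistics for bone age predictions.

MAD (mean absolute difference, months), RMSE, r^2 (squared Pearson
correlation, as read off correlation plots — not the regression coefficient of
determination, which differs for biased predictors), Bland-Altman analysis
with high-error flagging, quadratic-weighted Cohen's kappa over GP classes,
and exact / within-±k-class agreement percentages.

Sign convention for Bland-Altman: difference = prediction - ground truth, so a
positive bias means systematic overprediction.  Limits of agreement use
bias ± k_sd·sd with the sample (n-1) standard deviation and k_sd = 2 by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import InvalidInputError, NumericalError
from .fusion import PredictionRecord
from .gp_scale import GPScale, snap_array

__all__ = [
    "AgreementReport", "mad", "rmse", "r_squared", "bland_altman",
    "weighted_kappa", "class_agreement", "evaluate", "dice",
]


def _pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise InvalidInputError("pred and truth must be 1-D arrays of equal length")
    if p.size == 0:
        raise InvalidInputError("empty input")
    return p, t


def mad(pred, truth) -> float:
    """Mean absolute difference in months."""
    p, t = _pair(pred, truth)
    return float(np.mean(np.abs(p - t)))


def rmse(pred, truth) -> float:
    p, t = _pair(pred, truth)
    return float(np.sqrt(np.mean((p - t) ** 2)))


def r_squared(pred, truth) -> float:
    """Squared Pearson correlation coefficient."""
    p, t = _pair(pred, truth)
    if p.size < 2:
        raise InvalidInputError("need at least 2 pairs")
    p_c, t_c = p - p.mean(), t - t.mean()
    denom = np.sqrt((p_c ** 2).sum() * (t_c ** 2).sum())
    if denom == 0:
        raise NumericalError("r^2 undefined: zero variance in pred or truth")
    r = float((p_c * t_c).sum() / denom)
    return r * r


def bland_altman(pred, truth, k_sd: float = 2.0):
    """Bias, limits of agreement, and indices of high-error cases.

    Differences d_i = pred_i - truth_i; bias = mean(d); limits are
    bias ± k_sd·sd(d) (sample sd); cases with d_i strictly outside the limits
    are flagged as high-error.
    """
    p, t = _pair(pred, truth)
    if p.size < 2:
        raise InvalidInputError("Bland-Altman needs at least 2 pairs")
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - k_sd * sd, bias + k_sd * sd
    flagged = [int(i) for i in np.nonzero((d < lo) | (d > hi))[0]]
    return bias, lo, hi, flagged


def _class_indices(labels, scale: GPScale) -> np.ndarray:
    arr = np.asarray(labels, dtype=float)
    grid = np.asarray(scale.classes)
    match = np.isclose(arr[:, None], grid[None, :], rtol=0, atol=1e-6)
    if not match.any(axis=1).all():
        bad = arr[~match.any(axis=1)][0]
        raise InvalidInputError(f"label {bad} is not a class of scale {scale.name!r}")
    return match.argmax(axis=1)


def weighted_kappa(a, b, scale: GPScale, weighting: str = "quadratic") -> float:
    """Quadratic-weighted Cohen's kappa over GP grid indices.

    Weights are computed on class indices in the ordered grid (not raw
    months), so unequal class spacing does not distort the penalty:
    w_ij = 1 - ((i-j)/(K-1))^2 and kappa = 1 - sum((1-w)*O)/sum((1-w)*E)
    with observed proportions O and chance-expected E from the marginals.
    """
    if weighting != "quadratic":
        raise InvalidInputError(f"unsupported weighting {weighting!r}")
    ia = _class_indices(a, scale)
    ib = _class_indices(b, scale)
    if ia.shape != ib.shape:
        raise InvalidInputError("label lists must have equal length")
    k = len(scale.classes)
    if k < 2:
        raise NumericalError("kappa undefined for a single-class scale")
    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0)
    obs /= ia.size
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    idx = np.arange(k)
    penalty = ((idx[:, None] - idx[None, :]) / (k - 1)) ** 2  # = 1 - w
    denom = (penalty * exp).sum()
    if denom == 0:
        raise NumericalError("kappa undefined: degenerate marginals")
    return float(1.0 - (penalty * obs).sum() / denom)


def class_agreement(a, b, scale: GPScale, k: int = 0) -> float:
    """Percentage of pairs whose GP grid-index distance is <= k."""
    ia = _class_indices(a, scale)
    ib = _class_indices(b, scale)
    if ia.shape != ib.shape:
        raise InvalidInputError("label lists must have equal length")
    return float(100.0 * np.mean(np.abs(ia - ib) <= k))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError("masks must have the same shape")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


@dataclass
class AgreementReport:
    n: int
    mad: float
    rmse: float
    r2: float
    r2_snapped: float
    bias: float
    loa_low: float
    loa_high: float
    high_error_ids: list[str]
    kappa: float
    pct_exact: float
    pct_within_1: float

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["_conventions"] = ("diff = prediction - ground truth; "
                                   "limits = bias +/- 2*sd (sample sd)")
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def evaluate(records: list[PredictionRecord], pred: np.ndarray,
             scale: GPScale, k_sd: float = 2.0,
             plots_dir: str | Path | None = None,
             plot_prefix: str = "eval") -> AgreementReport:
    """Bundle all agreement statistics for one predictor against y.

    ``pred`` is the continuous prediction per record (months).  Class-level
    statistics (kappa, agreement percentages, the snapped r^2) first snap the
    predictions to the GP grid; continuous statistics (MAD, RMSE, r^2,
    Bland-Altman) use the raw values.  Both r^2 variants are reported because
    it is ambiguous which one a correlation plot of snapped classes shows.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != (len(records),):
        raise InvalidInputError("one prediction per record required")
    truth = np.array([r.y for r in records])
    snapped = snap_array(pred, scale)
    bias, lo, hi, flagged = bland_altman(pred, truth, k_sd=k_sd)
    report = AgreementReport(
        n=len(records),
        mad=mad(pred, truth),
        rmse=rmse(pred, truth),
        r2=r_squared(pred, truth),
        r2_snapped=r_squared(snapped, truth),
        bias=bias, loa_low=lo, loa_high=hi,
        high_error_ids=[records[i].id for i in flagged],
        kappa=weighted_kappa(snapped, truth, scale),
        pct_exact=class_agreement(snapped, truth, scale, k=0),
        pct_within_1=class_agreement(snapped, truth, scale, k=1),
    )
    if plots_dir is not None:
        _write_plots(pred, truth, report, Path(plots_dir), plot_prefix)
    return report


def _write_plots(pred, truth, report: AgreementReport, plots_dir: Path,
                 prefix: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(truth, pred, s=8, alpha=0.6)
    lim = [min(truth.min(), pred.min()), max(truth.max(), pred.max())]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("ground truth (months)")
    ax.set_ylabel("prediction (months)")
    ax.set_title(f"r^2 = {report.r2:.3f}")
    fig.tight_layout()
    fig.savefig(plots_dir / f"{prefix}_correlation.png", dpi=100)
    plt.close(fig)

    d = pred - truth
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter((pred + truth) / 2, d, s=8, alpha=0.6)
    for yv, style in ((report.bias, "-"), (report.loa_low, "--"), (report.loa_high, "--")):
        ax.axhline(yv, color="r", ls=style, lw=1)
    ax.set_xlabel("mean of prediction and truth (months)")
    ax.set_ylabel("prediction - truth (months)")
    ax.set_title(f"bias = {report.bias:+.2f} months")
    fig.tight_layout()
    fig.savefig(plots_dir / f"{prefix}_bland_altman.png", dpi=100)
    plt.close(fig)
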