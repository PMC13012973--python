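"""The discrete Greulich-Pyle (GP) age grid and nearest-class snapping.

The GP method assigns a radiograph the age of the closest atlas standard, so
every GP bone age is a member of a small ordered set ``G`` of ages in months.
Continuous model outputs are mapped ("snapped") onto this grid.  The grid is
sex-specific; the shipped default is an illustrative grid, not the clinical
atlas class list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, SchemaError

__all__ = ["GPScale", "snap_to_gp", "snap_array", "load_scale", "default_scale", "SEXES"]

SEXES = ("male", "female")

# Illustrative per-sex grids spanning infancy to skeletal maturity, with the
# denser spacing around puberty that atlas standards show.  Editable via the
# CSV interface of load_scale; not the published atlas values.
_DEFAULT_CLASSES = {
    "male": [
        12, 24, 36, 48, 60, 72, 84, 96, 108, 120,
        132, 138, 150, 162, 168, 180, 192, 204, 216, 228,
    ],
    "female": [
        12, 24, 36, 48, 60, 69, 82, 94, 106, 118,
        130, 138, 150, 162, 174, 186, 198, 210, 216,
    ],
}


@dataclass(frozen=True)
class GPScale:
    """Ordered grid of discrete GP ages (months) for one sex."""

    sex: str
    classes: tuple[float, ...]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        cls = tuple(float(c) for c in self.classes)
        if len(cls) == 0:
            raise ConfigError("GP scale must have at least one class")
        if any(not math.isfinite(c) for c in cls):
            raise ConfigError("GP classes must be finite")
        if any(c <= 0 or c > 300 for c in cls):
            raise ConfigError("GP classes must lie in (0, 300] months")
        if any(b <= a for a, b in zip(cls, cls[1:])):
            raise ConfigError("GP classes must be strictly increasing")
        object.__setattr__(self, "classes", cls)

    @property
    def lo(self) -> float:
        return self.classes[0]

    @property
    def hi(self) -> float:
        return self.classes[-1]

    def index_of(self, value: float) -> int:
        """Grid index of an exact class member; raises for non-members."""
        arr = np.asarray(self.classes)
        hits = np.nonzero(np.isclose(arr, value, rtol=0, atol=1e-9))[0]
        if hits.size == 0:
            raise InvalidInputError(f"{value} is not a class of scale {self.name!r}")
        return int(hits[0])


def snap_to_gp(value: float, scale: GPScale) -> float:
    """Map a continuous age (months) to the closest GP class.

    Exact midpoints between two classes snap to the LOWER class (a
    conservative, younger estimate).  Idempotent on members of the grid.
    """
    if not math.isfinite(value):
        raise InvalidInputError(f"cannot snap non-finite value {value!r}")
    return float(snap_array(np.asarray([value]), scale)[0])


def snap_array(values: np.ndarray, scale: GPScale) -> np.ndarray:
    """Vectorised :func:`snap_to_gp` with the same lower-class tie rule."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("cannot snap non-finite values")
    grid = np.asarray(scale.classes)
    # searchsorted gives the first class >= v; compare with its left neighbour.
    hi_idx = np.clip(np.searchsorted(grid, v, side="left"), 0, grid.size - 1)
    lo_idx = np.clip(hi_idx - 1, 0, grid.size - 1)
    d_hi = np.abs(grid[hi_idx] - v)
    d_lo = np.abs(grid[lo_idx] - v)
    # ties (d_lo == d_hi) go to the lower class
    take_lo = d_lo <= d_hi
    return np.where(take_lo, grid[lo_idx], grid[hi_idx])


def default_scale(sex: str) -> GPScale:
    """The shipped illustrative grid for one sex."""
    if sex not in SEXES:
        raise ConfigError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return GPScale(sex=sex, classes=tuple(_DEFAULT_CLASSES[sex]), name="digibone-default")


def load_scale(path: str | Path, sex: str) -> GPScale:
    """Load a GP grid for one sex from a CSV with columns ``sex,age_months``."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ConfigError(f"empty GP scale file {path}") from exc
    missing = {"sex", "age_months"} - set(df.columns)
    if missing:
        raise SchemaError(f"GP scale file {path} missing columns {sorted(missing)}")
    rows = df[df["sex"] == sex]
    if rows.empty:
        raise ConfigError(f"GP scale file {path} has no rows for sex {sex!r}")
    ages = [float(a) for a in rows["age_months"]]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ConfigError(f"GP grid for {sex!r} in {path} is not strictly increasing")
    return GPScale(sex=sex, classes=tuple(ages), name=path.stem)


def save_scale(scales: list[GPScale], path: str | Path) -> None:
    rows = [{"sex": s.sex, "age_months": c} for s in scales for c in s.classes]
    pd.DataFrame(rows).to_csv(path, index=False)
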