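"""Synthetic hand-phantom radiographs with ground-truth masks and labels.

Skeletal maturation is asynchronous across the hand: short bones (metacarpals
and phalanges), carpals, and the wrist (distal radius and ulna) mature at
different rates.  The phantom encodes one maturity cue per segment:

* short bones — four elongated "fingers", each interrupted by two epiphyseal
  gaps whose width narrows monotonically to fusion as shortbone age grows;
* carpals — a cluster of seven ossification-centre blobs whose total ossified
  area grows monotonically with carpal age and saturates near the top of the
  grid (carpals are fully ossified after puberty);
* wrist — two thick bars (radius, ulna) with a single epiphyseal gap that
  narrows with wrist age.

Geometry is a fixed layout table; only texture noise and a small sub-pixel
jitter of structure centres are random, so ground-truth masks are exact by
construction and everything is reproducible from the seed.  Latent ages are
continuous; labels are snapped to the discrete GP grid, mirroring how
clinician labels are discrete atlas classes while maturity itself is
continuous.

The module also provides a global intensity/contrast "domain shift" transform
(the failure mode that motivates test-time adaptation) and a generator of
synthetic prediction tables with a known generative mixing weight alpha0 for
exercising the fusion stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, DataError, InvalidInputError
from .fusion import PredictionRecord
from .gp_scale import GPScale, snap_array, snap_to_gp

__all__ = [
    "SEGMENTS", "PhantomParams", "ShiftParams", "RadiographSample", "SamplerConfig",
    "generate_phantom", "apply_domain_shift", "generate_prediction_table",
    "sample_phantoms", "make_dataset", "load_dataset", "phantom_metrics",
    "save_mask", "load_mask",
]

SEGMENTS = ("shortbones", "carpals", "wrist")

MANIFEST_COLUMNS = [
    "id", "sex", "fullhand_age", "shortbones_age", "carpals_age", "wrist_age",
    "image_path", "mask_shortbones", "mask_carpals", "mask_wrist",
]


@dataclass(frozen=True)
class PhantomParams:
    image_size: int = 128
    sex: str = "male"
    fullhand_age: float = 120.0
    segment_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ConfigError("image_size must be >= 64 to place all regions")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if len(self.segment_offsets) != 3:
            raise ConfigError("segment_offsets must have exactly 3 entries")


@dataclass(frozen=True)
class ShiftParams:
    """Global intensity transform clip(gain * image**gamma + offset, 0, 1)."""

    gain: float = 1.0
    offset: float = 0.0
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gain <= 0:
            raise InvalidInputError("gain must be > 0")
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be > 0")


@dataclass
class RadiographSample:
    image: np.ndarray                       # float in [0,1], shape (S,S)
    sex: str
    y: float                                # full-hand GP age (months), in G
    segment_ages: dict[str, float]          # GP-snapped per-segment ages
    masks: dict[str, np.ndarray] | None     # boolean masks keyed by segment
    id: str = ""


@dataclass(frozen=True)
class SamplerConfig:
    """How make_dataset / sample_phantoms draw phantom parameters.

    Latent full-hand age is uniform over the GP grid range; per-segment
    offsets are Gaussian with sd ``offset_sd`` months (the asynchrony between
    hand regions).
    """

    image_size: int = 128
    noise_sd: float = 0.02
    offset_sd: float = 9.0


# fixed layout table, in fractions of the image side --------------------------

_FINGER_X = (0.20, 0.40, 0.60, 0.80)
_FINGER_HALF_W = 0.030
_FINGER_Y = (0.06, 0.40)
_FINGER_GAP_Y = (0.17, 0.29)
_SB_GAP_HALF_MAX = 0.016

_CARPAL_CENTERS = (
    (0.50, 0.38), (0.49, 0.52), (0.52, 0.64), (0.60, 0.33),
    (0.60, 0.47), (0.62, 0.60), (0.69, 0.42),
)  # (row_frac, col_frac)
_CARPAL_R_MIN = 0.016
_CARPAL_R_GROWTH = 0.026
_CARPAL_SATURATION = 0.85   # fraction of the grid range at which area saturates

_WRIST_X = (0.38, 0.62)
_WRIST_HALF_W = 0.055
_WRIST_Y = (0.78, 0.97)
_WRIST_GAP_Y = 0.84
_WRIST_GAP_HALF_MAX = 0.020

_SEX_FACTOR = {"male": 1.0, "female": 0.96}
_BACKGROUND = 0.10
_BONE_INTENSITY = 0.82


def _maturity(age: float, scale: GPScale) -> float:
    return float(np.clip((age - scale.lo) / (scale.hi - scale.lo), 0.0, 1.0))


def _snapped_segment_ages(params: PhantomParams, scale: GPScale) -> dict[str, float]:
    out = {}
    for seg, off in zip(SEGMENTS, params.segment_offsets):
        raw = float(np.clip(params.fullhand_age + off, scale.lo, scale.hi))
        out[seg] = snap_to_gp(raw, scale)
    return out


def generate_phantom(params: PhantomParams, scale: GPScale) -> RadiographSample:
    """Render one phantom; identical params (incl. seed) give bit-identical output."""
    if params.sex != scale.sex:
        raise DataError(f"params.sex={params.sex!r} does not match scale.sex={scale.sex!r}")
    S = params.image_size
    f = _SEX_FACTOR[params.sex]
    rng = np.random.default_rng(params.seed)
    # jitter is drawn up-front in a fixed order so it depends on the seed only,
    # never on the ages: age sweeps at fixed seed stay comparable
    jit_f = rng.uniform(-0.005, 0.005, size=len(_FINGER_X))
    jit_c = rng.uniform(-0.008, 0.008, size=(len(_CARPAL_CENTERS), 2))
    jit_w = rng.uniform(-0.005, 0.005, size=len(_WRIST_X))

    seg_ages = _snapped_segment_ages(params, scale)
    t_sb = _maturity(seg_ages["shortbones"], scale)
    t_ca = _maturity(seg_ages["carpals"], scale)
    t_wr = _maturity(seg_ages["wrist"], scale)

    rows = np.arange(S)[:, None] / S
    cols = np.arange(S)[None, :] / S

    def sc(v):  # scale a position fraction around the image centre by sex factor
        return 0.5 + (v - 0.5) * f

    masks = {}
    # --- short bones -------------------------------------------------------
    sb = np.zeros((S, S), dtype=bool)
    gap_half = _SB_GAP_HALF_MAX * (1.0 - t_sb) * f
    for x0, jx in zip(_FINGER_X, jit_f):
        band = np.abs(cols - sc(x0 + jx)) <= _FINGER_HALF_W * f
        extent = (rows >= sc(_FINGER_Y[0])) & (rows <= sc(_FINGER_Y[1]))
        bone = band & extent
        for gy in _FINGER_GAP_Y:
            bone &= ~(np.abs(rows - sc(gy)) < gap_half)
        sb |= bone
    masks["shortbones"] = sb
    # --- carpals -----------------------------------------------------------
    ca = np.zeros((S, S), dtype=bool)
    r = (_CARPAL_R_MIN + _CARPAL_R_GROWTH * min(t_ca / _CARPAL_SATURATION, 1.0)) * f
    for (ry, cx), (jy, jx) in zip(_CARPAL_CENTERS, jit_c):
        ca |= (rows - sc(ry + jy)) ** 2 + (cols - sc(cx + jx)) ** 2 <= r * r
    masks["carpals"] = ca
    # --- wrist -------------------------------------------------------------
    wr = np.zeros((S, S), dtype=bool)
    wgap_half = _WRIST_GAP_HALF_MAX * (1.0 - t_wr) * f
    for x0, jx in zip(_WRIST_X, jit_w):
        band = np.abs(cols - sc(x0 + jx)) <= _WRIST_HALF_W * f
        extent = (rows >= sc(_WRIST_Y[0])) & (rows <= sc(_WRIST_Y[1]))
        bone = band & extent & ~(np.abs(rows - sc(_WRIST_GAP_Y)) < wgap_half)
        wr |= bone
    masks["wrist"] = wr

    image = np.full((S, S), _BACKGROUND)
    for seg in SEGMENTS:
        image[masks[seg]] = _BONE_INTENSITY
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=(S, S))
    image = np.clip(image, 0.0, 1.0)

    return RadiographSample(
        image=image, sex=params.sex, y=snap_to_gp(
            float(np.clip(params.fullhand_age, scale.lo, scale.hi)), scale),
        segment_ages=seg_ages, masks=masks, id=f"phantom-{params.seed}",
    )


def apply_domain_shift(image: np.ndarray, shift: ShiftParams) -> np.ndarray:
    """Global intensity/contrast change emulating a scanner/protocol shift."""
    img = np.asarray(image, dtype=float)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise InvalidInputError("image values must lie in [0, 1]")
    return np.clip(shift.gain * np.power(img, shift.gamma) + shift.offset, 0.0, 1.0)


def phantom_metrics(sample: RadiographSample) -> dict[str, float]:
    """Maturity cues measured from the ground-truth masks.

    Returns the carpal ossified area (pixels), and the shortbone / wrist
    epiphyseal gap widths (total mask-free rows inside the bone extents).
    """
    if sample.masks is None:
        raise DataError("sample has no masks")
    S = sample.image.shape[0]
    f = _SEX_FACTOR[sample.sex]

    def rows_without_bone(mask, y_lo, y_hi):
        r0 = int(math.ceil((0.5 + (y_lo - 0.5) * f) * S))
        r1 = int(math.floor((0.5 + (y_hi - 0.5) * f) * S))
        rows_any = mask[r0:r1 + 1].any(axis=1)
        return float(np.count_nonzero(~rows_any))

    return {
        "carpal_area": float(sample.masks["carpals"].sum()),
        "shortbone_gap_rows": rows_without_bone(sample.masks["shortbones"], *_FINGER_Y),
        "wrist_gap_rows": rows_without_bone(sample.masks["wrist"], *_WRIST_Y),
    }


# ---------------------------------------------------------------------------
# prediction tables with a known generative alpha
# ---------------------------------------------------------------------------

def generate_prediction_table(
    n: int,
    alpha0: float,
    noise_sd_fh: float,
    noise_sd_seg: float,
    scale: GPScale,
    seed: int,
    disagreement_sd: float | None = None,
) -> list[PredictionRecord]:
    """Synthetic per-image prediction records whose optimal mixing weight is alpha0.

    Latent true ages are uniform over the grid range and snapped to give the
    ground truth y.  The combined estimate is generated first,
    ``combo = latent + eps`` with eps ~ N(0, noise_sd_fh), and then split into
    a disagreeing pair ``fh = combo - alpha0*delta`` and
    ``Seg_Avg = combo + (1-alpha0)*delta`` with delta ~ N(0, disagreement_sd),
    so ``alpha*Seg_Avg + (1-alpha)*fh = combo + (alpha-alpha0)*delta`` and the
    expected snapped L2 loss is minimized exactly at alpha0.  The three
    segment predictions scatter around Seg_Avg with mean-centred noise of sd
    ``noise_sd_seg``, leaving the average untouched.  ``disagreement_sd``
    defaults to twice the larger noise sd, so the noiseless case degenerates
    to fh = Seg_Avg = latent.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0.0 <= alpha0 <= 1.0:
        raise InvalidInputError("alpha0 must lie in [0, 1]")
    if noise_sd_fh < 0 or noise_sd_seg < 0:
        raise InvalidInputError("noise sds must be >= 0")
    if disagreement_sd is None:
        disagreement_sd = 2.0 * max(noise_sd_fh, noise_sd_seg)
    if disagreement_sd < 0:
        raise InvalidInputError("disagreement_sd must be >= 0")

    rng = np.random.default_rng(seed)
    latent = rng.uniform(scale.lo, scale.hi, size=n)
    delta = rng.normal(0.0, disagreement_sd, size=n)
    combo = latent + rng.normal(0.0, noise_sd_fh, size=n)
    fh = combo - alpha0 * delta
    seg_avg = combo + (1.0 - alpha0) * delta
    nu = rng.normal(0.0, noise_sd_seg, size=(n, 3))
    segs = seg_avg[:, None] + (nu - nu.mean(axis=1, keepdims=True))
    y = snap_array(latent, scale)
    return [
        PredictionRecord(
            id=f"rec-{seed}-{i}", sex=scale.sex, fh=float(fh[i]),
            seg_shortbones=float(segs[i, 0]), seg_carpals=float(segs[i, 1]),
            seg_wrist=float(segs[i, 2]), y=float(y[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def sample_phantoms(n: int, sampler: SamplerConfig, scale: GPScale,
                    seed: int) -> list[RadiographSample]:
    """Draw n phantoms with sampled ages and asynchronous segment offsets."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        age = float(rng.uniform(scale.lo, scale.hi))
        offsets = tuple(float(o) for o in rng.normal(0.0, sampler.offset_sd, size=3))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample = generate_phantom(
            PhantomParams(image_size=sampler.image_size, sex=scale.sex,
                          fullhand_age=age, segment_offsets=offsets,
                          noise_sd=sampler.noise_sd, seed=sub_seed),
            scale)
        sample.id = f"{scale.sex}-{seed}-{i:04d}"
        out.append(sample)
    return out


def save_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def load_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def _save_image(image: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(image * 255).astype(np.uint8), mode="L").save(path)


def _load_image(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def make_dataset(n: int, sampler: SamplerConfig, scale: GPScale,
                 out_dir: str | Path, seed: int) -> pd.DataFrame:
    """Write n phantoms (image + three masks as PNG) and a CSV manifest."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc
    samples = sample_phantoms(n, sampler, scale, seed)
    rows = []
    for s in samples:
        img_path = f"{s.id}.png"
        _save_image(s.image, out_dir / img_path)
        mask_paths = {}
        for seg in SEGMENTS:
            mp = f"{s.id}_{seg}.png"
            save_mask(s.masks[seg], out_dir / mp)
            mask_paths[seg] = mp
        rows.append({
            "id": s.id, "sex": s.sex, "fullhand_age": s.y,
            "shortbones_age": s.segment_ages["shortbones"],
            "carpals_age": s.segment_ages["carpals"],
            "wrist_age": s.segment_ages["wrist"],
            "image_path": img_path,
            "mask_shortbones": mask_paths["shortbones"],
            "mask_carpals": mask_paths["carpals"],
            "mask_wrist": mask_paths["wrist"],
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[RadiographSample]:
    """Read a make_dataset manifest back into RadiographSample objects."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"manifest missing columns {sorted(missing)}")
    base = manifest_path.parent
    out = []
    for _, row in df.iterrows():
        masks = {seg: load_mask(base / row[f"mask_{seg}"]) for seg in SEGMENTS}
        out.append(RadiographSample(
            image=_load_image(base / row["image_path"]), sex=row["sex"],
            y=float(row["fullhand_age"]),
            segment_ages={seg: float(row[f"{seg}_age"]) for seg in SEGMENTS},
            masks=masks, id=str(row["id"])))
    return out
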