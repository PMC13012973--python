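"""Table and configuration plumbing.

Prediction tables are CSV with columns
``id,sex,fh,seg_shortbones,seg_carpals,seg_wrist,seg_avg,y`` (``seg_avg`` is
optional on read and recomputed/checked); unknown columns round-trip
untouched.  Floats are written at 6-decimal precision.

The pipeline configuration is a single YAML file; every effective value is
echoed into the run manifest together with a content hash, so a run is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, SchemaError
from .fusion import PredictionRecord

__all__ = [
    "read_prediction_table", "write_prediction_table", "records_to_frame",
    "PipelineConfig", "load_pipeline_config", "config_hash", "substream",
    "dicom_to_png",
]

_REQUIRED = ["id", "sex", "fh", "seg_shortbones", "seg_carpals", "seg_wrist", "y"]
_CANONICAL = _REQUIRED[:6] + ["seg_avg", "y"]


def read_prediction_table(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"prediction table {path} missing column {col!r}")
    extras = [c for c in df.columns if c not in _CANONICAL]
    records = []
    for _, row in df.iterrows():
        seg_avg = float(row["seg_avg"]) if "seg_avg" in df.columns else None
        try:
            rec = PredictionRecord(
                id=str(row["id"]), sex=str(row["sex"]), fh=float(row["fh"]),
                seg_shortbones=float(row["seg_shortbones"]),
                seg_carpals=float(row["seg_carpals"]),
                seg_wrist=float(row["seg_wrist"]), y=float(row["y"]),
                seg_avg=seg_avg, extra={c: row[c] for c in extras})
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from exc
        records.append(rec)
    return records


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "sex": r.sex, "fh": r.fh,
               "seg_shortbones": r.seg_shortbones, "seg_carpals": r.seg_carpals,
               "seg_wrist": r.seg_wrist, "seg_avg": r.seg_avg, "y": r.y}
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_prediction_table(records: list[PredictionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end run; defaults are a small CPU-scale study."""

    seed: int = 0
    sexes: tuple[str, ...] = ("male", "female")
    scale_file: str | None = None          # None -> shipped default grids
    # phantom cohorts (per sex)
    n_per_sex: int = 40
    train_fraction: float = 0.6
    image_size: int = 96
    noise_sd: float = 0.02
    offset_sd: float = 9.0
    # target-domain shift (the "new scanner" the transfer stage adapts to)
    shift_gain: float = 0.55
    shift_offset: float = 0.35
    shift_gamma: float = 1.15
    # segmenter
    seg_epochs: int = 10
    seg_input_size: int = 64
    seg_lr: float = 3e-3
    # mask refinement: tuned for the phantom anatomy at segmenter resolution
    # (fingers are ~2-4 px wide, so no opening; segments are multi-component:
    # finger pieces, 7 carpal centres, radius+ulna halves)
    refine_min_area: int | None = 3
    refine_mean_intensity_min: float = 0.15
    refine_open_radius: int = 0
    refine_close_radius: int = 1
    refine_keep_top_k: int = 12
    # regressors
    reg_epochs: int = 25
    reg_lr: float = 3e-3
    crop_size: int = 64
    # fusion
    fusion_grid_step: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.n_per_sex < 4:
            raise ConfigError("n_per_sex must be >= 4")
        for sex in self.sexes:
            if sex not in ("male", "female"):
                raise ConfigError(f"unknown sex {sex!r}")
        if self.scale_file is not None and not Path(self.scale_file).exists():
            raise ConfigError(f"scale_file {self.scale_file} does not exist")

    @property
    def n_train(self) -> int:
        return int(round(self.n_per_sex * self.train_fraction))

    @property
    def n_val(self) -> int:
        return self.n_per_sex - self.n_train


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"config {path} has unknown keys {sorted(unknown)}")
    if "sexes" in raw:
        raw["sexes"] = tuple(raw["sexes"])
    return PipelineConfig(**raw)


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def substream(root_seed: int, *tags: str) -> int:
    """Named deterministic sub-seed (< 2^31) derived from the root seed."""
    h = zlib.crc32("/".join(tags).encode())
    return int(np.random.SeedSequence(entropy=root_seed, spawn_key=(h,))
               .generate_state(1)[0] % (2**31 - 1))


def dicom_to_png(dicom_path: str | Path, png_path: str | Path) -> None:
    """Convenience import: window a DICOM to 8-bit grayscale PNG.

    The pipeline proper speaks PNG + CSV only; this is the only DICOM
    touch-point and requires the optional pydicom dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ConfigError("DICOM import requires the optional pydicom dependency") from exc
    from PIL import Image

    ds = pydicom.dcmread(str(dicom_path))
    arr = ds.pixel_array.astype(float)
    lo, hi = np.percentile(arr, [1, 99])
    if hi <= lo:
        lo, hi = float(arr.min()), float(max(arr.max(), arr.min() + 1))
    arr = np.clip((arr - lo) / (hi - lo), 0, 1)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(png_path)
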