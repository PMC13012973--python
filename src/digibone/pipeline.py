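"""End-to-end orchestration: simulate -> segment -> train -> transfer -> fuse -> evaluate.

The run emulates the full study design at desk scale:

1. generate a *source* phantom cohort (clean images) and a *target* cohort
   (independent phantoms passed through a global intensity/contrast shift);
2. train the segmenter on source phantoms with ground-truth masks;
3. train base full-hand and per-segment regressors on the source cohort
   (segment models on ground-truth-mask crops);
4. transfer to the target cohort by re-fitting only each model's head on
   target training images, with segment crops obtained from the segmenter run
   with test-time adaptation and classical mask refinement;
5. build a prediction table on the target validation split, fit the per-sex
   SGP weight alpha*, and produce SGP predictions;
6. write agreement reports for the full-hand model, each segment model, and
   the SGP fusion, plus a run manifest sufficient to re-create the run.

All randomness flows from one root seed through named substreams, so the run
is byte-reproducible in single-threaded mode.  Timing appears only in the
log, never in reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .errors import DigiboneError, EmptySegmentError
from .fusion import PredictionRecord, fit_alpha, save_fusion_model, sgp_predict
from .gp_scale import default_scale, load_scale
from .io import PipelineConfig, config_hash, substream, write_prediction_table
from .metrics import evaluate
from .regression import (LabeledImage, RegressorState, TrainConfig,
                         fine_tune_head, predict_age, save_regressor, train_base)
from .segmentation import (MaskSet, RefineConfig, SegTrainConfig, SegmenterModel,
                           crop_segments, predict_masks, refine_masks,
                           resize_image, save_segmenter, train_segmenter)
from .synthdata import (SEGMENTS, RadiographSample, SamplerConfig, ShiftParams,
                        apply_domain_shift, sample_phantoms)

__all__ = ["run_pipeline"]

log = logging.getLogger("digibone.pipeline")


def _stage(name: str, seed: int | None = None):
    t0 = time.perf_counter()

    def done():
        log.info("stage=%s seed=%s elapsed=%.1fs", name, seed, time.perf_counter() - t0)

    return done


def _crop_with_fallback(image: np.ndarray, raw: MaskSet, refined: MaskSet,
                        crop_size: int, warnings: list[str], tag: str):
    """Crop from refined masks; fall back per segment to the raw mask, then to
    the whole image, recording a warning."""
    crops = {}
    for seg in SEGMENTS:
        for masks, level in ((refined, None), (raw, "raw"), (None, "full")):
            use = (masks.as_dict()[seg] if masks is not None
                   else np.ones_like(image, dtype=bool))
            if not use.any():
                continue
            one = MaskSet.from_dict({s: (use if s == seg else np.ones_like(use))
                                     for s in SEGMENTS})
            try:
                crops[seg] = crop_segments(image, one, out_size=crop_size)[seg]
            except EmptySegmentError:
                continue
            if level is not None:
                warnings.append(f"{tag}: segment {seg} fell back to {level} mask")
            break
        else:  # pragma: no cover - full-image mask always succeeds
            raise EmptySegmentError(f"{tag}: segment {seg} unrecoverable")
    return crops


def _segment_crops(segmenter: SegmenterModel, sample: RadiographSample,
                   refine_cfg: RefineConfig, crop_size: int, tta: bool,
                   warnings: list[str]) -> dict[str, np.ndarray]:
    img = resize_image(sample.image, segmenter.input_size)
    raw = predict_masks(segmenter, img, tta=tta)
    refined = refine_masks(raw, img, refine_cfg)
    return _crop_with_fallback(img, raw, refined, crop_size, warnings, sample.id)


def _gt_crops(sample: RadiographSample, crop_size: int) -> dict[str, np.ndarray]:
    return crop_segments(sample.image, MaskSet.from_dict(sample.masks),
                         out_size=crop_size)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full scaled-down study; returns (and writes) the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "models": {}, "fusion": {}, "reports": {}, "tables": {},
        "warnings": [],
    }
    warnings = manifest["warnings"]
    current_stage = "setup"
    try:
        scales = {sex: (load_scale(cfg.scale_file, sex) if cfg.scale_file
                        else default_scale(sex)) for sex in cfg.sexes}
        sampler = SamplerConfig(image_size=cfg.image_size, noise_sd=cfg.noise_sd,
                                offset_sd=cfg.offset_sd)
        shift = ShiftParams(gain=cfg.shift_gain, offset=cfg.shift_offset,
                            gamma=cfg.shift_gamma)
        refine_cfg = RefineConfig(
            min_area=cfg.refine_min_area,
            mean_intensity_min=cfg.refine_mean_intensity_min,
            morph_open_radius=cfg.refine_open_radius,
            morph_close_radius=cfg.refine_close_radius,
            keep_top_k=cfg.refine_keep_top_k)

        # ------------------------------------------------------ cohorts
        current_stage = "simulate"
        done = _stage(current_stage, cfg.seed)
        cohorts = {}
        for sex in cfg.sexes:
            src = sample_phantoms(cfg.n_per_sex, sampler, scales[sex],
                                  substream(cfg.seed, "source", sex))
            tgt = sample_phantoms(cfg.n_per_sex, sampler, scales[sex],
                                  substream(cfg.seed, "target", sex))
            for s in tgt:
                s.image = apply_domain_shift(s.image, shift)
                s.id = f"{s.id}-shifted"
            k = cfg.n_train
            cohorts[sex] = {"src_train": src[:k], "src_val": src[k:],
                            "tgt_train": tgt[:k], "tgt_val": tgt[k:]}
        done()

        # ------------------------------------------------------ segmenter
        current_stage = "train_segmenter"
        done = _stage(current_stage)
        seg_train = [s for sex in cfg.sexes for s in cohorts[sex]["src_train"]]
        segmenter = train_segmenter(seg_train, SegTrainConfig(
            epochs=cfg.seg_epochs, input_size=cfg.seg_input_size, lr=cfg.seg_lr,
            seed=substream(cfg.seed, "segmenter")))
        seg_path = out_dir / "segmenter"
        save_segmenter(segmenter, seg_path)
        manifest["models"]["segmenter"] = str(seg_path.with_suffix(".npz"))
        done()

        for sex in cfg.sexes:
            scale = scales[sex]
            parts = cohorts[sex]
            manifest["models"][sex] = {}
            manifest["reports"][sex] = {}

            # -------------------------------------------------- base models
            current_stage = f"train_base[{sex}]"
            done = _stage(current_stage)
            reg_cfg = lambda tag: TrainConfig(  # noqa: E731
                epochs=cfg.reg_epochs, lr=cfg.reg_lr, input_size=cfg.crop_size,
                seed=substream(cfg.seed, "reg", sex, tag))
            base: dict[str, RegressorState] = {}
            base["fullhand"] = train_base(
                [LabeledImage(s.image, s.y, sex) for s in parts["src_train"]],
                reg_cfg("fullhand"), segment="fullhand")
            src_crops = [_gt_crops(s, cfg.crop_size) for s in parts["src_train"]]
            for seg in SEGMENTS:
                base[seg] = train_base(
                    [LabeledImage(c[seg], s.segment_ages[seg], sex)
                     for c, s in zip(src_crops, parts["src_train"])],
                    reg_cfg(seg), segment=seg)
            done()

            # -------------------------------------------------- transfer
            current_stage = f"fine_tune[{sex}]"
            done = _stage(current_stage)
            tgt_crops = [_segment_crops(segmenter, s, refine_cfg, cfg.crop_size,
                                        tta=True, warnings=warnings)
                         for s in parts["tgt_train"]]
            tuned: dict[str, RegressorState] = {}
            tuned["fullhand"] = fine_tune_head(
                base["fullhand"],
                [LabeledImage(s.image, s.y, sex) for s in parts["tgt_train"]])
            for seg in SEGMENTS:
                tuned[seg] = fine_tune_head(
                    base[seg],
                    [LabeledImage(c[seg], s.segment_ages[seg], sex)
                     for c, s in zip(tgt_crops, parts["tgt_train"])])
            for tag, model in tuned.items():
                mp = out_dir / f"regressor_{sex}_{tag}"
                save_regressor(model, mp)
                manifest["models"][sex][tag] = str(mp.with_suffix(".npz"))
            done()

            # -------------------------------------------------- predictions
            current_stage = f"predict[{sex}]"
            done = _stage(current_stage)
            records = []
            for s in parts["tgt_val"]:
                crops = _segment_crops(segmenter, s, refine_cfg, cfg.crop_size,
                                       tta=True, warnings=warnings)
                fh = predict_age(tuned["fullhand"],
                                 resize_image(s.image, cfg.crop_size))
                segs = {seg: predict_age(tuned[seg], crops[seg]) for seg in SEGMENTS}
                records.append(PredictionRecord(
                    id=s.id, sex=sex, fh=fh,
                    seg_shortbones=segs["shortbones"],
                    seg_carpals=segs["carpals"], seg_wrist=segs["wrist"],
                    y=s.y))
            table_path = out_dir / f"predictions_{sex}.csv"
            write_prediction_table(records, table_path)
            manifest["tables"][sex] = str(table_path)
            done()

            # -------------------------------------------------- fusion + reports
            current_stage = f"fuse[{sex}]"
            done = _stage(current_stage)
            fusion = fit_alpha(records, scale, grid_step=cfg.fusion_grid_step)
            fpath = out_dir / f"fusion_{sex}.json"
            save_fusion_model(fusion, fpath)
            manifest["fusion"][sex] = {"path": str(fpath),
                                       "alpha_star": fusion.alpha_star}
            sgp = sgp_predict(records, fusion)
            predictors = {
                "fullhand": np.array([r.fh for r in records]),
                "shortbones": np.array([r.seg_shortbones for r in records]),
                "carpals": np.array([r.seg_carpals for r in records]),
                "wrist": np.array([r.seg_wrist for r in records]),
                "sgp": sgp,
            }
            for tag, pred in predictors.items():
                report = evaluate(records, pred, scale)
                rpath = out_dir / f"report_{sex}_{tag}.json"
                report.to_json(rpath)
                manifest["reports"][sex][tag] = {
                    "path": str(rpath), "mad": report.mad, "r2": report.r2,
                    "bias": report.bias, "kappa": report.kappa}
            done()
    except DigiboneError:
        manifest["failed_stage"] = current_stage
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
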