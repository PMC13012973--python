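"""Hand-region segmentation with optional test-time normalization adaptation.

A small encoder-decoder network predicts three mask channels (shortbones,
carpals, wrist) from a grayscale hand image.  At inference the batch-norm
layers either use their stored training statistics (``tta=False``) or
recompute statistics from the current input alone (``tta=True``); the latter
makes thresholded masks invariant to positive affine intensity transforms of
the input and is the defence against global intensity/contrast domain shift.
No parameters or buffers are ever updated at inference time.

Raw network masks are refined classically: morphological opening/closing,
connected-component analysis with area and mean-intensity thresholds, keeping
the largest component(s), and resolving overlaps between segments in favour of
the larger component.  Refined masks drive tight, letterboxed segment crops
with everything outside the mask zeroed, which are the inputs of the
per-segment age regressors.

Coordinates are row-major, 0-based; bounding boxes are half-open
[r0, r1) x [c0, c1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as _closing, disk, opening as _opening
from skimage.transform import resize

from . import nn
from .errors import DataError, EmptySegmentError, InvalidInputError
from .metrics import dice
from .synthdata import SEGMENTS, RadiographSample

__all__ = [
    "MaskSet", "RefineConfig", "SegTrainConfig", "SegmenterModel",
    "train_segmenter", "predict_masks", "refine_masks", "crop_segments",
    "resize_image", "resize_mask", "evaluate_segmenter",
    "save_segmenter", "load_segmenter",
]


@dataclass
class MaskSet:
    shortbones: np.ndarray
    carpals: np.ndarray
    wrist: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in self.as_dict().values()}
        if len(shapes) != 1:
            raise InvalidInputError("masks must share one shape")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"shortbones": self.shortbones, "carpals": self.carpals,
                "wrist": self.wrist}

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray]) -> "MaskSet":
        return cls(**{k: np.asarray(d[k], dtype=bool) for k in SEGMENTS})


@dataclass(frozen=True)
class RefineConfig:
    """Thresholds of the classical mask-refinement stage.

    ``min_area=None`` resolves to 0.1% of the image area at refinement time.
    """

    min_area: int | None = None
    mean_intensity_min: float = 0.15
    morph_open_radius: int = 2
    morph_close_radius: int = 2
    keep_top_k: int = 1

    def __post_init__(self):
        if self.keep_top_k < 1:
            raise InvalidInputError("keep_top_k must be >= 1")
        if (self.min_area is not None and self.min_area < 0) or \
                self.morph_open_radius < 0 or self.morph_close_radius < 0 or \
                not 0.0 <= self.mean_intensity_min <= 1.0:
            raise InvalidInputError("invalid RefineConfig values")


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 8
    batch_size: int = 8
    lr: float = 3e-3
    input_size: int = 64
    base_channels: int = 8
    seed: int = 0
    threshold: float = 0.5


class TinyUNet(nn.Layer):
    """Two-level U-Net; first layer is Conv->BN so per-input normalization
    cancels affine intensity transforms of the input exactly."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.c = c

        def block(cin, cout):
            return nn.Sequential(
                nn.Conv2d(cin, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU(),
                nn.Conv2d(cout, cout, 3, rng), nn.BatchNorm2d(cout), nn.ReLU())

        self.enc1 = block(1, c)
        self.pool1 = nn.MaxPool2()
        self.enc2 = block(c, 2 * c)
        self.pool2 = nn.MaxPool2()
        self.bott = block(2 * c, 4 * c)
        self.up2 = nn.Upsample2()
        self.dec2 = block(4 * c + 2 * c, 2 * c)
        self.up1 = nn.Upsample2()
        self.dec1 = block(2 * c + c, c)
        self.head = nn.Conv2d(c, 3, 1, rng)

    def _children(self):
        return [self.enc1, self.pool1, self.enc2, self.pool2, self.bott,
                self.up2, self.dec2, self.up1, self.dec1, self.head]

    def parameters(self):
        return [p for ch in self._children() for p in ch.parameters()]

    def gradients(self):
        return [g for ch in self._children() for g in ch.gradients()]

    def buffers(self):
        out = {}
        names = ["enc1", "pool1", "enc2", "pool2", "bott", "up2", "dec2",
                 "up1", "dec1", "head"]
        for name, ch in zip(names, self._children()):
            for k, v in ch.buffers().items():
                out[f"{name}.{k}"] = v
        return out

    def forward(self, x, mode):
        e1 = self.enc1.forward(x, mode)
        e2 = self.enc2.forward(self.pool1.forward(e1, mode), mode)
        b = self.bott.forward(self.pool2.forward(e2, mode), mode)
        u2 = np.concatenate([self.up2.forward(b, mode), e2], axis=1)
        d2 = self.dec2.forward(u2, mode)
        u1 = np.concatenate([self.up1.forward(d2, mode), e1], axis=1)
        d1 = self.dec1.forward(u1, mode)
        return self.head.forward(d1, mode)

    def backward(self, dy):
        c = self.c
        d_d1 = self.head.backward(dy)
        d_u1 = self.dec1.backward(d_d1)
        d_d2 = self.up1.backward(d_u1[:, :2 * c])
        d_e1_skip = d_u1[:, 2 * c:]
        d_u2 = self.dec2.backward(d_d2)
        d_b = self.up2.backward(d_u2[:, :4 * c])
        d_e2_skip = d_u2[:, 4 * c:]
        d_p2 = self.bott.backward(d_b)
        d_e2 = self.pool2.backward(d_p2) + d_e2_skip
        d_p1 = self.enc2.backward(d_e2)
        d_e1 = self.pool1.backward(d_p1) + d_e1_skip
        return self.enc1.backward(d_e1)


@dataclass
class SegmenterModel:
    net: TinyUNet
    input_size: int
    threshold: float
    config: SegTrainConfig
    loss_trajectory: list[float] = field(default_factory=list)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.shape == (size, size):
        return img
    return resize(img, (size, size), order=1, anti_aliasing=True,
                  preserve_range=True)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.shape == (size, size):
        return m
    return resize(m.astype(float), (size, size), order=0,
                  anti_aliasing=False, preserve_range=True) > 0.5


def train_segmenter(samples: list[RadiographSample],
                    cfg: SegTrainConfig = SegTrainConfig()) -> SegmenterModel:
    """Train the mask predictor on phantoms with ground-truth masks."""
    if len(samples) == 0:
        raise DataError("empty training set")
    for s in samples:
        if s.masks is None or set(s.masks) != set(SEGMENTS):
            raise DataError(f"sample {s.id!r} is missing ground-truth masks")
    rng = np.random.default_rng(cfg.seed)
    net = TinyUNet(cfg.base_channels, rng)
    size = cfg.input_size
    x = np.stack([resize_image(s.image, size) for s in samples])[:, None].astype(nn.F32)
    t = np.stack([
        np.stack([resize_mask(s.masks[seg], size) for seg in SEGMENTS])
        for s in samples]).astype(nn.F32)
    opt = nn.Adam(net.parameters(), net.gradients(), lr=cfg.lr)
    n = len(samples)
    # per-channel positive weighting against foreground sparsity (thin bones)
    # sqrt keeps the push gentle enough not to trade away precision
    pos_frac = t.mean(axis=(0, 2, 3)).clip(1e-4, None)
    pos_weight = np.sqrt((1.0 - pos_frac) / pos_frac)[None, :, None, None]
    traj: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward(x[idx], "train")
            loss, dlogits = nn.bce_with_logits(logits, t[idx], pos_weight)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        traj.append(epoch_loss / n)
    return SegmenterModel(net=net, input_size=size, threshold=cfg.threshold,
                          config=cfg, loss_trajectory=traj)


def predict_masks(model: SegmenterModel, image: np.ndarray,
                  tta: bool = False) -> MaskSet:
    """Raw thresholded masks; ``tta`` selects per-input normalization statistics.

    Neither mode updates any parameter or running-statistics buffer.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != (model.input_size, model.input_size):
        raise InvalidInputError(
            f"image shape {img.shape} does not match model input size "
            f"{model.input_size}; resize first (resize_image)")
    mode = "adapt" if tta else "eval"
    logits = model.net.forward(img[None, None].astype(nn.F32), mode)[0]
    probs = 1.0 / (1.0 + np.exp(-logits.astype(float)))
    masks = probs > model.threshold
    return MaskSet(shortbones=masks[0], carpals=masks[1], wrist=masks[2])


def refine_masks(raw: MaskSet, image: np.ndarray,
                 cfg: RefineConfig = RefineConfig()) -> MaskSet:
    """Classical cleanup of raw network masks.

    Per mask: opening then closing, connected components, drop components with
    area < min_area or mean underlying intensity < mean_intensity_min, keep
    the keep_top_k largest survivors.  Pixels claimed by several segments go
    to the segment whose covering component has the larger area.  A fully
    filtered-out mask comes back empty (the caller decides how to react).
    """
    img = np.asarray(image, dtype=float)
    min_area = cfg.min_area if cfg.min_area is not None else \
        max(1, int(round(0.001 * img.size)))
    kept: dict[str, np.ndarray] = {}
    comp_area: dict[str, np.ndarray] = {}
    for seg, mask in raw.as_dict().items():
        m = np.asarray(mask, dtype=bool)
        if m.shape != img.shape:
            raise InvalidInputError("mask and image shapes differ")
        if cfg.morph_open_radius > 0:
            m = _opening(m, disk(cfg.morph_open_radius))
        if cfg.morph_close_radius > 0:
            m = _closing(m, disk(cfg.morph_close_radius))
        labels = cc_label(m, connectivity=2)
        survivors = []
        for prop in regionprops(labels, intensity_image=img):
            if prop.area < min_area:
                continue
            if prop.intensity_mean < cfg.mean_intensity_min:
                continue
            survivors.append(prop)
        survivors.sort(key=lambda p: (-p.area, p.label))
        survivors = survivors[:cfg.keep_top_k]
        out = np.zeros_like(m)
        areas = np.zeros(img.shape, dtype=np.int64)
        for prop in survivors:
            sel = labels == prop.label
            out |= sel
            areas[sel] = prop.area
        kept[seg] = out
        comp_area[seg] = areas
    # resolve overlaps: the larger component wins; earlier segment on ties
    stack_area = np.stack([comp_area[seg] for seg in SEGMENTS])
    stack_mask = np.stack([kept[seg] for seg in SEGMENTS])
    winner = np.argmax(np.where(stack_mask, stack_area, -1), axis=0)
    multi = stack_mask.sum(axis=0) > 1
    for i, seg in enumerate(SEGMENTS):
        kept[seg] = kept[seg] & ~(multi & (winner != i))
    return MaskSet.from_dict(kept)


def crop_segments(image: np.ndarray, masks: MaskSet, out_size: int = 64,
                  pad_fraction: float = 0.05) -> dict[str, np.ndarray]:
    """Tight masked crops of each segment, letterboxed to out_size x out_size.

    Pixels outside the segment mask are exactly 0 in the crop.
    """
    img = np.asarray(image, dtype=float)
    out = {}
    for seg, mask in masks.as_dict().items():
        m = np.asarray(mask, dtype=bool)
        if not m.any():
            raise EmptySegmentError(f"segment {seg!r} has an empty mask")
        rows = np.nonzero(m.any(axis=1))[0]
        cols = np.nonzero(m.any(axis=0))[0]
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        pr = int(round((r1 - r0) * pad_fraction))
        pc = int(round((c1 - c0) * pad_fraction))
        r0, r1 = max(0, r0 - pr), min(img.shape[0], r1 + pr)
        c0, c1 = max(0, c0 - pc), min(img.shape[1], c1 + pc)
        crop = (img * m)[r0:r1, c0:c1]
        h, w = crop.shape
        s = out_size / max(h, w)
        nh, nw = max(1, int(round(h * s))), max(1, int(round(w * s)))
        small = resize(crop, (nh, nw), order=1, anti_aliasing=True,
                       preserve_range=True)
        canvas = np.zeros((out_size, out_size))
        ro, co = (out_size - nh) // 2, (out_size - nw) // 2
        canvas[ro:ro + nh, co:co + nw] = small
        out[seg] = canvas
    return out


def evaluate_segmenter(model: SegmenterModel, samples: list[RadiographSample],
                       tta: bool = False,
                       refine: RefineConfig | None = None) -> dict[str, float]:
    """Mean per-segment Dice against ground-truth masks (at model resolution)."""
    scores = {seg: [] for seg in SEGMENTS}
    for s in samples:
        if s.masks is None:
            raise DataError(f"sample {s.id!r} has no ground-truth masks")
        img = resize_image(s.image, model.input_size)
        pred = predict_masks(model, img, tta=tta)
        if refine is not None:
            pred = refine_masks(pred, img, refine)
        for seg in SEGMENTS:
            truth = resize_mask(s.masks[seg], model.input_size)
            scores[seg].append(dice(pred.as_dict()[seg], truth))
    out = {seg: float(np.mean(v)) for seg, v in scores.items()}
    out["mean"] = float(np.mean(list(out.values())))
    return out


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_segmenter(model: SegmenterModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **nn.state_dict(model.net))
    sidecar = {
        "architecture": "tiny_unet",
        "input_size": model.input_size,
        "threshold": model.threshold,
        "config": asdict(model.config),
        "loss_trajectory": model.loss_trajectory,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_segmenter(path: str | Path) -> SegmenterModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = SegTrainConfig(**sidecar["config"])
    net = TinyUNet(cfg.base_channels, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as state:
        nn.load_state_dict(net, dict(state))
    return SegmenterModel(net=net, input_size=sidecar["input_size"],
                          threshold=sidecar["threshold"], config=cfg,
                          loss_trajectory=list(sidecar["loss_trajectory"]))
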