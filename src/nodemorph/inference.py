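"""Whole-section inference: overlapping-tile prediction and stitching.

A trained model is applied over a section's bounding box in overlapping
tiles; per-pixel probabilities from overlapping tiles are averaged
(arithmetic mean, seam-free by construction), the stitched raster is
clipped to the section contour and thresholded into a binary mask.
Edge tiles extending past the section are reflect-padded and the
padded area is discarded before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

from .slides import LNSection, SlideImage
from .training import tile_grid

__all__ = ["InferenceConfig", "StructureMask", "binarize", "segment_section",
           "error_overlay"]


@dataclass
class InferenceConfig:
    tile_px: int = 256
    overlap_px: int = 128
    threshold: float = 0.5
    batch_size: int = 8

    def __post_init__(self):
        if not 0 <= self.overlap_px < self.tile_px:
            raise ValueError("overlap_px must satisfy 0 <= overlap < tile_px")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class StructureMask:
    """Stitched per-section probability and binary masks (bbox frame)."""

    structure: str
    prob: np.ndarray
    binary: np.ndarray
    threshold: float
    section_id: str = ""


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Elementwise ``prob >= threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(prob) >= threshold


def error_overlay(image: np.ndarray, pred: np.ndarray, truth: np.ndarray,
                  alpha: float = 0.6) -> np.ndarray:
    """RGB overlay of prediction errors on an H&E crop.

    True positives are tinted green, false positives red and false
    negatives blue, the usual reading-study colour convention.
    """
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape or pred.shape != image.shape[:2]:
        raise ValueError("image, prediction and truth must share a frame")
    out = np.asarray(image, dtype=np.float64).copy()
    for mask, color in (((pred & truth), (0, 200, 0)),
                        ((pred & ~truth), (220, 0, 0)),
                        ((~pred & truth), (0, 0, 220))):
        out[mask] = (1 - alpha) * out[mask] + alpha * np.array(color)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _reflect_pad_to(img: np.ndarray, height: int, width: int) -> np.ndarray:
    ph, pw = height - img.shape[0], width - img.shape[1]
    if ph <= 0 and pw <= 0:
        return img
    pad = [(0, max(ph, 0)), (0, max(pw, 0))] + [(0, 0)] * (img.ndim - 2)
    # reflect needs size >= 2 along the padded axis; fall back to edge
    mode = "reflect" if img.shape[0] > 1 and img.shape[1] > 1 else "edge"
    return np.pad(img, pad, mode=mode)


def segment_section(model, slide, section: LNSection,
                    cfg: InferenceConfig | None = None,
                    structure: str | None = None) -> StructureMask:
    """Predict one structure over a whole section and stitch the tiles.

    ``slide`` may be a SlideImage or a plain RGB raster in whose frame
    the section's bbox/contour are expressed.  Overlapping predictions
    are averaged per pixel; the probability raster is clipped to the
    section contour before thresholding.
    """
    cfg = cfg or InferenceConfig()
    img = slide.levels[0] if isinstance(slide, SlideImage) else np.asarray(slide)
    r0, c0, r1, c1 = section.bbox
    if r1 <= r0 or c1 <= c0:
        raise ValueError("degenerate section bounding box")
    if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
        raise ValueError("section bbox outside slide bounds")
    crop = img[r0:r1, c0:c1]
    h, w = crop.shape[:2]
    tp = cfg.tile_px
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int32)
    origins = tile_grid(h, w, tp, cfg.overlap_px)
    batch_imgs, batch_info = [], []

    def flush():
        if not batch_imgs:
            return
        x = np.stack(batch_imgs).astype(np.float64)
        if crop.dtype == np.uint8:
            x = x / 255.0
        probs = model.predict(x.transpose(0, 3, 1, 2))
        for p, (r, c, hh, ww) in zip(probs, batch_info):
            acc[r:r + hh, c:c + ww] += p[:hh, :ww]
            cnt[r:r + hh, c:c + ww] += 1
        batch_imgs.clear()
        batch_info.clear()

    for (r, c) in origins:
        hh, ww = min(tp, h - r), min(tp, w - c)
        tile = _reflect_pad_to(crop[r:r + hh, c:c + ww], tp, tp)
        batch_imgs.append(tile)
        batch_info.append((r, c, hh, ww))
        if len(batch_imgs) == cfg.batch_size:
            flush()
    flush()
    assert (cnt > 0).all(), "tiling must cover every bbox pixel"
    prob = acc / cnt
    contour = np.asarray(section.contour, dtype=float) - np.array([c0, r0])
    inside = polygon2mask((h, w), contour[:, ::-1])
    prob = prob * inside
    return StructureMask(
        structure=structure or getattr(getattr(model, "spec", None), "structure", "gc"),
        prob=prob,
        binary=binarize(prob, cfg.threshold) & inside,
        threshold=cfg.threshold,
        section_id=section.section_id,
    )
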