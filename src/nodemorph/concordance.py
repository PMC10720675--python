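"""Dice-based agreement between annotators and between model and consensus.

The Dice coefficient 2|A∩B|/(|A|+|B|) measures pixel-set overlap.
Inter-annotator agreement is summarised per structure as the pairwise
matrix across annotators, averaged first within each lymph node and
then across nodes (with the standard error taken over nodes).
Consensus maps count, per pixel, how many annotators marked it; a model
can then be scored against the "at least k annotators" reference masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "AnnotationSet",
    "ConsensusMap",
    "PairwiseDiceResult",
    "dice",
    "pairwise_dice",
    "consensus_map",
    "model_vs_consensus",
    "rasterize_polygons",
]


def rasterize_polygons(polygons, shape) -> np.ndarray:
    """Fill (x, y)-vertex polygons into a boolean raster of ``shape``.

    Vertices sit at pixel centres; overlapping polygons are unioned.
    """
    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        mask |= polygon2mask(shape, poly[:, ::-1])  # (x,y) -> (row,col)
    return mask


@dataclass
class AnnotationSet:
    """One annotator's markup of one structure on one lymph node."""

    annotator_id: str
    structure: str
    polygons: list = field(default_factory=list)
    mask: np.ndarray | None = None

    def rasterize(self, shape) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask, dtype=bool)
        return rasterize_polygons(self.polygons, shape)


@dataclass
class ConsensusMap:
    counts: np.ndarray
    n_annotators: int

    def reference(self, k: int) -> np.ndarray:
        """Pixels marked by at least ``k`` annotators."""
        if not 1 <= k <= self.n_annotators:
            raise ValueError(f"consensus level {k} outside 1..{self.n_annotators}")
        return self.counts >= k


@dataclass
class PairwiseDiceResult:
    matrix: np.ndarray            # annotator x annotator, averaged over LNs
    annotators: list
    mean: float                   # over unique pairs and LNs
    se: float                     # standard error over LNs
    per_ln_mean: np.ndarray
    all_empty_flags: np.ndarray   # LNs where every annotator's mask was empty


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary rasters; both-empty is defined as 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def _as_per_ln(sets):
    if len(sets) and isinstance(sets[0], AnnotationSet):
        return [list(sets)]
    return [list(s) for s in sets]


def pairwise_dice(sets) -> PairwiseDiceResult:
    """Pairwise annotator agreement.

    ``sets`` is either one lymph node's list of AnnotationSet (with
    masks in a shared frame) or a list of such lists, one per node with
    annotators in identical order.
    """
    per_ln = _as_per_ln(sets)
    n = len(per_ln[0])
    if n < 2:
        raise ValueError("pairwise Dice needs at least 2 annotators")
    annotators = [s.annotator_id for s in per_ln[0]]
    mats = []
    ln_means = []
    empties = []
    for ln_sets in per_ln:
        if len(ln_sets) != n:
            raise ValueError("all lymph nodes must have the same annotators")
        shape = _shared_shape(ln_sets)
        masks = [s.rasterize(shape) for s in ln_sets]
        empties.append(all(m.sum() == 0 for m in masks))
        mat = np.eye(n)
        vals = []
        for i in range(n):
            for j in range(i + 1, n):
                d = dice(masks[i], masks[j])
                mat[i, j] = mat[j, i] = d
                vals.append(d)
        mats.append(mat)
        ln_means.append(float(np.mean(vals)))
    ln_means = np.asarray(ln_means)
    se = float(ln_means.std(ddof=1) / np.sqrt(len(ln_means))) if len(ln_means) > 1 else 0.0
    return PairwiseDiceResult(
        matrix=np.mean(mats, axis=0),
        annotators=annotators,
        mean=float(ln_means.mean()),
        se=se,
        per_ln_mean=ln_means,
        all_empty_flags=np.asarray(empties),
    )


def _shared_shape(ln_sets):
    shapes = {s.mask.shape for s in ln_sets if s.mask is not None}
    if len(shapes) > 1:
        raise ValueError("annotator masks for one lymph node must share a frame")
    if shapes:
        return shapes.pop()
    # polygons only: frame large enough for every vertex
    xy = np.vstack([np.asarray(p) for s in ln_sets for p in s.polygons])
    return (int(np.ceil(xy[:, 1].max())) + 2, int(np.ceil(xy[:, 0].max())) + 2)


def consensus_map(sets) -> ConsensusMap:
    """Per-pixel count of annotators marking the pixel."""
    sets = list(sets)
    shape = _shared_shape(sets)
    counts = np.zeros(shape, dtype=np.int32)
    for s in sets:
        counts += s.rasterize(shape).astype(np.int32)
    return ConsensusMap(counts=counts, n_annotators=len(sets))


def model_vs_consensus(model_mask: np.ndarray, cmap: ConsensusMap, k: int) -> float:
    """Dice between a model mask and the at-least-k-annotators reference."""
    return dice(model_mask, cmap.reference(k))
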