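"""Tile extraction, section-level data splits and model training.

Annotated sections are cut into overlapping fixed-size tiles; the
train/validation/test split is made at the *section* level so no
section leaks tiles into two partitions.  Training minimises a
configurable loss (default binary cross-entropy plus soft Dice) with
Adam, evaluates the validation Dice after every epoch and returns the
best-validation checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .concordance import dice
from .models import UNet

__all__ = [
    "TrainConfig",
    "Tile",
    "SectionSample",
    "TileSets",
    "tile_grid",
    "tile_dataset",
    "train",
    "predict_tile",
]


@dataclass
class TrainConfig:
    """Tiling, optimisation and augmentation settings."""

    tile_px: int = 256
    overlap_px: int = 128
    batch_size: int = 8
    epochs: int = 10
    learning_rate: float = 1e-3
    loss: str = "bce_plus_dice"
    augment_flip: bool = True
    augment_rot90: bool = True
    augment_color_jitter: bool = False
    split: tuple = (100, 9, 5)
    max_tiles_per_section: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.overlap_px < self.tile_px:
            raise ValueError("overlap_px must satisfy 0 <= overlap < tile_px")
        if any(s <= 0 for s in self.split):
            raise ValueError("split counts must be positive")
        if self.loss not in ("bce", "dice", "bce_plus_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class SectionSample:
    """One annotated section: RGB image with its ground-truth mask."""

    image: np.ndarray                # (H, W, 3) uint8
    mask: np.ndarray | None
    section_id: str


@dataclass
class Tile:
    image: np.ndarray                # (tile, tile, 3)
    mask: np.ndarray | None          # (tile, tile) bool
    valid: np.ndarray                # False where zero-padded
    origin: tuple                    # (row, col) in the section frame
    section_id: str = ""
    magnification: str = "x10"


@dataclass
class TileSets:
    train: list
    val: list
    test: list
    section_split: dict = field(default_factory=dict)


def tile_grid(height: int, width: int, tile: int, overlap: int) -> list[tuple]:
    """Top-left origins of an overlapping grid covering (height, width).

    Interior origins advance by ``tile - overlap``; a final origin is
    appended when needed so the last tile touches the far edge.  A
    dimension smaller than ``tile`` yields a single origin at 0.
    """
    step = tile - overlap

    def starts(n):
        if n <= tile:
            return [0]
        s = list(range(0, n - tile + 1, step))
        if s[-1] != n - tile:
            s.append(n - tile)
        return s

    return [(r, c) for r in starts(height) for c in starts(width)]


def _cut_tiles(sample: SectionSample, cfg: TrainConfig,
               rng: np.random.Generator | None = None) -> list[Tile]:
    img = sample.image
    h, w = img.shape[:2]
    tp = cfg.tile_px
    tiles = []
    for (r, c) in tile_grid(h, w, tp, cfg.overlap_px):
        him, wim = min(tp, h - r), min(tp, w - c)
        timg = np.zeros((tp, tp, 3), dtype=img.dtype)
        timg[:him, :wim] = img[r:r + him, c:c + wim]
        valid = np.zeros((tp, tp), dtype=bool)
        valid[:him, :wim] = True
        tmask = None
        if sample.mask is not None:
            tmask = np.zeros((tp, tp), dtype=bool)
            tmask[:him, :wim] = sample.mask[r:r + him, c:c + wim]
        tiles.append(Tile(image=timg, mask=tmask, valid=valid,
                          origin=(r, c), section_id=sample.section_id))
    if cfg.max_tiles_per_section is not None and len(tiles) > cfg.max_tiles_per_section:
        rng = rng or np.random.default_rng(cfg.seed)
        cap = cfg.max_tiles_per_section
        # prefer tiles containing foreground; fill up with random negatives
        pos = [i for i, t in enumerate(tiles) if t.mask is not None and t.mask.any()]
        neg = [i for i in range(len(tiles)) if i not in set(pos)]
        if len(pos) > cap:
            keep = list(rng.choice(pos, size=cap, replace=False))
        else:
            keep = pos + list(rng.choice(neg, size=min(cap - len(pos), len(neg)),
                                         replace=False))
        tiles = [tiles[i] for i in sorted(keep)]
    return tiles


def tile_dataset(sections, cfg: TrainConfig) -> TileSets:
    """Cut sections into tiles with a section-level train/val/test split.

    ``sections`` is a list of SectionSample (or (image, mask, id)
    tuples).  The shuffle is deterministic per ``cfg.seed`` and the
    partitions have exactly the sizes in ``cfg.split``.
    """
    samples = [s if isinstance(s, SectionSample) else SectionSample(*s) for s in sections]
    n_tr, n_va, n_te = cfg.split
    if n_tr + n_va + n_te > len(samples):
        raise ValueError(
            f"split {cfg.split} requires {n_tr + n_va + n_te} sections, got {len(samples)}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(samples))
    parts = {
        "train": [samples[i] for i in order[:n_tr]],
        "val": [samples[i] for i in order[n_tr:n_tr + n_va]],
        "test": [samples[i] for i in order[n_tr + n_va:n_tr + n_va + n_te]],
    }
    split_ids = {k: [s.section_id for s in v] for k, v in parts.items()}
    out = {}
    for k, secs in parts.items():
        tiles = []
        for s in secs:
            tiles.extend(_cut_tiles(s, cfg, rng))
        out[k] = tiles
    return TileSets(train=out["train"], val=out["val"], test=out["test"],
                    section_split=split_ids)


def _to_batch(tiles: list[Tile]):
    x = np.stack([t.image for t in tiles]).astype(np.float64) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([t.mask for t in tiles])[:, None].astype(np.float64)
    v = np.stack([t.valid for t in tiles])[:, None]
    return x, y, v


def _augment(x, y, v, rng, cfg: TrainConfig):
    n = x.shape[0]
    for i in range(n):
        if cfg.augment_flip and rng.uniform() < 0.5:
            x[i] = x[i, :, :, ::-1]
            y[i] = y[i, :, :, ::-1]
            v[i] = v[i, :, :, ::-1]
        if cfg.augment_rot90:
            k = int(rng.integers(0, 4))
            if k:
                x[i] = np.rot90(x[i], k, axes=(1, 2))
                y[i] = np.rot90(y[i], k, axes=(1, 2))
                v[i] = np.rot90(v[i], k, axes=(1, 2))
        if cfg.augment_color_jitter:
            x[i] = np.clip(x[i] * rng.uniform(0.9, 1.1) + rng.normal(0, 0.02), 0, 1)
    return x, y, v


def train(model: UNet, train_tiles: list[Tile], cfg: TrainConfig,
          val_tiles: list[Tile] | None = None):
    """Train a segmentation model; returns ``(model, history)``.

    ``history`` holds one record per epoch with the mean training loss
    and the validation Dice (computed over all validation pixels with
    the prediction thresholded at 0.5).  The parameters of the
    best-validation epoch are restored before returning.
    """
    if not train_tiles:
        raise ValueError("empty training set")
    if not any(t.mask is not None and t.mask.any() for t in train_tiles):
        raise ValueError("degenerate task: training masks contain no positive pixel")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history = []
    best = (-np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_tiles))
        losses = []
        for i0 in range(0, len(order), cfg.batch_size):
            batch = [train_tiles[i] for i in order[i0:i0 + cfg.batch_size]]
            x, y, v = _to_batch(batch)
            x, y, v = _augment(x.copy(), y.copy(), v.copy(), rng, cfg)
            logits = model.forward(x)
            loss, grad = nn.bce_dice_loss(logits, y, valid=v, mode=cfg.loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_dice = np.nan
        if val_tiles:
            val_dice = evaluate_dice(model, val_tiles)
            if val_dice > best[0]:
                best = (val_dice, model.state())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_dice": float(val_dice)})
    if best[1] is not None:
        model.load_state(best[1])
    return model, history


def evaluate_dice(model: UNet, tiles: list[Tile], threshold: float = 0.5,
                  batch_size: int = 8) -> float:
    """Dice over all (valid) pixels of a tile set, threshold 0.5."""
    preds, truths = [], []
    for i0 in range(0, len(tiles), batch_size):
        batch = tiles[i0:i0 + batch_size]
        x, y, v = _to_batch(batch)
        p = model.predict(x) >= threshold
        t = y[:, 0].astype(bool)
        val = v[:, 0]
        preds.append((p & val).ravel())
        truths.append((t & val).ravel())
    return dice(np.concatenate(preds), np.concatenate(truths))


def predict_tile(model: UNet, tile_image: np.ndarray) -> np.ndarray:
    """Probability raster in [0, 1] for one RGB tile (HWC, uint8 or float)."""
    img = np.asarray(tile_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) tile")
    x = img.astype(np.float64)
    if img.dtype == np.uint8:
        x = x / 255.0
    return model.predict(x.transpose(2, 0, 1)[None])[0]
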