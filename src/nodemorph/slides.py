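"""Slide reading and lymph-node section detection.

A digitised slide is a bright-field RGB raster (optionally pyramidal)
with a microns-per-pixel (mpp) scale at the finest level.  Individual
lymph-node sections are located by Otsu thresholding of the luminance
image (tissue is the dark class on a white background), morphological
cleanup, and external contour tracing; small debris is dropped by a
physical-area filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon, mapping, shape
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk

__all__ = [
    "SlideImage",
    "LNSection",
    "read_slide",
    "write_slide",
    "luminance",
    "otsu_threshold",
    "detect_ln_sections",
    "section_area",
    "sections_to_geojson",
    "sections_from_geojson",
]

INVOLVEMENT_LABELS = ("involved", "cancer_free", "unknown")


@dataclass
class SlideImage:
    """RGB raster(s) of a slide; ``levels[0]`` is the finest resolution.

    ``downsamples[i]`` is the integer factor between level i and the
    finest level; ``mpp`` is microns per pixel at the finest level.
    """

    levels: list
    mpp: float
    id: str = ""
    downsamples: list = field(default_factory=lambda: [1])

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if len(self.downsamples) != len(self.levels):
            raise ValueError("one downsample factor per level required")
        h0, w0 = self.levels[0].shape[:2]
        for img, f in zip(self.levels, self.downsamples):
            h, w = img.shape[:2]
            if h != -(-h0 // f) or w != -(-w0 // f):
                raise ValueError("level dimensions inconsistent with downsample factors")

    @property
    def shape(self) -> tuple:
        return self.levels[0].shape

    def level_for_pixels(self, max_pixels: float) -> int:
        """Coarsest-enough level with at most ``max_pixels`` pixels."""
        for i, img in enumerate(self.levels):
            if img.shape[0] * img.shape[1] <= max_pixels:
                return i
        return len(self.levels) - 1


@dataclass
class LNSection:
    """A detected lymph-node section in finest-level coordinates."""

    contour: np.ndarray               # (x, y) vertices
    bbox: tuple                       # (row0, col0, row1, col1), half-open
    area_mm2: float
    section_id: str
    involvement: str = "unknown"

    def __post_init__(self):
        if self.involvement not in INVOLVEMENT_LABELS:
            raise ValueError(f"involvement must be one of {INVOLVEMENT_LABELS}")


def read_slide(path, mpp: float | None = None, id: str | None = None) -> SlideImage:
    """Read a plain/pyramidal TIFF or a PNG into a SlideImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arrs = [lvl.asarray() for lvl in series.levels] if series.levels else [series.asarray()]
    else:
        import imageio.v3 as iio
        arrs = [iio.imread(str(path))]
    h0 = arrs[0].shape[0]
    downs = [int(round(h0 / a.shape[0])) for a in arrs]
    if mpp is None:
        raise ValueError("mpp must be given (not embedded in plain TIFF/PNG)")
    return SlideImage(levels=arrs, mpp=mpp, id=id or path.stem, downsamples=downs)


def write_slide(path, slide: SlideImage) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(str(path), slide.levels[0])
    else:
        import imageio.v3 as iio
        iio.imwrite(str(path), slide.levels[0])


def luminance(rgb: np.ndarray) -> np.ndarray:
    """8-bit luminance 0.299 R + 0.587 G + 0.114 B."""
    rgb = np.asarray(rgb, dtype=np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Threshold t in 0..255 maximizing between-class variance.

    Pixels <= t form the low class.  A constant raster has no defined
    threshold and raises ValueError.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty raster")
    hist = np.bincount(gray.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant raster")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # pixels <= t
    mu0 = np.cumsum(hist * levels)
    mu_t = mu0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu0 / w0
        m1 = (mu_t - mu0) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -1.0
    return int(np.argmax(var_between))


def _reading_order(sections: list[LNSection]) -> list[LNSection]:
    """Sort sections top-to-bottom into rows, then left-to-right."""
    remaining = sorted(sections, key=lambda s: s.bbox[0])
    rows = []
    for s in remaining:
        placed = False
        for row in rows:
            r0, r1 = row[0].bbox[0], row[0].bbox[2]
            overlap = min(r1, s.bbox[2]) - max(r0, s.bbox[0])
            if overlap > 0.5 * min(r1 - r0, s.bbox[2] - s.bbox[0]):
                row.append(s)
                placed = True
                break
        if not placed:
            rows.append([s])
    out = []
    for row in rows:
        out.extend(sorted(row, key=lambda s: s.bbox[1]))
    return out


def detect_ln_sections(slide: SlideImage, min_area_mm2: float = 0.5,
                       level: int | None = None,
                       cleanup_radius_px: int = 5,
                       max_detect_pixels: float = 4e6) -> list[LNSection]:
    """Detect lymph-node sections on a slide.

    Luminance -> Otsu foreground (dark class) -> morphological closing
    then opening -> hole filling -> external contours, rescaled to
    finest-level coordinates; components below ``min_area_mm2`` are
    dropped.  A blank slide yields an empty list.
    """
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    if level is None:
        level = slide.level_for_pixels(max_detect_pixels)
    img = slide.levels[level]
    factor = slide.downsamples[level]
    mpp_level = slide.mpp * factor
    gray = luminance(img)
    try:
        t = otsu_threshold(gray)
    except ValueError:
        return []
    fg = gray <= t
    if fg.sum() == 0:
        return []
    if cleanup_radius_px > 0:
        selem = disk(cleanup_radius_px)
        fg = ndi.binary_opening(ndi.binary_closing(fg, structure=selem), structure=selem)
    fg = ndi.binary_fill_holes(fg)
    lbl = label(fg, connectivity=2)
    sections = []
    for region in regionprops(lbl):
        area_mm2 = region.area * mpp_level ** 2 / 1e6
        if area_mm2 < min_area_mm2:
            continue
        minr, minc, maxr, maxc = region.bbox
        mask = np.zeros((maxr - minr, maxc - minc), dtype=bool)
        mask[region.coords[:, 0] - minr, region.coords[:, 1] - minc] = True
        contours = find_contours(np.pad(mask, 1).astype(float), 0.5)
        if not contours:
            continue
        rc = max(contours, key=len) - 1.0 + np.array([minr, minc], dtype=float)
        xy = rc[:, ::-1] * factor                     # to finest-level coords
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        sections.append(LNSection(
            contour=xy,
            bbox=(minr * factor, minc * factor, maxr * factor, maxc * factor),
            area_mm2=poly.area * slide.mpp ** 2 / 1e6,
            section_id="",
        ))
    sections = _reading_order(sections)
    for i, s in enumerate(sections):
        s.section_id = f"{slide.id or 'slide'}_s{i}"
    return sections


def section_area(section: LNSection, mpp: float) -> float:
    """Physical polygon area in mm^2 (shoelace x mpp^2 / 1e6)."""
    contour = np.asarray(section.contour, dtype=float)
    if contour.shape[0] < 3:
        raise ValueError("degenerate contour: need at least 3 vertices")
    return Polygon(contour).area * mpp ** 2 / 1e6


def sections_to_geojson(sections: list[LNSection], path=None) -> dict:
    """Serialize sections as a GeoJSON FeatureCollection."""
    features = []
    for s in sections:
        features.append({
            "type": "Feature",
            "geometry": mapping(Polygon(np.asarray(s.contour))),
            "properties": {
                "section_id": s.section_id,
                "area_mm2": s.area_mm2,
                "involvement": s.involvement,
            },
        })
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def sections_from_geojson(source) -> list[LNSection]:
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    sections = []
    for feat in source["features"]:
        poly = shape(feat["geometry"])
        xy = np.asarray(poly.exterior.coords)
        props = feat.get("properties", {})
        minx, miny, maxx, maxy = poly.bounds
        sections.append(LNSection(
            contour=xy,
            bbox=(int(np.floor(miny)), int(np.floor(minx)),
                  int(np.ceil(maxy)), int(np.ceil(maxx))),
            area_mm2=float(props.get("area_mm2", 0.0)),
            section_id=str(props.get("section_id", "")),
            involvement=str(props.get("involvement", "unknown")),
        ))
    return sections
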