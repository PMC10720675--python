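"""Synthetic lymph-node slides and patient cohorts with known ground truth.

The slide generator emulates the geometry of an H&E lymph-node slide at
low magnification: a near-white background carrying a handful of
roughly elliptical tissue sections, each with a thin eosinophilic
capsule, a pale subcapsular sinus (SCS) band directly beneath it,
branching pale intranodal sinus channels, and a set of darker
basophilic germinal-centre (GC) ellipses.  Every structure is rendered
from analytic geometry, so the paired ground truth (section contours,
GC/sinus masks, per-section feature values) is exact by construction.

The cohort generator draws per-patient lymph-node feature sets (either
sampled from realistic distributions or taken from slide ground truth)
and survival times from an exponential proportional-hazards model with
a planted effect: patients whose aggregated feature falls above a
cut-off have their hazard multiplied by a known hazard ratio.  Because
the baseline is exponential, proportional hazards hold exactly and the
planted effect is recoverable by Cox regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import line as draw_line
from skimage.morphology import disk
from skimage.transform import resize

from .morphometrics import LNFeatures
from .slides import SlideImage
from .survival import PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SlideSpec",
    "GroundTruth",
    "FeatureEffect",
    "CohortSpec",
    "PlacementError",
    "generate_slide",
    "render_magnification",
    "generate_cohort",
    "cohort_to_frame",
]

SUPPORTED_FACTORS = (1, 2, 4, 8, 16)


class PlacementError(RuntimeError):
    """Raised when requested structures cannot be placed without overlap."""


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide.

    Ranges are inclusive ``(lo, hi)`` tuples.  Default geometry gives
    sections of roughly 1-1.5 mm diameter at 4 um/pixel, GC follicles
    of 60-160 um diameter and a 16-28 um subcapsular sinus.
    """

    n_sections: int = 3
    slide_shape: tuple = (900, 1200)
    section_radius_px: tuple = (120, 180)
    section_eccentricity: tuple = (0.0, 0.5)
    gc_count_per_section: int | tuple = (2, 8)
    gc_radius_px: tuple = (8, 20)
    gc_eccentricity: tuple = (0.0, 0.6)
    sinus_fraction: float = 0.12
    scs_width_px: tuple = (4.0, 7.0)
    capsule_px: float = 3.0
    mpp: float = 4.0
    background_rgb: tuple = (247, 246, 248)
    tissue_rgb: tuple = (185, 135, 185)
    capsule_rgb: tuple = (200, 150, 190)
    gc_rgb: tuple = (120, 75, 150)
    sinus_rgb: tuple = (203, 185, 214)
    noise_sd: float = 5.0
    lowfreq_amp: float = 6.0
    branch_halfwidth_px: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.sinus_fraction <= 0.5:
            raise ValueError("sinus_fraction must lie in [0, 0.5]")
        for name in ("section_radius_px", "gc_radius_px", "scs_width_px"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a non-empty positive range")
        lo, hi = self.section_eccentricity
        if not (0 <= lo <= hi < 1):
            raise ValueError("section_eccentricity must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Exact ground truth paired with a generated slide."""

    section_contours: list            # (x, y) vertex arrays, one per section
    section_labels: np.ndarray        # int raster: 0 background, i+1 = section i
    gc_mask: np.ndarray
    sinus_mask: np.ndarray
    per_section_gc_params: list       # per section: list of (center_xy, (a, b), angle)
    planted_features: list            # per-section LNFeatures, analytic
    mpp: float

    def section_mask(self, i: int) -> np.ndarray:
        return self.section_labels == i + 1


def _ellipse_mask(shape, center, a, b, angle) -> np.ndarray:
    """Boolean raster of a rotated filled ellipse ((x, y) center, semi-axes)."""
    h, w = shape
    cy, cx = center[1], center[0]
    r0 = max(int(cy - max(a, b)) - 2, 0)
    r1 = min(int(cy + max(a, b)) + 3, h)
    c0 = max(int(cx - max(a, b)) - 2, 0)
    c1 = min(int(cx + max(a, b)) + 3, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - cx, yy - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _ellipse_polygon(center, a, b, angle, n=180) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    u = a * np.cos(t)
    v = b * np.sin(t)
    ca, sa = math.cos(angle), math.sin(angle)
    x = center[0] + u * ca - v * sa
    y = center[1] + u * sa + v * ca
    return np.column_stack([x, y])


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation, exact enough for ground-truth circularity
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def _sample_range(rng, rg):
    return rng.uniform(rg[0], rg[1])


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, GroundTruth]:
    """Render a slide and its exact ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.slide_shape
    margin = 8

    # ---- place sections (bounded rejection sampling) ----------------------
    sections = []   # (center_xy, a, b, angle)
    for i in range(spec.n_sections):
        placed = False
        for _ in range(300):
            a = _sample_range(rng, spec.section_radius_px)
            ecc = _sample_range(rng, spec.section_eccentricity)
            b = a * math.sqrt(1.0 - ecc ** 2)
            angle = rng.uniform(0, math.pi)
            r = max(a, b)
            if 2 * (r + margin) >= min(h, w):
                continue
            cx = rng.uniform(r + margin, w - r - margin)
            cy = rng.uniform(r + margin, h - r - margin)
            ok = all(math.hypot(cx - c0[0], cy - c0[1]) > r + max(a0, b0) + 2 * margin
                     for c0, a0, b0, _ in sections)
            if ok:
                sections.append(((cx, cy), a, b, angle))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place section {i + 1}/{spec.n_sections} without overlap "
                f"on a {h}x{w} slide with radii {spec.section_radius_px}")

    section_labels = np.zeros((h, w), dtype=np.int16)
    capsule_mask = np.zeros((h, w), dtype=bool)
    gc_mask = np.zeros((h, w), dtype=bool)
    sinus_mask = np.zeros((h, w), dtype=bool)
    contours, gc_params_all, planted = [], [], []
    selem = disk(spec.branch_halfwidth_px)

    for si, (center, a, b, angle) in enumerate(sections):
        full = _ellipse_mask((h, w), center, a, b, angle)
        cap = spec.capsule_px
        scs_w = _sample_range(rng, spec.scs_width_px)
        inner_scs = _ellipse_mask((h, w), center, a - cap - scs_w, b - cap - scs_w, angle)
        below_cap = _ellipse_mask((h, w), center, a - cap, b - cap, angle)
        scs_band = below_cap & ~inner_scs
        section_labels[full] = si + 1
        capsule_mask |= full & ~below_cap
        contour = _ellipse_polygon(center, a, b, angle)
        contours.append(contour)

        # ---- germinal centres ------------------------------------------
        if isinstance(spec.gc_count_per_section, tuple):
            n_gc = int(rng.integers(spec.gc_count_per_section[0],
                                    spec.gc_count_per_section[1] + 1))
        else:
            n_gc = int(spec.gc_count_per_section)
        gcs = []
        sec_gc = np.zeros((h, w), dtype=bool)
        for gi in range(n_gc):
            done = False
            for _ in range(400):
                ga = _sample_range(rng, spec.gc_radius_px)
                gecc = _sample_range(rng, spec.gc_eccentricity)
                gb = ga * math.sqrt(1.0 - gecc ** 2)
                gangle = rng.uniform(0, math.pi)
                gr = max(ga, gb)
                # fits strictly inside the tissue interior with margin
                fit_a = a - cap - scs_w - gr - 4
                fit_b = b - cap - scs_w - gr - 4
                if fit_a <= 0 or fit_b <= 0:
                    continue
                t = rng.uniform(0, 2 * math.pi)
                rad = math.sqrt(rng.uniform(0, 1))
                u = fit_a * rad * math.cos(t)
                v = fit_b * rad * math.sin(t)
                ca, sa = math.cos(angle), math.sin(angle)
                gx = center[0] + u * ca - v * sa
                gy = center[1] + u * sa + v * ca
                if all(math.hypot(gx - c0[0], gy - c0[1]) > gr + max(a0, b0) + 3
                       for c0, (a0, b0), _ in gcs):
                    gcs.append(((gx, gy), (ga, gb), gangle))
                    sec_gc |= _ellipse_mask((h, w), (gx, gy), ga, gb, gangle)
                    done = True
                    break
            if not done:
                raise PlacementError(
                    f"could not place GC {gi + 1}/{n_gc} in section {si} "
                    f"without overlap (section radius {a:.0f}px)")
        gc_mask |= sec_gc
        gc_params_all.append(gcs)

        # ---- sinus network ---------------------------------------------
        section_area_px = float(full.sum())
        target_px = spec.sinus_fraction * section_area_px
        sec_sinus = scs_band.copy()
        gc_keepout = ndi.binary_dilation(sec_gc, structure=disk(3))
        allowed = inner_scs & ~gc_keepout
        attempts = 0
        while sec_sinus.sum() < target_px and attempts < 300:
            attempts += 1
            thin = np.zeros((h, w), dtype=bool)
            theta = rng.uniform(0, 2 * math.pi)
            # start on the inner edge of the SCS band
            sx = center[0] + (a - cap - scs_w) * math.cos(theta) * 0.98
            sy = center[1] + (b - cap - scs_w) * math.sin(theta) * 0.98
            # rotate into slide frame
            ca, sa = math.cos(angle), math.sin(angle)
            px = center[0] + (sx - center[0]) * ca - (sy - center[1]) * sa
            py = center[1] + (sx - center[0]) * sa + (sy - center[1]) * ca
            pos = np.array([px, py])
            d = np.array([center[0] - px, center[1] - py])
            d = d / (np.linalg.norm(d) + 1e-9)
            n_seg = rng.integers(2, 5)
            seg_len = 0.22 * min(a, b)
            for _ in range(n_seg):
                turn = rng.normal(0, 0.5)
                c_t, s_t = math.cos(turn), math.sin(turn)
                d = np.array([d[0] * c_t - d[1] * s_t, d[0] * s_t + d[1] * c_t])
                nxt = pos + d * seg_len * rng.uniform(0.7, 1.3)
                rr, cc = draw_line(int(round(pos[1])), int(round(pos[0])),
                                   int(round(nxt[1])), int(round(nxt[0])))
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                thin[rr[keep], cc[keep]] = True
                if rng.uniform() < 0.4:   # side branch
                    bd = np.array([-d[1], d[0]]) * (1 if rng.uniform() < 0.5 else -1)
                    bnxt = nxt + bd * seg_len * 0.6
                    rr, cc = draw_line(int(round(nxt[1])), int(round(nxt[0])),
                                       int(round(bnxt[1])), int(round(bnxt[0])))
                    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                    thin[rr[keep], cc[keep]] = True
                pos = nxt
            branch = ndi.binary_dilation(thin, structure=selem) & allowed
            sec_sinus |= branch
        sinus_mask |= sec_sinus

        # ---- analytic planted features ----------------------------------
        poly = Polygon(contour)
        ln_area_mm2 = poly.area * spec.mpp ** 2 / 1e6
        if gcs:
            areas = [math.pi * ga * gb for _, (ga, gb), _ in gcs]
            circs = [4 * math.pi * (math.pi * ga * gb) / _ellipse_perimeter(ga, gb) ** 2
                     for _, (ga, gb), _ in gcs]
            mean_area = float(np.mean(areas)) * spec.mpp ** 2 / 1e6
            mean_circ = float(np.mean(circs))
        else:
            mean_area = mean_circ = None
        sinus_area_mm2 = float(sec_sinus.sum()) * spec.mpp ** 2 / 1e6
        planted.append(LNFeatures(
            section_id=f"synthetic_{spec.seed}_s{si}",
            involvement="unknown",
            gc_count=len(gcs),
            mean_gc_area_mm2=mean_area,
            mean_gc_circularity=mean_circ,
            sinus_area_mm2=sinus_area_mm2,
            normalized_sinus_area=min(sinus_area_mm2 / ln_area_mm2, 1.0),
            scs_width_um=scs_w * spec.mpp,
            ln_area_mm2=ln_area_mm2,
        ))

    # GC/sinus must stay disjoint; construction guarantees it, assert cheaply
    assert not np.logical_and(gc_mask, sinus_mask).any()

    # ---- render ------------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    tissue = section_labels > 0
    img[tissue] = spec.tissue_rgb
    img[capsule_mask] = spec.capsule_rgb
    img[sinus_mask] = spec.sinus_rgb
    img[gc_mask] = spec.gc_rgb
    if spec.lowfreq_amp > 0:
        grid = rng.uniform(-1, 1, size=(6, 8))
        fieldmap = resize(grid, (h, w), order=3, mode="reflect",
                          anti_aliasing=False) * spec.lowfreq_amp
        img += fieldmap[..., None]
    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    slide = SlideImage(levels=[img], mpp=spec.mpp,
                       id=f"synthetic_{spec.seed}", downsamples=[1])
    gt = GroundTruth(
        section_contours=contours,
        section_labels=section_labels,
        gc_mask=gc_mask,
        sinus_mask=sinus_mask,
        per_section_gc_params=gc_params_all,
        planted_features=planted,
        mpp=spec.mpp,
    )
    return slide, gt


def render_magnification(slide: SlideImage, factor: int) -> SlideImage:
    """Downsample the finest level by an integer pyramid factor.

    Output dimensions are ``ceil(input / factor)`` and the mpp scales
    by the same factor; factor 1 is the identity.
    """
    if factor not in SUPPORTED_FACTORS:
        raise ValueError(f"unsupported downsample factor {factor}; choose from {SUPPORTED_FACTORS}")
    img = slide.levels[0]
    if factor == 1:
        return SlideImage(levels=[img.copy()], mpp=slide.mpp,
                          id=slide.id, downsamples=[1])
    h, w = img.shape[:2]
    out_shape = (-(-h // factor), -(-w // factor))
    ds = resize(img.astype(np.float64), out_shape + img.shape[2:],
                order=1, mode="reflect", anti_aliasing=True)
    ds = np.clip(np.rint(ds), 0, 255).astype(np.uint8)
    return SlideImage(levels=[ds], mpp=slide.mpp * factor,
                      id=f"{slide.id}_x{factor}", downsamples=[1])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class FeatureEffect:
    """A planted survival effect on a dichotomized aggregated feature."""

    feature: str = "mean_gc_count"
    cutoff: float = 2.0
    hazard_ratio: float = 0.3
    orientation: str = "ge"

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class CohortSpec:
    """Parameters of a synthetic patient cohort."""

    n_patients: int = 400
    lns_per_patient: tuple = (2, 12)
    feature_effect: FeatureEffect = field(default_factory=FeatureEffect)
    baseline_hazard: float = 0.01     # events per month in the low group
    censoring_rate: float = 0.005     # independent exponential censoring
    involved_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring rate must be non-negative")


def _sample_ln_features(rng, spec: CohortSpec, idx: str) -> LNFeatures:
    """One lymph node's features from field-realistic distributions."""
    gc_count = int(rng.poisson(2.0))
    ln_area = float(np.exp(rng.normal(np.log(5.0), 0.5)))      # mm^2
    norm_sinus = float(rng.beta(2.0, 12.0))                    # mean ~0.14
    if gc_count > 0:
        mean_area = float(np.exp(rng.normal(np.log(0.055), 0.4)))
        mean_circ = float(np.clip(rng.normal(0.75, 0.08), 0.17, 0.9))
    else:
        mean_area = mean_circ = None
    return LNFeatures(
        section_id=idx,
        involvement="involved" if rng.uniform() < spec.involved_fraction else "cancer_free",
        gc_count=gc_count,
        mean_gc_area_mm2=mean_area,
        mean_gc_circularity=mean_circ,
        sinus_area_mm2=norm_sinus * ln_area,
        normalized_sinus_area=norm_sinus,
        scs_width_um=float(np.exp(rng.normal(np.log(20.0), 0.45))),
        ln_area_mm2=ln_area,
    )


def generate_cohort(cspec: CohortSpec,
                    ground_truths: list[GroundTruth] | None = None) -> list[PatientRecord]:
    """Draw a cohort with survival times tied to a planted feature effect.

    Per patient the named feature is averaged across that patient's
    lymph nodes; patients above the effect's cut-off have hazard
    ``baseline * hazard_ratio``, the rest ``baseline``.  Event and
    censoring times are independent exponentials.  When slide ground
    truths are supplied, node features are resampled from their planted
    feature records instead of parametric distributions.
    """
    from .survival import _feature_value, dichotomize

    rng = np.random.default_rng(cspec.seed)
    eff = cspec.feature_effect
    pool = None
    if ground_truths is not None:
        pool = [f for gt in ground_truths for f in gt.planted_features]
        if not pool:
            raise ValueError("ground truth source contains no planted features")
    records = []
    values = []
    for pi in range(cspec.n_patients):
        pid = f"P{pi:04d}"
        n_ln = int(rng.integers(cspec.lns_per_patient[0], cspec.lns_per_patient[1] + 1))
        if pool is not None:
            lns = [pool[int(rng.integers(len(pool)))] for _ in range(n_ln)]
        else:
            lns = [_sample_ln_features(rng, cspec, f"{pid}_ln{j}") for j in range(n_ln)]
        vals = [v for v in (_feature_value(ln, eff.feature) for ln in lns)
                if v is not None and np.isfinite(v)]
        agg = float(np.mean(vals)) if vals else np.nan
        values.append(agg)
        covariates = {
            "age": float(rng.normal(55, 12)),
            "grade": int(rng.choice([1, 2, 3], p=[0.2, 0.4, 0.4])),
        }
        records.append(PatientRecord(patient_id=pid, ln_features=lns,
                                     covariates=covariates, time=1.0, event=0))

    values = np.asarray(values)
    high = (values >= eff.cutoff) if eff.orientation == "ge" else (values > eff.cutoff)
    high &= np.isfinite(values)
    if high.all() or not high.any():
        logger.warning("generate_cohort: degenerate spec, all patients in one group")
    for rec, is_high in zip(records, high):
        hazard = cspec.baseline_hazard * (eff.hazard_ratio if is_high else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / cspec.censoring_rate) if cspec.censoring_rate > 0 else np.inf
        rec.time = float(min(t_event, t_cens))
        rec.event = int(t_event <= t_cens)
        rec.covariates["group_high"] = int(is_high)
    return records


def cohort_to_frame(records: list[PatientRecord]):
    from .survival import records_to_frame
    return records_to_frame(records)
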