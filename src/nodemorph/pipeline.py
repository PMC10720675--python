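"""End-to-end pipeline orchestration on the synthetic fixture.

Ties the stages together — synthesize slides and a cohort, detect
sections, train the tiny segmentation models, run whole-section
inference, quantify morphometric features, and run the outcome
analysis — with a single seed, a config hash and a run manifest of
per-stage artifact checksums so that deterministic stages can be
verified to reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("synth", "detect", "train", "infer", "quantify", "survive")


class PipelineDependencyError(RuntimeError):
    """A stage was requested before its upstream artifacts exist."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-fixture run.

    Sub-dicts override the defaults of the corresponding module
    dataclasses (SlideSpec, CohortSpec, TrainConfig, InferenceConfig).
    """

    seed: int = 0
    n_slides: int = 2
    slide: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    survive: dict = field(default_factory=dict)
    min_area_mm2: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_png(path, arr):
    import imageio.v3 as iio
    iio.imwrite(str(path), arr)


def _require(out: Path, relpaths, stage: str, needed_by: str):
    missing = [p for p in relpaths if not (out / p).exists()]
    if missing:
        raise PipelineDependencyError(
            f"stage '{needed_by}' needs artifacts {missing}; run stage '{stage}' first")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .benchmark import benchmark_slide_spec
    from .synthetic import CohortSpec, generate_slide, generate_cohort, cohort_to_frame

    arts = []
    planted_rows = []
    for i in range(cfg.n_slides):
        spec = benchmark_slide_spec(cfg.seed * 101 + i, **cfg.slide)
        slide, gt = generate_slide(spec)
        _write_png(out / f"slide_{i}.png", slide.levels[0])
        _write_png(out / f"slide_{i}_gc_mask.png", gt.gc_mask.astype(np.uint8) * 255)
        _write_png(out / f"slide_{i}_sinus_mask.png", gt.sinus_mask.astype(np.uint8) * 255)
        arts += [out / f"slide_{i}.png", out / f"slide_{i}_gc_mask.png",
                 out / f"slide_{i}_sinus_mask.png"]
        for f in gt.planted_features:
            row = f.to_dict()
            row["slide"] = i
            planted_rows.append(row)
        (out / f"slide_{i}_meta.json").write_text(json.dumps({"mpp": spec.mpp}))
        arts.append(out / f"slide_{i}_meta.json")
    pd.DataFrame(planted_rows).to_csv(out / "planted_features.csv", index=False)
    arts.append(out / "planted_features.csv")

    cohort = generate_cohort(CohortSpec(seed=cfg.seed, **cfg.cohort))
    cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)
    arts.append(out / "cohort.csv")
    return arts


def _stage_detect(cfg: PipelineConfig, out: Path) -> list[Path]:
    import imageio.v3 as iio
    from .slides import SlideImage, detect_ln_sections, sections_to_geojson

    _require(out, [f"slide_{i}.png" for i in range(cfg.n_slides)], "synth", "detect")
    arts = []
    for i in range(cfg.n_slides):
        mpp = json.loads((out / f"slide_{i}_meta.json").read_text())["mpp"]
        img = iio.imread(str(out / f"slide_{i}.png"))
        slide = SlideImage(levels=[img], mpp=mpp, id=f"slide_{i}")
        secs = detect_ln_sections(slide, min_area_mm2=cfg.min_area_mm2)
        sections_to_geojson(secs, out / f"slide_{i}_sections.geojson")
        arts.append(out / f"slide_{i}_sections.geojson")
    return arts


def _stage_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .benchmark import benchmark_train_config, benchmark_model_spec, make_benchmark_sections
    from .models import build_model, save_checkpoint
    from .training import tile_dataset, train

    arts = []
    epochs = int(cfg.train.get("epochs", 4))
    for structure in ("gc", "sinus"):
        tcfg = benchmark_train_config(cfg.seed, epochs=epochs)
        sections = make_benchmark_sections(structure, sum(tcfg.split), cfg.seed)
        tiles = tile_dataset(sections, tcfg)
        model = build_model(benchmark_model_spec(
            structure, variant=cfg.train.get("variant", "ms_unet"), seed=cfg.seed))
        model, history = train(model, tiles.train, tcfg, val_tiles=tiles.val)
        ckpt = out / f"model_{structure}.ckpt"
        save_checkpoint(ckpt, model, train_config=tcfg, history=history)
        pd.DataFrame(history).to_csv(out / f"train_log_{structure}.csv", index=False)
        arts += [ckpt, out / f"train_log_{structure}.csv"]
    return arts


def _stage_infer(cfg: PipelineConfig, out: Path) -> list[Path]:
    import imageio.v3 as iio
    from .inference import InferenceConfig, segment_section
    from .models import load_checkpoint
    from .slides import SlideImage, sections_from_geojson

    _require(out, ["model_gc.ckpt", "model_sinus.ckpt"], "train", "infer")
    _require(out, [f"slide_{i}_sections.geojson" for i in range(cfg.n_slides)],
             "detect", "infer")
    models = {s: load_checkpoint(out / f"model_{s}.ckpt")[0] for s in ("gc", "sinus")}
    icfg = InferenceConfig(tile_px=64, overlap_px=32, **cfg.inference)
    arts = []
    for i in range(cfg.n_slides):
        mpp = json.loads((out / f"slide_{i}_meta.json").read_text())["mpp"]
        img = iio.imread(str(out / f"slide_{i}.png"))
        slide = SlideImage(levels=[img], mpp=mpp, id=f"slide_{i}")
        secs = sections_from_geojson(out / f"slide_{i}_sections.geojson")
        for sec in secs:
            for structure, model in models.items():
                sm = segment_section(model, slide, sec, icfg, structure=structure)
                p = out / f"mask_{sec.section_id}_{structure}.png"
                _write_png(p, sm.binary.astype(np.uint8) * 255)
                arts.append(p)
    return arts


def _stage_quantify(cfg: PipelineConfig, out: Path) -> list[Path]:
    import imageio.v3 as iio
    from .morphometrics import extract_gc_instances, ln_features, scs_width
    from .slides import sections_from_geojson

    _require(out, [f"slide_{i}_sections.geojson" for i in range(cfg.n_slides)],
             "detect", "quantify")
    rows = []
    min_area_um2 = float(cfg.quantify.get("min_area_um2", 2000.0))
    for i in range(cfg.n_slides):
        mpp = json.loads((out / f"slide_{i}_meta.json").read_text())["mpp"]
        secs = sections_from_geojson(out / f"slide_{i}_sections.geojson")
        for sec in secs:
            gc_path = out / f"mask_{sec.section_id}_gc.png"
            sinus_path = out / f"mask_{sec.section_id}_sinus.png"
            _require(out, [gc_path.name, sinus_path.name], "infer", "quantify")
            r0, c0, r1, c1 = sec.bbox
            gc_bin = iio.imread(str(gc_path)) > 127
            sinus_bin = iio.imread(str(sinus_path)) > 127
            # masks are stored in the bbox frame; shift contour accordingly
            contour = np.asarray(sec.contour) - np.array([c0, r0])
            local = type("S", (), {"contour": contour, "area_mm2": sec.area_mm2,
                                   "section_id": sec.section_id,
                                   "involvement": sec.involvement})()
            inst = extract_gc_instances(gc_bin, contour, mpp, min_area_um2=min_area_um2)
            scs = scs_width(contour, sinus_bin, mpp)
            feats = ln_features(inst, sinus_bin, local, mpp, scs=scs)
            row = feats.to_dict()
            row["slide"] = i
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    return [out / "features.csv"]


def _stage_survive(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .survival import (PAPER_PRESET_CUTOFFS, cox_ph, dichotomize,
                           km_logrank, optimal_cutoff)

    _require(out, ["cohort.csv"], "synth", "survive")
    df = pd.read_csv(out / "cohort.csv")
    feature = cfg.survive.get("feature", "gc_count")
    per_patient = (df.groupby("patient_id")
                     .agg(value=(feature, "mean"), time=("time", "first"),
                          event=("event", "first")))
    preset_key = "mean_gc_count" if feature == "gc_count" else feature
    mode = cfg.survive.get("mode", "preset")
    if mode == "preset":
        cutoff, orientation = PAPER_PRESET_CUTOFFS[preset_key]
    else:
        cp = optimal_cutoff(per_patient["value"], per_patient["time"],
                            per_patient["event"])
        cutoff, orientation = cp.cutoff, "ge"
    groups = dichotomize(per_patient["value"], cutoff, orientation)
    curves, p_logrank = km_logrank(per_patient["time"], per_patient["event"], groups)
    cov = pd.DataFrame({"high": (groups == "high").astype(float)})
    res = cox_ph(per_patient["time"], per_patient["event"], cov)
    result = {
        "feature": feature,
        "cutoff": float(cutoff),
        "orientation": orientation,
        "group_sizes": {k: int((groups == k).sum()) for k in ("low", "high")},
        "hazard_ratio": res.hr,
        "ci95": [float(res.ci95["lower"].iloc[0]), float(res.ci95["upper"].iloc[0])],
        "p_likelihood": res.p_likelihood,
        "p_logrank": float(p_logrank),
    }
    (out / "survival_results.json").write_text(json.dumps(result, indent=2))
    arts = [out / "survival_results.json"]
    for label, curve in curves.items():
        p = out / f"km_{label}.csv"
        curve.to_csv(p, index=False)
        arts.append(p)
    return arts


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "detect": _stage_detect,
    "train": _stage_train,
    "infer": _stage_infer,
    "quantify": _stage_quantify,
    "survive": _stage_survive,
}


def run_pipeline(cfg: PipelineConfig, out_dir, stages=None) -> dict:
    """Run the requested stages in order and write a run manifest.

    Returns the manifest dict: config hash, seed, versions, and per-stage
    artifact checksums.  Re-running with identical config and seed
    reproduces identical checksums for the deterministic stages.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    stages.sort(key=STAGES.index)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest.update({
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {"nodemorph": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    })
    for s in stages:
        logger.info("pipeline stage: %s", s)
        artifacts = _STAGE_FUNCS[s](cfg, out)
        manifest["stages"][s] = {
            "status": "complete",
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
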