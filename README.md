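# nodemorph

Lymph-node morphometry from H&E whole-slide images: section detection,
germinal-centre and sinus segmentation, immune-feature quantification,
and outcome analysis.

## The problem

Axillary lymph nodes (LNs) removed during breast-cancer staging are
routinely examined only for metastatic deposits, yet their morphology
also records the patient's systemic immune response: germinal centres
(GCs) — follicular structures where B cells mature — and the lymphatic
sinus network, including the subcapsular sinus (SCS) directly beneath
the capsule. `nodemorph` implements a full computational pipeline to
quantify these structures on digitised H&E slides and to relate them to
time-to-event outcomes:

1. **Section detection** — Otsu thresholding of the luminance image and
   contour tracing delimit each LN section; areas are reported in mm²
   via the slide's microns-per-pixel (mpp) scale.
2. **Segmentation** — binary per-structure models from the U-Net
   family: plain U-Net, attention U-Net, and a multiscale U-Net whose
   encoder blocks run parallel atrous (dilated) convolutions at rates
   (1, 2, 4), fusing the fields of view of ×10/×5/×2.5 magnification in
   a single pass. Training tiles come from a section-level
   train/validation/test split; inference stitches overlapping tile
   predictions by per-pixel averaging.
3. **Morphometrics** — per LN: GC count, mean GC area (mm²), mean GC
   circularity 4πA/P², total sinus area normalised by LN area, and the
   four-point SCS width heuristic
   `SCS = (w1 + w2 + w3 + w4) / 4`,
   with the widths read where the LN's longest diameter and its
   orthogonal axis cross the capsule.
4. **Concordance** — pairwise Dice `2|A∩B|/(|A|+|B|)` between
   annotators, consensus maps (how many annotators marked each pixel),
   and model-vs-consensus Dice at each consensus level.
5. **Outcome analysis** — patient-level aggregation (mean across LNs,
   or total GC count / max sinus area), dichotomization at preset
   cut-offs (≥2 GCs, >0.015 mm² mean GC area, >0.69 circularity,
   >0.13 normalised sinus, ≥20 µm SCS width) or at a data-driven
   minimal-p cut-point, Kaplan–Meier curves with log-rank tests, and
   Cox proportional-hazards models with likelihood-ratio p values.

Everything is exercised end-to-end on a bundled **synthetic-histology
generator**: slides with known section contours, GC ellipses, sinus
networks and per-section feature values, plus patient cohorts whose
exponential survival times carry a planted hazard ratio — so every
stage has exact ground truth.

No deep-learning framework is required: the U-Net variants run on a
small NumPy convolution engine with hand-derived, finite-difference-
verified gradients, sized for desk-scale experiments.

## Worked example

```python
from nodemorph.synthetic import SlideSpec, generate_slide
from nodemorph.slides import detect_ln_sections
from nodemorph.morphometrics import extract_gc_instances

slide, gt = generate_slide(SlideSpec(seed=42))
sections = detect_ln_sections(slide, min_area_mm2=0.5)
print(len(sections))                      # 3  (all planted sections found)
print(f"{sections[0].area_mm2:.2f}")      # 1.36  (mm², matches the planted ellipse)

inst = extract_gc_instances(gt.gc_mask, gt.section_contours[0], gt.mpp)
print(len(inst), gt.planted_features[0].gc_count)   # 6 6  (exact recovery)
```

Running `python examples/05_survival_analysis.py` on the default cohort
(400 patients, planted hazard ratio 0.30 for mean GC count ≥ 2) prints

```
Cox estimate:   HR 0.25 (95% CI 0.18-0.33), likelihood-ratio p = 1.20e-20
minimal-p scan: cut-point 2.00 (p = 6.89e-22, 62 cuts examined)
```

— the confidence interval covers the planted 0.30 and the scan lands on
the planted boundary. The other `examples/*.py` scripts walk through
slide synthesis, detection, training/stitching and morphometrics, each
printing what it computes and what the numbers mean.

A thin CLI mirrors the library:
`nodemorph synth|detect|train|infer|quantify|concord|survive|run`
(see `nodemorph --help`).

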