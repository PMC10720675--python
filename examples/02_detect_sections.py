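"""Detect lymph-node sections on a slide by Otsu thresholding.

Tissue is the dark class on a bright-field slide; Otsu's threshold on
the luminance image separates it from the glass background, and
contour tracing yields one polygon per node section with its physical
area in mm^2.
"""

from nodemorph.slides import detect_ln_sections
from nodemorph.synthetic import SlideSpec, generate_slide

slide, gt = generate_slide(SlideSpec(seed=42))
sections = detect_ln_sections(slide, min_area_mm2=0.5)

print(f"planted sections: {len(gt.section_contours)}, detected: {len(sections)}")
for s in sections:
    print(f"  {s.section_id}: area {s.area_mm2:.2f} mm^2, bbox {s.bbox}")

# The detected count should equal the planted count, and each area
# should match the planted ellipse area (pi*a*b*mpp^2) to within the
# rasterization error of the contour.
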