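"""Recover a planted survival effect from a synthetic cohort.

Draws 400 patients whose hazard drops to 0.3x when their mean
germinal-centre count across lymph nodes is >= 2, then re-estimates
that effect: dichotomize at the preset cut-off, Kaplan-Meier + log-rank,
Cox proportional hazards, and a minimal-p cut-point scan.
"""

import pandas as pd

from nodemorph.survival import (aggregate_patient, cox_ph, dichotomize,
                                km_logrank, optimal_cutoff)
from nodemorph.synthetic import CohortSpec, generate_cohort

records = generate_cohort(CohortSpec(n_patients=400, seed=5))
values = aggregate_patient(records, "gc_count", "mean")
time = [r.time for r in records]
event = [r.event for r in records]

groups = dichotomize(values.values, cutoff=2.0, orientation="ge")
curves, p_logrank = km_logrank(time, event, groups)
res = cox_ph(time, event,
             pd.DataFrame({"high": (groups == "high").astype(float)}))
cp = optimal_cutoff(values.values, time, event)

lo, hi = res.ci95["lower"].iloc[0], res.ci95["upper"].iloc[0]
print(f"planted effect: HR 0.30 for mean GC count >= 2")
print(f"Cox estimate:   HR {res.hr:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
      f"likelihood-ratio p = {res.p_likelihood:.2e}")
print(f"log-rank p at preset cut 2.0: {p_logrank:.2e}")
print(f"minimal-p scan: cut-point {cp.cutoff:.2f} "
      f"(p = {cp.p:.2e}, {cp.n_cuts_examined} cuts examined)")

# The Cox CI should cover 0.30 and the scan should land near the
# planted boundary of 2 GCs per node. Note the scan's p is optimistic
# by construction - it is the minimum over many correlated tests.
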