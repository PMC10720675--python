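"""Patient-level aggregation and outcome analysis of lymph-node features.

Per-node morphometrics are aggregated per patient (mean across nodes,
or total GC count / maximum sinus area for sparse cohorts), dichotomised
at preset or data-driven cut-points, and related to time-to-event
outcomes with Kaplan-Meier curves, log-rank tests and Cox proportional
hazards models (model significance by likelihood-ratio test).  The
data-driven cut-point uses the minimal-p-value approach: every
admissible observed value is tried as a cut and the one minimising the
log-rank p is kept — a procedure whose optimism on null data is a known
property, quantified in the test suite.

Cox and Kaplan-Meier fits are delegated to lifelines; rank tests to
scipy; Benjamini-Hochberg adjustment to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .morphometrics import LNFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "SurvivalResult",
    "CutpointResult",
    "PAPER_PRESET_CUTOFFS",
    "aggregate_patient",
    "dichotomize",
    "optimal_cutoff",
    "logrank_p",
    "km_logrank",
    "cox_ph",
    "group_compare",
    "pearson_correlation",
]

# Published dichotomization presets: feature -> (cutoff, orientation).
# orientation 'ge': high group is value >= cutoff; 'gt': value > cutoff.
PAPER_PRESET_CUTOFFS = {
    "mean_gc_count": (2.0, "ge"),
    "mean_gc_area_mm2": (0.015, "gt"),
    "mean_gc_circularity": (0.69, "gt"),
    "normalized_sinus_area": (0.13, "gt"),
    "sinus_area_mm2": (0.13, "gt"),
    "scs_width_um": (20.0, "ge"),
}


@dataclass
class PatientRecord:
    """A patient's assessed lymph nodes, covariates and outcome."""

    patient_id: str
    ln_features: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)
    time: float = 0.0
    event: int = 0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("follow-up time must be non-negative")


@dataclass
class SurvivalResult:
    hazard_ratios: pd.Series
    ci95: pd.DataFrame               # columns lower / upper
    p_likelihood: float
    covariate_p: pd.Series
    group_sizes: dict | None = None
    cutoff: float | None = None
    km_curves: dict | None = None

    @property
    def hr(self) -> float:
        """Hazard ratio of the first (primary) covariate."""
        return float(self.hazard_ratios.iloc[0])


@dataclass
class CutpointResult:
    cutoff: float
    p: float
    n_cuts_examined: int


_FEATURE_FIELDS = {f: f for f in (
    "gc_count", "mean_gc_area_mm2", "mean_gc_circularity",
    "sinus_area_mm2", "normalized_sinus_area", "scs_width_um", "ln_area_mm2")}


def _feature_value(ln: LNFeatures, feature: str):
    if feature == "mean_gc_count":
        feature = "gc_count"
    if feature not in _FEATURE_FIELDS:
        raise KeyError(f"unknown lymph-node feature {feature!r}")
    return getattr(ln, feature)


def aggregate_patient(records: list[PatientRecord], feature: str = "gc_count",
                      mode: str = "mean", subset: str = "all") -> pd.Series:
    """Aggregate one feature across each patient's lymph nodes.

    ``mode`` is 'mean', 'total_gc' (sum of GC counts) or 'max_sinus'
    (the node with maximum sinus area); ``subset`` restricts nodes by
    involvement label ('all', 'involved', 'cancer_free').  Patients
    with no node in the subset (or no non-missing value) get NaN.
    """
    if mode not in ("mean", "total_gc", "max_sinus"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if subset not in ("all", "involved", "cancer_free"):
        raise ValueError(f"unknown subset {subset!r}")
    out = {}
    for rec in records:
        lns = [ln for ln in rec.ln_features
               if subset == "all" or ln.involvement == subset]
        if mode == "total_gc":
            vals = [ln.gc_count for ln in lns]
            out[rec.patient_id] = float(np.sum(vals)) if vals else np.nan
        elif mode == "max_sinus":
            vals = [ln.sinus_area_mm2 for ln in lns]
            out[rec.patient_id] = float(np.max(vals)) if vals else np.nan
        else:
            vals = [v for v in (_feature_value(ln, feature) for ln in lns)
                    if v is not None and np.isfinite(v)]
            out[rec.patient_id] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name=feature)


def dichotomize(values, cutoff: float, orientation: str = "ge") -> np.ndarray:
    """Split values into 'low'/'high' groups at a cut-off.

    orientation 'ge' labels value >= cutoff as high (the "< c versus
    >= c" convention); 'gt' labels value > cutoff as high ("<= c versus
    > c").  A one-sided split is allowed but logged as a warning.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if orientation not in ("ge", "gt"):
        raise ValueError("orientation must be 'ge' or 'gt'")
    v = np.asarray(values, dtype=float)
    high = v >= cutoff if orientation == "ge" else v > cutoff
    labels = np.where(high, "high", "low")
    if len(set(labels[np.isfinite(v)])) < 2:
        logger.warning("dichotomize: all patients fall on one side of cutoff %g", cutoff)
    return labels


def logrank_p(time, event, mask) -> float:
    """Two-group log-rank test p value (chi-square, 1 df).

    A direct vectorised implementation used by the cut-point scan,
    where calling a model-fitting routine per candidate cut would
    dominate the run time; agrees with lifelines' ``logrank_test``.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(mask, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    uniq, idx = np.unique(t, return_index=True)
    # at-risk counts just before each unique time
    n_total = t.size - idx
    cum_g = np.concatenate([[0], np.cumsum(g)])
    n1 = g.sum() - cum_g[idx]
    # events at each unique time, per group
    d_total = np.add.reduceat(e, idx)
    d1 = np.add.reduceat(e * g, idx)
    at = d_total > 0
    n_t, n1_t, d_t, d1_t = n_total[at], n1[at], d_total[at], d1[at]
    exp1 = d_t * n1_t / n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (d_t * (n1_t / n_t) * (1 - n1_t / n_t)
               * (n_t - d_t) / np.maximum(n_t - 1, 1))
    o_minus_e = (d1_t - exp1).sum()
    v = var.sum()
    if v <= 0:
        return 1.0
    chi2 = o_minus_e ** 2 / v
    return float(stats.chi2.sf(chi2, df=1))


def optimal_cutoff(values, time, event, min_group_frac: float = 0.1,
                   orientation: str = "ge") -> CutpointResult:
    """Minimal-p-value cut-point scan over observed values.

    Every unique observed value whose split keeps both groups at least
    ``min_group_frac`` of the cohort is tried; the cut minimising the
    log-rank p is returned along with the number of cuts examined.
    """
    if not 0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must be in (0, 0.5)")
    v = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    keep = np.isfinite(v)
    v, t, e = v[keep], t[keep], e[keep]
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct values to scan cut-points")
    n = v.size
    best = None
    examined = 0
    for cut in uniq:
        high = v >= cut if orientation == "ge" else v > cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_frac * n:
            continue
        examined += 1
        p = logrank_p(t, e, high)
        if best is None or p < best[1]:
            best = (float(cut), p)
    if best is None:
        raise ValueError("no admissible cut-point under the group-size constraint")
    return CutpointResult(cutoff=best[0], p=best[1], n_cuts_examined=examined)


def km_logrank(time, event, groups) -> tuple[dict, float]:
    """Kaplan-Meier curves per group and the two-group log-rank p.

    Returns ``(curves, p)`` where curves maps group label to a
    DataFrame with columns ``time`` and ``survival``.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("km_logrank expects exactly 2 groups")
    if any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("empty group")
    if e.sum() == 0:
        raise ValueError("no events observed")
    curves = {}
    for lab in labels:
        sel = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(lab))
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame({"time": sf.index.values,
                                    "survival": sf.iloc[:, 0].values})
    a, b = labels
    res = logrank_test(t[g == a], t[g == b], e[g == a], e[g == b])
    return curves, float(res.p_value)


def cox_ph(time, event, covariates: pd.DataFrame) -> SurvivalResult:
    """Cox proportional-hazards fit.

    Hazard ratios with 95% CIs per covariate, the model p from the
    likelihood-ratio test against the null model, and per-covariate
    Wald p values.  The first column of ``covariates`` is treated as
    the primary exposure for the ``hr`` shortcut.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() < cov.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    df = cov.copy()
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise RuntimeError(
            f"Cox fit failed for covariates {list(cov.columns)}: {exc}") from exc
    summ = cph.summary
    hr = np.exp(cph.params_)
    ci = pd.DataFrame({
        "lower": np.exp(summ["coef lower 95%"]),
        "upper": np.exp(summ["coef upper 95%"]),
    })
    llr = cph.log_likelihood_ratio_test()
    return SurvivalResult(
        hazard_ratios=hr,
        ci95=ci,
        p_likelihood=float(llr.p_value),
        covariate_p=summ["p"],
    )


def group_compare(values, groups, test: str = "wilcoxon", adjust: str = "none"):
    """Rank-based comparison of a feature (or several) across groups.

    ``values`` is a single array or a mapping name -> array (one family
    for FDR adjustment).  'wilcoxon' is the two-sided Wilcoxon rank-sum
    (Mann-Whitney) test for two groups; 'kruskal' the Kruskal-Wallis
    test for two or more.  ``adjust='fdr'`` applies Benjamini-Hochberg
    across the supplied family.
    """
    if test not in ("wilcoxon", "kruskal"):
        raise ValueError(f"unknown test {test!r}")
    if adjust not in ("none", "fdr"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    single = not isinstance(values, dict)
    family = {"_": values} if single else values
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ps = {}
    for name, vals in family.items():
        v = np.asarray(vals, dtype=float)
        samples = [v[g == lab] for lab in labels]
        if any(len(s) == 0 for s in samples):
            raise ValueError("empty group")
        if test == "wilcoxon":
            if len(labels) != 2:
                raise ValueError("wilcoxon rank-sum requires exactly 2 groups")
            a, b = samples
            exact_ok = (min(len(a), len(b)) < 20
                        and np.unique(np.concatenate([a, b])).size == len(a) + len(b))
            method = "exact" if exact_ok else "asymptotic"
            ps[name] = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                                method=method).pvalue)
        else:
            if all(np.array_equal(np.sort(samples[0]), np.sort(s)) for s in samples[1:]):
                ps[name] = 1.0   # identical samples: no evidence of difference
            else:
                ps[name] = float(stats.kruskal(*samples).pvalue)
    if adjust == "fdr":
        names = list(ps)
        adj = multipletests([ps[n] for n in names], method="fdr_bh")[1]
        ps = dict(zip(names, adj.tolist()))
    return ps["_"] if single else ps


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its t-test p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Long per-node table (one row per lymph node) from patient records."""
    rows = []
    for rec in records:
        for i, ln in enumerate(rec.ln_features):
            row = {"patient_id": rec.patient_id, "ln_id": ln.section_id or f"{rec.patient_id}_ln{i}"}
            row.update(ln.to_dict())
            row.update({f"cov_{k}": v for k, v in rec.covariates.items()})
            row["time"] = rec.time
            row["event"] = rec.event
            rows.append(row)
    return pd.DataFrame(rows)
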