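"""Cohort statistics: group comparison, survival, optimal cutpoints.

The statistical toolbox mirrors common practice in small imaging
cohorts: two-sided Mann-Whitney U tests for continuous variables,
Pearson chi-square (no continuity correction) for 2x2 tables,
Kaplan-Meier curves compared by the log-rank test, and an exhaustive
cutpoint scan that picks, for any continuous feature, the threshold
maximizing the log-rank statistic.  The scan reports the *unadjusted*
p-value with an explicit flag — maximizing over thresholds inflates
type-I error and the result is exploratory, as with X-tile-style tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .exceptions import ValidationError
from .io import CohortTable

__all__ = [
    "SurvivalCurve",
    "CutpointResult",
    "mann_whitney",
    "chi_square_2x2",
    "kaplan_meier",
    "logrank",
    "optimal_cutpoint",
    "tukey_quartiles",
    "summarize_by_mutation",
]


@dataclass
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function at the event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, float)
        self.survival_probs = np.asarray(self.survival_probs, float)
        self.n_at_risk = np.asarray(self.n_at_risk, int)
        if not (self.event_times.shape == self.survival_probs.shape
                == self.n_at_risk.shape):
            raise ValidationError("survival curve fields must align")
        if self.survival_probs.size:
            if np.any(np.diff(self.survival_probs) > 1e-12):
                raise ValidationError("survival probabilities must be non-increasing")
            if self.survival_probs.max() > 1 + 1e-12 or self.survival_probs.min() < 0:
                raise ValidationError("survival probabilities must lie in [0, 1]")


@dataclass
class CutpointResult:
    variable: str
    best_threshold: float
    logrank_chi2: float
    p_value: float
    group_sizes: tuple[int, int]
    multiple_testing_corrected: bool = field(default=False)
    note: str = "p-value is uncorrected for the threshold scan"


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is recomputed from midranks (so ties contribute half a win); the
    p-value is exact for small tie-free samples and otherwise uses the
    tie-corrected normal approximation.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return u_a, float(res.pvalue)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("all margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``events`` is True where the endpoint occurred and False for
    right-censored subjects, who leave the risk set after their time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.shape != events.shape:
        raise ValidationError("times and events must align")
    if np.any(times <= 0):
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    probs = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return SurvivalCurve(event_times, probs, at_risk)


def logrank(group_a: tuple, group_b: tuple) -> tuple[float, float]:
    """Two-group log-rank test; each group is a ``(times, events)`` pair."""
    (ta, ea), (tb, eb) = group_a, group_b
    ta, ea = np.asarray(ta, float), np.asarray(ea, bool)
    tb, eb = np.asarray(tb, float), np.asarray(eb, bool)
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def optimal_cutpoint(values, times, events, variable: str = "value",
                     min_group_frac: float = 0.1) -> CutpointResult:
    """Exhaustive threshold scan maximizing the log-rank statistic.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; a threshold is admissible when both sides retain at least
    ``min_group_frac`` of the cohort.  Ties in the statistic go to the
    lowest threshold.  The reported p-value is NOT corrected for the
    scan (see the result's flag).
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if not (values.shape == times.shape == events.shape):
        raise ValidationError("values, times and events must align")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValidationError("need at least 2 distinct values to scan")
    n = values.size
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    best = None
    for thr in (uniq[:-1] + uniq[1:]) / 2.0:
        hi = values > thr
        n_hi, n_lo = int(hi.sum()), int((~hi).sum())
        if n_hi < min_n or n_lo < min_n:
            continue
        if events[hi].sum() + events[~hi].sum() == 0:
            continue
        chi2, p = logrank((times[hi], events[hi]), (times[~hi], events[~hi]))
        if best is None or chi2 > best.logrank_chi2 + 1e-12:
            best = CutpointResult(variable, float(thr), chi2, p, (n_lo, n_hi))
    if best is None:
        raise ValidationError("no admissible threshold for the cutpoint scan")
    return best


def tukey_quartiles(x) -> tuple[float, float, float]:
    """(Q1, median, Q3) by the inclusive (Tukey hinge) convention.

    The median is the middle order statistic; each hinge is the median
    of the corresponding half, *including* the overall median when n is
    odd.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    if n == 0:
        raise ValidationError("empty sample")
    med = float(np.median(x))
    if n == 1:
        return med, med, med
    half = n // 2
    lower = x[: half + 1] if n % 2 else x[:half]
    upper = x[half:]
    return float(np.median(lower)), med, float(np.median(upper))


def summarize_by_mutation(cohort: CohortTable,
                          variables=("tbr_max", "tbr_mean", "ttp_min",
                                     "slope_suv_per_h")) -> pd.DataFrame:
    """Median (Q1;Q3) of conventional parameters, overall and by IDH1.

    One row per variable with Tukey quartiles for the whole cohort, the
    wild-type and the mutant subgroup, plus the Mann-Whitney p-value of
    the wild-type vs mutant comparison.
    """
    df = cohort.frame
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if "idh1_mutant" not in df.columns:
        raise ValidationError("cohort table lacks IDH1 labels")
    rows = []
    for var in variables:
        allq = tukey_quartiles(df[var])
        wt = df.loc[~df.idh1_mutant, var]
        mut = df.loc[df.idh1_mutant, var]
        wtq = tukey_quartiles(wt) if len(wt) else (np.nan,) * 3
        mutq = tukey_quartiles(mut) if len(mut) else (np.nan,) * 3
        p = mann_whitney(wt, mut)[1] if len(wt) and len(mut) else np.nan
        rows.append({
            "variable": var,
            "median_all": allq[1], "q1_all": allq[0], "q3_all": allq[2],
            "median_wt": wtq[1], "q1_wt": wtq[0], "q3_wt": wtq[2],
            "median_mut": mutq[1], "q1_mut": mutq[0], "q3_mut": mutq[2],
            "p_mann_whitney": p,
        })
    return pd.DataFrame(rows).set_index("variable")
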