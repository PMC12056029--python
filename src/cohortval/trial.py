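"""One-group and two-group analyses of validated cohorts.

Discrete variables get frequency tables and Pearson chi-square tests,
continuous variables get descriptive summaries / boxplots and two-sample
t-tests, and time-to-event variables get Kaplan-Meier product-limit
estimates and the two-group log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CONTINUOUS, DISCRETE, TIME_TO_EVENT, Cohort, CohortError
from .validation import BoxplotStats, UnivariateSummary, boxplot_stats, _describe

VARIANCE_WELCH = "welch"
VARIANCE_POOLED = "pooled"


@dataclass
class TestResult:
    """A hypothesis-test outcome with its effect summary."""

    test_name: str
    statistic: float
    p_value: float
    degrees_of_freedom: float | None = None
    effect_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise CohortError(f"{self.test_name}: non-finite statistic")
        if not 0.0 <= self.p_value <= 1.0:
            raise CohortError(f"{self.test_name}: p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "effect_summary": dict(self.effect_summary),
        }


# ---------------------------------------------------------------------------
# discrete variables
# ---------------------------------------------------------------------------


def _level_counts(cohort: Cohort, variable: str) -> dict[str, int]:
    if cohort.kind_of(variable) != DISCRETE:
        raise CohortError(f"variable {variable!r} is not discrete")
    col = cohort.data[variable]
    observed = col[~col.isna()]
    counts = observed.value_counts()
    return {str(level): int(c) for level, c in sorted(counts.items())}


def one_group_discrete(
    cohort: Cohort,
    variable: str,
    expected_probs: Mapping[str, float] | None = None,
) -> tuple[dict[str, int], TestResult]:
    """Level frequencies plus a Pearson chi-square goodness-of-fit test.

    The default null is equal proportions across the observed levels;
    ``expected_probs`` (summing to 1 over the observed levels) overrides it.
    """
    counts = _level_counts(cohort, variable)
    levels = list(counts)
    if len(levels) < 2:
        raise CohortError(
            f"variable {variable!r} has {len(levels)} observed level(s); "
            "the goodness-of-fit test needs at least 2"
        )
    observed = np.array([counts[lv] for lv in levels], dtype=float)
    total = observed.sum()
    if expected_probs is None:
        expected = np.full(len(levels), total / len(levels))
    else:
        missing = [lv for lv in levels if lv not in expected_probs]
        if missing:
            raise CohortError(f"expected_probs lacks levels {missing}")
        probs = np.array([expected_probs[lv] for lv in levels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise CohortError("expected_probs must sum to 1")
        expected = probs * total
    statistic, p_value = stats.chisquare(observed, expected)
    df = len(levels) - 1
    result = TestResult(
        test_name="chi-square goodness-of-fit",
        statistic=float(statistic),
        degrees_of_freedom=float(df),
        p_value=float(p_value),
        effect_summary={
            "n": int(total),
            "proportions": {lv: counts[lv] / total for lv in levels},
        },
    )
    return counts, result


def two_group_discrete(
    a: Cohort,
    b: Cohort,
    variable: str,
    continuity_correction: bool = False,
) -> tuple[pd.DataFrame, TestResult]:
    """Pearson chi-square on the group-by-level contingency table.

    Levels observed in either group enter with count 0 in the other, so the
    level universe is the union.  Yates continuity correction is off by
    default; pass ``continuity_correction=True`` for parity with ecosystem
    defaults on 2x2 tables.
    """
    counts_a = _level_counts(a, variable)
    counts_b = _level_counts(b, variable)
    levels = sorted(set(counts_a) | set(counts_b))
    if len(levels) < 2:
        raise CohortError(f"variable {variable!r} has a single level overall")
    table = pd.DataFrame(
        {
            "A": [counts_a.get(lv, 0) for lv in levels],
            "B": [counts_b.get(lv, 0) for lv in levels],
        },
        index=levels,
    ).T
    if table.sum(axis=1).min() == 0:
        raise CohortError("one group has no observations")
    statistic, p_value, df, expected = stats.chi2_contingency(
        table.to_numpy(), correction=continuity_correction
    )
    if np.any(expected <= 0):
        raise CohortError("degenerate table: expected cell count of zero")
    result = TestResult(
        test_name="chi-square homogeneity"
        + (" (Yates corrected)" if continuity_correction else ""),
        statistic=float(statistic),
        degrees_of_freedom=float(df),
        p_value=float(p_value),
        effect_summary={
            "levels": levels,
            "proportions_a": (table.loc["A"] / table.loc["A"].sum()).to_dict(),
            "proportions_b": (table.loc["B"] / table.loc["B"].sum()).to_dict(),
        },
    )
    return table, result


# ---------------------------------------------------------------------------
# continuous variables
# ---------------------------------------------------------------------------


def two_group_continuous(
    a: Cohort,
    b: Cohort,
    variable: str,
    variance_mode: str = VARIANCE_WELCH,
) -> TestResult:
    """Two-sample t-test (Welch by default; pooled-variance on request)
    with the mean difference and its standard error as effect summary."""
    if variance_mode not in (VARIANCE_WELCH, VARIANCE_POOLED):
        raise CohortError(f"unknown variance_mode {variance_mode!r}")
    xa = a.numeric(variable)
    xb = b.numeric(variable)
    if xa.size < 2 or xb.size < 2:
        raise CohortError("t-test needs at least 2 complete rows per group")
    va = xa.var(ddof=1)
    vb = xb.var(ddof=1)
    if va == 0.0 and vb == 0.0 and xa.mean() == xb.mean():
        raise CohortError("both groups constant and equal: t-test undefined")
    equal_var = variance_mode == VARIANCE_POOLED
    tt = stats.ttest_ind(xa, xb, equal_var=equal_var)
    if equal_var:
        sp2 = ((xa.size - 1) * va + (xb.size - 1) * vb) / (xa.size + xb.size - 2)
        se = float(np.sqrt(sp2 * (1 / xa.size + 1 / xb.size)))
    else:
        se = float(np.sqrt(va / xa.size + vb / xb.size))
    return TestResult(
        test_name=f"two-sample t-test ({variance_mode})",
        statistic=float(tt.statistic),
        degrees_of_freedom=float(tt.df),
        p_value=float(tt.pvalue),
        effect_summary={
            "mean_a": float(xa.mean()),
            "mean_b": float(xb.mean()),
            "mean_difference": float(xa.mean() - xb.mean()),
            "se_difference": se,
            "n_a": int(xa.size),
            "n_b": int(xb.size),
        },
    )


def one_group_continuous(
    cohort: Cohort, variable: str
) -> tuple[dict, BoxplotStats]:
    """Descriptive summary plus Tukey boxplot statistics for one variable."""
    values = cohort.numeric(variable)
    if values.size < 1:
        raise CohortError(f"variable {variable!r} has no complete rows")
    summary = {"variable": variable, **_describe(values)}
    return summary, boxplot_stats(cohort, variable)


# ---------------------------------------------------------------------------
# time-to-event variables
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate of the survivor function.

    ``survival[i]`` is the estimate just after ``event_times[i]``; the
    curve starts at 1 before the first event time and is non-increasing.
    Ties between events and censorings at one time are handled
    events-first (censored records remain at risk at their own time).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    censoring_times: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "at_risk": self.at_risk.tolist(),
            "events": self.events.tolist(),
            "survival": self.survival.tolist(),
            "censoring_times": self.censoring_times.tolist(),
            "n": self.n,
        }

    def survival_at(self, t: float) -> float:
        """S(t): the estimate at time t (right-continuous step function)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _tte_arrays(cohort: Cohort, variable: str) -> tuple[np.ndarray, np.ndarray]:
    spec = cohort.variable(variable)
    if spec.kind != TIME_TO_EVENT:
        raise CohortError(f"variable {variable!r} is not time-to-event")
    mask = cohort.complete_mask([variable])
    times = cohort.data[variable].to_numpy(dtype=float)[mask]
    events = cohort.data[spec.event_indicator_name].to_numpy(dtype=float)[mask]
    if np.any(times < 0):
        raise CohortError(f"negative time in {variable!r}")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise CohortError("event indicator outside {0, 1}")
    return times, events.astype(int)


def km_estimate(cohort: Cohort, variable: str) -> KMEstimate:
    """Product-limit estimator over the distinct event times."""
    times, events = _tte_arrays(cohort, variable)
    if times.size == 0:
        raise CohortError(f"variable {variable!r} has no complete rows")
    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    d = np.array(
        [((times == t) & (events == 1)).sum() for t in event_times], dtype=int
    )
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - d / at_risk)
    return KMEstimate(
        event_times=event_times,
        at_risk=at_risk,
        events=d,
        survival=survival,
        censoring_times=np.sort(times[events == 0]),
        n=int(times.size),
    )


def logrank_statistic(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float, float]:
    """Two-group log-rank: (chi-square statistic, observed A, expected A).

    Aggregates the 2x2 hypergeometric tables over the distinct event times
    of the pooled sample.
    """
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    event_times = np.unique(all_times[all_events == 1])
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in event_times:
        n1 = float((times_a >= t).sum())
        n2 = float((times_b >= t).sum())
        n = n1 + n2
        d1 = float(((times_a == t) & (events_a == 1)).sum())
        d2 = float(((times_b == t) & (events_b == 1)).sum())
        d = d1 + d2
        observed_a += d1
        expected_a += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if variance == 0.0:
        raise CohortError("log-rank variance is zero: no comparable event times")
    statistic = (observed_a - expected_a) ** 2 / variance
    return statistic, observed_a, expected_a


def two_group_tte(
    a: Cohort, b: Cohort, variable: str
) -> tuple[tuple[KMEstimate, KMEstimate], TestResult]:
    """Per-group Kaplan-Meier curves plus the two-group log-rank test
    (Mantel-Cox; chi-square with 1 degree of freedom, two-sided p)."""
    times_a, events_a = _tte_arrays(a, variable)
    times_b, events_b = _tte_arrays(b, variable)
    if events_a.sum() + events_b.sum() == 0:
        raise CohortError("no events in either group")
    statistic, observed_a, expected_a = logrank_statistic(
        times_a, events_a, times_b, events_b
    )
    p_value = float(stats.chi2.sf(statistic, 1))
    result = TestResult(
        test_name="log-rank",
        statistic=float(statistic),
        degrees_of_freedom=1.0,
        p_value=p_value,
        effect_summary={
            "observed_events_a": float(observed_a),
            "expected_events_a": float(expected_a),
            "events_a": int(events_a.sum()),
            "events_b": int(events_b.sum()),
            "n_a": int(times_a.size),
            "n_b": int(times_b.size),
        },
    )
    return (km_estimate(a, variable), km_estimate(b, variable)), result
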