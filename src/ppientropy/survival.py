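"""Kaplan-Meier survival, entropy-survival regression and cohort tests.

Five-year survival rates are read off the product-limit (Kaplan-Meier)
curve of each cancer type at 1825 days (100 * S(t), right-continuous step
lookup).  Cohort mean entropies are regressed on those rates by ordinary
least squares; entropy differences between cohorts are tested with a
Kruskal-Wallis test followed by pairwise two-sided Mann-Whitney rank-sum
tests under Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDistributionError, ValidationError

__all__ = [
    "FIVE_YEARS_DAYS",
    "DEFAULT_SURVIVAL_INTERVALS",
    "KMCurve",
    "RegressionResult",
    "GroupComparison",
    "km_curve",
    "survival_rate_at",
    "entropy_survival_regression",
    "kruskal_wallis",
    "pairwise_rank_tests",
    "bin_patients_by_survival",
]

#: default horizon for "5-year" survival, in days
FIVE_YEARS_DAYS = 1825.0

#: survival-rate intervals cut at the lower label bound: "100%-81%" covers
#: [81, 100], "80%-61%" covers [61, 81), and so on down to "20%-1%" which
#: catches (0, 21); together they partition (0, 100].
DEFAULT_SURVIVAL_INTERVALS: tuple[tuple[str, float, float], ...] = (
    ("100%-81%", 81.0, 100.0),
    ("80%-61%", 61.0, 81.0),
    ("60%-41%", 41.0, 61.0),
    ("40%-21%", 21.0, 41.0),
    ("20%-1%", 0.0, 21.0),
)


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit estimate over observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival must be non-increasing")


@dataclass(frozen=True)
class RegressionResult:
    """OLS line of cohort mean entropy (bits) on 5-year survival (%)."""

    slope: float
    intercept: float
    r: float
    p_value: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    kw_statistic: float
    kw_df: int
    kw_p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def km_curve(records: pd.DataFrame) -> KMCurve:
    """Product-limit estimator from one cohort's (event, time_days) records.

    Censored records (event 0) shrink the risk set without dropping the
    curve.  ``records`` needs columns ``event`` and ``time_days``.
    """
    if len(records) == 0:
        raise ValidationError("empty cohort")
    durations = records["time_days"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    mask = table.index.to_numpy(dtype=float) > 0
    times = table.index.to_numpy(dtype=float)[mask]
    survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=table["at_risk"].to_numpy(dtype=float)[mask],
        events=table["observed"].to_numpy(dtype=float)[mask],
    )


def survival_rate_at(curve: KMCurve, t_days: float) -> float:
    """100 * S(t) by right-continuous step lookup (percent).

    Before the first observed time the curve is 1; past the last time the
    last value carries forward.  Doubles as the per-patient lookup at each
    patient's days-to-death / last-follow-up.
    """
    if t_days <= 0:
        raise ValidationError("t_days must be > 0")
    idx = int(np.searchsorted(curve.times, t_days, side="right")) - 1
    if idx < 0:
        return 100.0
    return 100.0 * float(curve.survival[idx])


def entropy_survival_regression(
    points: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS of entropy (Y, bits) on 5-year survival (X, %), with Pearson r.

    The 95% slope CI uses the t distribution with n-2 degrees of freedom.
    """
    if len(points) < 3:
        raise ValidationError("regression needs at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDistributionError("all survival rates identical")
    if np.ptp(y) == 0:
        raise DegenerateDistributionError("all entropies identical")
    res = stats.linregress(x, y)
    tcrit = float(stats.t.ppf(0.975, len(x) - 2))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope_ci_low=float(res.slope - tcrit * res.stderr),
        slope_ci_high=float(res.slope + tcrit * res.stderr),
        n=len(x),
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> GroupComparison:
    """Rank-based Kruskal-Wallis test (tie-corrected, chi-squared p)."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            label = labels[i] if labels else str(i)
            raise ValidationError(f"group {label} has fewer than 2 values")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        # every relabeling is rank-identical; the statistic is 0 by definition
        return GroupComparison(kw_statistic=0.0, kw_df=len(groups) - 1, kw_p=1.0)
    statistic, p = stats.kruskal(*groups)
    return GroupComparison(
        kw_statistic=float(statistic), kw_df=len(groups) - 1, kw_p=float(p)
    )


_CORRECTIONS = {"holm": "holm", "bonferroni": "bonferroni", "none": None}


def pairwise_rank_tests(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    correction: str = "holm",
    paired: bool = False,
) -> dict[tuple[str, str], float]:
    """Two-sided pairwise rank tests for every unordered group pair.

    Unpaired mode (default) uses the Mann-Whitney rank-sum test, suitable
    for cohorts of different patients and sizes; ``paired=True`` switches
    to the Wilcoxon signed-rank test and requires equal sizes.  P-values
    are corrected jointly (Holm by default); the mapping is symmetric.
    """
    if correction not in _CORRECTIONS:
        raise ValidationError(
            f"unknown correction {correction!r}; choose from {sorted(_CORRECTIONS)}"
        )
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if len(labels) != len(groups):
        raise ValidationError("labels must match groups")
    pairs = list(combinations(range(len(groups)), 2))
    raw = []
    for i, j in pairs:
        a = np.asarray(groups[i], dtype=float)
        b = np.asarray(groups[j], dtype=float)
        if paired:
            if len(a) != len(b):
                raise ValidationError("paired mode requires equal group sizes")
            if np.all(a == b):
                raw.append(1.0)
                continue
            raw.append(float(stats.wilcoxon(a, b).pvalue))
        else:
            raw.append(float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue))
    method = _CORRECTIONS[correction]
    if method is None:
        corrected = raw
    else:
        corrected = list(multipletests(raw, method=method)[1])
    out: dict[tuple[str, str], float] = {}
    for (i, j), p in zip(pairs, corrected):
        out[(labels[i], labels[j])] = float(p)
        out[(labels[j], labels[i])] = float(p)
    return out


def bin_patients_by_survival(
    patients: Iterable[tuple[str, float]],
    intervals: Sequence[tuple[str, float, float]] = DEFAULT_SURVIVAL_INTERVALS,
    min_patients: int = 3,
) -> dict[str, dict[str, object]]:
    """Assign each patient's survival rate to a survival-rate interval.

    Intervals are scanned top-down and a rate joins the first interval
    whose lower bound it reaches (so a rate of 81 belongs to "100%-81%"
    and 80.5 to "80%-61%"); the bottom interval catches everything in
    (0, low).  Intervals holding fewer than ``min_patients`` patients are
    flagged ineligible for within-tissue averaging.
    """
    out: dict[str, dict[str, object]] = {
        label: {"patients": [], "eligible": False, "low": low, "high": high}
        for label, low, high in intervals
    }
    for patient_id, rate in patients:
        if not 0.0 < rate <= 100.0:
            raise ValidationError(
                f"survival rate {rate} for {patient_id} outside (0, 100]"
            )
        for label, low, high in intervals:
            if rate >= low:
                out[label]["patients"].append(patient_id)  # type: ignore[union-attr]
                break
    for label in out:
        out[label]["eligible"] = len(out[label]["patients"]) >= min_patients  # type: ignore[arg-type]
    return out
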