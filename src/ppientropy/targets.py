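"""Per-patient therapeutic target counting against an entropy goal.

The cohort-level regression of entropy on 5-year survival defines the
entropy associated with 100% survival (the line evaluated at X = 100).
For each patient the top-20 hubs of the baseline subnetwork are ranked
once, then removed cumulatively (top-1, top-2, ...); the number of targets
prescribed is the smallest n whose post-removal entropy is at or below the
goal.  Patients whose baseline entropy already meets the goal need zero
targets; patients not reaching it within 20 removals are reported as
"unreached" rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import Subnetwork, degree_distribution, rank_hubs, shannon_entropy
from .perturbation import remove_nodes
from .survival import RegressionResult, entropy_survival_regression

__all__ = [
    "TargetPlan",
    "CohortTargetSummary",
    "entropy_goal_full_survival",
    "targets_needed",
    "cohort_target_summary",
]


@dataclass(frozen=True)
class TargetPlan:
    """Cumulative hub-removal trajectory and the prescribed target count.

    ``n_required`` is None when the goal is not reached within ``max_n``
    removals ("unreached"); ``targets`` then stays empty.
    """

    patient_id: str
    h_goal: float
    baseline_h: float
    trajectory: tuple[tuple[int, float], ...]
    n_required: int | None
    targets: tuple[str, ...]
    emptied_at: int | None = None

    @property
    def unreached(self) -> bool:
        return self.n_required is None


@dataclass(frozen=True)
class CohortTargetSummary:
    per_cohort: pd.DataFrame = field(repr=False)
    regression: RegressionResult | None = None
    notice: str | None = None


def entropy_goal_full_survival(reg: RegressionResult) -> float:
    """Entropy on the fitted line at 100% five-year survival.

    A non-negative slope makes the goal an upper rather than lower bound
    on cohort entropies (every n_required collapses to 0); this is
    permitted but warned about.
    """
    if reg.slope >= 0:
        warnings.warn(
            "regression slope is non-negative; the 100%-survival entropy goal "
            "may exceed every baseline entropy",
            stacklevel=2,
        )
    return reg.intercept + reg.slope * 100.0


def targets_needed(sub: Subnetwork, h_goal: float, max_n: int = 20) -> TargetPlan:
    """Count cumulative top-hub removals needed to reach ``h_goal``.

    The ranking is frozen from the baseline subnetwork (hubs are not
    re-ranked between removals); each trajectory point removes the first n
    ranked nodes from the baseline graph.  An emptied subnetwork scores
    entropy 0 (goal trivially reached) and is flagged via ``emptied_at``.
    """
    if max_n < 1:
        raise ValidationError("max_n must be >= 1")
    if sub.n_nodes == 0:
        raise ValidationError("subnetwork is empty")
    baseline_h = shannon_entropy(degree_distribution(sub)).H
    ranking = [acc for acc, _ in rank_hubs(sub, max_n)]
    trajectory: list[tuple[int, float]] = []
    emptied_at: int | None = None
    for n in range(1, len(ranking) + 1):
        remaining = remove_nodes(sub, set(ranking[:n]))
        if remaining.n_nodes == 0:
            h_n = 0.0
            if emptied_at is None:
                emptied_at = n
        else:
            h_n = shannon_entropy(degree_distribution(remaining)).H
        trajectory.append((n, h_n))

    if baseline_h <= h_goal:
        n_required: int | None = 0
    else:
        n_required = next((n for n, h in trajectory if h <= h_goal), None)
    targets = tuple(ranking[:n_required]) if n_required else ()
    return TargetPlan(
        patient_id=sub.patient_id,
        h_goal=float(h_goal),
        baseline_h=float(baseline_h),
        trajectory=tuple(trajectory),
        n_required=n_required,
        targets=targets,
        emptied_at=emptied_at,
    )


def cohort_target_summary(
    plans: Sequence[TargetPlan],
    cohorts: Sequence[str],
    survival_rates: dict[str, float],
    max_n: int = 20,
) -> CohortTargetSummary:
    """Mean prescribed target count per cohort, regressed on 5-year survival.

    Unreached plans are counted at ``max_n`` (a lower bound on their true
    need) and tallied in the ``n_unreached`` column.  The regression reuses
    the entropy-survival OLS machinery on (survival %, mean n_required).
    """
    if len(plans) != len(cohorts):
        raise ValidationError("plans and cohorts must align")
    frame = pd.DataFrame(
        {
            "cohort": list(cohorts),
            "n_required": [
                max_n if p.unreached else int(p.n_required)  # type: ignore[arg-type]
                for p in plans
            ],
            "unreached": [p.unreached for p in plans],
        }
    )
    per_cohort = (
        frame.groupby("cohort")
        .agg(
            mean_n_required=("n_required", "mean"),
            n_patients=("n_required", "size"),
            n_unreached=("unreached", "sum"),
        )
        .reset_index()
    )
    per_cohort["survival_pct"] = per_cohort["cohort"].map(survival_rates)
    if len(per_cohort) < 3:
        raise ValidationError("need at least 3 cohorts for a target summary")
    points = list(zip(per_cohort["survival_pct"], per_cohort["mean_n_required"]))
    try:
        regression = entropy_survival_regression(points)
        notice = None
    except Exception as exc:  # degenerate inputs surface as a notice
        regression = None
        notice = f"target regression skipped: {exc}"
    return CohortTargetSummary(per_cohort=per_cohort, regression=regression, notice=notice)
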