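"""Cohort- and patient-level orchestration of the entropy pipeline.

``run_patient`` executes the per-patient chain: differential expression ->
frequency histogram -> Gaussian bulk fit -> up-regulation call -> induced
PPI subnetwork -> degree-distribution entropy -> hub ranking (top-10 and
top-20) -> random-removal null test.  ``run_cohort`` adds the cohort
layer: mean/SD entropies, Kaplan-Meier 5-year rates, Kruskal-Wallis and
pairwise rank tests, the entropy-survival regression, the 100%-survival
entropy goal and per-patient target plans, plus a within-tissue
survival-interval analysis for cohorts with enough patients per interval.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .errors import (
    DegenerateDistributionError,
    EmptySubnetworkError,
    FitError,
    PipelineError,
    ValidationError,
)
from .network import (
    Subnetwork,
    degree_distribution,
    induce_subnetwork,
    rank_hubs,
    shannon_entropy,
)
from .perturbation import random_removal_null
from .survival import (
    DEFAULT_SURVIVAL_INTERVALS,
    FIVE_YEARS_DAYS,
    GroupComparison,
    RegressionResult,
    bin_patients_by_survival,
    entropy_survival_regression,
    km_curve,
    kruskal_wallis,
    pairwise_rank_tests,
    survival_rate_at,
)
from .targets import (
    CohortTargetSummary,
    TargetPlan,
    cohort_target_summary,
    entropy_goal_full_survival,
    targets_needed,
)
from .upregulation import (
    build_histogram,
    differential_profile,
    fit_gaussian_threshold,
    select_upregulated,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PatientReport", "CohortReport", "run_patient", "run_cohort"]

#: cohorts below this many paired patients are flagged (but still processed)
MIN_COHORT_PATIENTS = 30


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a run; serializable to/from a YAML config file."""

    expression: str = ""
    sample_sheet: str = ""
    mapping: str = ""
    interactome: str = ""
    clinical: str = ""
    alpha: float = 0.05
    n_bins: int = 100
    null_reps: int = 1000
    null_remove: int = 5
    max_targets: int = 20
    five_years_days: float = FIVE_YEARS_DAYS
    correction: str = "holm"
    seed: int = 0
    goal_mode: str = "all-cohort"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValidationError("alpha must lie in (0, 0.5)")
        if self.n_bins < 10 or self.null_reps < 1 or self.null_remove < 1:
            raise ValidationError("n_bins/null_reps/null_remove out of range")
        if self.max_targets < 1 or self.five_years_days <= 0:
            raise ValidationError("max_targets/five_years_days out of range")
        if self.goal_mode not in {"all-cohort", "within-tissue"}:
            raise ValidationError(f"unknown goal_mode {self.goal_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )


@dataclass(frozen=True)
class PatientReport:
    """Every per-patient intermediate the report writer needs."""

    patient_id: str
    n_upregulated: int
    n_proteins: int
    subnetwork_nodes: int
    subnetwork_edges: int
    entropy: float
    top10: tuple[tuple[str, int], ...]
    top20: tuple[tuple[str, int], ...]
    empirical_p: float
    fit_mu: float
    fit_sigma: float
    fit_threshold: float
    fit_converged: bool
    flags: tuple[str, ...] = ()
    subnetwork: Subnetwork | None = field(default=None, repr=False, compare=False)

    @property
    def flagged_empty(self) -> bool:
        return "empty_subnetwork" in self.flags


@dataclass(frozen=True)
class CohortReport:
    patients: tuple[PatientReport, ...]
    cohort_of: Mapping[str, str]
    cohort_stats: pd.DataFrame = field(repr=False)
    comparison: GroupComparison | None
    regression: RegressionResult | None
    h_goal: float | None
    target_plans: tuple[TargetPlan, ...]
    target_summary: CohortTargetSummary | None
    within_tissue: Mapping[str, RegressionResult]
    notices: tuple[str, ...] = ()


def run_patient(
    config: RunConfig,
    pair: pio.PatientPair,
    interactome,
    idmap: pio.IdMap,
) -> PatientReport:
    """Run the full per-patient chain; failures become flags, not aborts."""
    flags: list[str] = []
    profile = differential_profile(pair)
    try:
        hist = build_histogram(profile, n_bins=config.n_bins)
        fit = fit_gaussian_threshold(hist, alpha=config.alpha)
    except (DegenerateDistributionError, FitError) as exc:
        logger.warning("patient %s: %s", pair.patient_id, exc)
        return PatientReport(
            patient_id=pair.patient_id,
            n_upregulated=0,
            n_proteins=0,
            subnetwork_nodes=0,
            subnetwork_edges=0,
            entropy=float("nan"),
            top10=(),
            top20=(),
            empirical_p=float("nan"),
            fit_mu=float("nan"),
            fit_sigma=float("nan"),
            fit_threshold=float("nan"),
            fit_converged=False,
            flags=("degenerate_profile",),
        )
    if not fit.converged:
        flags.append("fit_fallback")
    upset = select_upregulated(profile, fit, idmap)

    sub: Subnetwork | None = None
    entropy = float("nan")
    top10: tuple = ()
    top20: tuple = ()
    empirical_p = float("nan")
    if not upset.proteins:
        flags.append("empty_subnetwork")
    else:
        try:
            sub = induce_subnetwork(interactome, upset.proteins, pair.patient_id)
        except EmptySubnetworkError:
            flags.append("empty_subnetwork")
        else:
            entropy = shannon_entropy(degree_distribution(sub)).H
            top10 = tuple(rank_hubs(sub, 10))
            top20 = tuple(rank_hubs(sub, 20))
            if sub.n_nodes > config.null_remove:
                null = random_removal_null(
                    sub,
                    n_remove=config.null_remove,
                    reps=config.null_reps,
                    seed=config.seed,
                )
                empirical_p = null.empirical_p
            else:
                flags.append("subnetwork_too_small_for_null")
    return PatientReport(
        patient_id=pair.patient_id,
        n_upregulated=len(upset.genes),
        n_proteins=len(upset.proteins),
        subnetwork_nodes=0 if sub is None else sub.n_nodes,
        subnetwork_edges=0 if sub is None else sub.n_edges,
        entropy=entropy,
        top10=top10,
        top20=top20,
        empirical_p=empirical_p,
        fit_mu=fit.mu,
        fit_sigma=fit.sigma,
        fit_threshold=fit.threshold,
        fit_converged=fit.converged,
        flags=tuple(flags),
        subnetwork=sub,
    )


def run_cohort(
    config: RunConfig,
    pairs: Sequence[pio.PatientPair],
    interactome,
    idmap: pio.IdMap,
    clinical: pd.DataFrame,
) -> CohortReport:
    """Cohort-level analysis over per-patient runs.

    Cohort membership comes from the clinical table.  Cohorts with fewer
    than 30 paired patients are flagged but processed; with fewer than 3
    cohorts the cross-cohort regression is skipped with a notice and all
    other outputs are still produced.
    """
    notices: list[str] = []
    cohort_of = dict(zip(clinical["patient_id"], clinical["cohort"]))
    missing = [p.patient_id for p in pairs if p.patient_id not in cohort_of]
    if missing:
        raise ValidationError(
            f"patients absent from clinical table: {', '.join(missing[:5])}"
        )

    reports = [run_patient(config, pair, interactome, idmap) for pair in pairs]
    by_cohort: dict[str, list[PatientReport]] = {}
    for rep in reports:
        by_cohort.setdefault(cohort_of[rep.patient_id], []).append(rep)

    curves = {}
    stats_rows = []
    for cohort in sorted(by_cohort):
        reps = by_cohort[cohort]
        entropies = [r.entropy for r in reps if np.isfinite(r.entropy)]
        records = clinical[clinical["cohort"] == cohort]
        curves[cohort] = km_curve(records)
        rate = survival_rate_at(curves[cohort], config.five_years_days)
        if len(reps) < MIN_COHORT_PATIENTS:
            notices.append(f"cohort {cohort}: below-30 paired patients ({len(reps)})")
        stats_rows.append(
            {
                "cohort": cohort,
                "n_patients": len(reps),
                "mean_entropy": float(np.mean(entropies)) if entropies else float("nan"),
                "sd_entropy": float(np.std(entropies, ddof=1))
                if len(entropies) > 1
                else float("nan"),
                "survival_5y_pct": rate,
                "below_30": len(reps) < MIN_COHORT_PATIENTS,
            }
        )
    cohort_stats = pd.DataFrame(stats_rows)

    groups = [
        [r.entropy for r in by_cohort[c] if np.isfinite(r.entropy)]
        for c in sorted(by_cohort)
    ]
    labels = sorted(by_cohort)
    comparison: GroupComparison | None = None
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        comparison = kruskal_wallis(groups, labels)
        pairwise = pairwise_rank_tests(groups, labels, correction=config.correction)
        comparison = GroupComparison(
            kw_statistic=comparison.kw_statistic,
            kw_df=comparison.kw_df,
            kw_p=comparison.kw_p,
            pairwise_p=pairwise,
        )
    else:
        notices.append("group comparison skipped: need >= 2 cohorts of >= 2 patients")

    regression: RegressionResult | None = None
    if len(labels) >= 3:
        points = [
            (row["survival_5y_pct"], row["mean_entropy"])
            for _, row in cohort_stats.iterrows()
            if np.isfinite(row["mean_entropy"])
        ]
        try:
            regression = entropy_survival_regression(points)
        except (ValidationError, DegenerateDistributionError) as exc:
            notices.append(f"entropy-survival regression skipped: {exc}")
    else:
        notices.append("entropy-survival regression skipped: fewer than 3 cohorts")

    # within-tissue interval analysis (per-patient KM lookup, interval means)
    within_tissue: dict[str, RegressionResult] = {}
    time_of = dict(zip(clinical["patient_id"], clinical["time_days"]))
    for cohort in labels:
        curve = curves[cohort]
        rated = [
            (r.patient_id, survival_rate_at(curve, time_of[r.patient_id]))
            for r in by_cohort[cohort]
            if np.isfinite(r.entropy)
        ]
        rated = [(pid, max(rate, 1e-9)) for pid, rate in rated]
        bins = bin_patients_by_survival(rated)
        main = [lab for lab, _, _ in DEFAULT_SURVIVAL_INTERVALS[:4]]
        if not all(bins[lab]["eligible"] for lab in main):
            continue
        entropy_of = {r.patient_id: r.entropy for r in by_cohort[cohort]}
        rate_of = dict(rated)
        points = []
        for lab in main:
            members = bins[lab]["patients"]
            points.append(
                (
                    float(np.mean([rate_of[m] for m in members])),
                    float(np.mean([entropy_of[m] for m in members])),
                )
            )
        try:
            within_tissue[cohort] = entropy_survival_regression(points)
        except (ValidationError, DegenerateDistributionError) as exc:
            notices.append(f"within-tissue regression skipped for {cohort}: {exc}")

    h_goal: float | None = None
    if regression is not None:
        h_goal = entropy_goal_full_survival(regression)

    plans: list[TargetPlan] = []
    plan_cohorts: list[str] = []
    if h_goal is not None:
        for rep in reports:
            if rep.subnetwork is None:
                continue
            cohort = cohort_of[rep.patient_id]
            goal = h_goal
            if config.goal_mode == "within-tissue" and cohort in within_tissue:
                goal = entropy_goal_full_survival(within_tissue[cohort])
            plans.append(targets_needed(rep.subnetwork, goal, max_n=config.max_targets))
            plan_cohorts.append(cohort)

    target_summary: CohortTargetSummary | None = None
    if plans and len(set(plan_cohorts)) >= 3:
        rates = dict(zip(cohort_stats["cohort"], cohort_stats["survival_5y_pct"]))
        target_summary = cohort_target_summary(
            plans, plan_cohorts, rates, max_n=config.max_targets
        )
    elif h_goal is not None:
        notices.append("target summary skipped: fewer than 3 cohorts with plans")

    return CohortReport(
        patients=tuple(reports),
        cohort_of=cohort_of,
        cohort_stats=cohort_stats,
        comparison=comparison,
        regression=regression,
        h_goal=h_goal,
        target_plans=tuple(plans),
        target_summary=target_summary,
        within_tissue=within_tissue,
        notices=tuple(notices),
    )


def patient_report_rows(
    report: CohortReport, plans_by_patient: Mapping[str, TargetPlan] | None = None
) -> list[dict[str, object]]:
    """Flatten a CohortReport into rows for :func:`io.write_patient_report`."""
    if plans_by_patient is None:
        plans_by_patient = {p.patient_id: p for p in report.target_plans}
    rows = []
    for rep in report.patients:
        plan = plans_by_patient.get(rep.patient_id)
        if plan is None:
            n_targets: object = "NA"
        elif plan.unreached:
            n_targets = "unreached"
        else:
            n_targets = plan.n_required
        rows.append(
            {
                "patient_id": rep.patient_id,
                "cohort": report.cohort_of.get(rep.patient_id, "NA"),
                "n_upregulated": rep.n_upregulated,
                "n_proteins": rep.n_proteins,
                "subnetwork_nodes": rep.subnetwork_nodes,
                "subnetwork_edges": rep.subnetwork_edges,
                "entropy": rep.entropy,
                "top_hubs": ";".join(acc for acc, _ in rep.top10),
                "empirical_p": rep.empirical_p,
                "n_targets": n_targets,
                "flags": ";".join(rep.flags) if rep.flags else "",
                "hub_ranking": list(rep.top20),
            }
        )
    return rows
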