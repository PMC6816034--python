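"""Synthetic interactomes, paired expression cohorts and survival records.

The generator emulates the statistical structure the analysis assumes so
that every stage runs without any external download:

* a scale-free interactome (Barabasi-Albert preferential attachment) over
  accessions ``P000001...``;
* paired tumor/control expression whose differential distribution is an
  approximately Gaussian bulk (N(0, bulk_sigma)) plus a planted
  up-regulated tail shifted by ``effect_size``, with planted genes sampled
  with probability proportional to interactome degree so induced
  subnetworks contain hubs;
* censored exponential survival times whose true 5-year survival follows a
  negative linear link from cohort mean entropy.

Everything is a pure function of :class:`SyntheticSpec` (bit-identical
outputs per seed), and ``write_dataset`` emits exactly the file formats
the readers in :mod:`ppientropy.io` consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionTable, IdMap
from .survival import FIVE_YEARS_DAYS

__all__ = [
    "SyntheticSpec",
    "CohortData",
    "generate_interactome",
    "generate_paired_cohort",
    "generate_survival_records",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic generator.

    Defaults are desk-scale: 2,000 proteins and genes, 9 cohorts of 30
    paired patients (matching the minimum-30-paired-patients cohort rule),
    a unit-variance differential bulk with planted effects at 5 sigma, and
    a survival link mirroring an entropy-on-survival line of slope -0.004
    and intercept 2.507 (survival % = (2.507 - H) / 0.004, clamped to
    (1, 99)).  ``cohort_planted_spread`` scales the planted fraction from
    0.5x (first cohort) to 1.5x (last), so cohorts differ in subnetwork
    size and entropy.
    """

    seed: int = 0
    n_proteins: int = 2000
    attachment: int = 2
    n_genes: int = 2000
    n_patients_per_cohort: int = 30
    n_cohorts: int = 9
    planted_fraction: float = 0.02
    effect_size: float = 5.0
    bulk_sigma: float = 1.0
    survival_link: tuple[float, float] = (-250.0, 626.75)
    censoring_rate: float = 0.2
    degree_weighted_planting: bool = True
    cohort_planted_spread: float = 0.5

    def __post_init__(self) -> None:
        counts = (
            self.n_proteins,
            self.attachment,
            self.n_genes,
            self.n_patients_per_cohort,
            self.n_cohorts,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if not 0.0 < self.planted_fraction <= 0.2:
            raise ValidationError("planted_fraction must lie in (0, 0.2]")
        if self.bulk_sigma <= 0:
            raise ValidationError("bulk_sigma must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if self.n_genes > self.n_proteins:
            raise ValidationError("n_genes cannot exceed n_proteins (one protein per gene)")

    def cohort_labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_cohorts)]

    def patient_ids(self, cohort: str) -> list[str]:
        return [f"{cohort}-{i + 1:03d}" for i in range(self.n_patients_per_cohort)]


class CohortData(NamedTuple):
    """Everything generate_paired_cohort returns."""

    expression: ExpressionTable
    sample_sheet: pd.DataFrame
    idmap: IdMap
    planted_truth: dict[str, frozenset[str]]
    patient_cohorts: dict[str, str]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, stream])
    )


def generate_interactome(spec: SyntheticSpec) -> nx.Graph:
    """Barabasi-Albert graph with ``attachment`` edges per arriving node.

    The construction starts from a star on ``attachment + 1`` nodes, so the
    edge count is exactly ``attachment * (n_proteins - attachment)``.
    """
    if spec.n_proteins <= spec.attachment:
        raise ValidationError("n_proteins must exceed attachment")
    raw = nx.barabasi_albert_graph(
        spec.n_proteins, spec.attachment, seed=_rng(spec, 1)
    )
    return nx.relabel_nodes(raw, {i: f"P{i + 1:06d}" for i in raw.nodes})


def generate_paired_cohort(
    spec: SyntheticSpec, interactome: nx.Graph
) -> CohortData:
    """Paired tumor/control expression with degree-biased planted genes.

    Controls draw a log-normal baseline (RSEM-like scale); tumor values add
    N(0, bulk_sigma) noise, plus ``effect_size`` for each patient's planted
    set.  Gene ``G00001``... maps one-to-one onto a seeded permutation of
    interactome proteins.  Values are floored at 0 to respect the
    expression-table invariant (the floor is hit with negligible
    probability at the default baseline scale).
    """
    rng = _rng(spec, 2)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    proteins = sorted(interactome.nodes)
    assignment = rng.permutation(len(proteins))[: spec.n_genes]
    entries = {g: proteins[j] for g, j in zip(genes, assignment)}
    idmap = IdMap(entries=entries)

    degrees = np.array(
        [interactome.degree(entries[g]) for g in genes], dtype=float
    )
    if spec.degree_weighted_planting:
        plant_p = degrees / degrees.sum()
    else:
        plant_p = np.full(spec.n_genes, 1.0 / spec.n_genes)

    labels = spec.cohort_labels()
    spread = (
        np.linspace(
            1.0 - spec.cohort_planted_spread,
            1.0 + spec.cohort_planted_spread,
            spec.n_cohorts,
        )
        if spec.n_cohorts > 1
        else np.array([1.0])
    )

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[tuple[str, str, str]] = []
    truth: dict[str, frozenset[str]] = {}
    patient_cohorts: dict[str, str] = {}
    for c_idx, cohort in enumerate(labels):
        n_planted = int(round(spec.planted_fraction * spread[c_idx] * spec.n_genes))
        n_planted = max(1, min(n_planted, spec.n_genes))
        for patient_id in spec.patient_ids(cohort):
            control = rng.lognormal(mean=4.0, sigma=1.0, size=spec.n_genes)
            delta = rng.normal(0.0, spec.bulk_sigma, size=spec.n_genes)
            planted_idx = rng.choice(
                spec.n_genes, size=n_planted, replace=False, p=plant_p
            )
            delta[planted_idx] += spec.effect_size
            tumor = np.maximum(control + delta, 0.0)
            t_id, c_id = f"{patient_id}-T", f"{patient_id}-N"
            columns[t_id] = tumor
            columns[c_id] = control
            sheet_rows.append((patient_id, t_id, c_id))
            truth[patient_id] = frozenset(genes[i] for i in planted_idx)
            patient_cohorts[patient_id] = cohort

    expression = ExpressionTable(
        values=pd.DataFrame(columns, index=genes, dtype=float)
    )
    sheet = pd.DataFrame(
        sheet_rows, columns=["patient_id", "tumor_sample", "control_sample"]
    )
    return CohortData(expression, sheet, idmap, truth, patient_cohorts)


def generate_survival_records(
    spec: SyntheticSpec, cohort_entropies: list[float]
) -> pd.DataFrame:
    """Censored exponential survival per cohort, linked to mean entropy.

    The true five-year survival of cohort c is ``slope * H_c + intercept``
    (clamped to (1, 99) percent); event times are exponential with the rate
    solving S(1825 days) = that value.  With probability
    ``censoring_rate`` a record is censored uniformly before its event.
    Returns a DataFrame with patient_id, event, time_days, cohort.
    """
    slope, intercept = spec.survival_link
    if slope >= 0:
        raise ValidationError("survival_link slope must be negative")
    if len(cohort_entropies) != spec.n_cohorts:
        raise ValidationError("one entropy per cohort required")
    rng = _rng(spec, 3)
    rows = []
    for cohort, h in zip(spec.cohort_labels(), cohort_entropies):
        surv_pct = float(np.clip(slope * h + intercept, 1.0, 99.0))
        rate = -math.log(surv_pct / 100.0) / FIVE_YEARS_DAYS
        for patient_id in spec.patient_ids(cohort):
            t_event = rng.exponential(1.0 / rate)
            if rng.uniform() < spec.censoring_rate:
                time = rng.uniform(0.0, t_event)
                event = 0
            else:
                time, event = t_event, 1
            rows.append((patient_id, event, max(time, 0.5), cohort))
    return pd.DataFrame(
        rows, columns=["patient_id", "event", "time_days", "cohort"]
    )


def write_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full dataset and write it in the pipeline's input formats.

    Emits expression.tsv, sample_sheet.tsv, mapping.tsv, interactome.mitab
    (a minimal 15-column PSI-MITAB with uniprotkb ids and human taxids) and
    clinical.tsv.  The clinical link uses per-cohort pseudo-entropies spread
    over the range the desk-scale pipeline produces; the measured
    entropy-survival association then emerges from the analysis itself.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    interactome = generate_interactome(spec)
    data = generate_paired_cohort(spec, interactome)

    expr_path = out_dir / "expression.tsv"
    frame = data.expression.values
    with expr_path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(frame.columns) + "\n")
        for gene, row in zip(frame.index, frame.to_numpy()):
            fh.write(gene + "\t" + "\t".join(format(v, ".6f") for v in row) + "\n")

    sheet_path = out_dir / "sample_sheet.tsv"
    data.sample_sheet.to_csv(sheet_path, sep="\t", index=False)

    map_path = out_dir / "mapping.tsv"
    with map_path.open("w", encoding="utf-8") as fh:
        fh.write("symbol\taccession\n")
        for gene in sorted(data.idmap.entries):
            fh.write(f"{gene}\t{data.idmap.entries[gene]}\n")

    mitab_path = out_dir / "interactome.mitab"
    filler = ["-"] * 7
    with mitab_path.open("w", encoding="utf-8") as fh:
        fh.write("#ID(A)\tID(B)\t" + "\t".join(f"col{i}" for i in range(3, 16)) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in interactome.edges):
            fields = (
                [f"uniprotkb:{a}", f"uniprotkb:{b}"]
                + filler
                + ["taxid:9606(human)", "taxid:9606(human)"]
                + ["-"] * 4
            )
            fh.write("\t".join(fields) + "\n")

    # pseudo-entropies spaced over a desk-scale range; the analysis measures
    # the realised association from the data, not from these inputs
    pseudo_h = list(np.linspace(2.1, 2.5, spec.n_cohorts))
    clinical = generate_survival_records(spec, pseudo_h)
    clin_path = out_dir / "clinical.tsv"
    with clin_path.open("w", encoding="utf-8") as fh:
        fh.write("patient_id\tOS\tOS.time\tcohort\n")
        for row in clinical.itertuples(index=False):
            fh.write(
                f"{row.patient_id}\t{row.event}\t{row.time_days:.2f}\t{row.cohort}\n"
            )

    return {
        "expression": expr_path,
        "sample_sheet": sheet_path,
        "mapping": map_path,
        "interactome": mitab_path,
        "clinical": clin_path,
    }
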