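"""Readers and writers for every external format the pipeline touches.

Expression tables follow the TCGA RNASeqV2/RSEM layout (tab-separated, gene
identifier first, one column per sample); ``SYMBOL|ENTREZ`` identifiers are
truncated at the first ``|``.  The interactome is read from PSI-MITAB
(IntAct-style), keeping only human (taxid 9606) interactions where both
interactors carry a UniProtKB accession.  Clinical tables use the TCGA-CDR
convention: an ``OS`` event flag (1 = death, 0 = censored) and ``OS.time``
in days.  All text I/O is UTF-8, tab-separated, with "." as the decimal
mark, so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ResolutionError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "PatientPair",
    "IdMap",
    "read_expression_table",
    "read_sample_pairs",
    "read_id_mapping",
    "read_interactome_mitab",
    "read_clinical_table",
    "write_patient_report",
    "write_interactome_edgelist",
    "read_interactome_edgelist",
    "write_subnetwork_graphml",
]


@dataclass(frozen=True)
class ExpressionTable:
    """Genes x samples matrix of non-negative normalized expression."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene symbols: {', '.join(map(str, dupes[:5]))}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, sample: str) -> pd.Series:
        if sample not in self.values.columns:
            raise ResolutionError(f"sample not in table: {sample}")
        return self.values[sample]


@dataclass(frozen=True)
class PatientPair:
    """One patient's tumor and control vectors over the same gene universe."""

    patient_id: str
    tumor: pd.Series = field(repr=False)
    control: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.tumor.index) != list(self.control.index):
            raise ValidationError(
                f"patient {self.patient_id}: tumor/control gene universes differ"
            )


@dataclass(frozen=True)
class IdMap:
    """One-to-one gene symbol -> protein accession mapping."""

    entries: Mapping[str, str]
    n_duplicates_dropped: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, symbol: str) -> str | None:
        return self.entries.get(symbol)


def _truncate_symbol(raw: str) -> str:
    """TCGA-style 'SYMBOL|ENTREZ' -> 'SYMBOL'; bare symbols pass through."""
    return raw.split("|", 1)[0]


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TCGA-style expression TSV (header row, gene column first)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header has no sample columns")
        samples = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    f"{path} line {lineno}: expected {len(samples) + 1} fields, "
                    f"got {len(fields)}"
                )
            genes.append(_truncate_symbol(fields[0]))
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-numeric value ({exc})")
    frame = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionTable(values=frame)


def read_sample_pairs(table: ExpressionTable, sheet: str | Path) -> list[PatientPair]:
    """Resolve a patient_id/tumor_sample/control_sample sheet against a table."""
    frame = pd.read_csv(sheet, sep="\t", dtype=str)
    required = {"patient_id", "tumor_sample", "control_sample"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ParseError(f"{sheet}: missing columns {sorted(missing_cols)}")
    pairs: list[PatientPair] = []
    for row in frame.itertuples(index=False):
        for sample in (row.tumor_sample, row.control_sample):
            if sample not in table.values.columns:
                raise ResolutionError(
                    f"sample {sample!r} (patient {row.patient_id}) absent from table"
                )
        pairs.append(
            PatientPair(
                patient_id=str(row.patient_id),
                tumor=table.vector(row.tumor_sample),
                control=table.vector(row.control_sample),
            )
        )
    return pairs


def read_id_mapping(path: str | Path) -> IdMap:
    """Two-column TSV (symbol, accession); first occurrence wins."""
    entries: dict[str, str] = {}
    n_dupes = 0
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path} line {lineno}: expected 2 columns")
            symbol, accession = fields[0].strip(), fields[1].strip()
            if lineno == 1 and symbol.lower() in {"symbol", "gene", "genesymbol"}:
                continue
            if not accession:
                raise ValidationError(f"{path} line {lineno}: empty accession")
            if symbol in entries:
                n_dupes += 1
                continue
            entries[symbol] = accession
    if not entries:
        raise ValidationError(f"{path}: no mapping entries")
    if n_dupes:
        logger.warning("%s: dropped %d duplicate symbol row(s)", path, n_dupes)
    return IdMap(entries=entries, n_duplicates_dropped=n_dupes)


def _mitab_uniprot(fieldtext: str) -> str | None:
    for token in fieldtext.split("|"):
        if token.startswith("uniprotkb:"):
            acc = token.split(":", 1)[1].strip()
            if acc:
                return acc
    return None


def _mitab_is_human(fieldtext: str) -> bool:
    for token in fieldtext.split("|"):
        if not token.startswith("taxid:"):
            continue
        taxid = token.split(":", 1)[1].split("(", 1)[0].strip()
        if taxid == "9606":
            return True
    return False


def read_interactome_mitab(path: str | Path) -> nx.Graph:
    """Build an undirected simple interactome from a PSI-MITAB file.

    Rows survive only if both interactors carry a ``uniprotkb:`` accession
    and both taxon columns are human (taxid 9606).  Self-interactions are
    dropped and duplicate pairs collapse to one undirected edge.  Skipped
    row counts land in ``graph.graph['n_skipped']``.
    """
    path = Path(path)
    graph = nx.Graph()
    n_skipped = 0
    try:
        fh = path.open("r", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read MITAB file {path}: {exc}") from exc
    with fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                n_skipped += 1
                continue
            a = _mitab_uniprot(fields[0])
            b = _mitab_uniprot(fields[1])
            if a is None or b is None:
                n_skipped += 1
                continue
            if not (_mitab_is_human(fields[9]) and _mitab_is_human(fields[10])):
                n_skipped += 1
                continue
            if a == b:
                n_skipped += 1
                continue
            if graph.has_edge(a, b):
                n_skipped += 1  # duplicate pair collapses to one edge
                continue
            graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValidationError(f"{path}: no human UniProtKB interaction survived")
    if n_skipped:
        logger.info("%s: skipped %d MITAB row(s)", path, n_skipped)
    graph.graph["n_skipped"] = n_skipped
    return graph


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """TSV with patient_id, OS, OS.time, cohort -> validated DataFrame.

    Returned columns: patient_id (str), event (int 0/1), time_days (float),
    cohort (str).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "cohort": str})
    required = {"patient_id", "OS", "OS.time", "cohort"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "patient_id": frame["patient_id"].astype(str),
            "event": frame["OS"],
            "time_days": frame["OS.time"].astype(float),
            "cohort": frame["cohort"].astype(str),
        }
    )
    bad_event = ~out["event"].isin([0, 1])
    if bad_event.any():
        row = int(np.flatnonzero(bad_event.to_numpy())[0]) + 2
        raise ValidationError(f"{path} row {row}: OS must be 0 or 1")
    bad_time = ~(out["time_days"] > 0)
    if bad_time.any():
        row = int(np.flatnonzero(bad_time.to_numpy())[0]) + 2
        raise ValidationError(f"{path} row {row}: OS.time must be > 0")
    out["event"] = out["event"].astype(int)
    return out


def _fmt(value: object) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return format(value, ".6g")
    if value is None:
        return "NA"
    return str(value)


_REPORT_COLUMNS = (
    "patient_id",
    "cohort",
    "n_upregulated",
    "n_proteins",
    "subnetwork_nodes",
    "subnetwork_edges",
    "entropy",
    "top_hubs",
    "empirical_p",
    "n_targets",
    "flags",
)


def write_patient_report(report: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write per-patient results as a TSV plus a JSON sidecar.

    The TSV carries one row per patient in input order; the JSON sidecar
    (same stem, ``.json``) holds the full hub rankings.  Output is
    deterministic given the report.
    """
    path = Path(path)
    lines = ["\t".join(_REPORT_COLUMNS)]
    for rec in report:
        lines.append("\t".join(_fmt(rec.get(col, "NA")) for col in _REPORT_COLUMNS))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {
        str(rec.get("patient_id", "")): {
            "hub_ranking": [list(t) for t in rec.get("hub_ranking", [])]
        }
        for rec in report
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_interactome_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Canonical (sorted) two-column edge list; round-trips exactly."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    Path(path).write_text(
        "".join(f"{a}\t{b}\n" for a, b in edges), encoding="utf-8"
    )


def read_interactome_edgelist(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path} line {lineno}: expected 2 columns")
            if fields[0] != fields[1]:
                graph.add_edge(fields[0], fields[1])
    return graph


def write_subnetwork_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
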