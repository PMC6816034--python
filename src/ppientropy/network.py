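"""Per-patient PPI subnetworks and their degree-distribution Shannon entropy.

A patient's subnetwork is the edge-induced subgraph of the human interactome
on the proteins encoded by that patient's up-regulated genes: only edges with
both endpoints in the protein set are kept, and proteins left without any
partner inside the set are excluded.  Complexity of the subnetwork is
summarised by the Shannon entropy of its degree distribution,

    H = - sum_k p(k) * log2 p(k),

where p(k) is the fraction of subnetwork nodes with exactly k incident edges.
H is measured in bits and depends only on the proportions p(k), never on the
absolute node count, so subnetworks of very different sizes are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import EmptySubnetworkError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Subnetwork",
    "DegreeDistribution",
    "EntropyResult",
    "induce_subnetwork",
    "degree_distribution",
    "shannon_entropy",
    "entropy_from_degrees",
    "rank_hubs",
]


@dataclass(frozen=True)
class Subnetwork:
    """An undirected simple graph over protein accessions.

    Every node has degree >= 1 by construction; isolated proteins are
    dropped at induction time (and counted), because the degree formula
    has no defined probability mass for k = 0.
    """

    graph: nx.Graph
    patient_id: str = ""
    n_isolated_dropped: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def degrees_array(self) -> np.ndarray:
        """Node degrees as an int array (node order is irrelevant for H)."""
        return np.fromiter((d for _, d in self.graph.degree()), dtype=np.int64)


@dataclass(frozen=True)
class DegreeDistribution:
    """The empirical degree distribution p(k) of a subnetwork.

    ``support`` holds the distinct observed degrees in ascending order, so
    p carries no zero entries and the entropy sum never meets a 0*log(0)
    term.
    """

    support: tuple[int, ...]
    p: tuple[float, ...]
    n_nodes: int

    def __post_init__(self) -> None:
        if not self.support:
            raise ValidationError("degree distribution needs a nonempty support")
        total = float(np.sum(self.p))
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"p(k) sums to {total!r}, not 1")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.support, self.p))


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy H (bits) together with the distribution it came from."""

    H: float
    distribution: DegreeDistribution = field(repr=False)


def induce_subnetwork(
    interactome: nx.Graph, proteins: Iterable[str], patient_id: str = ""
) -> Subnetwork:
    """Edge-induce the interactome on ``proteins``.

    Keeps exactly the interactome edges with both endpoints in the protein
    set; proteins without any such edge (including proteins absent from the
    interactome) are excluded and counted in ``n_isolated_dropped``.

    Raises
    ------
    EmptySubnetworkError
        If no edge survives.  Callers running a cohort should catch this
        and flag the patient rather than abort.
    """
    proteins = set(proteins)
    if not proteins:
        raise ValidationError("protein set is empty")
    induced = interactome.subgraph(proteins)
    graph = nx.Graph()
    graph.add_edges_from(induced.edges())
    if graph.number_of_edges() == 0:
        raise EmptySubnetworkError(
            f"no interactome edge has both endpoints in the {len(proteins)} "
            f"proteins of patient {patient_id or '<unnamed>'}"
        )
    n_dropped = len(proteins) - graph.number_of_nodes()
    if n_dropped:
        logger.info(
            "patient %s: dropped %d isolated protein(s) at induction",
            patient_id or "<unnamed>",
            n_dropped,
        )
    return Subnetwork(graph=graph, patient_id=patient_id, n_isolated_dropped=n_dropped)


def degree_distribution(sub: Subnetwork) -> DegreeDistribution:
    """p(k) = (# nodes of degree k) / (# nodes), over observed degrees."""
    if sub.n_nodes == 0:
        raise ValidationError("cannot form p(k) of an empty subnetwork")
    degrees = sub.degrees_array()
    counts = np.bincount(degrees)
    ks = np.nonzero(counts)[0]
    p = counts[ks] / degrees.size
    return DegreeDistribution(
        support=tuple(int(k) for k in ks),
        p=tuple(float(x) for x in p),
        n_nodes=int(degrees.size),
    )


def entropy_from_degrees(degrees: np.ndarray) -> float:
    """H in bits straight from a degree array (fast path shared with nulls).

    Identical summation order to ``shannon_entropy`` (ascending k), so both
    paths produce bit-identical floats for the same graph.
    """
    counts = np.bincount(degrees)
    counts = counts[counts > 0]
    p = counts / degrees.size
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(dist: DegreeDistribution) -> EntropyResult:
    """Shannon entropy H = -sum_k p(k) log2 p(k), in bits.

    No normalisation by network size is applied; H is a function of the
    degree proportions only and is bounded by log2(#distinct degrees).
    """
    p = np.asarray(dist.p)
    h = float(-(p * np.log2(p)).sum())
    # -0.0 can arise from the single-class case; canonicalise.
    return EntropyResult(H=abs(h) if h == 0 else h, distribution=dist)


def rank_hubs(sub: Subnetwork, n: int) -> list[tuple[str, int]]:
    """Top-``n`` nodes by subnetwork degree, ties broken by accession.

    Degrees are counted inside the induced subnetwork, not in the whole
    interactome.  The ordering (descending degree, then ascending
    accession) is total, so rankings are reproducible across runs.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranked = sorted(sub.graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    return [(str(a), int(d)) for a, d in ranked[:n]]
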