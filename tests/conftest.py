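import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppientropy.io import IdMap, PatientPair
from ppientropy.network import Subnetwork
from ppientropy.synthetic import SyntheticSpec, generate_interactome, generate_paired_cohort


def make_subnetwork(edges, patient_id="p1") -> Subnetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return Subnetwork(graph=g, patient_id=patient_id)


@pytest.fixture
def star4() -> Subnetwork:
    """Star with center 'C' and 4 leaves: p(1)=0.8, p(4)=0.2."""
    return make_subnetwork([("C", f"L{i}") for i in range(4)])


@pytest.fixture
def path3() -> Subnetwork:
    """Path A-B-C: p(1)=2/3, p(2)=1/3."""
    return make_subnetwork([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle() -> Subnetwork:
    return make_subnetwork([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def double_star() -> Subnetwork:
    """Two joined centers with 4 leaves each (centers degree 5)."""
    edges = [("X", "Y")]
    edges += [("X", f"a{i}") for i in range(4)]
    edges += [("Y", f"b{i}") for i in range(4)]
    return make_subnetwork(edges)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced-scale study: 3 cohorts x 6 patients over 600 proteins."""
    return SyntheticSpec(
        seed=7,
        n_proteins=600,
        n_genes=600,
        n_cohorts=3,
        n_patients_per_cohort=6,
        planted_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    interactome = generate_interactome(small_spec)
    data = generate_paired_cohort(small_spec, interactome)
    return interactome, data


def pairs_from(data) -> list[PatientPair]:
    return [
        PatientPair(
            patient_id=row.patient_id,
            tumor=data.expression.vector(row.tumor_sample),
            control=data.expression.vector(row.control_sample),
        )
        for row in data.sample_sheet.itertuples(index=False)
    ]


@pytest.fixture
def gene_identity_map() -> IdMap:
    return IdMap({f"g{i}": f"P{i:04d}" for i in range(10_000)})


def normal_profile(seed: int, n: int = 9190, loc: float = 0.0, scale: float = 1.0):
    from ppientropy.upregulation import DifferentialProfile

    rng = np.random.default_rng(seed)
    values = rng.normal(loc, scale, n)
    return DifferentialProfile(
        patient_id=f"sim{seed}",
        diffs=pd.Series(values, index=[f"g{i}" for i in range(n)]),
    )
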