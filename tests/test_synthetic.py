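"""The synthetic-data generator: determinism, structure, recovery."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from ppientropy.errors import ValidationError
from ppientropy.io import (
    read_clinical_table,
    read_expression_table,
    read_id_mapping,
    read_interactome_mitab,
    read_sample_pairs,
)
from ppientropy.survival import entropy_survival_regression, km_curve, survival_rate_at
from ppientropy.synthetic import (
    SyntheticSpec,
    generate_interactome,
    generate_paired_cohort,
    generate_survival_records,
    write_dataset,
)
from ppientropy.upregulation import (
    build_histogram,
    differential_profile,
    fit_gaussian_threshold,
    select_upregulated,
)

from conftest import pairs_from


class TestInteractome:
    def test_edge_count_closed_form(self):
        spec = SyntheticSpec(seed=0, n_proteins=100, n_genes=100, attachment=2)
        g = generate_interactome(spec)
        assert g.number_of_edges() == 2 * (100 - 2)

    def test_attachment_one_gives_tree(self):
        spec = SyntheticSpec(seed=0, n_proteins=80, n_genes=80, attachment=1)
        g = generate_interactome(spec)
        assert g.number_of_edges() == 79
        assert nx.is_tree(g)

    def test_same_seed_identical_edges(self):
        spec = SyntheticSpec(seed=5, n_proteins=150, n_genes=150)
        assert set(generate_interactome(spec).edges) == set(
            generate_interactome(spec).edges
        )

    def test_degree_distribution_right_skew(self):
        spec = SyntheticSpec(seed=2, n_proteins=400, n_genes=400)
        degs = np.array([d for _, d in generate_interactome(spec).degree()])
        assert degs.max() >= 5 * np.median(degs)


class TestPairedCohort:
    def test_determinism(self, small_spec):
        inter = generate_interactome(small_spec)
        a = generate_paired_cohort(small_spec, inter)
        b = generate_paired_cohort(small_spec, inter)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.planted_truth == b.planted_truth

    def test_planted_recovery_end_to_end(self, small_spec, small_dataset):
        """Calling up-regulation on a synthetic patient recovers >=90% of its
        planted genes (effect 5 sigma)."""
        interactome, data = small_dataset
        pair = pairs_from(data)[0]
        profile = differential_profile(pair)
        fit = fit_gaussian_threshold(build_histogram(profile, 50))
        called = select_upregulated(profile, fit, data.idmap)
        truth = data.planted_truth[pair.patient_id]
        assert len(called.genes & truth) / len(truth) >= 0.9

    def test_null_effect_gives_no_enrichment(self):
        spec = SyntheticSpec(
            seed=9,
            n_proteins=600,
            n_genes=600,
            n_cohorts=1,
            n_patients_per_cohort=2,
            effect_size=0.0,
            planted_fraction=0.05,
        )
        inter = generate_interactome(spec)
        data = generate_paired_cohort(spec, inter)
        pair = pairs_from(data)[0]
        profile = differential_profile(pair)
        fit = fit_gaussian_threshold(build_histogram(profile, 50))
        called = select_upregulated(profile, fit, data.idmap)
        truth = data.planted_truth[pair.patient_id]
        # planted genes are statistically indistinguishable from nulls
        hit_rate = len(called.genes & truth) / len(truth)
        assert hit_rate < 0.25

    def test_planted_biased_toward_hubs(self, small_spec, small_dataset):
        interactome, data = small_dataset
        degs = {v: d for v, d in interactome.degree()}
        planted_deg = [
            degs[data.idmap.entries[g]]
            for t in data.planted_truth.values()
            for g in t
        ]
        assert np.mean(planted_deg) > 2 * np.mean(list(degs.values()))


class TestSurvivalRecords:
    def test_link_slope_must_be_negative(self):
        spec = SyntheticSpec(seed=0, n_cohorts=2, survival_link=(1.0, 0.0))
        with pytest.raises(ValidationError):
            generate_survival_records(spec, [2.0, 2.5])

    def test_monotone_link_orders_cohorts(self):
        spec = SyntheticSpec(
            seed=4, n_cohorts=2, n_patients_per_cohort=200, censoring_rate=0.0
        )
        frame = generate_survival_records(spec, [2.1, 2.5])
        rates = {}
        for cohort, grp in frame.groupby("cohort"):
            rates[cohort] = survival_rate_at(km_curve(grp), 1825)
        assert rates["C1"] > rates["C2"]

    def test_heavy_hazard_reaches_zero_without_censoring(self):
        spec = SyntheticSpec(
            seed=1, n_cohorts=1, n_patients_per_cohort=50, censoring_rate=0.0
        )
        frame = generate_survival_records(spec, [10.0])  # link clamps S to 1%
        assert (frame["event"] == 1).all()
        curve = km_curve(frame)
        assert curve.survival[-1] == 0.0

    def test_regression_recovery_across_seeds(self):
        """KM 5-year rates vs generating entropies recover a negative slope
        with p < 0.05 in >= 90% of seeds (9 cohorts x 50 patients)."""
        entropies = list(np.linspace(2.1, 2.5, 9))
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            spec = SyntheticSpec(seed=seed, n_cohorts=9, n_patients_per_cohort=50)
            frame = generate_survival_records(spec, entropies)
            points = []
            for cohort, h in zip(spec.cohort_labels(), entropies):
                grp = frame[frame["cohort"] == cohort]
                points.append((survival_rate_at(km_curve(grp), 1825), h))
            res = entropy_survival_regression(points)
            hits += res.slope < 0 and res.p_value < 0.05
        assert hits >= 0.9 * n_seeds


class TestWriteDataset:
    def test_files_round_trip_through_the_readers(self, tmp_path, small_spec):
        paths = write_dataset(small_spec, tmp_path)
        table = read_expression_table(paths["expression"])
        pairs = read_sample_pairs(table, paths["sample_sheet"])
        idmap = read_id_mapping(paths["mapping"])
        interactome = read_interactome_mitab(paths["interactome"])
        clinical = read_clinical_table(paths["clinical"])

        expected = generate_interactome(small_spec)
        assert set(interactome.nodes) == set(expected.nodes)
        assert set(map(frozenset, interactome.edges)) == set(
            map(frozenset, expected.edges)
        )
        assert len(pairs) == small_spec.n_cohorts * small_spec.n_patients_per_cohort
        assert len(idmap) == small_spec.n_genes
        assert set(clinical["cohort"]) == set(small_spec.cohort_labels())

        data = generate_paired_cohort(small_spec, expected)
        sample = pairs[0].tumor
        regenerated = data.expression.vector(sample.name)
        np.testing.assert_allclose(sample.to_numpy(), regenerated.to_numpy(), atol=5e-7)

    def test_rewrite_is_byte_identical(self, tmp_path, small_spec):
        first = write_dataset(small_spec, tmp_path / "a")
        second = write_dataset(small_spec, tmp_path / "b")
        for key in first:
            assert first[key].read_bytes() == second[key].read_bytes()
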