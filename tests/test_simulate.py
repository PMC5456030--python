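"""Synthetic library generator: structure, determinism, gap control."""

import numpy as np
import pytest

from barcodekit.cluster import concordance, single_linkage_clusters
from barcodekit.distances import distance_matrix, encode_sequence
from barcodekit.identify import loo_nearest_neighbour, summary_table
from barcodekit.simulate import (
    SimulationConfig,
    empirical_gap,
    evolve_sequence,
    simulate_library,
)


class TestStructure:
    def test_record_and_cluster_counts(self):
        bundle = simulate_library(
            SimulationConfig(seed=7, n_species=5, specimens_per_species=3)
        )
        assert len(bundle.library) == 15
        assert bundle.true_partition.n_clusters == 5
        dm = distance_matrix(bundle.library)
        labels = np.array(bundle.library.species_labels)
        same = labels[:, None] == labels[None, :]
        triu = np.triu(np.ones_like(same, dtype=bool), 1)
        assert dm.values[same & triu].mean() < dm.values[~same & triu].mean()

    def test_cryptic_split_adds_one_cluster(self):
        bundle = simulate_library(
            SimulationConfig(seed=2, n_species=6, n_cryptic_splits=1)
        )
        assert bundle.true_partition.n_clusters == 7
        assert bundle.library.species_count == 6

    def test_merge_removes_one_cluster(self):
        bundle = simulate_library(
            SimulationConfig(seed=2, n_species=6, n_merges=1)
        )
        assert bundle.true_partition.n_clusters == 5
        assert bundle.library.species_count == 6

    def test_singletons_have_one_specimen(self):
        bundle = simulate_library(
            SimulationConfig(seed=5, n_species=5, n_singletons=2)
        )
        counts = {}
        for sp in bundle.library.species_labels:
            counts[sp] = counts.get(sp, 0) + 1
        assert sorted(counts.values()) == [1, 1, 4, 4, 4]
        assert len([e for e in bundle.events if e["type"] == "singleton"]) == 2

    def test_tree_tips_match_library(self):
        bundle = simulate_library(SimulationConfig(seed=9, n_species=4))
        tips = sorted(l.taxon.label for l in bundle.true_tree.leaf_node_iter())
        assert tips == sorted(bundle.library.ids)

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_species=3, n_merges=2).validate()
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, n_species=4, specimens_per_species=1,
                             n_cryptic_splits=1).validate()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(seed=13, n_species=5, n_cryptic_splits=1,
                               n_merges=1)
        a, b = simulate_library(cfg), simulate_library(cfg)
        assert a.library.records == b.library.records
        assert a.true_partition == b.true_partition
        assert a.events == b.events

    def test_different_seed_differs(self):
        a = simulate_library(SimulationConfig(seed=1, n_species=4))
        b = simulate_library(SimulationConfig(seed=2, n_species=4))
        assert a.library.records != b.library.records


class TestEmpiricalGap:
    def test_strong_gap_config_positive_gap(self):
        bundle = simulate_library(SimulationConfig(seed=3, n_species=8))
        gap = empirical_gap(bundle)
        assert gap["gap"] > 0
        assert gap["max_intra"] < gap["min_inter"]

    def test_equal_depths_erase_the_gap(self):
        # intra == inter: the gap should be non-positive in most replicates
        negatives = 0
        for seed in range(20):
            bundle = simulate_library(
                SimulationConfig(seed=seed, n_species=4,
                                 specimens_per_species=3, seq_length=300,
                                 intra_depth=0.04, inter_depth=0.04)
            )
            if empirical_gap(bundle)["gap"] <= 0:
                negatives += 1
        assert negatives >= 15

    def test_all_singletons_have_undefined_max_intra(self):
        bundle = simulate_library(
            SimulationConfig(seed=4, n_species=4, specimens_per_species=1)
        )
        gap = empirical_gap(bundle)
        assert gap["max_intra"] is None


class TestSubstitutionModel:
    def test_transition_transversion_ratio_approaches_kappa(self):
        # on a long branch the observed ts : (tv/2) count ratio estimates
        # the rate ratio kappa (each transversion has two targets)
        rng = np.random.default_rng(99)
        kappa = 3.0
        root = rng.integers(0, 4, size=10_000).astype(np.uint8)
        beta = 1.0 / (kappa + 2.0)
        child = evolve_sequence(root, 0.08, kappa * beta, beta, rng)
        diff = root != child
        same_class = (root & 1) == (child & 1)
        ts = int(np.count_nonzero(diff & same_class))
        tv = int(np.count_nonzero(diff & ~same_class))
        assert ts / (tv / 2) == pytest.approx(kappa, rel=0.25)

    def test_jc69_option_balances_substitution_types(self):
        bundle_jc = simulate_library(
            SimulationConfig(seed=8, n_species=2, specimens_per_species=2,
                             seq_length=5000, inter_depth=0.3,
                             intra_depth=0.1, model="jc69")
        )
        codes = [encode_sequence(r.sequence) for r in bundle_jc.library.records]
        a, b = codes[0], codes[2]
        diff = a != b
        ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
        tv = int(np.count_nonzero(diff & ((a & 1) != (b & 1))))
        assert ts / (tv / 2) == pytest.approx(1.0, rel=0.35)

    def test_branch_length_matches_expected_divergence(self):
        rng = np.random.default_rng(5)
        root = rng.integers(0, 4, size=50_000).astype(np.uint8)
        child = evolve_sequence(root, 0.05, 0.6, 0.2, rng)
        from barcodekit.distances import _k2p_from_counts  # noqa: PLC2701

        diff = root != child
        ts = int(np.count_nonzero(diff & ((root & 1) == (child & 1))))
        tv = int(np.count_nonzero(diff & ((root & 1) != (child & 1))))
        d = _k2p_from_counts(root.size, ts, tv)
        assert d == pytest.approx(0.05, rel=0.08)


class TestRecoveryProperty:
    def test_gapped_default_config_recovers_truth(self):
        # the default study conditions (20 species x 4, intra 0.005,
        # inter 0.08) should let a 2.2% single-linkage threshold recover
        # the true partition and give perfect NN identification
        hits = 0
        for seed in range(10):
            bundle = simulate_library(SimulationConfig(seed=seed))
            dm = distance_matrix(bundle.library)
            part = single_linkage_clusters(dm, 0.022)
            if part.same_grouping(bundle.true_partition):
                hits += 1
        assert hits >= 9

    def test_injected_pathologies_reported_exactly(self):
        bundle = simulate_library(
            SimulationConfig(seed=17, n_species=10, n_cryptic_splits=1,
                             n_merges=1)
        )
        dm = distance_matrix(bundle.library)
        part = single_linkage_clusters(dm, 0.022)
        res = concordance(part, bundle.library)
        assert res["counts"]["split"] == 1
        assert res["counts"]["merge"] == 1
        assert res["counts"]["mixed"] == 0

    def test_truth_level_nn_identification_is_perfect(self):
        bundle = simulate_library(SimulationConfig(seed=23, n_species=8))
        dm = distance_matrix(bundle.library)
        cluster_labels = {i: str(c) for i, c in
                          bundle.true_partition.assignment.items()}
        report = summary_table(loo_nearest_neighbour(dm, cluster_labels),
                               level="cluster_id")
        assert report.success_rate == 1.0
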