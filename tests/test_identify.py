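"""Leave-one-out identification criteria, threshold optimisation, summaries."""

import numpy as np
import pytest

from barcodekit.identify import (
    LeaveOneOutIdentifier,
    eligible_queries,
    loo_best_close_match,
    loo_nearest_neighbour,
    loo_thresh_id,
    optimize_threshold,
    summary_table,
)
from barcodekit.distances import DistanceMatrix

from conftest import matrix_from_pairs


def outcomes_by_id(outcomes):
    return {o.specimen_id: o for o in outcomes}


class TestEligibleQueries:
    def test_all_species_doubly_represented(self):
        labels = {f"s{i}": f"sp{i // 2}" for i in range(6)}
        queries, singletons = eligible_queries(labels)
        assert len(queries) == 6 and singletons == []

    def test_singleton_stays_matchable_but_not_query(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        queries, singletons = eligible_queries(labels)
        assert sorted(queries) == ["a1", "a2", "b1", "b2"]
        assert singletons == ["c1"]

    def test_all_singletons_refused_at_evaluation(self):
        dm = matrix_from_pairs(["a", "b"], {("a", "b"): 0.1})
        with pytest.raises(ValueError, match="singleton"):
            loo_nearest_neighbour(dm, {"a": "A", "b": "B"})


class TestNearestNeighbour:
    def test_identical_conspecific_correct(self):
        dm = matrix_from_pairs(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.0, ("a1", "b1"): 0.1, ("a1", "b2"): 0.1,
             ("a2", "b1"): 0.1, ("a2", "b2"): 0.1, ("b1", "b2"): 0.02},
        )
        got = outcomes_by_id(loo_nearest_neighbour(
            dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}))
        assert got["a1"].category == "correct"
        assert got["a1"].nn_distance == 0.0

    def test_nearest_heterospecific_incorrect(self):
        dm = matrix_from_pairs(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.09, ("a1", "b1"): 0.01, ("a1", "b2"): 0.05,
             ("a2", "b1"): 0.09, ("a2", "b2"): 0.09, ("b1", "b2"): 0.01},
        )
        got = outcomes_by_id(loo_nearest_neighbour(
            dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}))
        assert got["a1"].category == "incorrect"

    def test_mixed_tie_ambiguous_and_foldable(self):
        dm = matrix_from_pairs(
            ["q", "a2", "b1", "b2"],
            {("q", "a2"): 0.02, ("q", "b1"): 0.02, ("q", "b2"): 0.07,
             ("a2", "b1"): 0.05, ("a2", "b2"): 0.07, ("b1", "b2"): 0.01},
        )
        labels = {"q": "A", "a2": "A", "b1": "B", "b2": "B"}
        got = outcomes_by_id(loo_nearest_neighbour(dm, labels))
        assert got["q"].category == "ambiguous"
        folded = outcomes_by_id(loo_nearest_neighbour(dm, labels, fold_ties=True))
        assert folded["q"].category == "correct"


class TestBestCloseMatch:
    def test_distance_above_threshold_is_no_id(self):
        dm = matrix_from_pairs(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.03, ("a1", "b1"): 0.09, ("a1", "b2"): 0.09,
             ("a2", "b1"): 0.09, ("a2", "b2"): 0.09, ("b1", "b2"): 0.004},
        )
        got = outcomes_by_id(loo_best_close_match(
            dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, threshold=0.025))
        assert got["a1"].category == "no_id"
        assert got["b1"].category == "correct"

    def test_agrees_with_nn_when_within_threshold(self, rng):
        # property: BCM equals NN whenever the nearest distance is inside
        # the threshold, and is no_id otherwise
        for _ in range(5):
            n = 8
            vals = rng.uniform(0.0, 0.06, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            ids = [f"s{i}" for i in range(n)]
            labels = {sid: f"sp{i // 2}" for i, sid in enumerate(ids)}
            dm = DistanceMatrix(tuple(ids), vals)
            t = 0.03
            nn = outcomes_by_id(loo_nearest_neighbour(dm, labels))
            bcm = outcomes_by_id(loo_best_close_match(dm, labels, t))
            for sid, o in bcm.items():
                if nn[sid].nn_distance <= t:
                    assert o.category == nn[sid].category
                else:
                    assert o.category == "no_id"


class TestThreshId:
    def test_no_match_within_threshold_is_no_id(self):
        dm = matrix_from_pairs(
            ["a1", "a2"], {("a1", "a2"): 0.05}
        )
        got = outcomes_by_id(loo_thresh_id(dm, {"a1": "A", "a2": "A"}, 0.01))
        assert all(o.category == "no_id" for o in got.values())

    def test_wider_match_set_creates_ambiguity(self):
        # conspecific at 0.01 plus heterospecific at 0.018 under t=0.019:
        # BCM sees only the closest (correct), threshold-ID sees both
        dm = matrix_from_pairs(
            ["q", "a2", "b1", "b2"],
            {("q", "a2"): 0.01, ("q", "b1"): 0.018, ("q", "b2"): 0.05,
             ("a2", "b1"): 0.02, ("a2", "b2"): 0.05, ("b1", "b2"): 0.002},
        )
        labels = {"q": "A", "a2": "A", "b1": "B", "b2": "B"}
        bcm = outcomes_by_id(loo_best_close_match(dm, labels, 0.019))
        tid = outcomes_by_id(loo_thresh_id(dm, labels, 0.019))
        assert bcm["q"].category == "correct"
        assert tid["q"].category == "ambiguous"

    def test_match_set_contains_bcm_matches_and_ambiguity_dominates(self, rng):
        for _ in range(5):
            n = 10
            vals = rng.uniform(0.0, 0.05, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            ids = [f"s{i}" for i in range(n)]
            labels = {sid: f"sp{i % 3}" for i, sid in enumerate(ids)}
            dm = DistanceMatrix(tuple(ids), vals)
            t = 0.025
            bcm = loo_best_close_match(dm, labels, t)
            tid = outcomes_by_id(loo_thresh_id(dm, labels, t))
            for o in bcm:
                if o.category == "no_id":
                    assert tid[o.specimen_id].category == "no_id"
                else:
                    assert set(o.matched_species) <= set(
                        tid[o.specimen_id].matched_species
                    )
            n_amb_bcm = sum(o.category == "ambiguous" for o in bcm)
            n_amb_tid = sum(o.category == "ambiguous" for o in tid.values())
            assert n_amb_tid >= n_amb_bcm

    def test_no_id_count_monotone_in_threshold(self, rng):
        n = 10
        vals = rng.uniform(0.0, 0.08, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = {sid: f"sp{i // 2}" for i, sid in enumerate(ids)}
        dm = DistanceMatrix(tuple(ids), vals)
        prev = None
        for t in (0.005, 0.02, 0.04, 0.08):
            n_no_id = sum(o.category == "no_id"
                          for o in loo_thresh_id(dm, labels, t))
            if prev is not None:
                assert n_no_id <= prev
            prev = n_no_id


class TestMaskedDistances:
    def test_fully_masked_query_excluded_with_warning(self):
        values = np.array(
            [[0.0, np.nan, np.nan],
             [np.nan, 0.0, 0.01],
             [np.nan, 0.01, 0.0]]
        )
        dm = DistanceMatrix(("x", "y", "z"), values)
        labels = {"x": "A", "y": "A", "z": "A"}
        with pytest.warns(UserWarning, match="undefined"):
            outcomes = loo_nearest_neighbour(dm, labels)
        assert sorted(o.specimen_id for o in outcomes) == ["y", "z"]

    def test_masked_pair_never_within_threshold(self):
        values = np.array(
            [[0.0, np.nan, 0.03],
             [np.nan, 0.0, 0.01],
             [0.03, 0.01, 0.0]]
        )
        dm = DistanceMatrix(("x", "y", "z"), values)
        labels = {"x": "A", "y": "A", "z": "B"}
        got = outcomes_by_id(loo_thresh_id(dm, labels, 0.02))
        # x's only in-threshold candidate would be y, but that pair is
        # undefined; z at 0.03 is outside -> no_id
        assert got["x"].category == "no_id"


class TestOptimizeThreshold:
    def test_perfect_gap_returns_smallest_zero_error_threshold(self):
        # max intra 0.005, min inter 0.04: every grid point in [0.005,
        # 0.039] is error-free and the smallest wins
        ids = ["a1", "a2", "b1", "b2"]
        pairs = {("a1", "a2"): 0.005, ("b1", "b2"): 0.003}
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                pairs[(x, y)] = 0.04
        dm = matrix_from_pairs(ids, pairs)
        t, curve = optimize_threshold(dm, {"a1": "A", "a2": "A",
                                           "b1": "B", "b2": "B"})
        assert t == pytest.approx(0.005)
        zero_rows = curve[curve["total"] == 0]
        assert zero_rows["threshold"].min() == pytest.approx(0.005)
        assert zero_rows["threshold"].max() == pytest.approx(0.039)

    def test_single_species_library_has_no_false_negatives(self):
        ids = ["a1", "a2", "a3"]
        dm = matrix_from_pairs(ids, {("a1", "a2"): 0.01, ("a1", "a3"): 0.02,
                                     ("a2", "a3"): 0.015})
        _, curve = optimize_threshold(dm, {i: "A" for i in ids})
        assert (curve["false_negative"] == 0).all()
        assert (curve.loc[curve["threshold"] >= 0.02, "false_positive"] == 0).all()

    def test_matches_brute_force_on_overlapping_fixture(self, rng):
        n = 12
        vals = rng.uniform(0.0, 0.06, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"s{i}" for i in range(n)]
        labels = {sid: f"sp{i // 3}" for i, sid in enumerate(ids)}
        dm = DistanceMatrix(tuple(ids), vals)
        grid = np.round(np.arange(0.001, 0.061, 0.001), 3)
        t, curve = optimize_threshold(dm, labels, grid=grid)
        # brute-force objective, recomputed per query and candidate
        best_t, best_total = None, None
        for cand in grid:
            total = 0
            for i, sid in enumerate(ids):
                others = [j for j in range(n) if j != i]
                con = [vals[i, j] for j in others if labels[ids[j]] == labels[sid]]
                het = [vals[i, j] for j in others if labels[ids[j]] != labels[sid]]
                total += int(min(con) > cand) + int(min(het) <= cand)
            if best_total is None or total < best_total:
                best_t, best_total = cand, total
        assert t == pytest.approx(best_t)
        assert curve["total"].min() == best_total

    def test_empty_grid_rejected(self):
        dm = matrix_from_pairs(["a", "b"], {("a", "b"): 0.01})
        with pytest.raises(ValueError):
            optimize_threshold(dm, {"a": "A", "b": "A"}, grid=[])


class TestSummary:
    def test_counts_and_success_rate(self):
        dm = matrix_from_pairs(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.004, ("a1", "b1"): 0.09, ("a1", "b2"): 0.09,
             ("a2", "b1"): 0.09, ("a2", "b2"): 0.09, ("b1", "b2"): 0.004},
        )
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        report = summary_table(loo_nearest_neighbour(dm, labels))
        assert report.n_evaluated == 4
        assert report.correct == 4
        assert report.success_rate == 1.0

    def test_mixed_criteria_rejected(self):
        dm = matrix_from_pairs(["a1", "a2"], {("a1", "a2"): 0.004})
        labels = {"a1": "A", "a2": "A"}
        mixed = (loo_nearest_neighbour(dm, labels)
                 + loo_thresh_id(dm, labels, 0.01))
        with pytest.raises(ValueError, match="mix"):
            summary_table(mixed)


class TestEstimator:
    def test_auto_threshold_flows_into_report(self):
        ids = ["a1", "a2", "b1", "b2"]
        pairs = {("a1", "a2"): 0.005, ("b1", "b2"): 0.003}
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                pairs[(x, y)] = 0.04
        dm = matrix_from_pairs(ids, pairs)
        est = LeaveOneOutIdentifier(criterion="bcm").fit(
            dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert est.threshold_ == pytest.approx(0.005)
        assert est.report_.threshold == est.threshold_
        assert est.report_.success_rate == 1.0
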