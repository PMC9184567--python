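import numpy as np
import pytest

from kinphase.assignment import (
    Assignment,
    ClusterInterval,
    UNPHASED,
    assignment_to_phasing,
    brute_force_assignment,
    intervals_from_partition,
    is_compatible,
    phasing_to_matrix,
    solve_assignment,
)


def iv(cid, start, end, weight=1):
    return ClusterInterval(cid, start, end, weight)


class TestCompatibility:
    def test_separated_by_window(self):
        assert is_compatible(iv(0, 10, 50), iv(1, 2000, 2100), W=1500)

    def test_gap_below_window(self):
        assert not is_compatible(iv(0, 10, 50), iv(1, 60, 100), W=1500)

    def test_overlap_incompatible_for_any_window(self):
        a, b = iv(0, 10, 100), iv(1, 50, 200)
        for W in (1, 10, 1500):
            assert not is_compatible(a, b, W)

    def test_boundary_is_inclusive(self):
        # gap of exactly W is allowed
        assert is_compatible(iv(0, 0, 10), iv(1, 10 + 7, 20), W=7)
        assert not is_compatible(iv(0, 0, 10), iv(1, 10 + 6, 20), W=7)

    def test_symmetric(self):
        a, b = iv(0, 0, 5), iv(1, 600, 700)
        assert is_compatible(a, b, 100) == is_compatible(b, a, 100)


class TestSolveAssignment:
    def test_five_conflicting_clusters_keep_best_four(self):
        intervals = [iv(i, 0, 10, w) for i, w in enumerate([5, 4, 3, 2, 1])]
        result = solve_assignment(intervals, k=4, W=100)
        assert result.objective == 14
        assigned = result.assigned()
        assert len(assigned) == 4
        assert 4 not in assigned  # the weight-1 cluster stays unphased

    def test_single_cluster(self):
        result = solve_assignment([iv(0, 5, 9, 7)], k=4, W=10)
        assert result.objective == 7
        assert result.haplotype_of[0] == 1

    def test_all_compatible_single_machine(self):
        intervals = [iv(i, i * 100, i * 100 + 1, 2) for i in range(4)]
        result = solve_assignment(intervals, k=1, W=10)
        assert result.objective == 8
        assert all(h == 1 for h in result.haplotype_of.values())

    def test_empty_instance(self):
        assert solve_assignment([], k=4, W=10).objective == 0

    def test_canonical_labels_by_start_index(self):
        # two conflicting pairs; labels assigned lowest-first by start
        intervals = [iv(0, 0, 10, 3), iv(1, 5, 15, 3), iv(2, 500, 510, 3)]
        result = solve_assignment(intervals, k=2, W=100)
        assert result.haplotype_of[0] == 1
        assert result.haplotype_of[1] == 2
        assert result.haplotype_of[2] == 1  # compatible with cluster 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 5))
            W = int(rng.integers(50, 400))
            intervals = []
            for cid in range(n):
                start = int(rng.integers(0, 2000))
                end = start + int(rng.integers(0, 400))
                intervals.append(iv(cid, start, end, int(rng.integers(1, 10))))
            exact = solve_assignment(intervals, k=k, W=W)
            assert exact.objective == brute_force_assignment(intervals, k, W)
            _assert_feasible(intervals, exact, k, W)

    def test_adding_compatible_cluster_never_decreases_objective(self):
        intervals = [iv(0, 0, 10, 5), iv(1, 3, 20, 4)]
        base = solve_assignment(intervals, k=2, W=50).objective
        extended = intervals + [iv(2, 10_000, 10_001, 2)]
        assert solve_assignment(extended, k=2, W=50).objective >= base


def _assert_feasible(intervals, assignment: Assignment, k, W):
    """Independent post-hoc check of the one-haplotype and conflict rules."""
    by_hap = {}
    for iv_ in intervals:
        h = assignment.haplotype_of.get(iv_.cluster_id, UNPHASED)
        assert 0 <= h <= k
        if h != UNPHASED:
            by_hap.setdefault(h, []).append(iv_)
    for members in by_hap.values():
        for a_idx, a in enumerate(members):
            for b in members[a_idx + 1 :]:
                assert is_compatible(a, b, W)


class TestBruteForce:
    def test_conflicting_clusters(self):
        intervals = [iv(i, 0, 10, w) for i, w in enumerate([5, 4, 3, 2, 1])]
        assert brute_force_assignment(intervals, k=4, W=100) == 14

    def test_empty(self):
        assert brute_force_assignment([], k=4, W=10) == 0

    def test_refuses_large_instances(self):
        intervals = [iv(i, 0, 1, 1) for i in range(11)]
        with pytest.raises(ValueError):
            brute_force_assignment(intervals, k=4, W=10)


class TestPhasing:
    def test_cluster_to_variant_propagation(self):
        partition = [[0, 2], [1, 3, 4]]
        assignment = Assignment({0: 2, 1: UNPHASED}, objective=2.0)
        phasing = assignment_to_phasing(assignment, partition, n_variants=5, k=4)
        np.testing.assert_array_equal(
            phasing.haplotype_of_variant, [2, 0, 2, 0, 0]
        )
        assert phasing.phased_fraction == pytest.approx(0.4)

    def test_matrix_single_dose(self):
        assignment = Assignment({0: 2}, objective=2.0)
        phasing = assignment_to_phasing(assignment, [[0, 1]], n_variants=2, k=4)
        mat = phasing_to_matrix(phasing)
        np.testing.assert_array_equal(mat[:, 0], [0, 1, 0, 0])
        assert mat.sum() == 2

    def test_matrix_duplex_fills_extra_copy(self):
        assignment = Assignment({0: 1}, objective=1.0)
        phasing = assignment_to_phasing(assignment, [[0]], n_variants=1, k=4)
        mat = phasing_to_matrix(phasing, dosages_sprime=[2])
        assert mat[0, 0] == 1  # assigned haplotype
        assert mat[:, 0].sum() == 2  # duplex dosage preserved

    def test_interval_construction(self):
        intervals = intervals_from_partition([[3, 7, 5], [9]])
        assert intervals[0] == ClusterInterval(0, 3, 7, 3)
        assert intervals[1] == ClusterInterval(1, 9, 9, 1)
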