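import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinphase.inheritance import (
    depth_likelihood,
    pair_depth_likelihood,
    pair_score,
    pair_transmission_priors,
    prior_log_odds,
    priors_by_enumeration,
    simplex_nulliplex_priors,
)
from kinphase.variants import VariantClass

EVEN_PLOIDIES = [2, 4, 6, 8]


class TestSimplexNulliplexPriors:
    def test_tetraploid_closed_form(self):
        pr = simplex_nulliplex_priors(4)
        assert pr.same == {(0, 0): Fraction(1, 2), (1, 1): Fraction(1, 2)}
        assert pr.diff == {
            (0, 0): Fraction(1, 6),
            (1, 1): Fraction(1, 6),
            (0, 1): Fraction(1, 3),
            (1, 0): Fraction(1, 3),
        }

    def test_hexaploid_cells(self):
        pr = simplex_nulliplex_priors(6)
        assert pr.diff[(1, 1)] == Fraction(1, 5)
        assert pr.diff[(0, 1)] == Fraction(3, 10)

    @pytest.mark.parametrize("k", EVEN_PLOIDIES)
    def test_normalized_and_symmetric(self, k):
        pr = simplex_nulliplex_priors(k)
        for dist in (pr.same, pr.diff):
            assert sum(dist.values()) == 1
            for (a, b), p in dist.items():
                assert dist.get((b, a)) == p

    @pytest.mark.parametrize("k", EVEN_PLOIDIES)
    def test_co_inheritance_never_splits(self, k):
        assert (0, 1) not in simplex_nulliplex_priors(k).same

    @pytest.mark.parametrize("k", [3, 0, -2])
    def test_invalid_ploidy(self, k):
        with pytest.raises(ValueError):
            simplex_nulliplex_priors(k)

    @pytest.mark.parametrize("k", EVEN_PLOIDIES)
    def test_matches_gamete_enumeration_exactly(self, k):
        pr = simplex_nulliplex_priors(k)
        assert priors_by_enumeration(k, 1, 1, 0, 0, 1) == pr.same
        assert priors_by_enumeration(k, 1, 1, 0, 0, 0) == pr.diff


class TestEnumeration:
    def test_inconsistent_shared_count(self):
        with pytest.raises(ValueError):
            priors_by_enumeration(4, 1, 1, 0, 0, 2)
        with pytest.raises(ValueError):
            priors_by_enumeration(4, 3, 3, 0, 0, 1)  # 3+3-1 > 4 haplotypes

    def test_simplex_simplex_other_parent_marginal(self):
        """Each s'' simplex marker is inherited with probability 1/2."""
        dist = priors_by_enumeration(4, 1, 1, 1, 1, 1)
        p_i_marginal = sum(p for (ni, _), p in dist.items() if ni >= 1)
        # s' same-haplotype marker inherited w.p. 1/2, s'' copy w.p. 1/2
        assert p_i_marginal == Fraction(3, 4)
        assert set(n for cell in dist for n in cell) <= {0, 1, 2}

    def test_pair_priors_reduce_to_closed_form(self):
        pr = pair_transmission_priors(4, VariantClass.SIMPLEX_NULLIPLEX,
                                      VariantClass.SIMPLEX_NULLIPLEX)
        closed = simplex_nulliplex_priors(4)
        assert pr.same == closed.same and pr.diff == closed.diff

    @pytest.mark.parametrize(
        "ci, cj",
        [
            (VariantClass.SIMPLEX_SIMPLEX, VariantClass.SIMPLEX_SIMPLEX),
            (VariantClass.DUPLEX_NULLIPLEX, VariantClass.DUPLEX_NULLIPLEX),
            (VariantClass.SIMPLEX_NULLIPLEX, VariantClass.DUPLEX_NULLIPLEX),
            (VariantClass.SIMPLEX_NULLIPLEX, VariantClass.SIMPLEX_SIMPLEX),
        ],
    )
    def test_mixed_class_priors_normalized(self, ci, cj):
        pr = pair_transmission_priors(4, ci, cj)
        assert sum(pr.same.values()) == 1
        assert sum(pr.diff.values()) == 1
        assert all(p >= 0 for p in pr.same.values())


class TestDepthLikelihood:
    def test_hand_value(self):
        assert depth_likelihood((3, 1), 1, 4) == pytest.approx(0.421875)

    def test_zero_coverage_is_one(self):
        for g in range(5):
            assert depth_likelihood((0, 0), g, 4) == 1.0

    def test_impossible_observation(self):
        assert depth_likelihood((3, 1), 0, 4) == 0.0
        assert depth_likelihood((1, 3), 4, 4) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            depth_likelihood((-1, 0), 1, 4)
        with pytest.raises(ValueError):
            depth_likelihood((1, 1), 5, 4)


class TestPairDepthLikelihood:
    def test_zero_coverage_normalization(self):
        pr = simplex_nulliplex_priors(4)
        assert pair_depth_likelihood((0, 0), (0, 0), pr.same, 4) == pytest.approx(1.0)
        assert pair_depth_likelihood((0, 0), (0, 0), pr.diff, 4) == pytest.approx(1.0)

    def test_hand_expansion_same(self):
        # only (1,1) contributes: 0.5 * (0.25^2)^2
        pr = simplex_nulliplex_priors(4)
        expected = 0.5 * (0.25**2) ** 2
        assert pair_depth_likelihood((0, 2), (0, 2), pr.same, 4) == pytest.approx(
            expected
        )

    def test_concentrated_prior(self):
        assert pair_depth_likelihood(
            (2, 0), (2, 0), {(0, 0): Fraction(1)}, 4
        ) == pytest.approx(1.0)


class TestPairScore:
    def test_all_zero_coverage_leaves_only_placement_prior(self):
        depths = [(0, 0)] * 20
        assert pair_score(depths, depths, 4) == math.log(1 / 3)

    def test_zero_coverage_progeny_are_neutral(self):
        rng = np.random.default_rng(0)
        di = [tuple(rng.integers(0, 6, 2)) for _ in range(15)]
        dj = [tuple(rng.integers(0, 6, 2)) for _ in range(15)]
        w = pair_score(di, dj, 4)
        w_padded = pair_score(di + [(0, 0)] * 7, dj + [(0, 0)] * 7, 4)
        assert w_padded == w

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        di = [tuple(rng.integers(0, 8, 2)) for _ in range(30)]
        dj = [tuple(rng.integers(0, 8, 2)) for _ in range(30)]
        assert pair_score(di, dj, 4) == pytest.approx(pair_score(dj, di, 4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_score([(1, 0)], [(1, 0), (0, 1)], 4)

    def test_sign_separates_true_hypotheses(self):
        """Simulated same-haplotype pairs score positive, different negative."""
        from kinphase.simulate import SimulationConfig, simulate_cross

        sim = simulate_cross(SimulationConfig(k=4, m=40, p=50, coverage=6.0, seed=4))
        labels = [sim.truth.cluster_label(i) for i in range(40)]
        same_scores, diff_scores = [], []
        for i in range(0, 40, 2):
            j = i + 1
            di = list(zip(sim.depth_major[i], sim.depth_minor[i]))
            dj = list(zip(sim.depth_major[j], sim.depth_minor[j]))
            w = pair_score(di, dj, 4)
            (same_scores if labels[i] == labels[j] else diff_scores).append(w)
        assert np.mean(same_scores) > 0
        assert np.mean(diff_scores) < 0


@settings(deadline=None, max_examples=25)
@given(
    k=st.sampled_from([2, 4, 6]),
    depths=st.lists(
        st.tuples(st.integers(0, 10), st.integers(0, 10)), min_size=1, max_size=8
    ),
)
def test_pair_score_finite(k, depths):
    """Any finite depth input yields a finite score."""
    w = pair_score(depths, depths, k)
    assert math.isfinite(w)


def test_prior_log_odds():
    assert prior_log_odds(4) == pytest.approx(math.log(1 / 3))
    assert prior_log_odds(2) == 0.0
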