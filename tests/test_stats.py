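"""Mid-p hypergeometric tests, Bonferroni, empirical-null mid-p and
Mann-Whitney against enumeration and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from dxsite.stats import (
    HypergeomParams,
    bonferroni_cutoff,
    discrete_midp,
    mann_whitney,
    midp_lower,
    midp_two_tailed,
    midp_upper,
)


class TestMidpUpper:
    @pytest.mark.parametrize(
        "N,K,n,k,expected,tol",
        [
            (60, 3, 1, 1, 0.025, 1e-12),       # single motif from a 3-motif consensus
            (60, 3, 11, 2, 0.044, 5e-4),       # >= 2 of 11 motifs in the consensus
            (1770, 3, 11, 1, 9.3e-3, 5e-5),    # >= 1 consensus pair among 11 pairs
        ],
    )
    def test_consensus_overlap_values(self, N, K, n, k, expected, tol):
        assert midp_upper(HypergeomParams(N, K, n, k)) == pytest.approx(expected, abs=tol)

    def test_no_successes_gives_half(self):
        # P(X=0)=1 so the mid-p assigns exactly half its mass
        assert midp_upper(HypergeomParams(25, 0, 7, 0)) == pytest.approx(0.5)

    def test_invariant_violations_are_named(self):
        with pytest.raises(ValueError, match="successes_K"):
            HypergeomParams(10, 11, 5, 2)
        with pytest.raises(ValueError, match="observed_k"):
            HypergeomParams(10, 5, 3, 4)
        with pytest.raises(ValueError, match="support minimum"):
            HypergeomParams(10, 9, 9, 5)


class TestMidpTwoTailed:
    def test_symmetric_two_by_two(self):
        # Hypergeometric(4,2,2): both one-sided mid-p equal 0.5 at k=1
        assert midp_two_tailed(HypergeomParams(4, 2, 2, 1)) == pytest.approx(1.0)

    def test_extreme_draw_doubles_upper_tail(self):
        # P(X=3) = C(4,3)C(6,0)/C(10,3) = 1/30; upper mid-p = 1/60
        assert midp_two_tailed(HypergeomParams(10, 4, 3, 3)) == pytest.approx(2 / 60)

    def test_degenerate_distribution(self):
        assert midp_two_tailed(HypergeomParams(5, 5, 5, 5)) == pytest.approx(1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_midp_bounded_by_conventional_p(data):
    """mid-p never exceeds the conventional exact p (full weight on P(X=k))."""
    N = data.draw(st.integers(1, 80))
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
    params = HypergeomParams(N, K, n, k)
    dist = hypergeom(N, K, n)
    conventional_upper = dist.sf(k) + dist.pmf(k)
    assert midp_upper(params) <= conventional_upper + 1e-12
    assert 0 < midp_upper(params) <= 1
    assert 0 < midp_two_tailed(params) <= 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(1, 120))
def test_hypergeom_pmf_sums_to_one(N):
    rng = np.random.default_rng(N)
    K = int(rng.integers(0, N + 1))
    n = int(rng.integers(0, N + 1))
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    assert hypergeom(N, K, n).pmf(support).sum() == pytest.approx(1.0, abs=1e-12)


def test_one_sided_tails_complement():
    # upper + lower mid-p = 1 for any parameter set
    params = HypergeomParams(40, 12, 9, 3)
    assert midp_upper(params) + midp_lower(params) == pytest.approx(1.0)


class TestBonferroni:
    def test_pair_family_cutoff(self):
        assert bonferroni_cutoff(1770, 0.05) == pytest.approx(2.825e-5, rel=1e-3)

    def test_small_families(self):
        assert bonferroni_cutoff(60, 0.05) == pytest.approx(0.05 / 60)
        assert bonferroni_cutoff(1, 0.05) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_cutoff(0, 0.05)


class TestDiscreteMidp:
    def test_two_point_null_upper(self):
        p, bound = discrete_midp({0: 0.5, 1: 0.5}, 1, sided="upper")
        assert p == pytest.approx(0.25)
        assert not bound

    def test_observation_beyond_support_is_flagged_bound(self):
        null = np.zeros(10**4, dtype=int)
        p, bound = discrete_midp(null, 3, sided="upper")
        assert p == pytest.approx(1e-4)
        assert bound

    def test_symmetric_two_point_null_two_sided(self):
        # at the symmetric center both tails weigh 0.5: doubled mid-p = 1
        p, bound = discrete_midp({0: 0.5, 2: 0.5}, 1, sided="two")
        assert p == pytest.approx(1.0)
        assert not bound
        # at a support point: min tail = 0.25 (half the point mass), doubled
        p, _ = discrete_midp({0: 0.5, 2: 0.5}, 0, sided="two")
        assert p == pytest.approx(0.5)

    def test_matches_closed_form_on_enumerated_null(self):
        # fully enumerated Poisson-binomial null for p = (0.3, 0.6)
        null = {0: 0.7 * 0.4, 1: 0.3 * 0.4 + 0.7 * 0.6, 2: 0.3 * 0.6}
        upper, _ = discrete_midp(null, 1, sided="upper")
        assert upper == pytest.approx(0.18 + 0.5 * 0.54)

    def test_empty_null_is_state_error(self):
        with pytest.raises(RuntimeError):
            discrete_midp({}, 0)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)  # 2/C(6,3) doubled

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_singletons(self):
        U, p = mann_whitney([1], [2])
        assert U == 0
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=40).astype(float)
        b = rng.integers(2, 7, size=40).astype(float)
        _, p = mann_whitney(a, b)
        assert 0 < p < 1
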