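"""Monte Carlo protein-cleavage null: closed-form and enumeration oracles."""

from itertools import product
from math import comb

import numpy as np
import pytest

from dxsite.models import Motif, MotifPair
from dxsite.montecarlo import (
    consensus_overlap_test,
    mc_screen,
    null_cleavage_probabilities,
    observed_protein_cleavages,
    pr_cleaved_at_motif,
    replicate_frequencies,
    simulate_null,
    total_protein_cleavages,
)

from conftest import make_event

GD = Motif.from_label("GD")
RD = Motif.from_label("RD")
TD = Motif.from_label("TD")


def poisson_binomial_pmf(probs):
    """Exact distribution of a sum of independent Bernoullis by direct
    enumeration of all outcomes (oracle; exponential in len(probs))."""
    pmf = {}
    for outcome in product((0, 1), repeat=len(probs)):
        mass = 1.0
        for x, p in zip(outcome, probs):
            mass *= p if x else 1.0 - p
        total = sum(outcome)
        pmf[total] = pmf.get(total, 0.0) + mass
    return pmf


def exact_two_sided_midp(pmf, observed):
    upper = sum(m for v, m in pmf.items() if v > observed)
    lower = sum(m for v, m in pmf.items() if v < observed)
    eq = pmf.get(observed, 0.0)
    return min(1.0, 2.0 * min(upper + 0.5 * eq, lower + 0.5 * eq))


class TestPrCleavedAtMotif:
    @pytest.mark.parametrize(
        "S,k,n,expected",
        [
            (1, 0, 10, 0.0),
            (2, 1, 10, 0.2),    # 1 - (9/10)(8/9) = 1 - C(9,2)/C(10,2)
            (3, 2, 4, 1.0),     # third factor hits zero: certainty
        ],
    )
    def test_hand_values(self, S, k, n, expected):
        assert pr_cleaved_at_motif(S, k, n) == pytest.approx(expected)

    def test_closed_form_exhaustive(self):
        """Product form equals 1 - C(n-k,S)/C(n,S) for every valid triple
        with n <= 50."""
        for n in range(1, 51):
            for S in range(1, n + 1):
                for k in range(0, n + 1):
                    closed = 1.0 - comb(n - k, S) / comb(n, S) if S <= n - k else 1.0
                    assert pr_cleaved_at_motif(S, k, n) == pytest.approx(closed, abs=1e-12)

    def test_monotonicity(self):
        assert pr_cleaved_at_motif(3, 2, 10) >= pr_cleaved_at_motif(2, 2, 10)
        assert pr_cleaved_at_motif(2, 3, 10) >= pr_cleaved_at_motif(2, 2, 10)
        assert pr_cleaved_at_motif(2, 2, 12) <= pr_cleaved_at_motif(2, 2, 10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pr_cleaved_at_motif(11, 2, 10)
        with pytest.raises(ValueError):
            pr_cleaved_at_motif(1, 5, 4)


class TestObservedCounts:
    def test_per_replicate_counting(self):
        events = [make_event(r, "A", 10, "G") for r in ("r1", "r2", "r3")]
        assert observed_protein_cleavages(events, {"A"}, GD) == 3

    def test_at_least_once_within_replicate(self):
        events = [make_event("r1", "A", p1, "G") for p1 in (10, 20, 30, 40, 50)]
        assert observed_protein_cleavages(events, {"A"}, GD) == 1

    def test_pair_counts_once_even_when_both_match(self):
        events = [make_event("r1", "A", 10, "G"), make_event("r1", "A", 20, "R")]
        assert observed_protein_cleavages(events, {"A"}, MotifPair(GD, RD)) == 1

    def test_small_instance_frequencies(self, small_null_instance):
        events, flagged = small_null_instance
        freqs = {f.replicate_id: (f.k, f.n) for f in replicate_frequencies(events, GD)}
        assert freqs == {"r1": (3, 6), "r2": (2, 4)}
        assert observed_protein_cleavages(events, flagged, GD) == 3
        assert total_protein_cleavages(events, flagged) == 4

    def test_null_probabilities_hand_values(self, small_null_instance):
        events, flagged = small_null_instance
        probs = sorted(null_cleavage_probabilities(events, flagged, GD))
        # A(r1,S=2): 1-C(3,2)/C(6,2)=0.8; B(r1,S=1)=0.5; A(r2,S=1)=0.5;
        # C(r2,S=2): 1-C(2,2)/C(4,2)=5/6
        assert probs == pytest.approx([0.5, 0.5, 0.8, 5 / 6])


class TestSimulateNull:
    def test_mean_matches_linearity_of_expectation(self, small_null_instance):
        events, flagged = small_null_instance
        res = simulate_null(events, flagged, GD, n_sims=200_000, seed=42)
        analytic = 0.5 + 0.5 + 0.8 + 5 / 6
        se = np.sqrt(sum(p * (1 - p) for p in [0.5, 0.5, 0.8, 5 / 6]) / 200_000)
        assert res.expected_analytic == pytest.approx(analytic)
        assert abs(res.expected_mean - analytic) < 4 * se

    def test_matches_exact_poisson_binomial(self, small_null_instance):
        """Simulated two-sided mid-p agrees with full enumeration of the
        Bernoulli outcome space."""
        events, flagged = small_null_instance
        n_sims = 200_000
        res = simulate_null(events, flagged, GD, n_sims=n_sims, seed=7)
        pmf = poisson_binomial_pmf([0.5, 0.5, 0.8, 5 / 6])
        exact = exact_two_sided_midp(pmf, res.observed_C)
        half = exact / 2  # SE governed by the one-sided tail estimate
        se = 2 * np.sqrt(half * (1 - half) / n_sims)
        assert abs(res.p_mid - exact) <= 3 * se + 1e-9

    def test_same_seed_reproducible(self, small_null_instance):
        events, flagged = small_null_instance
        a = simulate_null(events, flagged, GD, n_sims=5000, seed=3)
        b = simulate_null(events, flagged, GD, n_sims=5000, seed=3)
        assert (a.p_mid, a.expected_mean, a.observed_C) == (b.p_mid, b.expected_mean, b.observed_C)

    def test_no_flagged_substrate_is_state_error(self, small_null_instance):
        events, _ = small_null_instance
        with pytest.raises(RuntimeError):
            simulate_null(events, {"ZZZ"}, GD, n_sims=10, seed=0)


class TestMcScreen:
    def test_cardinality_and_q_assignment(self, small_null_instance):
        events, flagged = small_null_instance
        targets = [MotifPair(GD, RD), MotifPair(GD, TD), MotifPair(RD, TD)]
        results = mc_screen(events, flagged, targets, n_sims=2000, seed=1)
        assert len(results) == 3
        assert all(r.q_fdr is not None for r in results)

    def test_screen_order_invariance(self, small_null_instance):
        """Per-target substreams make each target's p independent of the
        other targets in the screen."""
        events, flagged = small_null_instance
        targets = [GD, RD, TD]
        full = {r.target: r.p_mid for r in mc_screen(events, flagged, targets,
                                                     n_sims=4000, seed=9)}
        solo = mc_screen(events, flagged, [GD], n_sims=4000, seed=9)[0]
        assert solo.p_mid == full[GD]


class TestConsensusOverlap:
    @pytest.mark.parametrize(
        "population,consensus,drawn,overlap,expected,tol",
        [
            (60, 3, 1, 1, 0.025, 1e-12),
            (60, 3, 11, 2, 0.044, 5e-4),
            (1770, 3, 11, 1, 9.3e-3, 5e-5),
        ],
    )
    def test_printed_meta_values(self, population, consensus, drawn, overlap,
                                 expected, tol):
        p = consensus_overlap_test(population, consensus, drawn, overlap)
        assert p == pytest.approx(expected, abs=tol)
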