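"""Inferential primitives: mid-p hypergeometric tests, adaptive FDR,
Bonferroni FWER, empirical-null mid-p, and the Mann-Whitney comparison.

Discrete exact tests are conservative because the observed outcome's whole
probability mass sits in the tail.  The mid-p variant counts only half of
P(X = k), which brings the realized error rate close to the nominal level
while retaining exactness of the underlying distribution.  All
hypergeometric tails are evaluated through scipy's exact routines (no
normal approximation); tail probabilities down to ~1e-6 are meaningful
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of one hypergeometric draw.

    population_N slots (e.g. replicate-weighted aspartate count), of which
    successes_K carry the motif; draws_n slots are cleaved; observed_k of
    the cleaved slots carry the motif.
    """

    population_N: int
    successes_K: int
    draws_n: int
    observed_k: int

    def __post_init__(self) -> None:
        N, K, n, k = self.population_N, self.successes_K, self.draws_n, self.observed_k
        for name, value in (("population_N", N), ("successes_K", K),
                            ("draws_n", n), ("observed_k", k)):
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if K > N:
            raise ValueError(f"successes_K ({K}) exceeds population_N ({N})")
        if n > N:
            raise ValueError(f"draws_n ({n}) exceeds population_N ({N})")
        if k > n:
            raise ValueError(f"observed_k ({k}) exceeds draws_n ({n})")
        if k > K:
            raise ValueError(f"observed_k ({k}) exceeds successes_K ({K})")
        if k < max(0, n + K - N):
            raise ValueError(
                f"observed_k ({k}) below support minimum max(0, n+K-N) = {max(0, n + K - N)}"
            )

    def _dist(self) -> sps.rv_frozen:
        return sps.hypergeom(self.population_N, self.successes_K, self.draws_n)


def midp_upper(params: HypergeomParams) -> float:
    """Upper-tail mid-p: P(X > k) + 0.5 P(X = k)."""
    dist = params._dist()
    k = params.observed_k
    return float(dist.sf(k) + 0.5 * dist.pmf(k))


def midp_lower(params: HypergeomParams) -> float:
    """Lower-tail mid-p: P(X < k) + 0.5 P(X = k)."""
    dist = params._dist()
    k = params.observed_k
    return float(dist.cdf(k - 1) + 0.5 * dist.pmf(k))


def midp_two_tailed(params: HypergeomParams) -> float:
    """Two-sided mid-p: twice the smaller one-sided mid-p, capped at 1."""
    return min(1.0, 2.0 * min(midp_upper(params), midp_lower(params)))


def bonferroni_cutoff(m: int, alpha: float = 0.05) -> float:
    """Per-test p cutoff controlling family-wise error at ``alpha`` over m tests."""
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / m


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (linear step-up), input order kept."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bky_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Adjusted q-values from the two-stage linear step-up FDR procedure.

    Stage 1 runs a linear step-up at level alpha/(1+alpha) to estimate the
    number of true nulls m0 = m - (stage-1 rejections); stage 2 reruns the
    step-up at the sharpened level alpha*m/m0.  The returned q-values are
    calibrated so that ``q <= alpha`` reproduces the two-stage rejection
    decision; when m0 < m they can fall below the raw p-values.

    Order of the input is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    m = p.size
    fact = 1.0 + alpha
    qbh = _bh_adjust(p)
    r1 = int(np.sum(qbh <= alpha / fact))
    if r1 in (0, m):
        q = qbh * fact
    else:
        m0 = m - r1
        q = qbh * fact * (m0 / m)
    return np.minimum(q, 1.0)


def discrete_midp(
    null_counts: Union[Mapping[int, float], Sequence[int], np.ndarray],
    observed: int,
    sided: str = "upper",
) -> tuple[float, bool]:
    """Mid-p of an observed count against an empirical discrete null.

    ``null_counts`` is either a histogram mapping value -> mass/count or an
    array of simulated values.  Returns ``(p, is_upper_bound)``; when the
    observation lies outside the simulated support, the returned p is the
    simulation resolution 1/total and is flagged as an upper-bound
    estimate.
    """
    if sided not in ("upper", "two"):
        raise ValueError(f"sided must be 'upper' or 'two', got {sided!r}")
    if isinstance(null_counts, Mapping):
        if not null_counts:
            raise RuntimeError("empty null histogram")
        values = np.fromiter(null_counts.keys(), dtype=float)
        weights = np.fromiter(null_counts.values(), dtype=float)
    else:
        values = np.asarray(null_counts, dtype=float)
        if values.size == 0:
            raise RuntimeError("empty null histogram")
        weights = np.ones_like(values)
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("null histogram has zero total mass")

    if observed > values.max() or observed < values.min():
        # outside simulated support: best resolvable bound, flagged
        return 1.0 / total, True

    mass_eq = weights[values == observed].sum() / total
    upper = weights[values > observed].sum() / total + 0.5 * mass_eq
    if sided == "upper":
        return float(upper), False
    lower = weights[values < observed].sum() / total + 0.5 * mass_eq
    return float(min(1.0, 2.0 * min(upper, lower))), False


def mann_whitney(
    group_a: Iterable[float], group_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for combined n <= 20 without ties; tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))
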