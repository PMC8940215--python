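"""Monte Carlo protein-cleavage null model for motif-annotation association.

Tests whether annotation-flagged substrates (e.g. proteins bearing the GO
term "Structural Constituent of Cytoskeleton") are cleaved at a motif more
often than chance, given each substrate's own number of observed sites.
Within a replicate, a flagged substrate with S observed sites is "cleaved
at the motif" under the null with probability

    Pr = 1 - prod_{i=0}^{S-1} (1 - k / (n - i)),

the chance that S site slots drawn without replacement from the
replicate's n slots (k of which carry the motif) include at least one
motif slot; algebraically Pr = 1 - C(n-k, S) / C(n, S).  Each simulation
draws one Bernoulli(Pr) per flagged substrate per replicate and sums them
into a total protein-cleavage count, whose empirical distribution is
compared with the observed count by the discrete mid-p method.

The null conditions on the observed per-replicate motif frequencies and
per-substrate site counts, so heavy cleavage of flagged substrates alone
(more sites, any motif) does not register as motif association.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from . import stats
from .models import CleavageEvent, MonteCarloResult, Motif, MotifPair
from .stats import HypergeomParams

Target = Union[Motif, MotifPair]

_SIM_CHUNK = 4_000_000  # random draws per chunk, keeps memory flat


@dataclass(frozen=True)
class ReplicateMotifFrequency:
    """Per-replicate motif frequency among all cleavage-site observations."""

    replicate_id: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("require 0 <= k <= n")


def replicate_frequencies(
    events: Sequence[CleavageEvent], target: Target
) -> list[ReplicateMotifFrequency]:
    """(k, n) per replicate: sites matching the target vs all sites."""
    k_by_rep: Counter = Counter()
    n_by_rep: Counter = Counter()
    for event in events:
        n_by_rep[event.replicate_id] += 1
        if target.matches(event.context):
            k_by_rep[event.replicate_id] += 1
    return [
        ReplicateMotifFrequency(replicate_id=rep, k=k_by_rep[rep], n=n_by_rep[rep])
        for rep in sorted(n_by_rep)
    ]


def pr_cleaved_at_motif(S: int, k: int, n: int) -> float:
    """Null probability that a substrate with S observed sites is cleaved
    at the motif at least once, at motif frequency k/n in the replicate.

    Equals 1 - C(n-k, S)/C(n, S): the complement of drawing S site slots
    without replacement and hitting none of the k motif slots.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 1 <= S <= n:
        raise ValueError(f"require 1 <= S <= n, got S={S}, n={n}")
    miss = 1.0
    for i in range(S):
        factor = 1.0 - k / (n - i)
        miss *= min(1.0, max(0.0, factor))
    return 1.0 - miss


def _flagged(annotation_flag: Union[Iterable[str], dict]) -> set[str]:
    if isinstance(annotation_flag, dict):
        return {acc for acc, flagged in annotation_flag.items() if flagged}
    return set(annotation_flag)


def observed_protein_cleavages(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
    target: Target,
) -> int:
    """Observed protein-cleavage total: over replicates, the number of
    distinct flagged substrates with at least one site matching the target."""
    flagged = _flagged(annotation_flag)
    hit: set[tuple[str, str]] = set()
    for event in events:
        if event.accession in flagged and target.matches(event.context):
            hit.add((event.replicate_id, event.accession))
    return len(hit)


def total_protein_cleavages(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
) -> int:
    """All observed flagged protein-cleavages regardless of motif: over
    replicates, distinct flagged substrates with any site."""
    flagged = _flagged(annotation_flag)
    return len(
        {(e.replicate_id, e.accession) for e in events if e.accession in flagged}
    )


def null_cleavage_probabilities(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
    target: Target,
) -> np.ndarray:
    """One Bernoulli probability per (replicate, flagged substrate cleaved
    in that replicate), in deterministic order."""
    flagged = _flagged(annotation_flag)
    freqs = {f.replicate_id: f for f in replicate_frequencies(events, target)}
    sites: Counter = Counter()
    for event in events:
        if event.accession in flagged:
            sites[(event.replicate_id, event.accession)] += 1
    if not sites:
        raise RuntimeError("no flagged substrate is cleaved in any replicate")
    probs = []
    for (rep, _acc), S in sorted(sites.items()):
        f = freqs[rep]
        probs.append(pr_cleaved_at_motif(S, f.k, f.n))
    return np.asarray(probs, dtype=float)


def simulate_null(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
    target: Target,
    n_sims: int = 100_000,
    seed: Union[int, np.random.SeedSequence] = 0,
    sided: str = "two",
) -> MonteCarloResult:
    """Monte Carlo test of one motif or pair against the protein-cleavage null.

    Simulates ``n_sims`` protein-cleavage totals, compares the observed
    total to the empirical distribution by the discrete mid-p method
    (two-sided by doubling, by default), and reports fold enrichment as
    observed / simulated mean.  Fully reproducible from ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    probs = null_cleavage_probabilities(events, annotation_flag, target)
    observed = observed_protein_cleavages(events, annotation_flag, target)

    if isinstance(seed, np.random.SeedSequence):
        seed_sequence, seed_label = seed, int(seed.entropy)
    else:
        seed_sequence, seed_label = np.random.SeedSequence(seed), int(seed)
    rng = np.random.Generator(np.random.PCG64(seed_sequence))

    counts: Counter = Counter()
    total_sum = 0.0
    chunk_rows = max(1, _SIM_CHUNK // max(1, probs.size))
    done = 0
    while done < n_sims:
        rows = min(chunk_rows, n_sims - done)
        totals = (rng.random((rows, probs.size)) < probs).sum(axis=1)
        counts.update(totals.tolist())
        total_sum += totals.sum()
        done += rows

    expected_mean = total_sum / n_sims
    p_mid, is_bound = stats.discrete_midp(dict(counts), observed, sided=sided)
    return MonteCarloResult(
        target=target,
        observed_C=observed,
        expected_mean=float(expected_mean),
        p_mid=p_mid,
        p_is_upper_bound=is_bound,
        n_sims=n_sims,
        seed=seed_label,
        expected_analytic=float(probs.sum()),
    )


def mc_screen(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
    targets: Sequence[Target],
    n_sims: int = 100_000,
    seed: int = 0,
    sided: str = "two",
    alpha: float = 0.05,
) -> list[MonteCarloResult]:
    """Run simulate_null over a family of targets with FDR across the screen.

    Each target draws from its own counter-based substream of ``seed``
    (SeedSequence spawning), so results are independent of screen order
    and reproducible target-by-target.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(targets))
    results = [
        simulate_null(events, annotation_flag, target, n_sims=n_sims,
                      seed=child, sided=sided)
        for target, child in zip(targets, children)
    ]
    for result in results:
        result.seed = seed
    q = stats.bky_fdr([r.p_mid for r in results], alpha=alpha)
    for result, qv in zip(results, q):
        result.q_fdr = float(qv)
    return results


def consensus_overlap_test(
    population: int, consensus_size: int, drawn: int, observed_overlap: int
) -> float:
    """Upper-tail mid-p that a selection of motifs (or pairs) overlaps a
    reference consensus set at least as much as observed, by chance.

    E.g. the chance that >= 2 of 11 SCoC-associated motifs fall in a
    3-motif reference consensus drawn from the 60-motif population.
    """
    return stats.midp_upper(
        HypergeomParams(
            population_N=population,
            successes_K=consensus_size,
            draws_n=drawn,
            observed_k=observed_overlap,
        )
    )


def screen_frame(results: Sequence[MonteCarloResult]):
    """Tabular view of a Monte Carlo screen (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "target": [r.target.label for r in results],
            "observed_C": [r.observed_C for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "fold": [r.fold for r in results],
            "p_mid": [r.p_mid for r in results],
            "p_is_upper_bound": [r.p_is_upper_bound for r in results],
            "q_fdr": [r.q_fdr for r in results],
            "n_sims": [r.n_sims for r in results],
            "seed": [r.seed for r in results],
        }
    )
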