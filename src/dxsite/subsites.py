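"""Subsite enrichment: the 60 single-residue P4-P2 motifs and the
replicate-weighted consensus table.

For each motif the test compares the motif's frequency among observed
cleavage sites (k/n) with its frequency among all aspartates in the
sequences of cleaved substrates (K/N).  Counts are replicate-weighted: a
substrate cleaved in r replicates contributes its sequence background r
times, and each replicate contributes its own site counts, so k, n, K, N
are sums over replicates.  Background aspartates are restricted to
positions >= 5 (a full P4 window exists), which keeps one shared
background across all three subsites.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .models import AMINO_ACIDS, SUBSITES, CleavageEvent, Motif, MotifPair, ProteinRecord, TestResult
from .stats import HypergeomParams


def enumerate_motifs() -> list[Motif]:
    """The 60 single-residue motifs: subsites P2 < P3 < P4, residues A..Y."""
    return [Motif(subsite=s, residue=r) for s in SUBSITES for r in AMINO_ACIDS]


def enumerate_pairs() -> list[MotifPair]:
    """All C(60, 2) = 1,770 unordered motif pairs, in canonical order."""
    return [MotifPair(a, b) for a, b in combinations(enumerate_motifs(), 2)]


@dataclass(frozen=True)
class SubsiteCounts:
    """Replicate-summed hypergeometric inputs for one motif."""

    k_total: int
    n_total: int
    K_total: int
    N_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_total <= self.n_total):
            raise ValueError("require 0 <= k_total <= n_total")
        if not (0 <= self.k_total <= self.K_total <= self.N_total):
            raise ValueError("require 0 <= k_total <= K_total <= N_total")

    def as_params(self) -> HypergeomParams:
        return HypergeomParams(
            population_N=self.N_total,
            successes_K=self.K_total,
            draws_n=self.n_total,
            observed_k=self.k_total,
        )


def _background_profile(sequence: str) -> tuple[int, dict[tuple[str, str], int]]:
    """Aspartate background of one protein sequence.

    Returns (N, counts) where N is the number of aspartates at 1-based
    position >= 5 and counts[(subsite, residue)] is how many of those
    aspartates carry ``residue`` at ``subsite``.  Non-standard residues
    (X/U/B/Z) count toward N but toward no motif.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    n_asp = 0
    offsets = {"P2": 1, "P3": 2, "P4": 3}
    for pos0, residue in enumerate(sequence):
        if residue != "D" or pos0 < 4:  # pos0 = 4 is 1-based position 5
            continue
        n_asp += 1
        for subsite, off in offsets.items():
            upstream = sequence[pos0 - off]
            if upstream in AMINO_ACIDS:
                counts[(subsite, upstream)] += 1
    return n_asp, dict(counts)


def subsite_count_table(
    events: Sequence[CleavageEvent],
    proteome: Iterable[ProteinRecord],
) -> dict[Motif, SubsiteCounts]:
    """Replicate-weighted (k, n, K, N) for all 60 motifs in one pass."""
    index = {rec.accession: rec for rec in proteome}
    missing = sorted({e.accession for e in events} - set(index))
    if missing:
        raise KeyError(f"event accessions absent from proteome: {missing}")

    # replicate -> accessions cleaved in it; foreground subsite tallies
    cleaved_by_rep: dict[str, set[str]] = defaultdict(set)
    k_counts: dict[tuple[str, str], int] = defaultdict(int)
    n_total = 0
    context_index = {"P4": 0, "P3": 1, "P2": 2}
    for event in events:
        cleaved_by_rep[event.replicate_id].add(event.accession)
        n_total += 1
        for subsite in SUBSITES:
            residue = event.context[context_index[subsite]]
            if residue in AMINO_ACIDS:
                k_counts[(subsite, residue)] += 1

    # replicate weight of each protein = number of replicates it is cleaved in
    weight: dict[str, int] = defaultdict(int)
    for accessions in cleaved_by_rep.values():
        for acc in accessions:
            weight[acc] += 1

    profiles = {acc: _background_profile(index[acc].sequence) for acc in weight}
    N_total = sum(w * profiles[acc][0] for acc, w in weight.items())
    K_counts: dict[tuple[str, str], int] = defaultdict(int)
    for acc, w in weight.items():
        for key, count in profiles[acc][1].items():
            K_counts[key] += w * count

    table: dict[Motif, SubsiteCounts] = {}
    for motif in enumerate_motifs():
        key = (motif.subsite, motif.residue)
        table[motif] = SubsiteCounts(
            k_total=k_counts.get(key, 0),
            n_total=n_total,
            K_total=K_counts.get(key, 0),
            N_total=N_total,
        )
    return table


def count_subsite(
    events: Sequence[CleavageEvent],
    proteome: Iterable[ProteinRecord],
    motif: Motif,
) -> SubsiteCounts:
    """Replicate-weighted (k, n, K, N) for a single motif."""
    return subsite_count_table(events, proteome)[motif]


def _fold(k: int, n: int, K: int, N: int) -> float:
    if n > 0 and K > 0:
        return (k / n) / (K / N)
    return float("nan")


def consensus_table(
    events: Sequence[CleavageEvent],
    proteome: Iterable[ProteinRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """The consensus-sequence table: all 60 motifs tested at once.

    Two-tailed mid-p per motif, FDR q across the 60 tests by the two-stage
    linear step-up, Bonferroni FWER flag at alpha/60.  Sorted by p
    ascending.
    """
    if not events:
        raise RuntimeError("consensus_table requires at least one cleavage event")
    counts = subsite_count_table(events, proteome)
    motifs = enumerate_motifs()
    rows = []
    for motif in motifs:
        c = counts[motif]
        p = stats.midp_two_tailed(c.as_params())
        rows.append(
            {
                "motif": motif.label,
                "subsite": motif.subsite,
                "residue": motif.residue,
                "k": c.k_total,
                "n": c.n_total,
                "K": c.K_total,
                "N": c.N_total,
                "fold": _fold(c.k_total, c.n_total, c.K_total, c.N_total),
                "p_mid": p,
            }
        )
    frame = pd.DataFrame(rows)
    frame["q_fdr"] = stats.bky_fdr(frame["p_mid"].to_numpy(), alpha=alpha)
    frame["bonferroni_flag"] = frame["p_mid"] < stats.bonferroni_cutoff(len(motifs), alpha)
    return frame.sort_values("p_mid", kind="mergesort").reset_index(drop=True)


def consensus_results(
    events: Sequence[CleavageEvent],
    proteome: Iterable[ProteinRecord],
    alpha: float = 0.05,
) -> list[tuple[Motif, TestResult]]:
    """The consensus table as (Motif, TestResult) pairs (same order)."""
    frame = consensus_table(events, proteome, alpha=alpha)
    out = []
    for row in frame.itertuples(index=False):
        fold = None if np.isnan(row.fold) else float(row.fold)
        out.append(
            (
                Motif.from_label(row.motif),
                TestResult(p_mid=row.p_mid, fold_enrichment=fold, q_fdr=row.q_fdr),
            )
        )
    return out
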