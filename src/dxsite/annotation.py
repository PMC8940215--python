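"""Generic annotation-term enrichment against a substrate background.

Replaces web-service GO analysis with a user-supplied annotation map
(accession -> set of (category, term)).  Enrichment of a term among
substrates cleaved at chosen motifs is tested against the background of
all substrates by the upper-tail hypergeometric mid-p, with FDR control
applied within each annotation category (e.g. the three GO namespaces)
separately.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Set, Union

import pandas as pd

from . import stats
from .models import CleavageEvent, Motif
from .stats import HypergeomParams

AnnotationMap = Mapping[str, Set[tuple]]  # accession -> {(category, term), ...}


def read_annotation_map(path: Union[str, Path]) -> dict[str, set]:
    """Read a delimited annotation table (accession, category, term)."""
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"accession", "category", "term"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation map {path} lacks columns: {sorted(missing)}")
    out: dict[str, set] = defaultdict(set)
    for row in table.itertuples(index=False):
        out[str(row.accession)].add((str(row.category), str(row.term)))
    return dict(out)


def motif_foreground(
    events: Sequence[CleavageEvent], motifs: Sequence[Motif]
) -> set[str]:
    """Accessions with at least one event (any replicate) at any listed motif."""
    if not motifs:
        return set()
    return {
        event.accession
        for event in events
        if any(motif.matches(event.context) for motif in motifs)
    }


def term_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term enrichment of the foreground against the background.

    For each (category, term): k = foreground accessions carrying the
    term, n = foreground size, K = background carriers, N = background
    size; upper-tail mid-p; q by the two-stage step-up within each
    category.  Sorted by category then p.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")

    carriers: dict[tuple, set] = defaultdict(set)
    for acc in bg:
        for cat_term in annotations.get(acc, ()):
            carriers[cat_term].add(acc)

    rows = []
    n, N = len(fg), len(bg)
    for (category, term), accs in sorted(carriers.items()):
        K = len(accs)
        k = len(accs & fg)
        p = stats.midp_upper(
            HypergeomParams(population_N=N, successes_K=K, draws_n=n, observed_k=k)
        )
        fold = (k / n) / (K / N) if K > 0 else float("nan")
        rows.append(
            {"category": category, "term": term, "k": k, "n": n, "K": K, "N": N,
             "fold": fold, "p_mid": p}
        )
    frame = pd.DataFrame(rows)
    frame["q_fdr"] = 1.0
    for category, block in frame.groupby("category"):
        frame.loc[block.index, "q_fdr"] = stats.bky_fdr(
            block["p_mid"].to_numpy(), alpha=alpha
        )
    return (
        frame.sort_values(["category", "p_mid"], kind="mergesort")
        .reset_index(drop=True)
    )


def sites_per_protein_comparison(
    events: Sequence[CleavageEvent],
    annotation_flag: Union[Iterable[str], dict],
) -> dict:
    """Do flagged substrates carry more cleavage sites per protein per
    replicate than other substrates?

    The unit of observation is the (protein, replicate) site count;
    groups are compared by the two-sided Mann-Whitney U test.
    """
    if isinstance(annotation_flag, dict):
        flagged = {a for a, f in annotation_flag.items() if f}
    else:
        flagged = set(annotation_flag)
    counts: dict[tuple, int] = defaultdict(int)
    for event in events:
        counts[(event.replicate_id, event.accession)] += 1
    group_flagged = [c for (rep, acc), c in counts.items() if acc in flagged]
    group_other = [c for (rep, acc), c in counts.items() if acc not in flagged]
    if not group_flagged or not group_other:
        raise RuntimeError("both flagged and unflagged substrates must be cleaved")
    U, p = stats.mann_whitney(group_flagged, group_other)
    med = lambda xs: float(pd.Series(xs).median())
    return {
        "U": U,
        "p": p,
        "n_flagged": len(group_flagged),
        "n_other": len(group_other),
        "median_flagged": med(group_flagged),
        "median_other": med(group_other),
    }
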