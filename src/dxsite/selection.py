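"""Stepwise specificity/coverage candidate selection for motif pairs.

A pair screen positions each motif pair on a plane of fold enrichment
(specificity of flagged-substrate proteolysis) versus the proportion of
flagged protein-cleavages it covers.  Candidates are accumulated by
walking pairs in descending fold order and admitting a pair only when its
coverage strictly exceeds every previously admitted pair's — which is the
strict Pareto frontier of (fold, proportion) among eligible, significant
points.  A visibility/eligibility filter removes pairs whose fold is
inflated by near-zero observed counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .models import PairPoint

DEFAULT_EXCLUDED_P4 = ("IXXD", "CXXD", "GXXD")


def eligibility_filter(
    points: Sequence[PairPoint],
    observed_counts: Mapping[str, int],
    excluded_motifs: Sequence[str] = DEFAULT_EXCLUDED_P4,
    enabled: bool = True,
) -> list[PairPoint]:
    """Mark pairs with artificially inflated folds as ineligible.

    A pair is ineligible when one member is on the exclusion list
    (rarely-observed P4 motifs by default) and the other member has at
    most one observed flagged protein-cleavage.  ``observed_counts`` maps
    single-motif labels to their observed protein-cleavage totals.
    """
    excluded = {label.upper() for label in excluded_motifs}
    out: list[PairPoint] = []
    for point in points:
        eligible = True
        if enabled:
            members = (point.pair.first, point.pair.second)
            for member, other in (members, members[::-1]):
                if member.label in excluded and observed_counts.get(other.label, 0) <= 1:
                    eligible = False
                    break
        out.append(
            PairPoint(
                pair=point.pair,
                fold=point.fold,
                scoc_proportion=point.scoc_proportion,
                p_mid=point.p_mid,
                eligible=eligible,
            )
        )
    return out


def select_candidates(
    points: Sequence[PairPoint], fwer_cutoff: float
) -> list[PairPoint]:
    """Stepwise selection of consensus-candidate pairs.

    Considers eligible points significant at ``fwer_cutoff``; sorts them
    by fold descending (ties: proportion descending, then pair label);
    emits the first point and thereafter every point whose coverage
    proportion strictly exceeds the last emitted one.  The result is the
    strict Pareto frontier of (fold, proportion).
    """
    if not points:
        raise ValueError("points must be non-empty")
    pool = [p for p in points if p.eligible and p.p_mid < fwer_cutoff]
    if not pool:
        if not any(p.eligible for p in points):
            raise RuntimeError("no eligible points to select from")
        return []
    pool.sort(key=lambda p: (-p.fold, -p.scoc_proportion, p.pair.label))
    selected = [pool[0]]
    for point in pool[1:]:
        if point.scoc_proportion > selected[-1].scoc_proportion:
            selected.append(point)
    return selected
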