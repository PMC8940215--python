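"""Core domain objects for D|X degradome analysis.

The unit of evidence is a *cleavage event*: one observation, in one
biological replicate, of a neo-N-terminal peptide whose preceding residue
(P1) is aspartate.  Subsites are numbered outward from the scissile bond:
P4-P3-P2-P1 on the N-terminal (non-prime) side, P1'-P4' on the C-terminal
side.  Every event carries its 8-residue P4-P4' context window; only the
P4-P2 half enters the statistics (P1 is fixed to D by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SUBSITES = ("P2", "P3", "P4")

#: index of each subsite within the 8-character P4-P4' context window
_SUBSITE_INDEX = {"P4": 0, "P3": 1, "P2": 2}


@dataclass(frozen=True, order=True)
class Motif:
    """A single-residue constraint at subsite P2, P3 or P4 (P1 fixed to D).

    Rendered in the field's shorthand: ``GD`` is glycine at P2, ``KXD``
    lysine at P3, ``IXXD`` isoleucine at P4 (X = unconstrained).
    """

    subsite: str
    residue: str

    def __post_init__(self) -> None:
        if self.subsite not in SUBSITES:
            raise ValueError(f"subsite must be one of {SUBSITES}, got {self.subsite!r}")
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"residue must be a standard amino acid, got {self.residue!r}")

    @property
    def label(self) -> str:
        gap = {"P2": "", "P3": "X", "P4": "XX"}[self.subsite]
        return f"{self.residue}{gap}D"

    @property
    def context_index(self) -> int:
        return _SUBSITE_INDEX[self.subsite]

    def matches(self, context: str) -> bool:
        """True if the P4-P4' window has this motif's residue at its subsite."""
        return context[self.context_index] == self.residue

    @classmethod
    def from_label(cls, label: str) -> "Motif":
        body = label.upper()
        if not body.endswith("D") or len(body) < 2 or len(body) > 4:
            raise ValueError(f"cannot parse motif label {label!r}")
        residue, gap = body[0], body[1:-1]
        subsite = {"": "P2", "X": "P3", "XX": "P4"}.get(gap)
        if subsite is None:
            raise ValueError(f"cannot parse motif label {label!r}")
        return cls(subsite=subsite, residue=residue)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True, order=True)
class MotifPair:
    """An unordered pair of distinct single-residue motifs.

    A site matches the pair if it matches either member ("at least one"
    semantics); a substrate cleaved at both members in one replicate still
    counts a single protein-cleavage.
    """

    first: Motif
    second: Motif

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("pair members must be distinct motifs")
        if self.second < self.first:
            # canonicalize order so (a, b) == (b, a)
            a, b = self.second, self.first
            object.__setattr__(self, "first", a)
            object.__setattr__(self, "second", b)

    @property
    def label(self) -> str:
        return f"{self.first.label}+{self.second.label}"

    def matches(self, context: str) -> bool:
        return self.first.matches(context) or self.second.matches(context)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry with optional annotation terms and SCoC-style flag."""

    accession: str
    sequence: str
    terms: frozenset = frozenset()
    scoc_flag: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")


@dataclass(frozen=True)
class CleavageEvent:
    """One observed D|X proteolysis site in one biological replicate.

    ``p1_position`` is the 1-based index of the P1 aspartate; the cut lies
    between P1 and P1'.  ``context`` is the P4-P4' octamer (positions
    p1-3 .. p1+4), right-padded with X past the C terminus.  Events read
    from context-only site tables may omit the coordinate.
    """

    replicate_id: str
    accession: str
    context: str
    p1_position: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.context) != 8:
            raise ValueError(
                f"context must be 8 residues (P4-P4'), got {self.context!r}"
            )
        if self.context[3] != "D":
            raise ValueError(f"context {self.context!r} lacks the P1 aspartate at index 3")
        if self.p1_position is not None and self.p1_position < 5:
            raise ValueError(
                f"p1_position {self.p1_position} < 5: no full P4 context exists"
            )

    @property
    def site_key(self) -> tuple:
        return (self.accession, self.p1_position, self.context)


@dataclass
class TestResult:
    """Outcome of one enrichment test: fold, mid-p, optional FDR q."""

    p_mid: float
    fold_enrichment: Optional[float] = None
    q_fdr: Optional[float] = None

    @property
    def direction(self) -> str:
        if self.fold_enrichment is None:
            return "none"
        if self.fold_enrichment > 1:
            return "enriched"
        if self.fold_enrichment < 1:
            return "de-enriched"
        return "none"


@dataclass
class MonteCarloResult:
    """Observed vs simulated protein-cleavage totals for one motif or pair."""

    target: object  # Motif or MotifPair
    observed_C: int
    expected_mean: float
    p_mid: float
    p_is_upper_bound: bool
    n_sims: int
    seed: int
    expected_analytic: float = 0.0
    q_fdr: Optional[float] = None

    @property
    def fold(self) -> Optional[float]:
        if self.expected_mean > 0:
            return self.observed_C / self.expected_mean
        return None


@dataclass
class PairPoint:
    """A motif pair positioned on the specificity/coverage plane.

    ``scoc_proportion`` is the share of all observed flagged
    protein-cleavages attributable to the pair; ``fold`` is the Monte Carlo
    fold enrichment.
    """

    pair: MotifPair
    fold: float
    scoc_proportion: float
    p_mid: float
    eligible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.scoc_proportion <= 1.0:
            raise ValueError("scoc_proportion must lie in [0, 1]")
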