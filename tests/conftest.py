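"""Shared fixtures: hand-sized degradomes with known counts."""

from __future__ import annotations

import pytest

from dxsite.models import CleavageEvent, ProteinRecord


def make_event(replicate: str, accession: str, p1: int, p2_residue: str = "A",
               p3_residue: str = "A", p4_residue: str = "A") -> CleavageEvent:
    """Event with an explicit P4-P2 context (P1' side is irrelevant here)."""
    context = f"{p4_residue}{p3_residue}{p2_residue}DAAAA"
    return CleavageEvent(replicate_id=replicate, accession=accession,
                         p1_position=p1, context=context)


@pytest.fixture
def tiny_protein():
    # D at 1-based positions 6, 8, 11; full P4 windows for all three
    return ProteinRecord(accession="P1", sequence="MAIRGDSDGVDK")


@pytest.fixture
def small_null_instance():
    """Two replicates, flagged {A,B,C}, hand-computable GD frequencies.

    rep1: n=6 sites, k=3 at GD (A: 2 sites 1 GD; B: 1 GD site; D: 3 sites 1 GD)
    rep2: n=4 sites, k=2 at GD (A: 1 non-GD; C: 2 sites 1 GD; E: 1 GD)
    Observed flagged protein-cleavages at GD: A(rep1), B(rep1), C(rep2) = 3.
    """
    events = [
        make_event("r1", "A", 10, "G"),
        make_event("r1", "A", 20, "A"),
        make_event("r1", "B", 10, "G"),
        make_event("r1", "D", 10, "G"),
        make_event("r1", "D", 20, "A"),
        make_event("r1", "D", 30, "A"),
        make_event("r2", "A", 30, "A"),
        make_event("r2", "C", 10, "G"),
        make_event("r2", "C", 20, "A"),
        make_event("r2", "E", 10, "G"),
    ]
    return events, {"A", "B", "C"}
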