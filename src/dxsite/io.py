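"""Readers and writers for proteomes, peptide evidence and site tables.

Conventions (stated in every file this module writes): coordinates are
1-based; cleavage falls between P1 and P1'; contexts are the 8-residue
P4-P4' window, right-padded with X past the carboxy terminus.

Evidence tables are delimited text (tab or comma, sniffed) with columns
``replicate``, ``peptide``, ``accession`` and optionally ``start`` (1-based
position of the peptide's first residue).  Site tables come in two
dialects: long (``accession``, ``p1``, ``context``, ``replicate``) and
wide Degrabase-style (``accession``, ``context`` and one 0/1 indicator
column per replicate).  Gzip-compressed inputs are handled transparently.
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .models import CleavageEvent, ProteinRecord

PathLike = Union[str, Path]

COORDINATE_HEADER = (
    "# coordinates: 1-based; cleavage between P1 and P1'; "
    "context = P4-P4' octamer, X-padded at the C terminus\n"
)


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_accession(header_token: str) -> str:
    # UniProt convention: "db|ACCESSION|ENTRY_NAME"
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_token


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a proteome FASTA into ProteinRecords.

    The accession is the first whitespace-delimited header token, with
    UniProt ``db|ACC|name`` headers reduced to ACC.  Sequences are
    uppercased.  Duplicate accessions and empty files are format errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            accession = _parse_accession(entry.id)
            if accession in seen:
                raise ValueError(f"duplicate accession {accession!r} in {path}")
            seen.add(accession)
            records.append(ProteinRecord(accession=accession, sequence=str(entry.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def proteome_index(proteome: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.accession: rec for rec in proteome}


def context_at(sequence: str, p1: int) -> str:
    """P4-P4' octamer around the 1-based P1 position, X-padded on the right."""
    window = sequence[p1 - 4 : p1 + 4]
    return window + "X" * (8 - len(window))


def read_evidence(path: PathLike, replicate_col: str = "replicate") -> pd.DataFrame:
    """Read a peptide-evidence table (replicate, peptide, accession[, start])."""
    with _open_text(path) as handle:
        table = pd.read_csv(handle, sep=None, engine="python", comment="#")
    table = table.rename(columns={replicate_col: "replicate"})
    required = {"replicate", "peptide", "accession"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"evidence table {path} lacks columns: {sorted(missing)}")
    table["peptide"] = table["peptide"].astype(str).str.upper()
    table["replicate"] = table["replicate"].astype(str)
    table["accession"] = table["accession"].astype(str)
    return table


def extract_cleavage_sites(
    evidence: pd.DataFrame,
    proteome: Iterable[ProteinRecord],
) -> list[CleavageEvent]:
    """Derive D|X cleavage events from neo-N-terminal peptide evidence.

    A row contributes an event when the residue immediately preceding the
    peptide's start is aspartate; P1 = start - 1.  Events with P1 < 5 are
    dropped (no full P4 context).  Peptides without a stated start are
    located by exact substring search and yield one event per match, in
    every protein whose accession matches when the accession is ambiguous
    only through duplicates.  Events are deduplicated within
    (replicate, accession, P1).
    """
    index = proteome_index(proteome)
    missing = sorted(set(evidence["accession"]) - set(index))
    if missing:
        raise KeyError(f"accessions absent from proteome: {missing}")

    have_start = "start" in evidence.columns
    seen: set[tuple] = set()
    events: list[CleavageEvent] = []
    for row in evidence.itertuples(index=False):
        peptide = row.peptide
        # (accession, sequence, start) triples the peptide maps to
        matches: list[tuple[str, str, int]] = []
        if have_start and not pd.isna(getattr(row, "start")):
            sequence = index[row.accession].sequence
            start = int(getattr(row, "start"))
            if sequence[start - 1 : start - 1 + len(peptide)] != peptide:
                raise ValueError(
                    f"peptide {peptide!r} not found at stated start {start} "
                    f"in {row.accession}"
                )
            matches.append((row.accession, sequence, start))
        else:
            # no coordinate: exact substring search; a peptide shared by
            # several proteins yields an event per match (family collapse
            # may merge them later)
            for record in index.values():
                pos = record.sequence.find(peptide)
                while pos != -1:
                    matches.append((record.accession, record.sequence, pos + 1))
                    pos = record.sequence.find(peptide, pos + 1)
            if not matches:
                raise ValueError(
                    f"peptide {peptide!r} (accession {row.accession}) not found "
                    "in any proteome sequence"
                )
        for accession, sequence, start in matches:
            p1 = start - 1
            if p1 < 5:
                continue  # P1 at the very N terminus or missing P4 context
            if sequence[p1 - 1] != "D":
                continue  # not a D|X neo-N terminus
            key = (row.replicate, accession, p1)
            if key in seen:
                continue
            seen.add(key)
            events.append(
                CleavageEvent(
                    replicate_id=row.replicate,
                    accession=accession,
                    p1_position=p1,
                    context=context_at(sequence, p1),
                )
            )
    return events


def collapse_family_duplicates(
    events: Sequence[CleavageEvent],
    enabled: bool = True,
) -> tuple[list[CleavageEvent], list[dict]]:
    """Merge same-replicate events from different proteins with identical
    P4-P4' contexts (family duplicates) into a single event.

    Protein families are not computable from sequence headers alone, so an
    identical context octamer across accessions is used as a conservative
    proxy.  The surviving event keeps the lexicographically smallest
    accession; a merge log records what was discarded.  Identical contexts
    within one accession (distinct sites) are never merged.
    """
    if not enabled:
        return list(events), []
    groups: dict[tuple, list[CleavageEvent]] = defaultdict(list)
    for event in events:
        groups[(event.replicate_id, event.context)].append(event)
    kept: list[CleavageEvent] = []
    log: list[dict] = []
    for (replicate, context), members in groups.items():
        accessions = sorted({m.accession for m in members})
        if len(accessions) == 1:
            kept.extend(members)
            continue
        keep_acc = accessions[0]
        survivors = [m for m in members if m.accession == keep_acc]
        kept.extend(survivors)
        log.append(
            {
                "replicate": replicate,
                "context": context,
                "kept": keep_acc,
                "discarded": [a for a in accessions if a != keep_acc],
            }
        )
    return kept, log


def read_site_table(path: PathLike) -> list[CleavageEvent]:
    """Read a cleavage-site table into events.

    Long dialect rows are (accession, p1, context, replicate); wide
    Degrabase-style rows are (accession[, p1], context, one indicator
    column per replicate), expanding to one event per truthy indicator.
    Contexts must carry the P1 aspartate at index 3.
    """
    with _open_text(path) as handle:
        table = pd.read_csv(handle, sep=None, engine="python", comment="#")
    cols = set(table.columns)
    if not {"accession", "context"} <= cols:
        raise ValueError(f"site table {path} needs 'accession' and 'context' columns")
    events: list[CleavageEvent] = []
    replicate_cols = [c for c in table.columns if c not in {"accession", "context", "p1"}]
    long_format = "replicate" in cols
    for i, row in enumerate(table.itertuples(index=False), start=2):
        context = str(row.context).upper()
        if len(context) != 8 or context[3] != "D":
            raise ValueError(
                f"{path} row {i}: context {context!r} lacks a P1 aspartate at P4-P4' index 3"
            )
        p1 = int(row.p1) if "p1" in cols and not pd.isna(row.p1) else None
        accession = str(row.accession)
        if long_format:
            events.append(
                CleavageEvent(
                    replicate_id=str(row.replicate),
                    accession=accession,
                    p1_position=p1,
                    context=context,
                )
            )
        else:
            for col in replicate_cols:
                if bool(int(getattr(row, col))):
                    events.append(
                        CleavageEvent(
                            replicate_id=str(col),
                            accession=accession,
                            p1_position=p1,
                            context=context,
                        )
                    )
    return events


def write_site_table(events: Sequence[CleavageEvent], path: PathLike) -> None:
    """Write events in the long site-table dialect (round-trips through
    :func:`read_site_table`)."""
    frame = pd.DataFrame(
        {
            "accession": [e.accession for e in events],
            "p1": [e.p1_position for e in events],
            "context": [e.context for e in events],
            "replicate": [e.replicate_id for e in events],
        }
    )
    with open(path, "wt") as handle:
        handle.write(COORDINATE_HEADER)
        frame.to_csv(handle, sep="\t", index=False)
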