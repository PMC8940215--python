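"""Synthetic degradome generator with known ground truth.

Emulates the statistical structure the analysis assumes: a proteome of
i.i.d. random sequences; a flagged ("SCoC-like") substrate subset; and
replicate-structured D|X cleavage events drawn without replacement within
each replicate, with per-site propensity shaped by multiplicative subsite
motif weights, an extra motif boost restricted to flagged substrates, and
a flagged-substrate site-count multiplier.  Evidence rows carry the
C-terminal (neo-N-terminal) peptide so the D|X extraction path is
exercised end to end.

What it deliberately does not emulate: mass-spectral detectability bias,
missed/semi-specific cleavages beyond the tryptic-like C terminus, and
protein abundance structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .io import COORDINATE_HEADER, context_at
from .models import AMINO_ACIDS, CleavageEvent, Motif, ProteinRecord

SCOC_TERM = ("MF", "Structural Constituent of Cytoskeleton")

#: Swiss-Prot-like background amino-acid frequencies (aspartate ~5.5%)
DEFAULT_AA_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


def _as_motif(key: Union[str, Motif]) -> Motif:
    return key if isinstance(key, Motif) else Motif.from_label(key)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a null three-replicate study.

    ``subsite_weights`` multiplies a site's sampling propensity for every
    motif its context matches (global preference); ``scoc_motif_boost``
    applies the same way but only in flagged substrates (annotation-linked
    preference); ``scoc_sites_multiplier`` inflates every flagged
    substrate's site propensity (heavier per-protein cleavage, motif-blind).
    """

    seed: int = 0
    n_replicates: int = 3
    n_proteins: int = 1000
    protein_length: tuple = (450.0, 120.0)  # mean, spread (gamma)
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    scoc_fraction: float = 0.1
    subsite_weights: Mapping[Union[str, Motif], float] = field(default_factory=dict)
    scoc_motif_boost: Mapping[Union[str, Motif], float] = field(default_factory=dict)
    events_per_replicate: int = 1000
    scoc_sites_multiplier: float = 1.0
    peptide_max_length: int = 30
    emit_start: bool = True

    def __post_init__(self) -> None:
        freqs = np.array([self.aa_frequencies[a] for a in AMINO_ACIDS], dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-6:
            freqs = freqs / freqs.sum()
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("aa_frequencies must sum to 1")
        self._freq_vector = freqs
        if not 0.0 < self.scoc_fraction < 1.0:
            raise ValueError("scoc_fraction must lie in (0, 1)")
        if self.events_per_replicate < 1:
            raise ValueError("events_per_replicate must be >= 1")
        for mapping in (self.subsite_weights, self.scoc_motif_boost):
            for key, w in mapping.items():
                _as_motif(key)
                if w <= 0:
                    raise ValueError(f"weight for {key} must be positive, got {w}")
        if self.scoc_sites_multiplier <= 0:
            raise ValueError("scoc_sites_multiplier must be positive")

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["subsite_weights"] = {_as_motif(k).label: v for k, v in self.subsite_weights.items()}
        raw["scoc_motif_boost"] = {_as_motif(k).label: v for k, v in self.scoc_motif_boost.items()}
        raw["protein_length"] = list(self.protein_length)
        return raw


@dataclass
class SyntheticDegradome:
    """Generator output: inputs for every pipeline stage plus ground truth."""

    proteome: list
    evidence: pd.DataFrame
    annotations: dict
    manifest: dict

    @property
    def flagged(self) -> set[str]:
        return set(self.manifest["flagged_accessions"])

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write FASTA / evidence TSV / annotation TSV / manifest JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "evidence": outdir / "evidence.tsv",
            "annotations": outdir / "annotations.tsv",
            "manifest": outdir / "manifest.json",
        }
        with open(paths["fasta"], "wt") as fh:
            for rec in self.proteome:
                fh.write(f">{rec.accession}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        with open(paths["evidence"], "wt") as fh:
            fh.write(COORDINATE_HEADER)
            self.evidence.to_csv(fh, sep="\t", index=False)
        rows = [
            {"accession": acc, "category": cat, "term": term}
            for acc, terms in sorted(self.annotations.items())
            for cat, term in sorted(terms)
        ]
        pd.DataFrame(rows, columns=["accession", "category", "term"]).to_csv(
            paths["annotations"], sep="\t", index=False
        )
        with open(paths["manifest"], "wt") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return paths


def _site_weight(
    context: str,
    flagged: bool,
    weights: Mapping[Motif, float],
    boosts: Mapping[Motif, float],
    sites_multiplier: float,
) -> float:
    w = 1.0
    for motif, value in weights.items():
        if motif.matches(context):
            w *= value
    if flagged:
        for motif, value in boosts.items():
            if motif.matches(context):
                w *= value
        w *= sites_multiplier
    return w


def generate(config: SyntheticConfig) -> SyntheticDegradome:
    """Draw a proteome and replicate-structured cleavage evidence.

    Candidate sites are aspartates at 1-based position >= 5 with at least
    five downstream residues (so the emitted peptide is detectable-length).
    Each replicate samples ``events_per_replicate`` distinct sites without
    replacement with probability proportional to the site weight (Gumbel
    top-k).  Byte-identical outputs for identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    mean, spread = config.protein_length
    shape = (mean / spread) ** 2
    scale = spread**2 / mean

    weights = {_as_motif(k): v for k, v in config.subsite_weights.items()}
    boosts = {_as_motif(k): v for k, v in config.scoc_motif_boost.items()}

    n_flagged = max(1, round(config.scoc_fraction * config.n_proteins))
    flagged_idx = set(
        rng.choice(config.n_proteins, size=n_flagged, replace=False).tolist()
    )

    proteome: list[ProteinRecord] = []
    site_acc: list[str] = []
    site_p1: list[int] = []
    site_context: list[str] = []
    site_w: list[float] = []
    digits = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        length = max(60, int(rng.gamma(shape, scale)))
        seq = "".join(rng.choice(alphabet, size=length, p=config._freq_vector))
        accession = f"SYN{i:0{digits}d}"
        is_flagged = i in flagged_idx
        terms = frozenset({SCOC_TERM}) if is_flagged else frozenset()
        proteome.append(
            ProteinRecord(accession=accession, sequence=seq, terms=terms,
                          scoc_flag=is_flagged)
        )
        for p1 in range(5, length - 4):  # 1-based; leaves >= 5 downstream residues
            if seq[p1 - 1] != "D":
                continue
            context = context_at(seq, p1)
            site_acc.append(accession)
            site_p1.append(p1)
            site_context.append(context)
            site_w.append(
                _site_weight(context, is_flagged, weights, boosts,
                             config.scoc_sites_multiplier)
            )

    n_sites = len(site_w)
    if n_sites < config.events_per_replicate:
        raise RuntimeError(
            f"only {n_sites} candidate sites for {config.events_per_replicate} "
            "events per replicate; enlarge the proteome or protein length"
        )
    log_w = np.log(np.asarray(site_w, dtype=float))

    rows = []
    replicate_ids = [f"rep{r + 1}" for r in range(config.n_replicates)]
    for replicate in replicate_ids:
        # Gumbel top-k == weighted sampling without replacement
        keys = log_w + rng.gumbel(size=n_sites)
        chosen = np.argsort(keys)[::-1][: config.events_per_replicate]
        for idx in sorted(chosen.tolist()):
            acc, p1 = site_acc[idx], site_p1[idx]
            seq = proteome[int(acc[3:])].sequence
            peptide = _tryptic_peptide(seq, p1, config.peptide_max_length)
            row = {"replicate": replicate, "peptide": peptide, "accession": acc}
            if config.emit_start:
                row["start"] = p1 + 1
            rows.append(row)
    evidence = pd.DataFrame(rows)

    annotations = {
        rec.accession: set(rec.terms) for rec in proteome if rec.terms
    }
    manifest = {
        "config": config.to_dict(),
        "flagged_accessions": sorted(r.accession for r in proteome if r.scoc_flag),
        "n_candidate_sites": n_sites,
        "n_events": len(rows),
        "replicates": replicate_ids,
    }
    return SyntheticDegradome(
        proteome=proteome, evidence=evidence, annotations=annotations,
        manifest=manifest,
    )


def _tryptic_peptide(sequence: str, p1: int, max_length: int) -> str:
    """Neo-N-terminal peptide: P1' onward, ending after the first K/R at
    least five residues in (tryptic-like C terminus) or at ``max_length``."""
    tail = sequence[p1 : p1 + max_length]
    for j in range(4, len(tail)):
        if tail[j] in "KR":
            return tail[: j + 1]
    return tail


def events_from(degradome: SyntheticDegradome) -> list[CleavageEvent]:
    """Ground-truth events straight from the evidence table (bypasses the
    peptide-mapping path; useful for speed in calibration runs)."""
    if "start" not in degradome.evidence.columns:
        from .io import extract_cleavage_sites

        return extract_cleavage_sites(degradome.evidence, degradome.proteome)
    index = {rec.accession: rec for rec in degradome.proteome}
    events = []
    seen = set()
    for row in degradome.evidence.itertuples(index=False):
        p1 = int(row.start) - 1
        key = (row.replicate, row.accession, p1)
        if key in seen:
            continue
        seen.add(key)
        events.append(
            CleavageEvent(
                replicate_id=row.replicate,
                accession=row.accession,
                p1_position=p1,
                context=context_at(index[row.accession].sequence, p1),
            )
        )
    return events


def degrabase_like(config: SyntheticConfig) -> pd.DataFrame:
    """Wide site table (accession, p1, context, one indicator column per
    replicate), the dialect of large curated cleavage-site compendia."""
    degradome = generate(config)
    events = events_from(degradome)
    replicates = degradome.manifest["replicates"]
    sites: dict[tuple, dict] = {}
    for event in events:
        key = (event.accession, event.p1_position, event.context)
        row = sites.setdefault(
            key,
            {"accession": event.accession, "p1": event.p1_position,
             "context": event.context, **{rep: 0 for rep in replicates}},
        )
        row[event.replicate_id] = 1
    return pd.DataFrame(sorted(sites.values(), key=lambda r: (r["accession"], r["p1"])))
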