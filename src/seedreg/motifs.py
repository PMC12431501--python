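"""IUPAC consensus motif matching against promoter sequences.

Plant cis-regulatory elements (PLACE-style) are short degenerate consensus
strings over the IUPAC nucleotide alphabet (R = A/G, Y = C/T, H = A/C/T, ...).
Matching is binary: a window matches when every position's base belongs to
the allowed set of the corresponding consensus code. All overlapping
occurrences are counted. A hard-masked N in the sequence satisfies only the
consensus code N, so masked regions never inflate counts.

Scanning is single-strand (the consensus orientation) by default; with
``both_strands`` the reverse complement of the consensus is scanned too and
such hits carry ``strand_of_match='revcomp'``.

The genome-wide background model for enrichment is the per-window occurrence
rate: total occurrences over total scannable windows (sum over promoters of
max(0, L - m + 1), doubled when both strands are scanned).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from seedreg.promoters import PromoterSet

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus element, e.g. RYREPEATGMGY2 = CATGCAT."""

    name: str
    consensus: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(
                f"motif {self.name}: consensus must be >= 4 bases, "
                f"got {self.consensus!r}"
            )
        iupac_matcher(self.consensus)  # validates characters

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    promoter_gene_id: str
    offset: int  # 0-based match start within the promoter sequence
    strand_of_match: str  # 'given' or 'revcomp'


@dataclass(frozen=True)
class BackgroundModel:
    """Genome-wide per-window occurrence rate of one motif."""

    motif_name: str
    total_occurrences: int
    total_windows: int

    @property
    def rate(self) -> float:
        return self.total_occurrences / self.total_windows


def iupac_matcher(consensus: str) -> list[frozenset[str]]:
    """Per-position allowed-base sets for an IUPAC consensus string."""
    sets = []
    for i, code in enumerate(consensus.upper()):
        if code not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC code {code!r} at position {i + 1} of {consensus!r}"
            )
        sets.append(IUPAC_CODES[code])
    return sets


def reverse_complement_consensus(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (degenerate codes mapped)."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus.upper()))


def _compile(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found; sequence N matches
    # only the consensus code N
    classes = []
    for code, allowed in zip(consensus.upper(), iupac_matcher(consensus)):
        chars = "".join(sorted(allowed)) + ("N" if code == "N" else "")
        classes.append(f"[{chars}]")
    return re.compile("(?=" + "".join(classes) + ")")


def scan_sequence(
    seq: str,
    motif: Motif,
    both_strands: bool = False,
    gene_id: str = "",
) -> list[MotifHit]:
    """All (overlapping) occurrences of a motif in one sequence, sorted by offset."""
    seq = seq.upper()
    hits = [
        MotifHit(motif.name, gene_id, m.start(), "given")
        for m in _compile(motif.consensus).finditer(seq)
    ]
    if both_strands:
        rc = reverse_complement_consensus(motif.consensus)
        hits.extend(
            MotifHit(motif.name, gene_id, m.start(), "revcomp")
            for m in _compile(rc).finditer(seq)
        )
    return sorted(hits, key=lambda h: (h.offset, h.strand_of_match))


def count_occurrences(
    ps: PromoterSet, motif: Motif, both_strands: bool = False
) -> pd.DataFrame:
    """Per-promoter hit and window counts for one motif.

    Windows per promoter = max(0, L - m + 1), doubled when both strands are
    scanned.
    """
    m = len(motif)
    factor = 2 if both_strands else 1
    rows = []
    for rec in ps:
        n_hits = len(scan_sequence(rec.seq, motif, both_strands, rec.gene_id))
        windows = factor * max(0, len(rec.seq) - m + 1)
        rows.append((rec.gene_id, n_hits, windows))
    return pd.DataFrame(rows, columns=["gene_id", "hits", "windows"])


def build_background(
    ps: PromoterSet,
    motifs: Sequence[Motif],
    both_strands: bool = False,
) -> dict[str, BackgroundModel]:
    """Genome-wide occurrence rate per motif over a (large) promoter set."""
    if len(ps) < 2:
        raise ValueError("background promoter set must contain >= 2 records")
    models = {}
    for motif in motifs:
        counts = count_occurrences(ps, motif, both_strands)
        total_windows = int(counts["windows"].sum())
        if total_windows == 0:
            raise ValueError(
                f"motif {motif.name} ({len(motif)} bp) is longer than every promoter"
            )
        models[motif.name] = BackgroundModel(
            motif_name=motif.name,
            total_occurrences=int(counts["hits"].sum()),
            total_windows=total_windows,
        )
        logger.info(
            "background %s: %d occurrence(s) / %d windows (rate %.3g)",
            motif.name,
            models[motif.name].total_occurrences,
            total_windows,
            models[motif.name].rate,
        )
    return models


def scan_promoter_set(
    ps: PromoterSet, motifs: Sequence[Motif], both_strands: bool = False
) -> list[MotifHit]:
    """All hits of all motifs across a promoter set."""
    hits: list[MotifHit] = []
    for rec in ps:
        for motif in motifs:
            hits.extend(scan_sequence(rec.seq, motif, both_strands, rec.gene_id))
    return hits


def write_hits_bed(hits: Iterable[MotifHit], motifs: Sequence[Motif], path) -> None:
    """BED-like TSV of hits: 0-based half-open promoter-local coordinates."""
    length_of = {m.name: len(m) for m in motifs}
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tmotif_name\tstrand_of_match\n")
        for h in hits:
            fh.write(
                f"{h.promoter_gene_id}\t{h.offset}\t"
                f"{h.offset + length_of[h.motif_name]}\t{h.motif_name}\t"
                f"{h.strand_of_match}\n"
            )


def read_motif_library(path) -> list[Motif]:
    """Read a motif library TSV with columns name, consensus, description."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "consensus"):
        if col not in table.columns:
            raise ValueError(f"motif library missing column {col!r}")
    return [
        Motif(row["name"], row["consensus"], row.get("description", ""))
        for _, row in table.iterrows()
    ]


def load_place_motifs() -> list[Motif]:
    """The packaged library of ten PLACE consensus elements."""
    with resources.as_file(
        resources.files("seedreg.data").joinpath("place_seed_elements.tsv")
    ) as p:
        return read_motif_library(p)
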