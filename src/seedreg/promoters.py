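"""Strand-aware extraction of fixed-length promoter windows upstream of the start codon.

The promoter of a gene is defined here as the window of ``length`` bases
(default 2000) immediately upstream of the translation start: the first CDS
base of the representative mRNA on the + strand, the last CDS base on the -
strand. Minus-strand promoters are reverse-complemented so the 3' end of the
returned sequence abuts the start codon. Windows are clipped at chromosome
boundaries and flagged ``truncated``; overlap with neighbouring genes is not
masked. Coordinates are 1-based inclusive (GFF3 convention) throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pyfaidx
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    seq: str
    chrom: str
    start: int  # 1-based inclusive genomic window
    end: int
    strand: str  # '+' or '-'
    truncated: bool

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.seq) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.seq)} does not "
                f"match window {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class PromoterSet:
    records: list[PromoterRecord]
    requested_length: int = 2000

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in promoter set")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, gene_id: str) -> PromoterRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)


def locate_start_codons(gff3_path) -> dict[str, tuple[str, str, int]]:
    """Map gene id -> (chrom, strand, start-codon coordinate) from a GFF3 file.

    The representative mRNA is the first child mRNA by ID order (no canonical
    flag handling); its start codon is the minimum CDS start (+ strand) or
    maximum CDS end (- strand). Genes whose representative transcript has no
    CDS are skipped with a warning. Genes carrying CDS features directly
    (no mRNA level) are accepted.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, tuple[str, str, int]] = {}
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA", level=1), key=lambda f: f.id
        )
        if mrnas:
            cds = list(db.children(mrnas[0], featuretype="CDS"))
        else:
            cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            n_skipped += 1
            continue
        if gene.strand == "+":
            coord = min(c.start for c in cds)
        else:
            coord = max(c.end for c in cds)
        out[gene.id] = (gene.seqid, gene.strand, coord)
    logger.info("located start codons for %d gene(s); %d skipped",
                len(out), n_skipped)
    return out


def _clean(seq: str) -> str:
    """Uppercase and collapse non-ACGT characters to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(b if b in _VALID_BASES else "N" for b in seq)


def extract_promoter(
    genome: pyfaidx.Fasta,
    gene_id: str,
    chrom: str,
    strand: str,
    cds_start: int,
    length: int = 2000,
) -> PromoterRecord:
    """Extract the ``length`` bases immediately upstream of the start codon.

    Plus strand: genomic window [cds_start - length, cds_start - 1], clipped
    at 1. Minus strand: [cds_start + 1, cds_start + length], clipped at the
    chromosome end, then reverse-complemented. Raises ValueError when no
    upstream base exists at all.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome FASTA")
    if length < 1:
        raise ValueError("length must be >= 1")
    chrom_len = len(genome[chrom])
    if strand == "+":
        start = max(1, cds_start - length)
        end = cds_start - 1
        if end < start:
            raise ValueError(
                f"{gene_id}: start codon at {chrom}:{cds_start} has no upstream sequence"
            )
        seq = genome[chrom][start - 1:end].seq
    elif strand == "-":
        start = cds_start + 1
        end = min(chrom_len, cds_start + length)
        if end < start:
            raise ValueError(
                f"{gene_id}: start codon at {chrom}:{cds_start} has no upstream sequence"
            )
        seq = str(Seq(genome[chrom][start - 1:end].seq).reverse_complement())
    else:
        raise ValueError(f"bad strand {strand!r}")
    seq = _clean(seq)
    return PromoterRecord(
        gene_id=gene_id,
        seq=seq,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        truncated=len(seq) < length,
    )


def extract_promoters(
    genome_fasta, gff3_path, length: int = 2000
) -> PromoterSet:
    """Extract promoters for every CDS-bearing gene in a GFF3 annotation."""
    genome = pyfaidx.Fasta(str(genome_fasta))
    starts = locate_start_codons(gff3_path)
    records = []
    n_failed = 0
    for gene_id, (chrom, strand, coord) in starts.items():
        try:
            records.append(
                extract_promoter(genome, gene_id, chrom, strand, coord, length)
            )
        except (ValueError, KeyError) as exc:
            logger.warning("promoter extraction failed for %s: %s", gene_id, exc)
            n_failed += 1
    logger.info("extracted %d promoter(s), %d failed", len(records), n_failed)
    return PromoterSet(records=records, requested_length=length)


def write_promoters(ps: PromoterSet, path) -> None:
    """Write a promoter set as FASTA, header ``gene_id chrom:start-end(strand)``."""
    if not ps.records:
        logger.warning("writing empty promoter set to %s", path)
    seq_records = [
        SeqRecord(
            Seq(r.seq),
            id=r.gene_id,
            description=f"{r.chrom}:{r.start}-{r.end}({r.strand})",
        )
        for r in ps.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_promoters(path, requested_length: int = 2000) -> PromoterSet:
    """Read back a promoter FASTA written by :func:`write_promoters`.

    Headers without the ``chrom:start-end(strand)`` annotation are accepted:
    coordinates then default to a 1-based window on an unnamed contig.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean(str(rec.seq))
        desc = rec.description.split(maxsplit=1)
        chrom, start, end, strand = rec.id, 1, len(seq), "+"
        if len(desc) == 2:
            m = re.fullmatch(r"(\S+):(\d+)-(\d+)\(([+-])\)", desc[1].strip())
            if m:
                chrom, start, end, strand = (
                    m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
                )
        records.append(
            PromoterRecord(
                gene_id=rec.id,
                seq=seq,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                truncated=len(seq) < requested_length,
            )
        )
    return PromoterSet(records=records, requested_length=requested_length)
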