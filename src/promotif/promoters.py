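"""Strand-aware promoter extraction from genome FASTA + GFF3 annotation.

The promoter of a gene is a fixed window around its transcription start
site (TSS): ``upstream`` bases before the TSS and ``downstream`` bases
after it, in transcription orientation. The TSS is the 5' end of the
``gene`` feature — the feature start for '+' genes, the feature end for
'-' genes. Minus-strand promoter sequences are reverse-complemented so
every returned sequence reads 5'->3' relative to transcription.

Coordinates are 0-based half-open throughout; GFF3's 1-based closed
intervals are converted at the reader boundary (see :mod:`promotif.io`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

from .errors import InputError

log = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 200


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Promoter:
    """A promoter window with its genomic footprint.

    ``sequence`` always reads 5'->3' relative to transcription: for a
    '-' strand gene it is the reverse complement of the genomic slice
    ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    clipped: bool = False

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise InputError(f"promoter {self.gene_id}: invalid interval "
                             f"[{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise InputError(f"promoter {self.gene_id}: sequence length "
                             f"{len(self.sequence)} != interval span {self.end - self.start}")


def promoter_interval(tss: int, strand: str, upstream: int, downstream: int,
                      chrom_length: int) -> tuple[int, int, bool]:
    """Genomic [start, end) of the promoter window, clipped to the chromosome.

    '+': [tss - upstream, tss + downstream); '-': [tss - downstream,
    tss + upstream). Returns (start, end, was_clipped).
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise InputError(f"invalid strand {strand!r}")
    clipped = start < 0 or end > chrom_length
    return max(0, start), min(chrom_length, end), clipped


def gene_tss(start: int, end: int, strand: str) -> int:
    """TSS of a gene feature in 0-based half-open terms (5' end of the gene)."""
    return start if strand == "+" else end


def extract_promoters(genome: Mapping[str, str], annotation: pd.DataFrame,
                      upstream: int = DEFAULT_UPSTREAM,
                      downstream: int = DEFAULT_DOWNSTREAM) -> list[Promoter]:
    """One promoter per annotated gene, in annotation order.

    Windows extending past a chromosome edge are clipped (and logged).
    Genes on chromosomes absent from the genome, or with a TSS outside the
    chromosome, are an input error listing the offenders.
    """
    if upstream < 0 or downstream < 0 or upstream + downstream <= 0:
        raise InputError("upstream/downstream must be >= 0 with a positive sum")
    missing = sorted(set(annotation["chrom"]) - set(genome))
    if missing:
        genes = annotation.loc[annotation["chrom"].isin(missing), "gene_id"].tolist()
        raise InputError(f"chromosomes {missing} absent from genome "
                         f"(genes: {genes})")
    promoters: list[Promoter] = []
    n_clipped = 0
    for row in annotation.itertuples(index=False):
        chrom_len = len(genome[row.chrom])
        tss = gene_tss(row.start, row.end, row.strand)
        if not 0 <= tss <= chrom_len:
            raise InputError(f"gene {row.gene_id}: TSS {tss} outside chromosome "
                             f"{row.chrom} (length {chrom_len})")
        start, end, clipped = promoter_interval(tss, row.strand, upstream,
                                                downstream, chrom_len)
        seq = genome[row.chrom][start:end]
        if row.strand == "-":
            seq = reverse_complement(seq)
        if clipped:
            n_clipped += 1
        promoters.append(Promoter(row.gene_id, row.chrom, start, end,
                                  row.strand, seq, clipped))
    if n_clipped:
        log.info("clipped %d promoter window(s) at chromosome bounds", n_clipped)
    return promoters


# ---------------------------------------------------------------------------
# Serialization

_HEADER_RE = re.compile(r"^(\S+)\s+(\S+):(\d+)-(\d+)\(([+-])\)(?:\s+clipped)?$")


def write_promoters_fasta(promoters, path: str | Path) -> None:
    """FASTA with headers ``>gene_id chrom:start-end(strand)`` (0-based half-open)."""
    with open(path, "w") as fh:
        for p in promoters:
            tag = " clipped" if p.clipped else ""
            fh.write(f">{p.gene_id} {p.chrom}:{p.start}-{p.end}({p.strand}){tag}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def read_promoters_fasta(path: str | Path) -> list[Promoter]:
    promoters = []
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        m = _HEADER_RE.match(header)
        if not m:
            raise InputError(f"unparseable promoter header: >{header}")
        gene_id, chrom, start, end, strand = m.groups()
        promoters.append(Promoter(gene_id, chrom, int(start), int(end), strand,
                                  "".join(chunks), clipped=header.endswith("clipped")))

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            header, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    if not promoters:
        raise InputError(f"no promoters found in {path}")
    return promoters


def write_promoters_bed(promoters, path: str | Path) -> None:
    """BED6 of promoter genomic intervals (score column carries 0)."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n")
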