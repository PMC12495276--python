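"""Readers and writers for the plain-text formats the pipeline exchanges.

Genome: FASTA (60-character lines, via Bio.SeqIO).
Annotation: GFF3, 1-based closed intervals, ``gene`` features with ``ID=``
attributes; converted to 0-based half-open coordinates at the read boundary.
Tables: TSV with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into ``{chrom: uppercase sequence}``."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise InputError(f"duplicate sequence id in FASTA: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise InputError(f"no sequences found in {path}")
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read ``gene`` features from GFF3 into a 0-based half-open table.

    Columns: gene_id, chrom, start, end, strand. GFF3 is 1-based closed, so
    start is shifted by -1 on read.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True,
                            merge_strategy="error")
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise InputError(f"duplicate gene ids in annotation: {dups}")
    return ann


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation table as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tpromotif\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix (first column gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise InputError("duplicate gene ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise InputError("count matrix contains negative values")
    return counts


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
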