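"""Synthetic genome, annotation, motif plantings and RNA-seq counts.

The simulator builds a complete, ground-truthed test bed for the promoter
binding-site enrichment pipeline:

* an i.i.d. random genome at a configurable GC content;
* non-overlapping single-transcript genes laid out in fixed-width slots so
  that every promoter window fits inside its slot without touching a
  neighbouring gene body;
* motif instances sampled column-wise from a PFM and written over promoter
  bases — Poisson(rate_enriched) instances per promoter for genes in a
  designated "enriched" set, Poisson(rate_background) elsewhere;
* negative-binomial counts for a two-group design with fold changes of
  magnitude 2**planted_lfc_magnitude planted in a random subset of genes
  (variance m + dispersion * m**2 around mean m).

Ground truth (which genes are enriched, where every instance sits, which
genes carry which fold change) is returned alongside the data so every
downstream stage can be scored for recovery.

All randomness derives from one master seed through named substreams
("genome", "annotation", "plant", "counts", "coupling"), so each stage is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .errors import ConfigurationError
from .motifs import PFM, consensus_pfm
from .promoters import promoter_interval, gene_tss, reverse_complement
from .rng import substream

log = logging.getLogger(__name__)

# DR1-like direct repeat used as the default planted motif
DEFAULT_CONSENSUS = "AGGTCAAAGGTCA"

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate a small two-group fibroblast-style contrast: 2000
    genes, 4 samples per group, 5% of genes differentially expressed at
    |log2FC| = 2, and a 50-gene subset of the DE genes whose promoters
    carry ~3 planted motif instances each versus ~0.3 in the background.
    """

    n_chromosomes: int = 4
    chrom_length: int = 3_000_000
    gc_content: float = 0.41
    n_genes: int = 2000
    gene_length: int = 1000
    gene_spacing: int = 500
    promoter_window: tuple[int, int] = (2000, 200)  # (upstream, downstream)
    enriched_set_size: int = 50
    rate_enriched: float = 3.0
    rate_background: float = 0.3
    n_samples_per_group: int = 4
    de_fraction: float = 0.05
    planted_lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    mean_expression: float = 100.0
    enriched_from_de: bool = True
    seed: int = 0

    @property
    def slot_width(self) -> int:
        pad = max(self.promoter_window)
        return self.gene_length + 2 * pad + self.gene_spacing

    def validate(self) -> list[str]:
        """Every violated constraint, as 'field: problem' strings."""
        problems = []
        if not 0.0 <= self.gc_content <= 1.0:
            problems.append("gc_content: must be in [0, 1]")
        if self.n_chromosomes < 1:
            problems.append("n_chromosomes: must be >= 1")
        if self.n_genes < 0:
            problems.append("n_genes: must be >= 0")
        if self.gene_length < 1:
            problems.append("gene_length: must be >= 1")
        up, down = self.promoter_window
        if up < 0 or down < 0 or up + down <= 0:
            problems.append("promoter_window: upstream/downstream >= 0, sum > 0")
        if self.rate_enriched < 0:
            problems.append("rate_enriched: must be >= 0")
        if self.rate_background < 0:
            problems.append("rate_background: must be >= 0")
        if not 0 <= self.enriched_set_size <= self.n_genes:
            problems.append("enriched_set_size: must be in [0, n_genes]")
        if self.n_samples_per_group < 2:
            problems.append("n_samples_per_group: must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            problems.append("de_fraction: must be in [0, 1]")
        if self.nb_dispersion <= 0:
            problems.append("nb_dispersion: must be > 0")
        if self.mean_expression <= 0:
            problems.append("mean_expression: must be > 0")
        if self.n_genes > 0:
            capacity = self.n_chromosomes * (self.chrom_length // self.slot_width)
            if capacity < self.n_genes:
                problems.append(
                    f"chrom_length: {self.n_genes} genes need "
                    f"{self.slot_width} bp slots but only {capacity} fit")
        return problems

    def check(self) -> "SimulationConfig":
        problems = self.validate()
        if problems:
            raise ConfigurationError("; ".join(problems))
        return self


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover."""

    enriched_gene_ids: frozenset[str] = frozenset()
    planted_instances: list[tuple[str, int, str]] = field(default_factory=list)
    de_log2fc: dict[str, float] = field(default_factory=dict)

    @property
    def de_gene_ids(self) -> frozenset[str]:
        return frozenset(self.de_log2fc)

    def instances_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.planted_instances,
                            columns=["gene_id", "offset", "strand"])

    def write_tsv(self, path: str | Path) -> None:
        """Sidecar TSV: one row per gene with its planted attributes."""
        genes = sorted(self.enriched_gene_ids | self.de_gene_ids |
                       {g for g, _, _ in self.planted_instances})
        inst = self.instances_frame()
        n_inst = inst.groupby("gene_id").size() if len(inst) else pd.Series(dtype=int)
        rows = [{"gene_id": g,
                 "enriched": g in self.enriched_gene_ids,
                 "n_planted_instances": int(n_inst.get(g, 0)),
                 "true_log2fc": self.de_log2fc.get(g, 0.0)} for g in genes]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _gene_id_format(n_genes: int) -> str:
    return "g{:0" + str(max(4, len(str(n_genes)))) + "d}"


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """i.i.d. genome at the configured GC content; substream 'genome'."""
    config.check()
    rng = substream(config.seed, "genome")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A,C,G,T
    genome = {}
    for c in range(config.n_chromosomes):
        codes = rng.choice(4, size=config.chrom_length, p=probs)
        genome[f"chr{c + 1}"] = bytes(_DECODE[codes]).decode("ascii")
    return genome


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay genes into fixed-width slots, round-robin over chromosomes.

    Each slot reserves max(upstream, downstream) of padding on both sides
    of the gene body, so promoters never reach a neighbouring gene body
    and never need clipping. Strands are drawn from substream 'annotation'.
    """
    config.check()
    if config.n_genes == 0:
        return pd.DataFrame(columns=pio.ANNOTATION_COLUMNS)
    rng = substream(config.seed, "annotation")
    pad = max(config.promoter_window)
    fmt = _gene_id_format(config.n_genes)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    rows = []
    per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    for i in range(config.n_genes):
        c = i % config.n_chromosomes
        start = per_chrom[c] * config.slot_width + pad
        per_chrom[c] += 1
        rows.append((fmt.format(i + 1), f"chr{c + 1}", start,
                     start + config.gene_length, strands[i]))
    return pd.DataFrame(rows, columns=pio.ANNOTATION_COLUMNS)


def _sample_instance(pfm: PFM, rng: np.random.Generator) -> str:
    """One motif instance drawn column-wise from the PFM probabilities."""
    probs = pfm.column_probabilities()
    return "".join("ACGT"[rng.choice(4, p=probs[:, j])] for j in range(pfm.length))


def plant_motifs(genome: Mapping[str, str], annotation: pd.DataFrame, pfm: PFM,
                 truth_set: Sequence[str] | frozenset[str],
                 config: SimulationConfig) -> tuple[dict[str, str], SyntheticTruth]:
    """Overwrite promoter bases with sampled motif instances.

    Per promoter, the number of instances is Poisson(rate_enriched) for
    genes in ``truth_set`` and Poisson(rate_background) otherwise. Each
    instance gets a uniform offset and strand within the promoter and never
    overlaps a previously planted instance there (instances that cannot be
    placed after 200 tries are skipped with a warning). Overwriting, not
    inserting, keeps all genomic coordinates stable.
    """
    config.check()
    up, down = config.promoter_window
    plen = up + down
    if pfm.length > plen:
        raise ConfigurationError(
            f"motif length {pfm.length} exceeds promoter length {plen}")
    unknown = set(truth_set) - set(annotation["gene_id"])
    if unknown:
        raise ConfigurationError(f"truth_set genes not in annotation: {sorted(unknown)}")
    rng = substream(config.seed, "plant")
    truth_set = frozenset(truth_set)
    mutable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    instances: list[tuple[str, int, str]] = []
    n_skipped = 0
    for row in annotation.itertuples(index=False):
        lam = config.rate_enriched if row.gene_id in truth_set else config.rate_background
        n = rng.poisson(lam)
        if n == 0:
            continue
        chrom_len = len(mutable[row.chrom])
        tss = gene_tss(row.start, row.end, row.strand)
        pstart, pend, clipped = promoter_interval(tss, row.strand, up, down, chrom_len)
        if clipped:  # slot layout should prevent this
            n_skipped += n
            continue
        occupied: list[tuple[int, int]] = []
        for _ in range(n):
            placed = False
            for _attempt in range(200):
                offset = int(rng.integers(0, plen - pfm.length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                if any(offset < e and offset + pfm.length > s for s, e in occupied):
                    continue
                placed = True
                break
            if not placed:
                n_skipped += 1
                continue
            occupied.append((offset, offset + pfm.length))
            inst = _sample_instance(pfm, rng)
            oriented = inst if strand == "+" else reverse_complement(inst)
            # map promoter offset -> genomic coordinates
            if row.strand == "+":
                gstart = pstart + offset
                genomic = oriented
            else:
                gstart = pend - offset - pfm.length
                genomic = reverse_complement(oriented)
            mutable[row.chrom][gstart:gstart + pfm.length] = genomic.encode("ascii")
            instances.append((row.gene_id, offset, strand))
    if n_skipped:
        log.warning("skipped %d motif instance(s) that could not be placed", n_skipped)
    planted = {chrom: bytes(buf).decode("ascii") for chrom, buf in mutable.items()}
    return planted, SyntheticTruth(enriched_gene_ids=truth_set,
                                   planted_instances=instances)


def generate_counts(config: SimulationConfig,
                    gene_ids: Sequence[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group negative-binomial counts with planted fold changes.

    Per-gene baseline means are log-normal around ``mean_expression``.
    Exactly round(de_fraction * n_genes) genes (random identity, random
    sign) have their group-2 mean scaled by 2**(+/-planted_lfc_magnitude).
    Counts are NB with variance m + dispersion * m**2. Returns the count
    matrix and a truth table (gene_id, true_log2fc, is_de).
    """
    config.check()
    rng = substream(config.seed, "counts")
    if gene_ids is None:
        fmt = _gene_id_format(config.n_genes)
        gene_ids = [fmt.format(i + 1) for i in range(config.n_genes)]
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    base_means = rng.lognormal(mean=np.log(config.mean_expression), sigma=1.0, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    lfc[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * config.planted_lfc_magnitude
    means2 = base_means * 2.0 ** lfc
    phi = config.nb_dispersion
    r = 1.0 / phi

    def draw(means: np.ndarray) -> np.ndarray:
        p = r / (r + means)  # mean m, variance m + phi*m^2
        return rng.negative_binomial(r, p[:, None],
                                     size=(n, config.n_samples_per_group))

    counts = np.hstack([draw(base_means), draw(means2)])
    samples = ([f"ctrl{i + 1}" for i in range(config.n_samples_per_group)] +
               [f"case{i + 1}" for i in range(config.n_samples_per_group)])
    matrix = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    truth = pd.DataFrame({"gene_id": gene_ids, "true_log2fc": lfc,
                          "is_de": lfc != 0.0})
    return matrix, truth


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, plus its ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    annotation: pd.DataFrame
    pfm: PFM
    counts: pd.DataFrame
    truth: SyntheticTruth


def simulate_all(config: SimulationConfig, pfm: PFM | None = None) -> SimulatedDataset:
    """Full synthetic study: genome, genes, counts, and planted motifs.

    With ``enriched_from_de`` (default) the motif-enriched truth set is a
    random subset of the planted DE genes — the scenario the enrichment
    statistic is meant to detect, where differentially expressed genes'
    promoters carry extra binding sites. Requires enriched_set_size <=
    number of DE genes in that mode.
    """
    config.check()
    if pfm is None:
        pfm = consensus_pfm(DEFAULT_CONSENSUS)
    genome = generate_genome(config)
    annotation = generate_annotation(config)
    counts, de_truth = generate_counts(config, annotation["gene_id"])
    de_genes = sorted(de_truth.loc[de_truth["is_de"], "gene_id"])
    rng = substream(config.seed, "coupling")
    if config.enriched_from_de:
        if config.enriched_set_size > len(de_genes):
            raise ConfigurationError(
                f"enriched_set_size ({config.enriched_set_size}) exceeds the "
                f"{len(de_genes)} planted DE genes; lower it or raise de_fraction")
        pool = de_genes
    else:
        pool = sorted(annotation["gene_id"])
    chosen = rng.choice(len(pool), size=config.enriched_set_size, replace=False)
    truth_set = frozenset(pool[i] for i in chosen)
    genome, truth = plant_motifs(genome, annotation, pfm, truth_set, config)
    truth.de_log2fc = dict(zip(de_truth.loc[de_truth["is_de"], "gene_id"],
                               de_truth.loc[de_truth["is_de"], "true_log2fc"]))
    return SimulatedDataset(config=config, genome=genome, annotation=annotation,
                            pfm=pfm, counts=counts, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Persist a dataset as FASTA / GFF3 / JASPAR / TSV; returns the paths."""
    from .motifs import write_jaspar

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fa",
             "annotation": outdir / "annotation.gff3",
             "motifs": outdir / "motifs.jaspar",
             "counts": outdir / "counts.tsv",
             "truth": outdir / "truth.tsv"}
    pio.write_genome_fasta(ds.genome, paths["genome"])
    pio.write_gene_annotation(ds.annotation, paths["annotation"])
    write_jaspar([ds.pfm], paths["motifs"])
    pio.write_counts_tsv(ds.counts, paths["counts"])
    ds.truth.write_tsv(paths["truth"])
    return paths
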