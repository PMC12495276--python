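"""End-to-end orchestration: simulate/load -> DE -> select -> promoters ->
scan -> enrichment, with a machine-readable run report.

A run is described by a :class:`RunConfig` (typically loaded from YAML).
Exactly one input mode is active: either a simulation block, or real input
paths (genome + annotation + motifs plus either a count matrix with group
labels or a precomputed DE table). All intermediate artifacts are persisted
to the output directory as plain-text formats, so any stage's output can be
inspected or fed back in. Re-running with the same config and seed
reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import io as pio
from .de import (DEFAULT_LFC_THRESHOLD, DEFAULT_P_THRESHOLD, read_de_table,
                 select_degs, simple_de, write_de_table)
from .enrichment import (DEFAULT_N_SETS, enrich_all, plot_null_curve,
                         write_null_sample)
from .errors import ConfigurationError, InputError, StageError
from .motifs import (DEFAULT_ALPHA, DEFAULT_PSEUDOCOUNT, count_hits,
                     estimate_background, pfm_to_pwm, read_jaspar,
                     scan_promoters)
from .promoters import (DEFAULT_DOWNSTREAM, DEFAULT_UPSTREAM, extract_promoters,
                        write_promoters_bed, write_promoters_fasta)
from .rng import substream_seed
from .simulate import SimulationConfig, simulate_all, write_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see ``RunConfig.from_yaml``."""

    outdir: str = "promotif_run"
    seed: int = 0
    # input mode A: simulation
    simulation: SimulationConfig | None = None
    # input mode B: real files
    genome: str | None = None
    annotation: str | None = None
    motifs: str | None = None
    counts: str | None = None
    groups: list[str] | None = None
    de_table: str | None = None
    # thresholds and windows
    p_threshold: float = DEFAULT_P_THRESHOLD
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    n_sets: int = DEFAULT_N_SETS
    upstream: int = DEFAULT_UPSTREAM
    downstream: int = DEFAULT_DOWNSTREAM
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        if sim is not None:
            if isinstance(sim, dict):
                if "promoter_window" in sim:
                    sim["promoter_window"] = tuple(sim["promoter_window"])
                sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
                bad = set(sim) - sim_known
                if bad:
                    raise ConfigurationError(f"unknown simulation keys: {sorted(bad)}")
                sim.setdefault("seed", config.seed)
                config.simulation = SimulationConfig(**sim)
            else:
                raise ConfigurationError("simulation block must be a mapping")
        return config

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Every problem with the config, each naming the offending field."""
    problems = []
    sim_mode = config.simulation is not None
    real_paths = [config.genome, config.annotation, config.motifs,
                  config.counts, config.de_table]
    real_mode = any(p is not None for p in real_paths)
    if sim_mode and real_mode:
        problems.append("simulation/inputs: exactly one of the simulation block "
                        "and real input paths may be set")
    if not sim_mode and not real_mode:
        problems.append("simulation/inputs: one input mode must be configured")
    if real_mode and not sim_mode:
        for name in ("genome", "annotation", "motifs"):
            if getattr(config, name) is None:
                problems.append(f"{name}: required for real-input runs")
        if (config.counts is None) == (config.de_table is None):
            problems.append("counts/de_table: exactly one expression input required")
        if config.counts is not None and not config.groups:
            problems.append("groups: required with a count matrix")
    if sim_mode:
        problems += [f"simulation.{p}" for p in config.simulation.validate()]
    if config.p_threshold <= 0 or config.p_threshold > 1:
        problems.append("p_threshold: must be in (0, 1]")
    if config.lfc_threshold <= 0:
        problems.append("lfc_threshold: must be > 0")
    if not 0 < config.alpha <= 1:
        problems.append("alpha: must be in (0, 1]")
    if config.pseudocount < 0:
        problems.append("pseudocount: must be >= 0")
    if config.n_sets < 1:
        problems.append("n_sets: must be >= 1")
    if config.upstream < 0 or config.downstream < 0 or \
            config.upstream + config.downstream <= 0:
        problems.append("upstream/downstream: must be >= 0 with positive sum")
    return problems


def _stage(report: dict, name: str):
    """Context manager recording stage success/failure in the report."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                report["failed_stage"] = name
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {"promotif": __version__, "python": platform.python_version()},
        "config": config.echo(),
        "seeds": {"master": config.seed},
        "stages": {},
    }
    failure_marker = outdir / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()
    try:
        truth = None
        if config.simulation is not None:
            with _stage(report, "simulate"):
                ds = simulate_all(config.simulation)
                paths = write_dataset(ds, outdir)
                truth = ds.truth
                genome, annotation, counts = ds.genome, ds.annotation, ds.counts
                pfms = [ds.pfm]
                report["stages"]["simulate"] = {
                    "n_genes": int(len(annotation)),
                    "n_chromosomes": len(genome),
                    "n_planted_instances": len(truth.planted_instances),
                    "n_enriched_genes": len(truth.enriched_gene_ids),
                    "n_de_genes_planted": len(truth.de_log2fc),
                    "seed": config.simulation.seed,
                }
            de_input_counts, groups = counts, None
        else:
            with _stage(report, "load"):
                genome = pio.read_genome_fasta(config.genome)
                annotation = pio.read_gene_annotation(config.annotation)
                pfms = read_jaspar(config.motifs)
                de_input_counts = (pio.read_counts_tsv(config.counts)
                                   if config.counts else None)
                groups = config.groups
                report["stages"]["load"] = {
                    "n_genes": int(len(annotation)),
                    "n_chromosomes": len(genome),
                    "n_motifs": len(pfms),
                }

        with _stage(report, "de"):
            if de_input_counts is not None:
                if groups is None:
                    n = de_input_counts.shape[1] // 2
                    groups = ["group1"] * n + ["group2"] * (de_input_counts.shape[1] - n)
                de_table = simple_de(de_input_counts, groups)
                report["stages"]["de"] = {
                    "engine": "simple_de",
                    "n_genes_tested": int(len(de_table)),
                    "n_dropped_all_zero": len(de_table.attrs["dropped_genes"]),
                }
            else:
                de_table = read_de_table(config.de_table)
                report["stages"]["de"] = {"engine": "external",
                                          "n_genes_tested": int(len(de_table))}
            write_de_table(de_table, outdir / "de_table.tsv")

        with _stage(report, "select"):
            selection = select_degs(de_table, config.p_threshold,
                                    config.lfc_threshold)
            pio.write_gene_list(selection.up, outdir / "degs_up.txt")
            pio.write_gene_list(selection.down, outdir / "degs_down.txt")
            report["stages"]["select"] = {
                "p_threshold": config.p_threshold,
                "lfc_threshold": config.lfc_threshold,
                "n_up": len(selection.up), "n_down": len(selection.down),
                "n_degs": len(selection.all_degs),
                "n_universe_tested": len(selection.universe),
            }

        with _stage(report, "promoters"):
            if config.simulation is not None:
                # keep the scanned window identical to the planted window
                up, down = config.simulation.promoter_window
            else:
                up, down = config.upstream, config.downstream
            promoters = extract_promoters(genome, annotation, up, down)
            write_promoters_fasta(promoters, outdir / "promoters.fa")
            write_promoters_bed(promoters, outdir / "promoters.bed")
            report["stages"]["promoters"] = {
                "n_promoters": len(promoters),
                "n_clipped": sum(p.clipped for p in promoters),
                "upstream": up, "downstream": down,
            }

        with _stage(report, "scan"):
            background = estimate_background(promoters)
            counts_per_motif: dict[str, pd.Series] = {}
            hit_frames = []
            for pfm in pfms:
                pwm = pfm_to_pwm(pfm, background, config.pseudocount).calibrated(
                    config.alpha)
                hit_frames.append(scan_promoters(promoters, pwm))
                counts_per_motif[pfm.motif_id] = count_hits(promoters, pwm)
            hits = pd.concat(hit_frames, ignore_index=True)
            hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
            count_table = pd.DataFrame(counts_per_motif)
            count_table.to_csv(outdir / "hit_counts.tsv", sep="\t",
                               index_label="gene_id")
            report["stages"]["scan"] = {
                "alpha": config.alpha,
                "background": [round(float(b), 6) for b in background],
                "hits_per_motif": {m: int(s.sum())
                                   for m, s in counts_per_motif.items()},
            }

        with _stage(report, "enrich"):
            promoter_genes = frozenset(p.gene_id for p in promoters)
            universe = frozenset(selection.universe) & promoter_genes
            excluded = selection.universe - universe
            if excluded:
                log.warning("%d DE-tested gene(s) lack promoters; excluded "
                            "from the enrichment universe", len(excluded))
            tables = []
            enrich_seed = substream_seed(config.seed, "enrich")
            report["seeds"]["enrich"] = enrich_seed
            for label, gene_set in (("up", selection.up),
                                    ("down", selection.down),
                                    ("all_degs", selection.all_degs)):
                usable = frozenset(gene_set) & universe
                if len(usable) < len(gene_set):
                    log.warning("set %s: %d gene(s) dropped (no promoter)",
                                label, len(gene_set) - len(usable))
                if not usable:
                    continue
                label_seed = substream_seed(enrich_seed, f"set:{label}")
                table, results = enrich_all(counts_per_motif, usable, universe,
                                            n_sets=config.n_sets,
                                            seed=label_seed, set_label=label)
                tables.append(table)
                for r in results:
                    write_null_sample(r, outdir / f"null_{r.motif_id}_{label}.tsv")
                    if config.figures:
                        plot_null_curve(r, outdir / f"null_{r.motif_id}_{label}.png")
            if not tables:
                raise InputError("no non-empty DEG set to test")
            enrichment = pd.concat(tables, ignore_index=True)
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.10g")
            report["stages"]["enrich"] = {
                "n_sets": config.n_sets,
                "n_universe": len(universe),
                "results": enrichment.drop(columns=["seed"]).to_dict("records"),
            }
    except StageError:
        failure_marker.write_text(report.get("failed_stage", "unknown") + "\n")
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=str))
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = [f"promotif {report['versions']['promotif']} run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, value in info.items():
            if key == "results":
                lines.append("  results:")
                for row in value:
                    lines.append(
                        f"    {row['motif_id']} {row['set_label']}: "
                        f"observed={row['observed']:.0f} "
                        f"null_mean={row['null_mean']:.2f} "
                        f"z={row['z_score']:.2f} p={row['empirical_p']:.4g} "
                        f"q={row['q_value']:.4g}")
            else:
                lines.append(f"  {key}: {value}")
        lines.append("")
    return "\n".join(lines)
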