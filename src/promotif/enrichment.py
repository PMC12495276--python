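"""Binding-site enrichment against an empirical random-gene-set null.

The statistic is the total number of motif hits over the promoters of a
gene set. Its null distribution is built by drawing ``n_sets`` random gene
sets of the same size, uniformly without replacement from the universe
(genes that entered differential-expression testing and have an extracted
promoter). The one-sided empirical p-value uses the add-one rule

    p = (1 + #{null_i >= observed}) / (n_sets + 1)

so it can never be zero; depletion shows up only as a negative z-score.
``exact_enrichment`` enumerates all equal-size subsets on small universes
and serves as the oracle for the sampled p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .rng import substream_seed

log = logging.getLogger(__name__)

DEFAULT_N_SETS = 1000
EXACT_ENUMERATION_CAP = 10 ** 6

RESULT_COLUMNS = ["motif_id", "set_label", "set_size", "observed", "null_mean",
                  "null_sd", "z_score", "empirical_p", "q_value", "n_sets", "seed"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed statistic, its sampled null, and derived significance."""

    motif_id: str
    set_label: str
    set_size: int
    observed: float
    null_sample: np.ndarray
    null_mean: float
    null_sd: float
    z_score: float  # nan when null_sd == 0
    empirical_p: float
    n_sets: int
    seed: int
    q_value: float = float("nan")

    def to_row(self) -> dict:
        return {"motif_id": self.motif_id, "set_label": self.set_label,
                "set_size": self.set_size, "observed": self.observed,
                "null_mean": self.null_mean, "null_sd": self.null_sd,
                "z_score": self.z_score, "empirical_p": self.empirical_p,
                "q_value": self.q_value, "n_sets": self.n_sets, "seed": self.seed}


def _aligned_counts(counts: Mapping[str, float] | pd.Series,
                    genes: Sequence[str]) -> np.ndarray:
    series = pd.Series(counts) if not isinstance(counts, pd.Series) else counts
    missing = sorted(set(genes) - set(series.index))
    if missing:
        raise InputError(f"genes absent from hit counts: {missing}")
    return series.reindex(genes).to_numpy(dtype=float)


def observed_statistic(counts: Mapping[str, float] | pd.Series,
                       gene_set: Sequence[str] | frozenset[str]) -> float:
    """Total hit count over the gene set."""
    gene_set = sorted(set(gene_set))
    if not gene_set:
        raise InputError("empty gene set")
    return float(_aligned_counts(counts, gene_set).sum())


def empirical_enrichment(counts: Mapping[str, float] | pd.Series,
                         deg_set: Sequence[str] | frozenset[str],
                         universe: Sequence[str] | frozenset[str],
                         n_sets: int = DEFAULT_N_SETS,
                         seed: int = 0,
                         motif_id: str = "motif",
                         set_label: str = "custom") -> EnrichmentResult:
    """Rank the observed statistic against random equal-size gene sets."""
    deg_set = sorted(set(deg_set))
    universe = sorted(set(universe))
    if not deg_set:
        raise InputError("empty gene set")
    if n_sets < 1:
        raise InputError("n_sets must be >= 1")
    stray = sorted(set(deg_set) - set(universe))
    if stray:
        raise InputError(f"gene set members outside the universe: {stray}")
    if len(deg_set) > len(universe):
        raise InputError("gene set larger than universe")
    values = _aligned_counts(counts, universe)
    observed = float(_aligned_counts(counts, deg_set).sum())
    rng = np.random.default_rng(seed)
    k, n = len(deg_set), len(universe)
    null = np.empty(n_sets)
    for i in range(n_sets):
        null[i] = values[rng.choice(n, size=k, replace=False)].sum()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_sets > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    p = (1.0 + float((null >= observed).sum())) / (n_sets + 1.0)
    return EnrichmentResult(motif_id=motif_id, set_label=set_label, set_size=k,
                            observed=observed, null_sample=null,
                            null_mean=null_mean, null_sd=null_sd, z_score=z,
                            empirical_p=p, n_sets=n_sets, seed=seed)


def exact_enrichment(counts: Mapping[str, float] | pd.Series,
                     deg_set: Sequence[str] | frozenset[str],
                     universe: Sequence[str] | frozenset[str],
                     cap: int = EXACT_ENUMERATION_CAP) -> float:
    """Exact P(null >= observed) by enumerating every equal-size subset."""
    deg_set = sorted(set(deg_set))
    universe = sorted(set(universe))
    if not deg_set:
        raise InputError("empty gene set")
    stray = sorted(set(deg_set) - set(universe))
    if stray:
        raise InputError(f"gene set members outside the universe: {stray}")
    n, k = len(universe), len(deg_set)
    total = math.comb(n, k)
    if total > cap:
        raise InputError(f"C({n},{k}) = {total} exceeds enumeration cap {cap}")
    values = _aligned_counts(counts, universe)
    observed = _aligned_counts(counts, deg_set).sum()
    at_least = sum(1 for combo in combinations(values, k)
                   if sum(combo) >= observed - 1e-9)
    return at_least / total


def enrich_all(counts_per_motif: Mapping[str, Mapping[str, float] | pd.Series],
               deg_set, universe, n_sets: int = DEFAULT_N_SETS, seed: int = 0,
               set_label: str = "custom") -> tuple[pd.DataFrame, list[EnrichmentResult]]:
    """Per-motif empirical enrichment with BH adjustment across motifs.

    Each motif gets its own seed substream so adding or removing motifs
    never perturbs another motif's null sample. Rows are sorted by
    empirical_p ascending, ties broken by motif_id.
    """
    if not counts_per_motif:
        raise InputError("no motifs supplied")
    results = []
    for motif_id in sorted(counts_per_motif):
        sub = substream_seed(seed, f"null:{motif_id}")
        results.append(empirical_enrichment(counts_per_motif[motif_id], deg_set,
                                            universe, n_sets=n_sets, seed=sub,
                                            motif_id=motif_id, set_label=set_label))
    pvals = np.array([r.empirical_p for r in results])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [EnrichmentResult(**{**r.__dict__, "q_value": float(q)})
               for r, q in zip(results, qvals)]
    results.sort(key=lambda r: (r.empirical_p, r.motif_id))
    table = pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
    return table, results


def null_curve(result: EnrichmentResult) -> pd.DataFrame:
    """ECDF of the null sample, for tabulation or plotting.

    One row per null draw: the sorted statistic and its ECDF value i/n.
    The stored empirical p is recomputable from the value column.
    """
    values = np.sort(result.null_sample)
    return pd.DataFrame({"value": values,
                         "ecdf": np.arange(1, values.size + 1) / values.size})


def plot_null_curve(result: EnrichmentResult, path: str | Path) -> None:
    """ECDF of the null with the observed statistic marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = null_curve(result)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve["value"], curve["ecdf"], where="post", color="black",
            label=f"{result.n_sets} random gene sets")
    ax.axvline(result.observed, color="tab:blue",
               label=f"observed ({result.set_label})")
    ax.set_xlabel("binding sites in promoters of gene set")
    ax.set_ylabel("ECDF")
    ax.set_title(f"{result.motif_id}: empirical p = {result.empirical_p:.4g}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_null_sample(result: EnrichmentResult, path: str | Path) -> None:
    null_curve(result).to_csv(path, sep="\t", index=False)
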