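"""Differential expression and volcano-threshold gene-set selection.

``simple_de`` is a deliberately plain two-group engine: library-size
normalisation to counts-per-million, a log2 fold change of CPM group
means with a 0.5 pseudo-count, and a Welch two-sample t-test on
log2(CPM+1). It stands in for whatever engine produced an externally
supplied DE table — the selection step accepts either.

``select_degs`` applies the volcano rule with strict inequalities:
up-regulated means p < p_threshold and log2FC > lfc_threshold, down
means p < p_threshold and log2FC < -lfc_threshold. Genes sitting exactly
on a threshold are excluded. Raw p-values drive selection; BH-adjusted
values are carried along for reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 1.0

DE_COLUMNS = ["gene_id", "log2fc", "pvalue"]


@dataclass(frozen=True)
class GeneSetSelection:
    """Up/down DEG sets with the universe and thresholds that produced them."""

    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]
    thresholds: tuple[float, float]  # (p_threshold, lfc_threshold)

    def __post_init__(self):
        if self.up & self.down:
            raise InputError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise InputError("selected genes outside the universe")

    @property
    def all_degs(self) -> frozenset[str]:
        return self.up | self.down


def simple_de(counts: pd.DataFrame, group_labels: Sequence[str]) -> pd.DataFrame:
    """Per-gene log2FC and Welch-t p-value for a two-group contrast.

    ``group_labels`` has one entry per count column; exactly two distinct
    levels, each with >= 2 samples. Levels are ordered by sorted label name
    and the second is the numerator of the fold change, so exchanging the
    two labels across samples negates every log2fc. Genes with zero counts
    in every sample are dropped (recorded in ``result.attrs['dropped_genes']``).

    Columns of the result: gene_id, log2fc, pvalue, padj (BH, reporting
    only), t, mean_cpm_1, mean_cpm_2.
    """
    group_labels = list(group_labels)
    if len(group_labels) != counts.shape[1]:
        raise InputError(f"{len(group_labels)} labels for {counts.shape[1]} samples")
    levels = sorted(set(group_labels))
    if len(levels) != 2:
        raise InputError(f"need exactly two groups, got {levels}")
    labels = np.asarray(group_labels)
    mask1, mask2 = labels == levels[0], labels == levels[1]
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise InputError("each group needs at least 2 samples")
    if counts.index.duplicated().any():
        raise InputError("duplicate gene ids in count matrix")

    mat = counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    dropped = counts.index[~nonzero].tolist()
    if dropped:
        log.info("dropping %d gene(s) with zero counts in all samples", len(dropped))
    mat = mat[nonzero]
    genes = counts.index[nonzero]

    totals = counts.to_numpy(dtype=float).sum(axis=0)
    if (totals == 0).any():
        raise InputError("a sample has zero total counts")
    cpm = mat / totals * 1e6
    mean1, mean2 = cpm[:, mask1].mean(axis=1), cpm[:, mask2].mean(axis=1)
    log2fc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    logcpm = np.log2(cpm + 1.0)
    t, p = stats.ttest_ind(logcpm[:, mask2], logcpm[:, mask1], axis=1,
                           equal_var=False)
    # zero variance in both groups with equal means -> nan; no evidence
    nan = ~np.isfinite(p)
    t = np.where(nan, 0.0, t)
    p = np.where(nan, 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "pvalue": p,
                        "padj": padj, "t": t, "mean_cpm_1": mean1,
                        "mean_cpm_2": mean2}).reset_index(drop=True)
    out.attrs["dropped_genes"] = dropped
    out.attrs["groups"] = levels
    return out


def select_degs(table: pd.DataFrame,
                p_threshold: float = DEFAULT_P_THRESHOLD,
                lfc_threshold: float = DEFAULT_LFC_THRESHOLD) -> GeneSetSelection:
    """Volcano selection with strict inequalities (boundary genes excluded)."""
    if p_threshold <= 0 or lfc_threshold <= 0:
        raise InputError("thresholds must be positive")
    if len(table) == 0:
        raise InputError("empty DE table")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"DE table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise InputError(f"duplicate gene ids in DE table: {dups}")
    if not np.isfinite(table["log2fc"]).all():
        raise InputError("non-finite log2fc values in DE table")
    pv, fc = table["pvalue"].to_numpy(), table["log2fc"].to_numpy()
    if ((pv < 0) | (pv > 1)).any():
        raise InputError("p-values outside [0, 1]")
    sig = pv < p_threshold
    up = frozenset(table.loc[sig & (fc > lfc_threshold), "gene_id"])
    down = frozenset(table.loc[sig & (fc < -lfc_threshold), "gene_id"])
    return GeneSetSelection(up=up, down=down,
                            universe=frozenset(table["gene_id"]),
                            thresholds=(p_threshold, lfc_threshold))


def read_de_table(path: str | Path) -> pd.DataFrame:
    """TSV with at least gene_id, log2fc, pvalue; extra columns preserved."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
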