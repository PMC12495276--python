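"""Position-weight-matrix construction, threshold calibration and scanning.

A motif starts life as a position frequency matrix (PFM): observed base
counts per column, base order A, C, G, T. ``pfm_to_pwm`` turns it into a
log2 odds matrix against a 0th-order background model, with a pseudocount
distributed proportionally to the background (a common motif-tool
convention). ``calibrate_threshold`` computes the exact distribution of the
score of a random background word by dynamic programming over columns, with
scores discretized to a configurable granularity, and places the hit-calling
threshold at a chosen tail probability ``alpha``. Scanning slides the PWM
over both strands of a promoter; every window at or above threshold is a
hit. Windows containing non-ACGT bases are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, InputError
from .promoters import Promoter

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BACKGROUND = np.full(4, 0.25)

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_ALPHA = 1e-4
DEFAULT_GRANULARITY = 1e-3


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: non-negative 4xL counts, rows A,C,G,T."""

    motif_id: str
    counts: np.ndarray
    name: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise InputError(f"PFM {self.motif_id}: counts must be 4xL with L >= 1")
        if (counts < 0).any():
            raise InputError(f"PFM {self.motif_id}: negative counts")
        if (counts.sum(axis=0) == 0).any():
            raise InputError(f"PFM {self.motif_id}: all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def column_probabilities(self) -> np.ndarray:
        """Per-column base probabilities (counts normalised per column)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class PWM:
    """Log2-odds matrix with background model and calibrated threshold."""

    motif_id: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    score_threshold: float | None = None
    threshold_alpha: float | None = None
    granularity: float = DEFAULT_GRANULARITY

    def __post_init__(self):
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "log_odds", np.asarray(self.log_odds, dtype=float))
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ConfigurationError("background probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def calibrated(self, alpha: float = DEFAULT_ALPHA,
                   granularity: float = DEFAULT_GRANULARITY) -> "PWM":
        """Return a copy with ``score_threshold`` set via :func:`calibrate_threshold`."""
        thr = calibrate_threshold(self, alpha, granularity)
        return replace(self, score_threshold=thr, threshold_alpha=alpha,
                       granularity=granularity)


@dataclass(frozen=True)
class MotifHit:
    """One PWM match inside a promoter.

    ``offset`` is 0-based along the promoter's own 5'->3' sequence;
    ``strand`` is '+' if the match reads along the promoter, '-' if along
    its reverse complement. Scores are log2-odds bits.
    """

    gene_id: str
    offset: int
    strand: str
    score: float
    motif_id: str


# ---------------------------------------------------------------------------
# PFM -> PWM

def pfm_to_pwm(pfm: PFM, background: Sequence[float] | None = None,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    """Convert counts to a log2-odds matrix.

    Column probabilities are ``(count_b + pseudocount * background_b) /
    (column_total + pseudocount)`` — i.e. the pseudocount mass is split
    across bases in proportion to the background.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ConfigurationError("background probabilities must be strictly positive")
    totals = pfm.counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ConfigurationError(
            f"PFM {pfm.motif_id}: zero column total with zero pseudocount")
    probs = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    if (probs == 0).any():
        raise ConfigurationError(
            f"PFM {pfm.motif_id}: zero probability cell with zero pseudocount; "
            "log-odds undefined")
    log_odds = np.log2(probs / bg[:, None])
    return PWM(motif_id=pfm.motif_id, log_odds=log_odds, background=bg,
               pseudocount=float(pseudocount))


# ---------------------------------------------------------------------------
# Exact score distribution and threshold calibration

def score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the PWM score of a random background word.

    Scores are discretized column-wise: each log-odds entry is rounded to
    the nearest multiple of ``granularity`` and the distribution of the sum
    is built by dynamic programming over columns. Returns ``(grid, probs)``
    where ``grid`` holds the achievable discretized scores (ascending) and
    ``probs`` their exact probabilities under the background model.
    """
    if granularity <= 0:
        raise ConfigurationError("granularity must be > 0")
    k = np.rint(pwm.log_odds / granularity).astype(np.int64)  # (4, L)
    bg = pwm.background
    dist = np.ones(1)
    offset = 0
    for j in range(pwm.length):
        col = k[:, j]
        cmin = int(col.min())
        width = int(col.max()) - cmin
        new = np.zeros(dist.size + width)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift:shift + dist.size] += bg[b] * dist
        dist = new
        offset += cmin
    grid = (offset + np.arange(dist.size)) * granularity
    return grid, dist


def calibrate_threshold(pwm: PWM, alpha: float = DEFAULT_ALPHA,
                        granularity: float = DEFAULT_GRANULARITY) -> float:
    """Smallest discretized score t with P(score >= t) <= alpha.

    The returned value is adjusted down by the worst-case column rounding
    error (granularity * L / 2) so that every word whose discretized score
    reaches t also passes on its exact floating-point score; the realized
    tail probability therefore sits within that discretization slack of
    the DP value. If even the maximal achievable score has tail probability
    above alpha, the threshold clamps there (the strictest callable rule)
    and a warning records the realized alpha.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    grid, probs = score_distribution(pwm, granularity)
    tail = np.cumsum(probs[::-1])[::-1]
    passing = np.nonzero(tail <= alpha)[0]
    if passing.size == 0:
        log.warning("motif %s: requested alpha=%.3g unreachable; threshold set to "
                    "max score (realized alpha=%.3g)", pwm.motif_id, alpha, tail[-1])
        t = float(grid[-1])
    else:
        t = float(grid[passing[0]])
    t -= granularity * pwm.length / 2.0
    return max(t, pwm.min_score)


# ---------------------------------------------------------------------------
# Scanning

def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to int8 codes A,C,G,T -> 0..3; anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every length-L window; NaN where a window contains non-ACGT."""
    L = log_odds.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = log_odds[safe, np.arange(L)].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def reverse_complement_matrix(log_odds: np.ndarray) -> np.ndarray:
    # complement of A,C,G,T is T,G,C,A = reversed base order
    return log_odds[::-1, ::-1]


def scan_promoter(promoter: Promoter, pwm: PWM) -> list[MotifHit]:
    """All (offset, strand) matches at or above the calibrated threshold.

    Hits are sorted by ascending offset, '+' before '-' at equal offsets.
    Both a window and its reverse complement can be hits (palindromes count
    twice, once per strand).
    """
    if pwm.score_threshold is None:
        raise ConfigurationError(f"PWM {pwm.motif_id} is not calibrated")
    codes = encode_sequence(promoter.sequence)
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, reverse_complement_matrix(pwm.log_odds))
    hits: list[MotifHit] = []
    thr = pwm.score_threshold
    for offset in range(fwd.size):
        if fwd[offset] >= thr:
            hits.append(MotifHit(promoter.gene_id, offset, "+", float(fwd[offset]),
                                 pwm.motif_id))
        if rev[offset] >= thr:
            hits.append(MotifHit(promoter.gene_id, offset, "-", float(rev[offset]),
                                 pwm.motif_id))
    return hits


def scan_promoters(promoters: Iterable[Promoter], pwm: PWM) -> pd.DataFrame:
    """Hit table over a promoter set: gene_id, offset, strand, score, motif_id."""
    rows = [(h.gene_id, h.offset, h.strand, h.score, h.motif_id)
            for p in promoters for h in scan_promoter(p, pwm)]
    return pd.DataFrame(rows, columns=["gene_id", "offset", "strand", "score",
                                       "motif_id"])


def count_hits(promoters: Sequence[Promoter], pwm: PWM) -> pd.Series:
    """Per-gene hit count, zero-hit genes included; index order follows input."""
    gene_ids = [p.gene_id for p in promoters]
    if len(set(gene_ids)) != len(gene_ids):
        dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise InputError(f"duplicate gene ids across promoters: {dups}")
    counts = {p.gene_id: len(scan_promoter(p, pwm)) for p in promoters}
    return pd.Series(counts, name=pwm.motif_id).reindex(gene_ids)


def estimate_background(promoters: Iterable[Promoter]) -> np.ndarray:
    """0th-order base frequencies over a promoter set; uniform fallback.

    Non-ACGT characters are ignored; if nothing is countable (or any base
    is absent) the uniform background is returned so log-odds stay finite.
    """
    totals = np.zeros(4)
    for p in promoters:
        codes = encode_sequence(p.sequence)
        totals += np.bincount(codes[codes >= 0], minlength=4)
    if totals.sum() == 0 or (totals == 0).any():
        return UNIFORM_BACKGROUND.copy()
    return totals / totals.sum()


# ---------------------------------------------------------------------------
# Motif file I/O

def read_jaspar(path: str | Path) -> list[PFM]:
    """Read a JASPAR-format motif library (``>id name`` + four count rows)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        pfms = []
        for m in records:
            counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
            motif_id = getattr(m, "matrix_id", None) or m.name
            pfms.append(PFM(motif_id=motif_id, counts=counts, name=m.name or ""))
    if not pfms:
        raise InputError(f"no motifs found in {path}")
    return pfms


def write_jaspar(pfms: Iterable[PFM], path: str | Path) -> None:
    from Bio.motifs import jaspar

    records = []
    for pfm in pfms:
        counts = {b: pfm.counts[i].tolist() for i, b in enumerate(BASES)}
        records.append(jaspar.Motif(matrix_id=pfm.motif_id,
                                    name=pfm.name or pfm.motif_id,
                                    counts=counts))
    Path(path).write_text(jaspar.write(records, "jaspar"))


def read_plain_matrix(path: str | Path, motif_id: str | None = None) -> PFM:
    """Read the 4-row whitespace-separated matrix dialect (rows A,C,G,T)."""
    mat = np.loadtxt(str(path), ndmin=2)
    if mat.shape[0] != 4:
        raise InputError(f"{path}: expected 4 rows (A,C,G,T), got {mat.shape[0]}")
    return PFM(motif_id=motif_id or Path(path).stem, counts=mat)


def consensus_pfm(consensus: str, motif_id: str = "synthetic_motif",
                  concentration: float = 0.85, total: float = 100.0) -> PFM:
    """Synthetic PFM concentrating ``concentration`` of each column's mass on
    the consensus base and splitting the rest evenly (used by the simulator)."""
    if not 0 < concentration <= 1:
        raise ConfigurationError("concentration must be in (0, 1]")
    L = len(consensus)
    counts = np.full((4, L), total * (1 - concentration) / 3)
    for j, base in enumerate(consensus.upper()):
        if base not in _BASE_INDEX:
            raise ConfigurationError(f"consensus contains non-ACGT base {base!r}")
        counts[_BASE_INDEX[base], j] = total * concentration
    return PFM(motif_id=motif_id, counts=counts)
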