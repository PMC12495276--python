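# Methods

## The statistic

`promotif` tests whether the promoters of a gene set — typically the
differentially expressed genes (DEGs) of a two-group contrast — carry more
binding sites for a transcription factor than expected by chance. The
observed statistic is

    T_obs = Σ_{g ∈ S} h(g)

the total number of PWM hits over the promoters of the set S. Its null
distribution is empirical: `n_sets` gene sets of size |S| are drawn
uniformly without replacement from the universe U (genes that both entered
differential-expression testing and have an extracted promoter), the
statistic is recomputed on each, and the one-sided enrichment p-value is
the add-one rank

    p = (1 + #{T_null_i ≥ T_obs}) / (n_sets + 1).

The add-one form keeps p strictly positive and in [1/(n_sets+1), 1]; ties
count against enrichment, the standard conservative convention for
permutation tests. `n_sets` defaults to 1000. Because all null sets have
the same size, the total and the per-gene mean are equivalent statistics.
Depletion is not tested; it is visible only in the sign of the z-score
(observed − null mean)/null sd. With several motifs, Benjamini–Hochberg
adjustment is applied across motifs within one set label (up, down,
all_degs analysed as separate families).

Null sets are unconstrained uniform draws — no GC- or length-matching. On
the synthetic data this is exactly the right null; on real promoters it
ignores composition biases, a known limitation (below).

The exact enumeration variant (`exact_enrichment`) computes
P(T_null ≥ T_obs) over all C(|U|, |S|) subsets when that count is below a
cap (10^6). It is an oracle for tests, not a practical engine.

## DEG selection

A DE table (gene, log2FC, p) is either supplied externally or produced by
`simple_de`: counts-per-million normalisation by sample totals, log2FC =
log2((mean2 + 0.5)/(mean1 + 0.5)) of group CPM means (pseudo-count 0.5
keeps the ratio finite), and a Welch two-sample t-test on log2(CPM + 1).
Groups are ordered by sorted label name, the second being the numerator,
so relabeling the groups negates every fold change. Genes with zero counts
in all samples are dropped and reported. `simple_de` is a documented
stand-in for a dispersion-aware engine, not a replacement for one; when a
better engine is available, feed its table in.

Selection uses the volcano rule with strict inequalities: up means
p < 0.05 and log2FC > 1, down means p < 0.05 and log2FC < −1 (defaults;
both thresholds configurable). Boundary genes (|log2FC| exactly 1, p
exactly 0.05) are excluded. Selection runs on raw p-values; BH-adjusted
values are computed and written for reporting only.

## Promoters

The promoter of a gene is the window [TSS − upstream, TSS + downstream) in
transcription orientation; the TSS is the 5' end of the `gene` feature
(GFF3 start for +, end for −; one feature per gene, no transcript
selection). Defaults: upstream 2000 bp, downstream 200 bp — a conventional
proximal-promoter span, exposed as a knob. Minus-strand sequences are
reverse-complemented so every promoter reads 5'→3'. Windows are clipped at
chromosome edges (logged); internal coordinates are 0-based half-open,
converted from GFF3 at the reader boundary. Ambiguity codes (N) are kept
in the sequence; the scanner skips windows containing them.

## Motif model and scanning

A position frequency matrix (counts, rows A,C,G,T) becomes a log2-odds
PWM against a 0th-order background with a background-proportional
pseudocount:

    p_b(j) = (n_b(j) + κ·q_b) / (N(j) + κ),   W_b(j) = log2(p_b(j) / q_b)

with κ = 0.8 by default. The background q is estimated from the full
promoter set (uniform fallback). A window is a hit when its summed score
meets a threshold calibrated to an exact tail probability: the score
distribution of a random background word is computed by dynamic
programming over columns with scores discretized to 1e−3 bits per cell,
and the threshold is the smallest discretized score t with
P(score ≥ t) ≤ α (default α = 1e−4). The returned threshold is lowered by
the worst-case rounding slack (granularity·L/2) so that every word whose
discretized score reaches t also passes on its exact floating-point
score; the realized α differs from the DP tail by at most that slack's
probability mass, and the DP itself agrees with exhaustive 4^L
enumeration to machine precision (tested for L ≤ 6). If α is smaller than
the probability of the best possible word, the threshold clamps to the
maximum achievable score and the realized α is logged.

Scanning slides the PWM over the promoter and, at the same offsets, its
reverse-complemented matrix — every (offset, strand) pass is counted,
including overlapping hits and both strands of a palindromic site. This
all-passes overlap policy is the simplest rule that an independent
brute-force scanner can reproduce exactly; it slightly inflates counts
for self-overlapping motifs on both observed and null sets alike, so the
enrichment comparison is unaffected.

## Synthetic data

The generator produces the entire input side with known ground truth:

* **Genome** — i.i.d. bases at configurable GC (default 0.41,
  human-like). No repeats, no composition heterogeneity.
* **Annotation** — single-transcript genes in fixed-width slots
  (gene body + max(upstream, downstream) padding on both sides +
  spacing), round-robin across chromosomes, random strand. Promoters
  therefore never overlap a neighbouring gene body and never need
  clipping.
* **Plantings** — per promoter, Poisson(λ_e) motif instances for genes in
  the enriched set, Poisson(λ_b) otherwise (Poisson is the minimal count
  model and keeps null expectations analytic). Each instance is sampled
  column-wise from the PFM, placed at a uniform offset and strand, never
  overlapping another instance in the same promoter, and written over the
  existing bases so all coordinates stay stable. Defaults λ_e = 3.0,
  λ_b = 0.3.
* **Counts** — negative binomial with mean m and variance m + φ·m²
  (φ = 0.1 default), per-gene baselines log-normal around 100, 4 samples
  per group. Exactly round(de_fraction·n_genes) genes get their group-2
  mean scaled by 2^(±2) (sign random).
* **Coupling** — by default the motif-enriched truth set is a random
  subset of the planted DE genes, so the planted expression signal and
  the planted promoter signal point at the same genes: the scenario the
  method exists to detect. Decoupled mode plants into an arbitrary set.

Default sizes: 2000 genes on 4 chromosomes of 3 Mb, 100 DE genes, 50
motif-enriched genes, DR1-like planted motif (consensus AGGTCAAAGGTCA,
85% column concentration). All randomness flows from one master seed
through named substreams (genome / annotation / plant / counts /
coupling / per-motif nulls), so each stage is independently reproducible
and fixed seeds give bit-identical outputs.

What the generator does **not** emulate: repeat structure, GC
heterogeneity and isochores, co-occurring motifs, multi-transcript genes,
library-size and batch effects, dispersion trends. Passing tests
demonstrate the statistic's correctness and calibration under its own
assumptions, not performance on real fibroblast data.

## Numerical and design choices

* DP granularity 1e−3 bits: fine enough that discretization error is
  invisible next to sampling noise; the enumeration-oracle tests run at
  1e−4.
* Hit threshold by exact-distribution p-value rather than
  fraction-of-maximum score: principled, and checkable against the
  enumeration oracle.
* Welch (unequal-variance) t rather than pooled: no reason to assume
  equal variances across groups. Genes with zero variance in both groups
  and equal means get t = 0, p = 1.
* Universe for the null = DE-tested genes ∩ genes with promoters; set
  members failing either criterion are dropped with a warning. Drawing
  from the expressed universe rather than all annotated genes avoids
  biasing the null toward never-expressed genes.
* The pipeline's promoter window follows the simulation's planted window
  in simulation mode, so the scanned and planted regions coincide.
* Empirical p and all null samples are persisted (ECDF tables), so every
  reported p is recomputable from its artifacts.

## Problem sizes used in the checks

The statistical checks use the following replicate sizes, chosen to give
stable verdicts at interactive runtimes: type-I calibration, 200
replicates (universe 1000, set 40, 500 null sets, promoter window
150/50); planted-signal recovery, 20 replicates (universe 2000, set 50,
1000 null sets, window 300/100, λ_e/λ_b = 10); permutation-vs-exact
agreement, 20 instances with universes ≤ 12 at 10 000 null sets. The
acceptance script runs the full default pipeline once plus 100 null
replicates and 20 signal replicates.

## Known limitations

* `simple_de` has no dispersion shrinkage; at n = 4 per group its power
  and FDR behaviour are far from a modern NB engine's. It exists so the
  pipeline is self-contained, and the realized false-discovery proportion
  on synthetic data is reported by the tests rather than bounded.
* The enrichment null ignores promoter composition; on real genomes,
  GC-matched or shuffled-sequence nulls would be more conservative for
  GC-rich motifs.
* A 0th-order background and an additive PWM ignore dinucleotide
  structure and inter-position dependence.
* The all-passes overlap policy counts overlapping occurrences of
  self-similar motifs multiply.
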