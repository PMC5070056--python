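# Methods

This note documents the models, estimators and numerical conventions
implemented in `mranet`, the choices made where the design was genuinely
open, and the limits of what the synthetic studies demonstrate.

## Synthetic-data generator

The generator emulates the study design the package targets: a large
reference cohort used only for network inference, plus small independent
case–control cohorts in which one TF's activity differs between classes.

**Model.** Each TF *t* has a latent activity a_t(s) ~ N(0, 1) per sample
*s*.  Observed log2-scale expression (centred at zero, as in log-ratio
arrays):

* TF: x_t = a_t + ε, ε ~ N(0, noise_sd²)
* target g: x_g = Σ_parents mode·weight·a_t + ε
* decoy: x_d ~ N(0, 1), independent of everything.

Under a perturbation of strength *s* (latent SD units), case samples draw
the perturbed TF's activity from N(+s, 1) (induced) or N(−s, 1)
(repressed).  The population Pearson sign of every TF–target pair equals
the planted mode, which is what the regulon extraction estimates.
Optionally a TF's activity can be coupled to another's
(a_b = ρ·a_a + √(1−ρ²)·z).  This is the construction used to test DPI:
with direct effect weight w < 1 the indirect partner–target correlation
ρ·w/√((1+σ²)(w²+σ²)) is strictly smaller than both the direct edge and
the TF–TF correlation ρ/(1+σ²), so the indirect edge is the weakest of
each triplet in population.

**Defaults.**  noise_sd = 0.5 (signal-to-noise ~2 on the latent scale,
giving TF–target correlations ≈ 0.8 at weight 1 — strong but realistic for
co-regulated probes); effect weight 1; perturbation shift 1.5 latent SD (a
large, disease-level effect appropriate for a method study); cohort sizes
mirror the emulated design — reference n = 269 with an "adult-only"-style
subsample of 180, case–control cohorts of 5 vs 6 and 30 vs 31.  Fraction
of repressing edges 0.4 (regulons in cortex networks commonly carry
substantial repressive arms; both tails must be populated for the
two-tailed analysis to be exercised).

**What it does not model.**  No probe-level noise, batch effects, missing
values, heavy-tailed noise, or confounder structure; decoys are fully
independent.  Passing recovery tests on this generator shows the
statistics behave as designed under the stated model, not that real
microarray cohorts satisfy that model.

**Seeding.**  Every stage derives a child seed from the master seed as the
first 31 bits of SHA-256("master|label|…"), so streams are independent of
stage order and reruns are byte-identical.

## Mutual-information estimator

Plug-in (maximum-likelihood) MI on equal-frequency bins, natural log.
Bins: ⌊√n⌋ clamped to [2, 10] ("auto"), keeping expected cell counts near
√n.  Binning is rank-based with stable ties (by sample position); constant
vectors occupy a single bin, making their entropy and any MI with them
exactly 0.  The estimator is biased upward on independent data
(≈ (B−1)²/2n nats), which is harmless here because every decision compares
MI values computed under the same n and B — the permutation threshold
carries the same bias as the statistics it gates.

## Network inference

* **CV filter**: retain the top keep_fraction of genes by sd/|mean|
  (sd with ddof = 1); genes with |mean| < 1e−12 get an infinite-CV
  sentinel and are retained only if their sd is positive; listed TFs are
  always retained so regulons are never decapitated.  Ties break by row
  position; row order is preserved.  On centred (log-ratio) data the CV is
  uninformative, so the pipeline default is keep_fraction = 1.
* **Permutation threshold**: per draw, one random gene row is
  sample-shuffled and scored against every TF row; the pooled null's
  (1−α) nearest-rank quantile is the single global threshold (one
  minimum-MI threshold for all pairs).
* **Bootstrap consensus**: columns resampled with replacement n_boot times
  (default 1000); an edge must pass in ≥ 95% of bootstraps and carries the
  full-matrix MI as weight.  *Numerical design choice*: resampling with
  replacement duplicates samples, which inflates the plug-in MI of
  independent pairs well above a threshold calibrated on unresampled data
  (at n = 120, B = 10 the inflation is large enough that every TF–gene
  pair in a null grid passes).  Each bootstrap therefore recalibrates its
  own pass threshold as the same (1−α) quantile of a within-bootstrap
  permutation null (30 shuffled-gene draws), and the fixed global
  threshold is additionally applied to the full-matrix MI.  Setting
  `null_alpha=None` restores the single-threshold behaviour.
* **DPI**: for every triplet (TF1, TF2, g) with all three edges present,
  the TF–target edge e is marked when mi(e) < min(other two)·(1−tolerance);
  marks are computed against the input network and applied at once, so the
  result is traversal-order independent.  TF–TF edges are never removed.
  Ties: two tied TF–target edges → the lexicographically larger (tf, gene)
  pair is removed; a TF–target edge tied only with the TF–TF edge is
  removed itself.  Default tolerance 0.

## Regulons

Mode of action = sign of Pearson r(TF, target) on the inference matrix.
Targets with r exactly 0 or undefined (zero variance) are dropped with a
logged notice — a mode-less target cannot enter the two-tailed analysis.
Minimum regulon size defaults to 15 (no size floor is prescribed by the
emulated analysis; 15 is common MR-analysis practice and is configurable).
TF–TF edges contribute each TF to the partner's regulon.  The association
map reports pairwise Jaccard coefficients over target sets, omitting
zero-overlap pairs.

## Signatures

logFC = mean(case) − mean(control) on log2-scale input; t and p from a
Welch two-sample test.  The Welch test stands in for moderated
empirical-Bayes statistics: only the logFC feeds the ranked phenotypes, so
downstream results are unaffected by the substitution, and the p-values
are reported for completeness only.  Rank orders: signed (descending
logFC) for the two-tailed analysis, |logFC| descending for the one-tailed
MRA; ties break by gene id ascending so permutation nulls are reproducible
across platforms.

## Enrichment statistics

The enrichment score is the weighted Kolmogorov–Smirnov running sum: hits
add |weight|^exponent (normalised by the hit total; uniform fallback if
the hit weights sum to 0), misses subtract 1/(N − N_hits); ES is the
running-sum value at the maximal |deviation| (first index on ties).
Exponent defaults to 1 (weighted statistic); 0 gives the classic KS form
used by the analytic test cases.

**Null model.**  Gene labels of the ranked phenotype are shuffled
(equivalently, hit positions are redrawn uniformly), n_perm = 1000 by
default; p = (1 + #{null ≥ observed})/(n_perm + 1), never zero.  For the
two-tailed test one shuffle scores both subgroups and the two-sided p is
computed on |dES|.  Adjustment: Benjamini–Hochberg within each
(network, signature) analysis.  *Caveat*: a gene-label null assumes the
tested set's signature values are exchangeable with the rest.  Decoy
(independent-gene) sets are calibrated — measured type-I error ≈ 0.05 at
nominal 0.05 — but a *correlated* regulon on a null signature is
anti-conservative, because one latent activity draw moves the whole
regulon coherently.  This matters for small cohorts (below) and is shared
by all gene-permutation GSEA variants; sample permutation would require
access to the per-sample data and is out of scope here.

**Direction call.**  induced iff dES > 0 and p_adj ≤ α; repressed iff
dES < 0 and p_adj ≤ α; otherwise inconclusive.  A tail below min_tail
(default 5) usable targets yields an inconclusive record with a flagged
reason rather than being dropped.  In the pipeline, the two-tailed
analysis runs on the regulons the one-tailed MRA found significant,
mirroring the intended screen → mode-of-action workflow.

**Permutation resolution.**  A permutation p-value cannot fall below
1/(n_perm + 1), and after BH adjustment over m regulons the effective
floor is ≈ m/(n_perm + 1).  With the default n_perm = 1000 and ~10
regulons, the floor (~0.01) sits *above* the stringent consensus threshold
α_strict = 0.001: stringent calls are then unreachable by construction,
and the consensus study therefore uses n_perm = 19 999 (floor 5·10⁻⁴
after BH over 10 regulons), and the strict two-tailed call n_perm = 4 999.
Choose n_perm ≥ 5·m/α for any threshold α you intend to resolve.

**Consensus.**  Standard: p_adj ≤ α (default 0.05) in every
network × signature combination; stringent: p_adj ≤ α_strict (default
0.001, the significance level associated with the strongest mode-of-action
calls in the emulated analysis).  Missing combinations count as
non-significant.

## Evaluation studies and problem sizes

The acceptance studies (`mranet.evaluate`, `scripts/acceptance.py`) use
sizes chosen to finish in minutes on one CPU while keeping each question
answerable: 1000 null draws for calibration; 50 TFs × 20 targets + 500
decoys at n = 300 over 10 seeds for edge recovery; 6 coupled TF pairs for
DPI pruning; 20 seeds of the 30 vs 31 design for MR recovery; 10 seeds of
the full two-network × two-signature design for consensus.  The consensus
study sizes both case–control cohorts at 30 vs 31: with a 5-vs-6 cohort
the realized case–control difference of every TF's latent activity has
standard error √(1/5 + 1/6) ≈ 0.60 latent SD, so null regulons regularly
out-enrich a planted shift of 1.5 and stringent (p ≤ 0.001) calls are not
supported at that size under this generator — the acceptance script
reports the 5-vs-6 variant as an informative number, and real small
cohorts should be interpreted with the same caution.

## Known limitations

* Agreement with any specific historical analysis of real cohorts is
  qualitative: the exact MI estimator, CV cutoff, bootstrap consensus
  criterion, GSEA exponent and adjustment method of existing pipelines
  vary, so networks are expected to agree in structure, not edge-for-edge.
* Gene-label permutation nulls are anti-conservative for correlated gene
  sets (see above).
* The linear-Gaussian generator cannot probe robustness to outliers,
  nonlinear regulation, or batch structure.
* No NES-style normalisation across regulon sizes and no leading-edge
  extraction; regulons of very different sizes are compared only through
  their permutation p-values.
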