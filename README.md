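# mranet — master-regulator analysis on mutual-information regulatory networks

`mranet` reimplements, as a tested and reusable Python library, a
master-regulator (MR) analysis workflow for tissue transcriptomics: which
transcription factors (TFs) coordinate the genes that are differentially
expressed in a case–control phenotype?  The approach was developed for
postmortem brain microarray cohorts (a large healthy reference cohort for
network inference plus small independent case–control cohorts), but the
package works with any gene-level log2 expression matrices supplied as TSV,
and ships a synthetic-data generator with planted regulons so every step
can be validated against known ground truth.

## The method

1. **Network inference.** From a reference cohort (genes × samples, log2
   scale), genes are optionally filtered by coefficient of variation, and
   the mutual information MI(TF, gene) is computed for every TF–gene pair
   (plug-in estimator on equal-frequency bins, nats).  Pairs below a
   permutation-derived significance threshold are dropped; edges must also
   survive bootstrap resampling of samples in ≥ 95% of replicates
   (the *relevance network*).  The Data Processing Inequality (DPI) then
   removes the weakest edge of every TF–TF–target triplet, eliminating
   likely-indirect interactions (tolerance 0 by default).
2. **Regulons with mode of action.** Each TF plus its inferred targets is a
   *regulon*; each target carries a mode of action, the sign of the Pearson
   correlation r(TF, target) on the inference cohort (+1 activated,
   −1 repressed).  Regulon overlap is summarised by Jaccard coefficients
   (the association map).
3. **Signatures.** A case–control cohort yields a per-gene signature
   logFC = mean(case) − mean(control) (with Welch t and p), ranked either
   signed (highest → lowest logFC, the "top-down" phenotype) or by |logFC|.
4. **One-tailed MRA.** Each regulon's target set is scored against the
   |logFC|-ranked phenotype with the weighted Kolmogorov–Smirnov enrichment
   score ES ∈ [−1, 1]; significance comes from gene-label permutation
   (p = (1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1)) with Benjamini–Hochberg
   adjustment across regulons.
5. **Two-tailed GSEA.** The regulon is split into positive (A) and negative
   (B) targets; both are scored on the signed ranking, and the differential
   score dES = ES_A − ES_B is tested the same way.  dES > 0: the phenotype
   *induced* the regulon; dES < 0: it *repressed* it (negative targets up,
   positive targets down).
6. **Consensus.** A TF significant in every network × signature combination
   is a consensus MR; a stricter adjusted-p threshold defines *stringent*
   consensus.

## Worked example

`examples/master_regulators.py` plants one repressed regulon (activity
shift 1.5 latent SD, 30 cases vs 31 controls, 8 TFs × 20 targets + 300
decoy genes) and runs both analyses:

```
one-tailed MRA (ES on the |logFC|-ranked phenotype):
  TF000: ES=0.998  p=0.000999  p_adj=0.007992
  TF002: ES=0.479  p=0.2238  p_adj=0.6633
  TF003: ES=-0.469  p=0.2667  p_adj=0.6633
  TF006: ES=0.448  p=0.3317  p_adj=0.6633

two-tailed analysis of the 1 significant regulon(s):
  TF000: ES_A=-0.998  ES_B=+1.000  dES=-1.998  p_adj=0.0002  -> repressed
```

The planted TF tops the one-tailed ranking (its targets crowd the top of
the |logFC| ranking), and the two-tailed test reads the geometry: its
positive targets sit at the repressed end of the signed ranking
(ES_A ≈ −1), its negative targets at the induced end (ES_B ≈ +1), so
dES ≈ −2 — the regulon is repressed in the phenotype.

Other entry points:

* `examples/simulate_cohorts.py` — the generative model and what a planted
  perturbation looks like in logFC space;
* `examples/infer_network.py` — threshold, bootstrap consensus, DPI,
  regulons, association map;
* `examples/full_pipeline.py` — the config-driven end-to-end run
  (`RunConfig` → `run_pipeline`), producing all tables plus a manifest that
  reproduces the run byte-identically;
* the `mranet` console script exposes the same steps as thin subcommands
  (`simulate`, `network`, `signature`, `mra`, `gsea2`, `consensus`, `run`,
  `report`).

## Limitations

See `docs/methods.md` for the generative model, parameter defaults, null
model caveats (gene-label permutation assumes independent gene sets), the
permutation-resolution requirement of stringent thresholds, and what the
synthetic studies do and do not say about real microarray data.
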