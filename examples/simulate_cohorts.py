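"""Simulate a reference cohort and a perturbed case-control cohort.

Builds a small ground-truth network (5 TFs x 15 targets, 40% repressing
edges, 100 decoy genes), draws a 200-sample reference cohort and a
30-case / 31-control cohort in which TF000's activity is repressed by 1.5
latent SD, and prints what the planted structure looks like in the data.
"""

import numpy as np

from mranet import PerturbationSpec, make_truth_network, simulate_cohort

truth = make_truth_network(
    n_tf=5, targets_per_tf=15, frac_negative=0.4, n_decoys=100, seed=1
)
print(f"truth network: {len(truth.tf_ids)} TFs, "
      f"{len(truth.target_ids)} targets, {len(truth.decoy_ids)} decoys")

reference = simulate_cohort(truth, n_samples=200, noise_sd=0.5, seed=2)
print(f"reference cohort: {reference.n_genes} genes x {reference.n_samples} samples")

# Pearson correlation of TF000 with one activated and one repressed target:
# the sign is the planted mode of action.
pos = next(a for a in truth.targets["TF000"] if a.mode == 1)
neg = next(a for a in truth.targets["TF000"] if a.mode == -1)
x = reference.values
r_pos = np.corrcoef(x.loc["TF000"], x.loc[pos.target])[0, 1]
r_neg = np.corrcoef(x.loc["TF000"], x.loc[neg.target])[0, 1]
print(f"corr(TF000, activated target {pos.target}) = {r_pos:+.3f}")
print(f"corr(TF000, repressed target {neg.target}) = {r_neg:+.3f}")

perturb = PerturbationSpec("TF000", "repressed", activity_shift=1.5)
cohort = simulate_cohort(
    truth, n_samples=61, noise_sd=0.5, perturbation=perturb, n_case=30, seed=3
)
case = cohort.values.loc[:, cohort.labels == "case"]
ctrl = cohort.values.loc[:, cohort.labels == "control"]
logfc = case.mean(axis=1) - ctrl.mean(axis=1)
pos_all = [a.target for a in truth.targets["TF000"] if a.mode == 1]
neg_all = [a.target for a in truth.targets["TF000"] if a.mode == -1]
print(f"mean logFC of TF000's activated targets: {logfc[pos_all].mean():+.3f} "
      "(down: the repressed TF no longer drives them)")
print(f"mean logFC of TF000's repressed targets: {logfc[neg_all].mean():+.3f} "
      "(up: released from repression)")
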