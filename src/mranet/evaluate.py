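"""Simulation studies of the pipeline's operating characteristics.

Each function plants known structure with the synthetic generator, runs the
corresponding part of the pipeline, and measures recovery or calibration:

* :func:`null_calibration` -- empirical type-I error of the one- and
  two-tailed enrichment tests on unperturbed data;
* :func:`edge_recovery` -- planted-edge recall and decoy false-positive
  rate of the relevance network;
* :func:`dpi_removal` -- fraction of indirect TF-target edges (created by
  coupling two TFs' latent activities) that DPI prunes;
* :func:`mr_recovery` -- whether the perturbed TF tops the one-tailed
  ranking and is called repressed (with the correct sign flip under an
  induced perturbation) by the two-tailed test;
* :func:`consensus_recovery` -- end-to-end: two networks x two signatures,
  checking that the planted TF is the unique stringent-consensus call.

Problem sizes are scaled so each study runs in minutes on one CPU; the
defaults mirror the cohort design the generator emulates (one large
reference cohort; case-control cohorts of 5 vs 6 and 30 vs 31 samples).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._seeds import child_seed
from .enrich import REPRESSED, consensus, mra, two_tailed_gsea, two_tailed_mra
from .expression import CASE, CONTROL, ExpressionMatrix
from .mi import MIEstimatorConfig
from .network import apply_dpi, bootstrap_consensus, permutation_threshold
from .regulons import Regulon, extract_regulons
from .signature import compute_signature
from .simulate import (
    INDUCED,
    PerturbationSpec,
    make_truth_network,
    regulons_from_truth,
    simulate_cohort,
)

import pandas as pd


# ---------------------------------------------------------------------------
# null calibration of the enrichment tests
# ---------------------------------------------------------------------------

def null_calibration(
    n_cohorts: int = 25,
    sets_per_cohort: int = 40,
    set_size: int = 20,
    n_decoys: int = 820,
    n_samples: int = 60,
    n_perm: int = 1000,
    nominal_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of ``mra`` and ``two_tailed_gsea`` on null data.

    Cohorts are simulated without perturbation and split into arbitrary
    halves to produce null signatures; the tested gene sets are built from
    decoy (independent) genes, matching the independence assumption of the
    gene-label permutation null.  Returns the rejection rates at
    ``nominal_alpha`` over ``n_cohorts * sets_per_cohort`` draws.
    """
    truth = make_truth_network(
        n_tf=5, targets_per_tf=10, frac_negative=0.4, n_decoys=n_decoys,
        seed=child_seed(seed, "calib-truth"),
    )
    decoys = truth.decoy_ids
    assert sets_per_cohort * set_size <= len(decoys)
    mra_rej = 0
    tt_rej = 0
    n_draws = 0
    for c in range(n_cohorts):
        expr = simulate_cohort(
            truth, n_samples, noise_sd=0.5, seed=child_seed(seed, "calib-cohort", c)
        )
        half = n_samples // 2
        labels = pd.Series(
            [CASE] * half + [CONTROL] * (n_samples - half),
            index=expr.sample_ids,
        )
        sig = compute_signature(ExpressionMatrix(expr.values, labels))
        fake_regs = []
        for k in range(sets_per_cohort):
            block = decoys[k * set_size : (k + 1) * set_size]
            half_set = set_size // 2
            targets = {g: (1, 1.0) for g in block[:half_set]}
            targets.update({g: (-1, -1.0) for g in block[half_set:]})
            fake_regs.append(Regulon(tf=f"NULL{k:03d}", targets=targets))
        recs = mra(
            fake_regs, sig, n_perm=n_perm, seed=child_seed(seed, "calib-mra", c),
            min_size=2,
        )
        mra_rej += sum(r.p_perm <= nominal_alpha for r in recs)
        for reg in fake_regs:
            rec = two_tailed_gsea(
                reg, sig, n_perm=n_perm, min_tail=2,
                seed=child_seed(seed, "calib-gsea2", c),
            )
            tt_rej += rec.p_perm <= nominal_alpha
        n_draws += sets_per_cohort
    return {
        "mra_type1": mra_rej / n_draws,
        "two_tailed_type1": tt_rej / n_draws,
        "n_draws": n_draws,
    }


# ---------------------------------------------------------------------------
# relevance-network recovery
# ---------------------------------------------------------------------------

def _relevance_network(
    expr, tf_ids, seed, alpha=0.01, n_perm=200, n_boot=40, consensus_fraction=0.95
):
    cfg = MIEstimatorConfig()
    thr = permutation_threshold(
        expr, tf_ids, cfg, n_perm=n_perm, alpha=alpha,
        seed=child_seed(seed, "thr"),
    )
    return bootstrap_consensus(
        expr, tf_ids, cfg, threshold=thr, n_boot=n_boot,
        consensus_fraction=consensus_fraction, seed=child_seed(seed, "boot"),
        null_alpha=alpha,
    )


def edge_recovery(
    n_seeds: int = 10,
    n_tf: int = 50,
    targets_per_tf: int = 20,
    n_decoys: int = 500,
    noise_sd: float = 0.5,
    n_samples: int = 300,
    alpha: float = 0.01,
    n_boot: int = 40,
    seed: int = 0,
) -> dict:
    """Planted-edge recall and TF-decoy false-positive rate of the
    relevance network, averaged over ``n_seeds`` replicates."""
    recalls, fprs = [], []
    for s in range(n_seeds):
        truth = make_truth_network(
            n_tf, targets_per_tf, frac_negative=0.4, n_decoys=n_decoys,
            seed=child_seed(seed, "edge-truth", s),
        )
        expr = simulate_cohort(
            truth, n_samples, noise_sd, seed=child_seed(seed, "edge-cohort", s)
        )
        net = _relevance_network(
            expr, truth.tf_ids, child_seed(seed, "edge-net", s),
            alpha=alpha, n_boot=n_boot,
        )
        found = net.edge_keys()
        true_edges = truth.true_edges()
        recalls.append(len(found & true_edges) / len(true_edges))
        decoy_pairs = len(truth.tf_ids) * len(truth.decoy_ids)
        decoy_hits = sum(1 for (t, g) in found if g.startswith("D"))
        fprs.append(decoy_hits / decoy_pairs)
    return {
        "recall": float(np.mean(recalls)),
        "decoy_fpr": float(np.mean(fprs)),
        "n_seeds": n_seeds,
    }


def dpi_removal(
    n_seeds: int = 10,
    n_pairs: int = 6,
    targets_per_tf: int = 10,
    noise_sd: float = 0.5,
    n_samples: int = 300,
    rho: float = 0.9,
    effect_weight: float = 0.6,
    seed: int = 0,
) -> dict:
    """Fraction of indirect TF-target edges removed by DPI.

    Pairs of TFs are coupled (rho) in their latent activities while each
    regulates only its own targets, so every TF acquires an indirect
    association with its partner's targets that is strictly weaker than
    both the direct edge and the TF-TF edge.  Reported: of the indirect
    edges present in the relevance network, the fraction DPI removes.
    """
    present = 0
    removed = 0
    for s in range(n_seeds):
        truth = make_truth_network(
            n_tf=2 * n_pairs, targets_per_tf=targets_per_tf, frac_negative=0.0,
            n_decoys=100, effect_weight=effect_weight,
            seed=child_seed(seed, "dpi-truth", s),
        )
        coupling = {
            truth.tf_ids[2 * i + 1]: (truth.tf_ids[2 * i], rho)
            for i in range(n_pairs)
        }
        expr = simulate_cohort(
            truth, n_samples, noise_sd, seed=child_seed(seed, "dpi-cohort", s),
            tf_coupling=coupling,
        )
        net = _relevance_network(expr, truth.tf_ids, child_seed(seed, "dpi-net", s))
        pruned = apply_dpi(net, tolerance=0.0)
        keys_rel = net.edge_keys()
        keys_dpi = pruned.edge_keys()
        for tf_b, (tf_a, _) in coupling.items():
            for a, b in ((tf_a, tf_b), (tf_b, tf_a)):
                # indirect: partner b vs the private targets of a
                for assign in truth.targets[a]:
                    e = (b, assign.target)
                    if e in keys_rel:
                        present += 1
                        removed += e not in keys_dpi
    return {
        "removed_fraction": removed / present if present else float("nan"),
        "indirect_edges_present": present,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# master-regulator recovery and direction
# ---------------------------------------------------------------------------

def mr_recovery(
    n_seeds: int = 20,
    n_tf: int = 10,
    targets_per_tf: int = 20,
    n_decoys: int = 300,
    noise_sd: float = 0.5,
    n_case: int = 30,
    n_control: int = 31,
    activity_shift: float = 1.5,
    n_perm_mra: int = 1000,
    n_perm_two_tailed: int = 4999,
    alpha: float = 0.05,
    strict_p: float = 0.001,
    seed: int = 0,
) -> dict:
    """Recovery of a planted repressed regulon from case-control cohorts.

    Per seed: does the perturbed TF attain the smallest BH-adjusted p in
    the one-tailed analysis; does the two-tailed analysis (run on the
    one-tailed significant set, as in the pipeline) call it repressed with
    adjusted p below ``strict_p``; and does flipping the perturbation to
    induced flip the sign of the differential score.
    """
    top = 0
    repressed_called = 0
    sign_flipped = 0
    for s in range(n_seeds):
        truth = make_truth_network(
            n_tf, targets_per_tf, frac_negative=0.4, n_decoys=n_decoys,
            seed=child_seed(seed, "mr-truth", s),
        )
        planted = truth.tf_ids[0]
        perturb = PerturbationSpec(planted, REPRESSED, activity_shift)
        cohort_seed = child_seed(seed, "mr-cohort", s)
        expr = simulate_cohort(
            truth, n_case + n_control, noise_sd, perturbation=perturb,
            n_case=n_case, seed=cohort_seed,
        )
        sig = compute_signature(expr)
        regs = regulons_from_truth(truth)
        recs = mra(regs, sig, n_perm=n_perm_mra, seed=child_seed(seed, "mr-mra", s))
        by_tf = {r.tf: r for r in recs}
        min_padj = min(r.p_adj for r in recs)
        top += planted in by_tf and by_tf[planted].p_adj == min_padj

        chosen = [r for r in regs if by_tf.get(r.tf) and by_tf[r.tf].p_adj <= alpha]
        recs2 = two_tailed_mra(
            chosen, sig, n_perm=n_perm_two_tailed,
            seed=child_seed(seed, "mr-gsea2", s),
        )
        rec_p = next((r for r in recs2 if r.tf == planted), None)
        repressed_called += (
            rec_p is not None
            and rec_p.direction == REPRESSED
            and rec_p.des < 0
            and rec_p.p_adj < strict_p
        )

        # paired induced run: identical cohort seed, flipped direction
        expr_i = simulate_cohort(
            truth, n_case + n_control, noise_sd,
            perturbation=replace(perturb, direction=INDUCED),
            n_case=n_case, seed=cohort_seed,
        )
        sig_i = compute_signature(expr_i)
        planted_reg = next(r for r in regs if r.tf == planted)
        rec_r = two_tailed_gsea(
            planted_reg, sig, n_perm=199, min_tail=2,
            seed=child_seed(seed, "mr-pair", s),
        )
        rec_i = two_tailed_gsea(
            planted_reg, sig_i, n_perm=199, min_tail=2,
            seed=child_seed(seed, "mr-pair", s),
        )
        sign_flipped += rec_r.des < 0 < rec_i.des
    return {
        "top_rate": top / n_seeds,
        "repressed_call_rate": repressed_called / n_seeds,
        "sign_flip_rate": sign_flipped / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# end-to-end consensus emulation
# ---------------------------------------------------------------------------

def consensus_recovery(
    n_seeds: int = 10,
    n_tf: int = 10,
    targets_per_tf: int = 20,
    n_decoys: int = 400,
    noise_sd: float = 0.5,
    n_reference: int = 269,
    subsample_size: int = 180,
    cohort1: tuple[int, int] = (30, 31),
    cohort2: tuple[int, int] = (30, 31),
    activity_shift: float = 1.5,
    n_perm_mra: int = 19999,
    alpha: float = 0.05,
    alpha_strict: float = 0.001,
    n_boot: int = 40,
    seed: int = 0,
) -> dict:
    """End-to-end consensus emulation: is the planted TF the unique
    stringent-consensus master regulator across two networks (full
    reference cohort and a subsample) and two independent case-control
    signatures?

    Both cohorts default to 30 cases vs 31 controls, the size at which the
    perturbation is reliably detectable; with a 5-vs-6 cohort the realized
    activity shift of every TF has a standard error of ~0.6 latent SD, so
    stringent calls are not supported (see the methods note).  The
    permutation count is large enough that the p-value floor after BH
    adjustment across ``n_tf`` regulons sits below ``alpha_strict``.
    """
    unique_stringent = 0
    planted_stringent = 0
    for s in range(n_seeds):
        truth = make_truth_network(
            n_tf, targets_per_tf, frac_negative=0.4, n_decoys=n_decoys,
            seed=child_seed(seed, "cons-truth", s),
        )
        planted = truth.tf_ids[0]
        reference = simulate_cohort(
            truth, n_reference, noise_sd, seed=child_seed(seed, "cons-ref", s)
        )
        networks = {
            "tn1": reference,
            "tn2": reference.subset_samples(reference.sample_ids[-subsample_size:]),
        }
        perturb = PerturbationSpec(planted, REPRESSED, activity_shift)
        sigs = {}
        for sig_id, (n_case, n_ctrl) in (("sig1", cohort1), ("sig2", cohort2)):
            cohort = simulate_cohort(
                truth, n_case + n_ctrl, noise_sd, perturbation=perturb,
                n_case=n_case, seed=child_seed(seed, "cons", sig_id, s),
            )
            sigs[sig_id] = compute_signature(cohort)

        all_records = []
        for net_id, expr in networks.items():
            net = _relevance_network(
                expr, truth.tf_ids, child_seed(seed, "cons-net", net_id, s),
                n_boot=n_boot,
            )
            regs = extract_regulons(apply_dpi(net, 0.0), expr, min_size=15)
            for sig_id, sig in sigs.items():
                all_records.extend(
                    mra(
                        regs, sig, n_perm=n_perm_mra,
                        seed=child_seed(seed, "cons-mra", net_id, sig_id, s),
                        network_id=net_id, signature_id=sig_id,
                    )
                )
        report = consensus(all_records, alpha=alpha, alpha_strict=alpha_strict)
        stringent = report.stringent_tfs
        planted_stringent += planted in stringent
        unique_stringent += stringent == [planted]
    return {
        "unique_stringent_rate": unique_stringent / n_seeds,
        "planted_stringent_rate": planted_stringent / n_seeds,
        "n_seeds": n_seeds,
    }
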