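"""Network inference: CV filter, MI estimator, thresholding, bootstrap
consensus and DPI pruning, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mranet import (
    ExpressionMatrix,
    MIEstimatorConfig,
    MINetwork,
    apply_dpi,
    bootstrap_consensus,
    compute_mi_matrix,
    filter_probes_cv,
    mutual_information,
    permutation_threshold,
)
from mranet.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    InvalidStageError,
)
from mranet.mi import equal_frequency_codes, mi_from_joint
from mranet.network import STAGE_RELEVANCE, _mi_matrix, _tf_indices
from oracles import dpi_bruteforce, mi_bruteforce


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestCVFilter:
    def test_zero_variance_gene_removed(self):
        expr = _expr([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        out = filter_probes_cv(expr, 0.5)
        assert out.gene_ids == ["g1"]

    def test_keep_fraction_one_is_identity(self, reference_cohort):
        out = filter_probes_cv(reference_cohort, 1.0)
        assert out.gene_ids == reference_cohort.gene_ids

    def test_matches_recomputed_cv_ranking(self, rng):
        x = rng.normal(loc=5.0, scale=rng.uniform(0.1, 3.0, size=(100, 1)), size=(100, 30))
        expr = _expr(x)
        out = filter_probes_cv(expr, 0.3)
        # independent recomputation: sd/|mean| per gene, top 30
        cv = x.std(axis=1, ddof=1) / np.abs(x.mean(axis=1))
        top = set(np.argsort(-cv, kind="stable")[:30])
        assert set(out.gene_ids) == {f"g{i}" for i in top}

    def test_tf_always_retained(self):
        x = np.vstack([np.full(10, 5.0), np.random.default_rng(1).normal(5, 2, (5, 10))])
        expr = _expr(x)
        out = filter_probes_cv(expr, 0.4, tf_ids=["g0"])
        assert "g0" in out.gene_ids  # constant TF survives the filter

    def test_row_order_preserved(self, reference_cohort):
        out = filter_probes_cv(reference_cohort, 0.5, tf_ids=["TF000"])
        pos = {g: i for i, g in enumerate(reference_cohort.gene_ids)}
        assert sorted(out.gene_ids, key=pos.get) == out.gene_ids

    def test_invalid_fraction(self, reference_cohort):
        with pytest.raises(InvalidParameterError):
            filter_probes_cv(reference_cohort, 0.0)


class TestMutualInformation:
    def test_identical_increasing_vectors_give_log_bins(self):
        x = np.arange(16.0)
        mi = mutual_information(x, x, MIEstimatorConfig(4))
        assert mi == pytest.approx(np.log(4), abs=1e-12)

    def test_constant_vector_gives_zero(self):
        x = np.arange(16.0)
        assert mutual_information(x, np.full(16, 3.0)) == 0.0

    def test_fixed_vectors_against_joint_histogram_oracle(self):
        x = np.array([0.3, 2.1, -1.2, 0.8, 1.9, -0.4, 0.0, 3.2, -2.2, 1.1, 0.6, -0.9])
        y = np.array([1.0, -0.5, 0.2, 2.2, -1.7, 0.9, 1.4, -0.1, 0.5, -2.0, 0.7, 1.8])
        mi = mutual_information(x, y, MIEstimatorConfig(3))
        assert mi == pytest.approx(mi_bruteforce(x, y, 3), abs=1e-12)

    def test_random_pairs_against_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 60))
            b = int(rng.integers(2, 6))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            mi = mutual_information(x, y, MIEstimatorConfig(b))
            assert mi == pytest.approx(mi_bruteforce(x, y, b), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(8, 64))
    def test_symmetry_and_entropy_bound(self, seed, n):
        g = np.random.default_rng(seed)
        x, y = g.normal(size=n), g.normal(size=n)
        cfg = MIEstimatorConfig()
        mab = mutual_information(x, y, cfg)
        mba = mutual_information(y, x, cfg)
        assert mab == pytest.approx(mba, abs=1e-12)
        b = cfg.resolve_bins(n)
        hx = mi_from_joint(np.diag(np.bincount(equal_frequency_codes(x, b), minlength=b)))
        hy = mi_from_joint(np.diag(np.bincount(equal_frequency_codes(y, b), minlength=b)))
        assert -1e-12 <= mab <= min(hx, hy) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            mutual_information(np.arange(10.0), np.arange(12.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            mutual_information(np.arange(5.0), np.arange(5.0))


class TestMIMatrix:
    def test_edge_count_single_tf(self):
        expr = _expr(np.random.default_rng(0).normal(size=(3, 20)))
        net = compute_mi_matrix(expr, ["g0"])
        assert net.n_edges == 2
        assert net.stage == "raw"

    def test_edge_count_two_tfs_stores_tf_tf_once(self):
        expr = _expr(np.random.default_rng(0).normal(size=(4, 20)))
        net = compute_mi_matrix(expr, ["g0", "g1"])
        # 2 TFs x 3 partners, minus the duplicated symmetric TF-TF edge
        assert net.n_edges == 5
        assert ("g0", "g1") in net.edge_keys()
        assert ("g1", "g0") not in net.edge_keys()

    def test_weights_match_elementwise_calls(self, reference_cohort, small_truth):
        net = compute_mi_matrix(reference_cohort, small_truth.tf_ids)
        cfg = MIEstimatorConfig()
        vals = reference_cohort.values
        for row in net.edges.sample(25, random_state=0).itertuples(index=False):
            direct = mutual_information(
                vals.loc[row.tf].to_numpy(), vals.loc[row.target].to_numpy(), cfg
            )
            assert row.mi == pytest.approx(direct, abs=1e-12)

    def test_unknown_tf_listed(self, reference_cohort):
        with pytest.raises(InvalidInputError, match="NOPE"):
            compute_mi_matrix(reference_cohort, ["TF000", "NOPE"])


class TestPermutationThreshold:
    def test_deterministic_for_seed(self, reference_cohort, small_truth):
        a = permutation_threshold(reference_cohort, small_truth.tf_ids, n_perm=100, seed=5)
        b = permutation_threshold(reference_cohort, small_truth.tf_ids, n_perm=100, seed=5)
        assert a == b

    def test_alpha_near_one_approaches_null_minimum(self, reference_cohort, small_truth):
        low = permutation_threshold(
            reference_cohort, small_truth.tf_ids, n_perm=100, alpha=0.999, seed=5
        )
        high = permutation_threshold(
            reference_cohort, small_truth.tf_ids, n_perm=100, alpha=0.01, seed=5
        )
        assert 0.0 <= low < high

    def test_n_perm_floor(self, reference_cohort, small_truth):
        with pytest.raises(InvalidParameterError):
            permutation_threshold(reference_cohort, small_truth.tf_ids, n_perm=50)


class TestBootstrapConsensus:
    def test_degenerate_single_bootstrap(self, small_truth, reference_cohort):
        """n_boot=1, consensus=1: output equals that bootstrap's thresholded net."""
        tf_ids = small_truth.tf_ids
        net = bootstrap_consensus(
            reference_cohort, tf_ids, threshold=0.3, n_boot=1,
            consensus_fraction=1.0, seed=42,
        )
        # replay the single bootstrap with the same stream and recount
        cfg = MIEstimatorConfig()
        b = cfg.resolve_bins(reference_cohort.n_samples)
        x = reference_cohort.values.to_numpy(dtype=float)
        idx = np.random.default_rng(42).integers(0, x.shape[1], size=x.shape[1])
        codes = equal_frequency_codes(x[:, idx], b)
        mi_b = _mi_matrix(codes, _tf_indices(reference_cohort, tf_ids), b)
        genes = reference_cohort.gene_ids
        expected = set()
        tf_set = set(tf_ids)
        for k, tf in enumerate(tf_ids):
            for j in np.nonzero(mi_b[k] > 0.3)[0]:
                g = genes[j]
                if g == tf:
                    continue
                expected.add((min(tf, g), max(tf, g)) if g in tf_set else (tf, g))
        assert net.edge_keys() == expected

    def test_planted_edges_survive_and_weights_from_full_matrix(
        self, small_truth, reference_cohort
    ):
        net = bootstrap_consensus(
            reference_cohort, small_truth.tf_ids, threshold=0.05,
            n_boot=20, consensus_fraction=0.95, seed=7, null_alpha=0.01,
        )
        found = net.edge_keys()
        true_edges = small_truth.true_edges()
        assert len(found & true_edges) / len(true_edges) >= 0.9
        full = compute_mi_matrix(reference_cohort, small_truth.tf_ids).mi_lookup()
        for key, mi in list(net.mi_lookup().items())[:20]:
            assert mi == pytest.approx(full[key], abs=1e-12)

    def test_too_few_samples(self, small_truth):
        from mranet import simulate_cohort

        expr = simulate_cohort(small_truth, 6, 0.5, seed=1)
        with pytest.raises(InvalidInputError):
            bootstrap_consensus(expr, small_truth.tf_ids, n_boot=2)


def _net_from_dict(edges, tf_ids):
    df = pd.DataFrame(
        [(t, g, m) for (t, g), m in sorted(edges.items())],
        columns=["tf", "target", "mi"],
    )
    return MINetwork(df, STAGE_RELEVANCE, sorted(tf_ids))


class TestDPI:
    def test_weakest_edge_of_triplet_removed(self):
        edges = {("A", "B"): 0.6, ("A", "g"): 0.5, ("B", "g"): 0.4}
        net = _net_from_dict(edges, ["A", "B"])
        out = apply_dpi(net, 0.0)
        assert out.edge_keys() == {("A", "B"), ("A", "g")}
        assert out.stage == "dpi"

    def test_no_complete_triplet_is_noop(self):
        edges = {("A", "g1"): 0.2, ("B", "g2"): 0.1, ("A", "B"): 0.9}
        net = _net_from_dict(edges, ["A", "B"])
        assert apply_dpi(net, 0.0).edge_keys() == set(edges)

    def test_requires_relevance_stage(self):
        df = pd.DataFrame([("A", "g", 0.5)], columns=["tf", "target", "mi"])
        raw = MINetwork(df, "raw", ["A"])
        with pytest.raises(InvalidStageError):
            apply_dpi(raw)

    def test_random_networks_match_bruteforce(self, rng):
        for trial in range(10):
            n_tf = int(rng.integers(2, 6))
            n_genes = int(rng.integers(5, 24))
            tf_ids = [f"T{i}" for i in range(n_tf)]
            genes = [f"g{i}" for i in range(n_genes)]
            edges = {}
            for i in range(n_tf):
                for j in range(i + 1, n_tf):
                    if rng.random() < 0.7:
                        edges[(tf_ids[i], tf_ids[j])] = float(rng.random())
                for g in genes:
                    if rng.random() < 0.5:
                        edges[(tf_ids[i], g)] = float(rng.random())
            net = _net_from_dict(edges, tf_ids)
            out = apply_dpi(net, tolerance=float(rng.choice([0.0, 0.0, 0.1])))
            tol = out.params["tolerance"]
            removed = set(edges) - out.edge_keys()
            assert removed == dpi_bruteforce(edges, tf_ids, tol)

    def test_subset_chain(self, small_truth, reference_cohort):
        tf_ids = small_truth.tf_ids
        raw = compute_mi_matrix(reference_cohort, tf_ids)
        thr = permutation_threshold(reference_cohort, tf_ids, n_perm=100, seed=3)
        rel = bootstrap_consensus(
            reference_cohort, tf_ids, threshold=thr, n_boot=10,
            consensus_fraction=0.9, seed=4, null_alpha=0.01,
        )
        dpi = apply_dpi(rel, 0.0)
        assert dpi.edge_keys() <= rel.edge_keys() <= raw.edge_keys()
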