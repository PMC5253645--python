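"""Tests for permutation inference, bootstrap RMI, entropy prefilter and
target-set definition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rmicell import simdata
from rmicell.inference import (
    define_targets,
    delta_rmi_test,
    entropy_prefilter,
    expression_bins,
    rmi_bootstrap_distribution,
    rmi_permutation_test,
)
from rmicell.preprocess import compute_size_factors
from rmicell.rmi import RMIConfig


def correlated_block_matrix(n_cells=60, n_genes=80, block=10, rho=0.6, seed=0):
    """Counts-free synthetic expression: a latent correlated block among
    independent genes; returned as genes x cells."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_cells, n_genes))
    shared = rng.standard_normal((n_cells, 1))
    X[:, :block] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * X[:, :block]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    return pd.DataFrame(X.T + 5.0, index=genes, columns=cells)


class TestExpressionBins:
    def make(self, n_genes):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            rng.random((n_genes, 4)) * 100,
            index=[f"g{i:05d}" for i in range(n_genes)],
            columns=list("abcd"),
        )

    def test_exact_split(self):
        bins = expression_bins(self.make(1000), bin_size=500)
        assert [len(b) for b in bins.bins] == [500, 500]

    def test_remainder_bin(self):
        bins = expression_bins(self.make(1001), bin_size=500)
        assert [len(b) for b in bins.bins] == [500, 500, 1]

    def test_sorted_descending_with_stable_ties(self):
        v = pd.DataFrame(
            {"a": [5.0, 9.0, 5.0, 1.0]},
            index=["g_z", "g_a", "g_b", "g_c"],
        )
        bins = expression_bins(v, bin_size=2)
        assert bins.bins[0] == ("g_a", "g_z")  # tie: original order
        assert bins.bins[1] == ("g_b", "g_c")


class TestRmiPermutationTest:
    def test_correlated_block_significant_and_p_floored(self):
        v = correlated_block_matrix(rho=0.8, seed=3)
        bins = expression_bins(v, bin_size=40)
        res = rmi_permutation_test(
            v, list(v.index[:10]), bins, trials=100, config=RMIConfig(seed=3), seed=3
        )
        assert res.observed > 0.3
        assert res.p == pytest.approx(1 / 100)  # floored, never 0

    def test_null_p_not_extreme(self):
        v = correlated_block_matrix(rho=0.0, seed=4)
        bins = expression_bins(v, bin_size=40)
        ps = [
            rmi_permutation_test(
                v, list(np.random.default_rng(s).choice(v.index, 10, replace=False)),
                bins, trials=100, config=RMIConfig(seed=s), seed=s,
            ).p
            for s in range(20)
        ]
        assert np.mean(np.array(ps) <= 0.05) <= 0.25
        assert min(ps) > 0.0

    def test_power_exceeds_null(self):
        hits = 0
        for s in range(5):
            v = correlated_block_matrix(rho=0.6, seed=100 + s)
            bins = expression_bins(v, bin_size=40)
            res = rmi_permutation_test(
                v, list(v.index[:10]), bins, trials=200,
                config=RMIConfig(seed=s), seed=s,
            )
            hits += res.p < 0.05
        assert hits >= 4

    def test_missing_gene_errors(self):
        v = correlated_block_matrix()
        bins = expression_bins(v, bin_size=40)
        with pytest.raises(KeyError):
            rmi_permutation_test(v, ["nope"], bins, trials=100)


class TestBootstrapDistribution:
    def test_independent_genes_centred_near_zero(self):
        v = correlated_block_matrix(rho=0.0, seed=5)
        dist = rmi_bootstrap_distribution(v, list(v.index), subset_size=10,
                                          trials=200, config=RMIConfig(seed=5), seed=5)
        assert abs(np.median(dist)) < 0.1

    def test_block_set_larger_than_matched_independent(self):
        v = correlated_block_matrix(rho=0.5, n_genes=60, block=20, seed=6)
        block = list(v.index[:20])
        indep = list(v.index[20:40])
        db = rmi_bootstrap_distribution(v, block, 8, 200, RMIConfig(seed=6), seed=6)
        di = rmi_bootstrap_distribution(v, indep, 8, 200, RMIConfig(seed=6), seed=7)
        assert np.median(db) > np.median(di)
        assert stats.mannwhitneyu(db, di, alternative="greater").pvalue < 1e-3

    def test_subset_size_robustness(self):
        v = correlated_block_matrix(rho=0.5, n_genes=60, block=20, seed=8)
        block = list(v.index[:20])
        indep = list(v.index[20:40])
        for size in (8, 10, 12):
            db = rmi_bootstrap_distribution(v, block, size, 100, RMIConfig(seed=8), seed=8)
            di = rmi_bootstrap_distribution(v, indep, size, 100, RMIConfig(seed=8), seed=9)
            assert np.median(db) > np.median(di)

    def test_small_set_rejected(self):
        v = correlated_block_matrix()
        with pytest.raises(ValueError):
            rmi_bootstrap_distribution(v, list(v.index[:5]), subset_size=10, trials=10)


class TestEntropyPrefilter:
    def test_constant_gene_excluded_and_count_exact(self):
        rng = np.random.default_rng(9)
        v = pd.DataFrame(rng.random((40, 30)) * 50,
                         index=[f"g{i:02d}" for i in range(40)],
                         columns=[f"c{i}" for i in range(30)])
        v.iloc[0] = 7.0  # constant gene
        kept = entropy_prefilter({"x": v}, percentile=5.0)
        assert "g00" not in kept
        assert len(kept) == 40 - int(np.ceil(0.05 * 40))

    def test_gene_must_survive_both_conditions(self):
        rng = np.random.default_rng(10)
        va = pd.DataFrame(rng.random((20, 25)), index=[f"g{i}" for i in range(20)],
                          columns=[f"a{i}" for i in range(25)])
        vb = va.copy()
        vb.columns = [f"b{i}" for i in range(25)]
        va.iloc[1] = 3.0   # constant in A only
        vb.iloc[2] = 4.0   # constant in B only
        kept = entropy_prefilter({"a": va, "b": vb}, percentile=5.0)
        assert "g1" not in kept and "g2" not in kept

    def test_high_variance_genes_retained(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            v = pd.DataFrame(rng.standard_normal((60, 40)) * rng.gamma(2, 1, 60)[:, None],
                             index=[f"g{i:02d}" for i in range(60)],
                             columns=[f"c{i}" for i in range(40)])
            variances = v.var(axis=1)
            top = set(variances.sort_values(ascending=False).index[:6])
            kept = set(entropy_prefilter({"x": v}, percentile=5.0))
            assert top <= kept


class TestDeltaRmi:
    def test_sign_antisymmetry_exact(self):
        va = correlated_block_matrix(rho=0.6, seed=11)
        vb = correlated_block_matrix(rho=0.0, seed=12)
        genes = list(va.index[:10])
        r1 = delta_rmi_test(va, vb, genes, trials=100, config=RMIConfig(seed=1), seed=1)
        r2 = delta_rmi_test(vb, va, genes, trials=100, config=RMIConfig(seed=1), seed=1)
        assert r2.observed == pytest.approx(-r1.observed, abs=1e-12)
        assert r2.p == pytest.approx(r1.p)

    def test_power_on_planted_block(self):
        hits = 0
        for s in range(5):
            va = correlated_block_matrix(rho=0.6, seed=200 + s)
            vb = correlated_block_matrix(rho=0.0, seed=300 + s)
            res = delta_rmi_test(va, vb, list(va.index[:10]), trials=200,
                                 config=RMIConfig(seed=s), seed=s)
            if res.observed > 0 and res.p < 0.05:
                hits += 1
        assert hits >= 4

    def test_split_null_p_moderate(self):
        ps = []
        for s in range(10):
            v = correlated_block_matrix(rho=0.0, n_cells=120, seed=400 + s)
            cells = list(v.columns)
            va, vb = v[cells[:60]], v[cells[60:]]
            genes = list(np.random.default_rng(s).choice(v.index, 10, replace=False))
            ps.append(delta_rmi_test(va, vb, genes, trials=100,
                                     config=RMIConfig(seed=s), seed=s).p)
        assert np.mean(np.array(ps) <= 0.05) <= 0.3
        assert np.mean(ps) > 0.2

    def test_binned_null_mode(self):
        va = correlated_block_matrix(rho=0.0, seed=13)
        vb = correlated_block_matrix(rho=0.0, seed=14)
        bins = expression_bins(va, bin_size=40)
        res = delta_rmi_test(va, vb, list(va.index[:8]), trials=100,
                             config=RMIConfig(seed=2), seed=2, binned=bins)
        assert 0 < res.p <= 1


class TestDefineTargets:
    def test_hand_set_algebra(self):
        ts = define_targets(
            de_down=["a", "b", "c"],
            sources={"TS": ["a", "b"], "MR": ["b", "d"], "ML": ["a"]},
        )
        assert set(ts.predicted) == {"a", "b"}
        assert set(ts.high_confidence) == {"a", "b"}
        assert ts.support["a"] == 2 and ts.support["b"] == 2

    def test_wt_filter_restricts_high_confidence(self):
        ts = define_targets(
            de_down=["a", "b", "c"],
            sources={"TS": ["a", "b"], "MR": ["b", "a"]},
            de_down_wt=["a"],
        )
        assert set(ts.predicted) == {"a", "b"}
        assert set(ts.high_confidence) == {"a"}

    def test_empty_down_list(self):
        ts = define_targets(de_down=[], sources={"TS": ["a"]})
        assert ts.predicted == () and ts.high_confidence == ()

    def test_requires_a_source(self):
        with pytest.raises(ValueError):
            define_targets(de_down=["a"], sources={})


class TestPipelineQualitativeClaim:
    def test_targets_down_yet_more_coexpressed(self):
        """The study's central observation as a recoverable property:
        in the transfected condition the miRNA's targets have reduced
        mean expression yet higher set-wise co-expression (RMI)."""
        cfg = simdata.default_config(seed=50, n_genes=300, n_cells_per_condition=60)
        em, truth = simdata.simulate_experiment(cfg)
        nm = compute_size_factors(em)
        targets = list(truth.true_targets["mir294"])[:10]
        tx = nm.values.loc[:, nm.conditions == "mir294"]
        ctrl = nm.values.loc[:, nm.conditions == "dgcr8"]
        # downregulated ...
        assert tx.loc[targets].mean(axis=1).sum() < 0.7 * ctrl.loc[targets].mean(axis=1).sum()
        # ... yet more co-expressed
        res = delta_rmi_test(tx, ctrl, targets, trials=200,
                             config=RMIConfig(seed=50), seed=50)
        assert res.observed > 0
        assert res.p < 0.05
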