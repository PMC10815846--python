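"""Co-expression network construction and module detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ppigat.coexpression import (
    CoexprConfig,
    adjacency_tom,
    detect_modules,
    filter_genes,
    gene_significance,
    module_eigengene,
    module_trait_stats,
    remove_outlier_samples,
    run_wgcna,
)
from ppigat.synthetic import SyntheticConfig, generate_expression


def _expr(x, genes=None, samples=None):
    x = np.asarray(x, dtype=float)
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    samples = samples or [f"s{j}" for j in range(x.shape[1])]
    return pd.DataFrame(x, index=genes, columns=samples)


class TestFilterGenes:
    def test_zero_quantile_is_identity(self, rng):
        expr = _expr(rng.standard_normal((10, 8)))
        out = filter_genes(expr, CoexprConfig())
        assert out.equals(expr)

    def test_quantile_removes_expected_count(self, rng):
        # oracle: direct MAD quantile on 100 genes -> 75 survivors
        expr = _expr(rng.standard_normal((100, 30)))
        cfg = CoexprConfig(variance_filter_quantile=0.25)
        out = filter_genes(expr, cfg)
        mad = stats.median_abs_deviation(expr.to_numpy(), axis=1)
        expected = (mad >= np.quantile(mad, 0.25)).sum()
        assert len(out) == expected == 75
        assert list(out.index) == [g for g in expr.index if g in set(out.index)]

    def test_constant_gene_always_removed(self, rng):
        x = rng.standard_normal((5, 20))
        x[2] = 1.0
        out = filter_genes(_expr(x), CoexprConfig(variance_filter_quantile=0.01))
        assert "g2" not in out.index


class TestOutlierRemoval:
    def test_none_z_is_identity(self, rng):
        expr = _expr(rng.standard_normal((10, 5)))
        assert remove_outlier_samples(expr, CoexprConfig()).equals(expr)

    def test_identical_samples_none_removed(self):
        expr = _expr(np.ones((6, 10)))
        out = remove_outlier_samples(expr, CoexprConfig(sample_outlier_z=2.0))
        assert out.shape == expr.shape

    def test_shifted_sample_removed(self, rng):
        x = rng.standard_normal((20, 30))
        x[:, 7] += 50.0
        cfg = CoexprConfig(sample_outlier_z=3.0)
        out = remove_outlier_samples(_expr(x), cfg)
        assert "s7" not in out.columns
        assert out.shape[1] == 29


class TestAdjacencyTom:
    def test_two_gene_hand_computation(self):
        # beta=1, cor=0.5: a=0.5, k_i=0.5, TOM=(0+0.5)/(0.5+1-0.5)=0.5
        rng = np.random.default_rng(2)
        f = rng.standard_normal(100_000)
        x0 = np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal(100_000)
        x1 = np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal(100_000)
        expr = _expr(np.stack([x0, x1]))
        r = abs(np.corrcoef(x0, x1)[0, 1])
        dis = adjacency_tom(expr, CoexprConfig(soft_power=1))
        expected_tom = r / (r + 1.0 - r)
        assert dis.iloc[0, 1] == pytest.approx(1.0 - expected_tom, abs=1e-12)
        assert dis.iloc[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_perfect_correlation_near_zero_dissimilarity(self, rng):
        base = rng.standard_normal(50)
        expr = _expr(np.stack([base, base * 2 + 1, base * 0.5 - 3, -0 * base + base]))
        dis = adjacency_tom(expr, CoexprConfig(soft_power=5)).to_numpy()
        off = dis[~np.eye(4, dtype=bool)]
        assert np.all(off < 0.05)

    def test_independent_genes_near_one_dissimilarity(self, rng):
        expr = _expr(rng.standard_normal((10, 5000)))
        dis = adjacency_tom(expr, CoexprConfig(soft_power=5)).to_numpy()
        off = dis[~np.eye(10, dtype=bool)]
        assert np.all(off > 0.9)

    def test_matrix_invariants(self, rng):
        expr = _expr(rng.standard_normal((15, 40)))
        dis = adjacency_tom(expr, CoexprConfig()).to_numpy()
        assert np.allclose(dis, dis.T)
        assert np.allclose(np.diag(dis), 0.0)
        assert dis.min() >= 0.0 and dis.max() <= 1.0

    def test_zero_variance_gene_rejected(self, rng):
        x = rng.standard_normal((4, 10))
        x[1] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency_tom(_expr(x), CoexprConfig())


class TestDetectModules:
    def _planted(self, seed=0, r=0.8, sizes=(50, 50, 50), n=93):
        cfg = SyntheticConfig(
            n_genes=sum(sizes), module_sizes=sizes, within_module_cor=r,
            signal_genes=0, n_major=n - 20, n_minor=20, seed=seed,
        )
        expr, labels, truth = generate_expression(cfg)
        true_labels = np.array([truth["module_membership"][g] for g in expr.index])
        return expr, labels, true_labels

    def test_planted_blocks_recovered(self):
        expr, _, true_labels = self._planted()
        cfg = CoexprConfig(soft_power=5, min_module_size=30)
        dis = adjacency_tom(expr, cfg)
        assign = detect_modules(dis, cfg)
        ari = adjusted_rand_score(true_labels, assign.labels.to_numpy())
        assert ari >= 0.8

    def test_cut_height_one_gives_single_module(self, rng):
        expr = _expr(rng.standard_normal((40, 30)))
        cfg = CoexprConfig(min_module_size=10, tree_cut_height=1.0)
        assign = detect_modules(adjacency_tom(expr, cfg), cfg)
        assert assign.module_ids == [1]
        assert (assign.labels == 1).all()

    def test_independent_genes_all_unassigned(self, rng):
        expr = _expr(rng.standard_normal((60, 2000)))
        cfg = CoexprConfig(min_module_size=30, tree_cut_height=0.1)
        assign = detect_modules(adjacency_tom(expr, cfg), cfg)
        assert (assign.labels == 0).all()

    def test_labels_invariant_to_gene_permutation(self):
        expr, _, _ = self._planted(seed=4)
        cfg = CoexprConfig(soft_power=5, min_module_size=30)
        a = detect_modules(adjacency_tom(expr, cfg), cfg).labels
        perm = np.random.default_rng(1).permutation(len(expr))
        b = detect_modules(adjacency_tom(expr.iloc[perm], cfg), cfg).labels
        assert (b.loc[a.index] == a).all()


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self, rng):
        base = rng.standard_normal(30)
        expr = _expr(np.stack([base, 2 * base + 5, 0.1 * base]))
        eg = module_eigengene(expr, ["g0", "g1", "g2"])
        z = (base - base.mean()) / base.std()
        z = z / np.linalg.norm(z)
        np.testing.assert_allclose(np.abs(eg.to_numpy()), np.abs(z), atol=1e-10)
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_explains_at_least_any_single_gene_variance(self, rng):
        expr = _expr(rng.standard_normal((8, 40)))
        genes = list(expr.index)
        eg = module_eigengene(expr, genes).to_numpy()
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1)).T.to_numpy()
        proj_var = ((z @ eg) ** 2).sum()
        single = max(((z @ (z[i] / np.linalg.norm(z[i]))) ** 2).sum()
                     for i in range(len(genes)))
        assert proj_var >= single - 1e-8

    def test_recovers_latent_factor(self):
        cfg = SyntheticConfig(n_genes=50, module_sizes=(50,),
                              within_module_cor=0.8, signal_genes=0,
                              n_major=73, n_minor=20, seed=3)
        rng = np.random.default_rng(cfg.seed)
        expr, _, _ = generate_expression(cfg, rng)
        # reconstruct the factor as the mean of standardized genes (consistent)
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1)).T
        factor_proxy = z.mean(axis=0)
        eg = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(eg, factor_proxy)[0, 1]) >= 0.9


class TestTraitStats:
    def test_eigengene_equal_to_trait(self):
        y = pd.Series(np.r_[np.zeros(40), np.ones(40)].astype(int),
                      index=[f"s{i}" for i in range(80)])
        eg = pd.DataFrame({1: y.astype(float)})
        out = module_trait_stats(eg, y)
        assert out.loc[1, "trait_cor"] == pytest.approx(1.0)
        assert out.loc[1, "p_value"] < 1e-20

    def test_null_p_values_calibrated(self):
        # type-I rate at alpha=0.05 over 1000 independent eigengene draws
        rng = np.random.default_rng(8)
        n = 93
        y = pd.Series(np.r_[np.zeros(73), np.ones(20)].astype(int),
                      index=[f"s{i}" for i in range(n)])
        eg = pd.DataFrame({m: rng.standard_normal(n) for m in range(1000)},
                          index=y.index)
        out = module_trait_stats(eg, y)
        rate = (out["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07
        ks = stats.kstest(out["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_constant_trait_rejected(self, rng):
        y = pd.Series(np.ones(10, dtype=int), index=[f"s{i}" for i in range(10)])
        eg = pd.DataFrame({1: rng.standard_normal(10)}, index=y.index)
        with pytest.raises(ValueError, match="constant"):
            module_trait_stats(eg, y)


class TestGeneSignificance:
    def test_signal_gene_ranks_in_top_decile(self):
        cfg = SyntheticConfig(n_genes=200, module_sizes=(50, 50),
                              within_module_cor=0.3, signal_genes=2,
                              effect_size_d=1.5, n_major=73, n_minor=20, seed=6)
        expr, labels, truth = generate_expression(cfg)
        gs = gene_significance(expr, labels)
        cutoff = gs.quantile(0.9)
        for g in truth["signal_genes"]:
            assert gs[g] >= cutoff

    def test_gs_in_unit_interval(self, rng):
        expr = _expr(rng.standard_normal((20, 30)))
        y = pd.Series(rng.integers(0, 2, 30), index=expr.columns)
        gs = gene_significance(expr, y)
        assert ((gs >= 0) & (gs <= 1)).all()


def test_run_wgcna_end_to_end(small_cohort):
    cfg, cohort = small_cohort
    assign = run_wgcna(cohort.expression, cohort.labels,
                       CoexprConfig(min_module_size=20))
    assert len(assign.module_ids) >= 2
    assert set(assign.eigengenes.columns) == set(assign.module_ids)
    assert ((assign.trait_stats["p_value"] >= 0) &
            (assign.trait_stats["p_value"] <= 1)).all()
    norms = np.linalg.norm(assign.eigengenes.to_numpy(), axis=0)
    np.testing.assert_allclose(norms, 1.0, atol=1e-8)
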