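"""Background-corrected trajectories, eigengenes, module-trait, hub calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from recescan.simulate import simulate_coexpression_module, simulate_expression
from recescan.trajectory import (corrected_trajectory, eigengene,
                                 expressed_genes, hub_genes, module_trait,
                                 trajectory_age_correlation)


def _matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


def _meta(n, ages=None, region="NCX"):
    ages = ages if ages is not None else np.linspace(0, 1, n)
    return pd.DataFrame({"age": ages, "region": [region] * n},
                        index=[f"s{j}" for j in range(n)])


class TestCorrectedTrajectory:
    def test_full_set_self_corrects_to_zero(self, rng):
        expr = _matrix(rng.uniform(2, 50, size=(30, 10)))
        traj = corrected_trajectory(expr, _meta(10), list(expr.index))
        assert np.allclose(traj["corrected"], 0.0, atol=1e-12)

    def test_uniform_log2_offset_recovered(self):
        base = np.full((21, 8), 8.0)  # log2(8+1) ~ 3.17
        expr = _matrix(base)
        boosted = expr.copy()
        set_genes = [f"g{i}" for i in range(5)]
        # shift the set by exactly +1 on the log2(x+1) scale
        boosted.loc[set_genes] = 2.0 ** (np.log2(8.0 + 1) + 1.0) - 1.0
        traj = corrected_trajectory(boosted, _meta(8), set_genes)
        assert np.allclose(traj["corrected"], 1.0, atol=1e-9)

    def test_planted_trend_detected(self):
        genes = [f"G{i}" for i in range(200)]
        expr, meta = simulate_expression(genes, seed=55, n_samples=40,
                                         trend_genes=genes[:20], beta=0.5,
                                         noise_sd=0.2)
        traj = corrected_trajectory(expr, meta, genes[:20])
        rho, p = trajectory_age_correlation(traj)
        assert rho > 0 and p < 0.05

    def test_missing_genes_listed(self):
        expr = _matrix(np.ones((4, 5)) * 10)
        with pytest.raises(ValueError, match="ghost"):
            corrected_trajectory(expr, _meta(5), ["ghost"])

    def test_median_robust_to_median_preserving_additions(self, rng):
        expr = _matrix(rng.uniform(4, 20, size=(11, 6)))
        gene_set = list(expr.index[:3])
        base = corrected_trajectory(expr, _meta(6), gene_set)
        med = np.log2(expr + 1).median(axis=0)
        # add one gene above and one below the background median everywhere
        hi = 2.0 ** (med + 3) - 1
        lo = 2.0 ** (med - 0.5) - 1
        bigger = pd.concat([expr, pd.DataFrame([hi, lo], index=["hi", "lo"])])
        again = corrected_trajectory(bigger, _meta(6), gene_set)
        assert np.allclose(base["corrected"], again["corrected"], atol=1e-9)

    def test_region_with_too_few_samples(self):
        expr = _matrix(np.ones((3, 4)) * 10)
        meta = _meta(4)
        meta.loc[:, "region"] = ["A", "A", "B", "B"]
        with pytest.raises(ValueError, match="fewer than 3"):
            corrected_trajectory(expr, meta, list(expr.index), region="A")

    def test_expressed_gene_rule(self):
        expr = _matrix([[0.1] * 10, [5.0] * 10,
                        [5.0] + [0.1] * 9])  # 10% exactly for the third
        idx = expressed_genes(expr)
        assert list(idx) == ["g1", "g2"]


class TestEigengene:
    def test_duplicated_gene_module(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = _matrix(np.tile(profile, (6, 1)))
        eg = eigengene(expr)
        assert eg.variance_explained == pytest.approx(1.0)
        r, _ = pearsonr(eg.values, profile)
        assert abs(r) == pytest.approx(1.0)
        assert r >= 0  # orientation follows the shared profile

    def test_orientation_nonnegative_with_mean_profile(self, rng):
        expr = _matrix(rng.normal(size=(20, 15)))
        eg = eigengene(expr)
        Z = ((expr - expr.mean(axis=1).values[:, None])
             / expr.std(axis=1).values[:, None])
        assert np.dot(eg.values, Z.mean(axis=0)) >= 0

    def test_two_orthogonal_groups_split_variance(self):
        a = np.array([1.0, -1.0] * 6)
        b = np.array([1.0, 1.0, -1.0, -1.0] * 3)
        expr = _matrix(np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))]))
        eg = eigengene(expr)
        assert eg.variance_explained == pytest.approx(0.5, abs=1e-8)

    def test_zero_variance_gene_dropped(self, rng):
        X = rng.normal(size=(5, 8))
        X[2] = 7.0
        eg = eigengene(_matrix(X))
        assert eg.dropped_genes == ["g2"]

    def test_gene_permutation_invariance(self, rng):
        expr = _matrix(rng.normal(size=(12, 9)))
        eg1 = eigengene(expr)
        eg2 = eigengene(expr.iloc[rng.permutation(12)])
        assert np.allclose(eg1.values, eg2.values, atol=1e-9)


class TestModuleTrait:
    def test_perfect_correlation_significant(self):
        ages = np.linspace(0, 1, 10)
        r, p, sig = module_trait(pd.Series(ages), ages)
        assert r == pytest.approx(1.0) and sig

    def test_r06_n5_not_significant(self):
        # exact r = 0.6 with n = 5 gives p ~ 0.28: fails the p < 0.05 arm
        ages = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        za = (ages - ages.mean()) / ages.std()
        v = np.array([2.0, -1.0, -2.0, -1.0, 2.0])  # orthogonal to ages & 1
        zv = (v - v.mean()) / v.std()
        eig = 0.6 * za + 0.8 * zv
        r, p, sig = module_trait(eig, ages)
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(0.2848, abs=5e-4) and not sig

    def test_low_r_fails_regardless_of_p(self, rng):
        ages = np.linspace(0, 1, 500)
        eig = 0.4 * (ages - 0.5) / np.std(ages) + rng.normal(0, 1, 500)
        r, p, sig = module_trait(eig, ages)
        if abs(r) <= 0.5:  # overwhelmingly likely at this noise level
            assert not sig

    def test_constant_eigengene_flagged(self):
        r, p, sig = module_trait(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and not sig


class TestHubGenes:
    def test_age_tracking_gene_is_hub(self):
        ages = np.linspace(0, 1, 20)
        profile = ages - ages.mean()
        expr = _matrix(np.vstack([profile * (i + 1) for i in range(4)]))
        expr.columns = [f"s{j}" for j in range(20)]
        eg = eigengene(expr)
        report = hub_genes(expr, eg.values, ages)
        assert report["hub"].all()

    def test_noise_genes_rarely_hubs(self, rng):
        # module whose eigengene is unrelated to age: both criteria are then
        # roughly independent for a pure-noise gene (~0.05^2 joint rate)
        n = 40
        ages = np.linspace(0, 1, n)
        profile = rng.normal(size=n)
        rows = [profile + rng.normal(0, 0.3, n) for _ in range(20)]
        rows += [rng.normal(size=n) for _ in range(500)]
        mat = _matrix(np.vstack(rows))
        mat.columns = [f"s{j}" for j in range(n)]
        eg = eigengene(mat)
        report = hub_genes(mat, eg.values, ages)
        noise = report.iloc[20:]
        assert noise["hub"].mean() < 0.02

    def test_threshold_is_strict(self):
        ages = np.linspace(0, 1, 15)
        rng = np.random.default_rng(3)
        x = ages + rng.normal(0, 0.5, 15)
        expr = _matrix(np.vstack([x, x * 2 + rng.normal(0, 0.1, 15)]))
        expr.columns = [f"s{j}" for j in range(15)]
        eg = eigengene(expr)
        report = hub_genes(expr, eg.values, ages)
        # with the threshold set to a gene's own p-value, strict '<' excludes it
        p_at = report.iloc[0]["p_GS"]
        again = hub_genes(expr, eg.values, ages, p_threshold=min(
            p_at, report.iloc[0]["p_MM"]))
        assert not again.iloc[0]["hub"]

    def test_planted_hub_recovery(self):
        mat, ages, hub_ids = simulate_coexpression_module(10, n_samples=40)
        eg = eigengene(mat)
        report = hub_genes(mat, eg.values, ages)
        called = set(report.index[report["hub"]])
        sens = len(called & set(hub_ids)) / len(hub_ids)
        fdr = len(called - set(hub_ids)) / max(1, len(called))
        assert sens >= 0.9 and fdr <= 0.1
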