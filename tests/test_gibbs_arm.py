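import numpy as np
import pytest

import magicqtl as m
from magicqtl.gibbs_arm import ArmConfig, ChainSummary, PosteriorSummary

from conftest import random_genotypes


def make_summary(per_chain_means, beta0=0.0):
    chains = tuple(
        ChainSummary(
            beta0_mean=beta0,
            beta_means=np.asarray(bm, dtype=float),
            sigma0_sq_mean=1.0,
            seed=i,
        )
        for i, bm in enumerate(per_chain_means)
    )
    beta_bar = np.mean([c.beta_means for c in chains], axis=0)
    return PosteriorSummary(chains=chains, beta0_bar=beta0, beta_bar=beta_bar)


class TestConfigValidation:
    def test_burn_in_must_precede_iterations(self):
        with pytest.raises(ValueError):
            ArmConfig(iterations=100, burn_in=100)

    def test_chain_seeds_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            ArmConfig(n_chains=2, seeds=(5, 5))

    def test_non_finite_response_rejected(self):
        X = np.ones((10, 1))
        y = np.full(10, np.nan)
        cfg = ArmConfig(iterations=50, burn_in=10, n_chains=1, seeds=(1,))
        with pytest.raises(ValueError, match="non-finite"):
            m.gibbs_chain(X, y, cfg, 1)


class TestSamplerDeterminismAndLimits:
    def test_identical_seed_bit_identical(self):
        G = random_genotypes(60, 10, seed=0)
        y = np.random.default_rng(1).normal(size=60)
        cfg = ArmConfig(iterations=400, burn_in=100, n_chains=1, seeds=(9,))
        a = m.gibbs_chain(G.values.astype(float), y, cfg, 9)
        b = m.gibbs_chain(G.values.astype(float), y, cfg, 9)
        assert a.beta0_mean == b.beta0_mean
        assert np.array_equal(a.beta_means, b.beta_means)
        assert a.sigma0_sq_mean == b.sigma0_sq_mean

    def test_intercept_only_posterior_centres_on_sample_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(5.0, 2.0, size=100)
        cfg = ArmConfig(iterations=20_000, burn_in=2_000, n_chains=1, seeds=(3,))
        cs = m.gibbs_chain(np.empty((100, 0)), y, cfg, 3)
        # MC standard error of the posterior-mean estimate of beta0
        mc_se = np.sqrt(y.var() / y.size) / np.sqrt((20_000 - 2_000) / 10)
        assert abs(cs.beta0_mean - y.mean()) < 3 * mc_se

    def test_ridge_mode_matches_conjugate_closed_form(self):
        s, v = 0.7, 1.3
        rng = np.random.default_rng(4)
        n, q = 50, 5
        X = np.where(rng.random((n, q)) < 0.5, 1.0, -1.0)
        y = 1.0 + X @ np.array([1.0, -0.5, 0.0, 0.3, 0.0]) + rng.normal(0, np.sqrt(v), n)
        cfg = ArmConfig(
            iterations=40_000, burn_in=5_000, n_chains=1, seeds=(5,),
            fixed_effect_variance=s, fixed_residual_variance=v,
        )
        cs = m.gibbs_chain(X, y, cfg, 5)
        # exact conjugate posterior mean: ridge with an unpenalised intercept
        Z = np.column_stack([np.ones(n), X])
        D = np.diag([0.0] + [1.0 / s] * q)
        closed = np.linalg.solve(Z.T @ Z / v + D, Z.T @ y / v)
        assert abs(cs.beta0_mean - closed[0]) < 0.02
        assert np.max(np.abs(cs.beta_means - closed[1:])) < 0.02

    def test_single_true_effect_recovered(self):
        rng = np.random.default_rng(6)
        n, q = 200, 20
        X = np.where(rng.random((n, q)) < 0.5, 1.0, -1.0)
        beta = np.zeros(q)
        beta[11] = 2.0
        y = X @ beta + rng.normal(0, 1.0, n)
        cfg = ArmConfig(iterations=4_000, burn_in=1_000, n_chains=1, seeds=(7,))
        cs = m.gibbs_chain(X, y, cfg, 7)
        assert int(np.argmax(np.abs(cs.beta_means))) == 11
        assert abs(cs.beta_means[11] - 2.0) < 0.3

    def test_null_shrinkage_tightens_with_sample_size(self):
        p = 50
        maxima = {}
        for n in (100, 400):
            rng = np.random.default_rng(8)
            X = np.where(rng.random((n, p)) < 0.5, 1.0, -1.0)
            y = rng.normal(0, 1.0, n)
            cfg = ArmConfig(iterations=3_000, burn_in=500, n_chains=1, seeds=(11,))
            cs = m.gibbs_chain(X, y, cfg, 11)
            maxima[n] = float(np.max(np.abs(cs.beta_means)))
        assert maxima[400] < maxima[100]

    def test_residual_variance_calibrated_on_null(self):
        rng = np.random.default_rng(9)
        n, p = 300, 100
        X = np.where(rng.random((n, p)) < 0.5, 1.0, -1.0)
        y = rng.normal(0, 1.0, n)
        cfg = ArmConfig(iterations=4_000, burn_in=1_000, n_chains=3, seeds=(1, 2, 3))
        summary = m.run_chains(X, y, cfg)
        s0 = np.mean([c.sigma0_sq_mean for c in summary.chains])
        assert abs(s0 - 1.0) < 0.1


class TestRunChains:
    def test_single_chain_average_is_exact(self):
        G = random_genotypes(50, 5, seed=10)
        y = np.random.default_rng(11).normal(size=50)
        cfg = ArmConfig(iterations=300, burn_in=50, n_chains=1, seeds=(13,))
        summary = m.run_chains(G.values.astype(float), y, cfg)
        assert np.array_equal(summary.beta_bar, summary.chains[0].beta_means)
        assert summary.beta0_bar == summary.chains[0].beta0_mean

    def test_cross_chain_average_is_arithmetic_mean(self):
        G = random_genotypes(50, 4, seed=12)
        y = np.random.default_rng(13).normal(size=50)
        cfg = ArmConfig(iterations=300, burn_in=50, n_chains=3, seeds=(1, 2, 3))
        summary = m.run_chains(G.values.astype(float), y, cfg)
        manual = np.mean([c.beta_means for c in summary.chains], axis=0)
        assert np.array_equal(summary.beta_bar, manual)


class TestSelectQtl:
    def test_all_zero_effects_empty_selection(self):
        s = make_summary([[0.0, 0.0]] * 5)
        assert m.select_qtl(s, m.SelectionRule(0.5)) == []

    def test_consistent_effect_selected(self):
        s = make_summary([[2.1], [2.0], [2.2], [1.9], [2.0]])
        assert m.select_qtl(s, m.SelectionRule(0.5)) == [0]

    def test_alternating_duplicated_signal_selected_nowhere(self):
        # chains alternate which of two interchangeable columns carries the
        # signal — the consensus rule drops both (the instability duplicate
        # markers cause, and why they are pruned at QC)
        s = make_summary([[2, 0], [0, 2], [2, 0], [0, 2], [2, 0]])
        assert m.select_qtl(s, m.SelectionRule(0.5)) == []
        assert m.select_qtl(s, m.SelectionRule(0.5, require_all_chains=False)) == [0, 1]


class TestComputeResiduals:
    def test_zero_effects_give_centred_response(self):
        y = np.arange(10, dtype=float)
        X = np.ones((10, 3))
        s = make_summary([[0.0, 0.0, 0.0]], beta0=y.mean())
        resid = m.compute_residuals(y, X, s)
        assert np.allclose(resid, y - y.mean())

    def test_exact_effects_give_zero_residual(self):
        G = random_genotypes(30, 3, seed=14)
        X = G.values.astype(float)
        beta = np.array([1.0, -2.0, 0.5])
        y = 4.0 + X @ beta
        s = make_summary([beta.tolist()], beta0=4.0)
        assert np.allclose(m.compute_residuals(y, X, s), 0.0)

    def test_column_subset_reconstruction(self):
        G = random_genotypes(30, 3, seed=15)
        X = G.values.astype(float)
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta
        s = make_summary([beta.tolist()], beta0=0.0)
        resid = m.compute_residuals(y, X, s, columns=[0, 2])
        assert np.allclose(resid, y - X[:, [0, 2]] @ beta[[0, 2]])

    def test_shape_mismatch_rejected(self):
        s = make_summary([[0.0, 0.0]])
        with pytest.raises(ValueError):
            m.compute_residuals(np.zeros(5), np.zeros((5, 3)), s)


def test_posterior_summary_serialization(tmp_path):
    from magicqtl.gibbs_arm import write_posterior_summary

    s = make_summary([[1.0, 2.0], [3.0, 4.0]])
    path = tmp_path / "post.tsv"
    write_posterior_summary(s, ["colA", "colB"], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3
    assert lines[1].split("\t")[0] == "colA"
    assert float(lines[1].split("\t")[-1]) == pytest.approx(2.0)
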