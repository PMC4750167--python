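"""Gibbs samplers: conditional-distribution oracles and chain behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from bayesqtl.bayes_alphabet import (
    MCMCConfig,
    ModelData,
    PriorSpec,
    build_model_data,
    common_variance_conditional,
    default_prior,
    derive_scales,
    gebv,
    locus_inclusion_probability,
    locus_variance_conditional,
    residual_variance_conditional,
    run_chain,
    sample_scaled_inv_chi2,
)
from bayesqtl.io_formats import GenotypeMatrix, PhenotypeTable


def _toy_data(rng, n=120, p=60, n_classes=2, h2=0.5):
    """Synthetic training set with known generating values."""
    freqs = rng.uniform(0.1, 0.5, size=p)
    X = rng.binomial(2, freqs, size=(n, p)).astype(float)
    effects = np.zeros(p)
    nz = rng.choice(p, size=max(2, p // 10), replace=False)
    effects[nz] = rng.normal(0, 0.3, size=nz.size)
    g = (X - 2 * freqs) @ effects
    sg = g.std() if g.std() > 0 else 1.0
    g = g / sg
    e = rng.normal(0, np.sqrt((1 - h2) / h2), size=n) * g.std() if h2 < 1 else 0
    cls = np.arange(n) % n_classes
    class_eff = rng.normal(0, 1, size=n_classes)
    y = class_eff[cls] + g + e
    records = pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "generation": 1,
            "hatch": [f"h{c}" for c in cls],
            "y": y,
        }
    )
    map_df = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(p)], "chrom": "1",
         "bp": np.arange(p) * 200_000 + 1000}
    )
    gm = GenotypeMatrix([f"a{i}" for i in range(n)], [f"s{j}" for j in range(p)], X, map_df)
    return gm, PhenotypeTable(records), effects, g


class TestDeriveScales:
    def test_single_snp_closed_form(self):
        prior = PriorSpec(pi=0.0, nu_alpha=4.0, nu_e=10.0,
                          target_genetic_variance=3.0, target_residual_variance=2.0)
        s2a, s2e = derive_scales(prior, np.array([0.5]))
        # sum 2pq = 0.5; S2_a = 3 * (2/4) / 0.5 = 3
        assert s2a == pytest.approx(3.0)
        assert s2e == pytest.approx(2.0 * 8 / 10)

    def test_pi_scales_inverse_one_minus_pi(self):
        base = dict(nu_alpha=4.0, nu_e=10.0, target_genetic_variance=1.0,
                    target_residual_variance=1.0)
        freqs = np.array([0.2, 0.4])
        s0, _ = derive_scales(PriorSpec(pi=0.0, **base), freqs)
        s99, _ = derive_scales(PriorSpec(pi=0.99, **base), freqs)
        assert s99 == pytest.approx(100 * s0)

    def test_monomorphic_panel_rejected(self):
        prior = PriorSpec(pi=0.0, target_genetic_variance=1.0,
                          target_residual_variance=1.0)
        with pytest.raises(ValueError, match="monomorphic"):
            derive_scales(prior, np.array([0.0, 1.0]))


class TestScaledInvChi2:
    def test_sampler_moments_match_closed_form(self):
        rng = np.random.default_rng(0)
        nu, s2 = 5.0, 2.0
        draws = sample_scaled_inv_chi2(rng, nu, s2, size=100_000)
        mean = nu * s2 / (nu - 2)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_conditional_families(self):
        # m = 0 included SNPs: conditional equals the prior
        assert common_variance_conditional(4.0, 1.5, np.array([])) == (4.0, 1.5)
        # m = 1: matches the BayesB single-locus formula
        df_c, sc_c = common_variance_conditional(4.0, 1.5, np.array([0.7]))
        df_b, sc_b = locus_variance_conditional(4.0, 1.5, 0.7)
        assert (df_c, sc_c) == (df_b, sc_b)
        # zero residuals: scale collapses to nu*S2/(nu+n)
        df_e, sc_e = residual_variance_conditional(10.0, 2.0, np.zeros(5))
        assert df_e == 15.0 and sc_e == pytest.approx(20.0 / 15.0)
        # conditional mean grows with alpha^2 (little shrinkage of large effects)
        _, sc_small = locus_variance_conditional(4.0, 1.5, 0.1)
        _, sc_large = locus_variance_conditional(4.0, 1.5, 5.0)
        assert sc_large > sc_small


class TestLocusInclusion:
    # 5-animal fixture with printed dosages and phenotypes
    X5 = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
    Y5 = np.array([-0.8, 0.3, 1.4, 0.1, -0.5])

    def _quadrature_probability(self, pi, sigma2_a, sigma2_e):
        """Oracle: integrate the likelihood over the effect numerically."""
        x = self.X5 - self.X5.mean()
        y = self.Y5

        def lik(alpha):
            r = y - x * alpha
            return np.exp(-0.5 * np.sum(r * r) / sigma2_e)

        m0 = lik(0.0)
        m1, _ = integrate.quad(
            lambda a: lik(a) * stats.norm.pdf(a, 0, np.sqrt(sigma2_a)),
            -np.inf, np.inf,
        )
        return (1 - pi) * m1 / ((1 - pi) * m1 + pi * m0)

    @pytest.mark.parametrize("pi,s2a,s2e", [(0.9, 0.5, 1.0), (0.99, 2.0, 0.3),
                                            (0.5, 0.1, 2.0)])
    def test_matches_numerical_integration(self, pi, s2a, s2e):
        x = self.X5 - self.X5.mean()
        c = float(x @ x)
        r = float(x @ self.Y5)
        p_closed = locus_inclusion_probability(r, c, s2a, s2e, pi)
        p_quad = self._quadrature_probability(pi, s2a, s2e)
        assert p_closed == pytest.approx(p_quad, abs=1e-6)

    def test_sampler_inclusion_frequency_matches_oracle(self):
        """The compiled chain's inclusion rate reproduces the closed form."""
        pi, s2a, s2e = 0.8, 0.5, 1.0
        n = 5
        gm = GenotypeMatrix(
            [f"a{i}" for i in range(n)], ["s0"], self.X5.reshape(-1, 1),
            pd.DataFrame({"snp": ["s0"], "chrom": ["1"], "bp": [1000]}),
        )
        phen = PhenotypeTable(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                          "generation": 1, "hatch": "h1", "y": self.Y5})
        )
        data = build_model_data(gm, phen)
        data.Xf = np.zeros((n, 0))          # no fixed effects: x fully known
        data.fixed_labels = []
        prior = PriorSpec(pi=pi, nu_alpha=4.0, nu_e=10.0,
                          target_genetic_variance=1.0, target_residual_variance=1.0)
        fit = run_chain(
            data, "bayesC", prior=prior,
            mcmc=MCMCConfig(n_iter=60_000, burn_in=1000, seed=5),
            fix_variances=True, sigma2_alpha=s2a, sigma2_e=s2e,
        )
        x = self.X5 - self.X5.mean()
        p_expect = locus_inclusion_probability(float(x @ self.Y5), float(x @ x),
                                               s2a, s2e, pi)
        # with fixed variances the single-locus chain draws i.i.d. indicators
        se = np.sqrt(p_expect * (1 - p_expect) / 59_000)
        assert abs(fit.inclusion_prob[0] - p_expect) < 4 * se


class TestFixedEffects:
    def test_intercept_only_posterior_mean(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.normal(2.0, 1.0, size=n)
        gm = GenotypeMatrix([f"a{i}" for i in range(n)], [],
                            np.zeros((n, 0)), pd.DataFrame(columns=["snp", "chrom", "bp"]))
        phen = PhenotypeTable(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                          "generation": 1, "hatch": "h1", "y": y})
        )
        data = build_model_data(gm, phen)
        fit = run_chain(data, "bayesC0",
                        mcmc=MCMCConfig(n_iter=4000, burn_in=500, seed=2),
                        fix_variances=True, sigma2_alpha=1.0, sigma2_e=1.0)
        assert fit.beta_mean[0] == pytest.approx(y.mean(), abs=4 / np.sqrt(n * 3500))

    def test_two_class_offsets_match_ols(self):
        rng = np.random.default_rng(3)
        gm, phen, _, _ = _toy_data(rng, n=200, p=10, n_classes=2)
        data = build_model_data(gm, phen)
        fit = run_chain(data, "bayesC0",
                        mcmc=MCMCConfig(n_iter=5000, burn_in=1000, seed=4),
                        fix_variances=True, sigma2_alpha=1e-8, sigma2_e=1.0)
        # with effects shrunk to zero the fixed solutions are the class means
        ols, *_ = np.linalg.lstsq(data.Xf, data.y, rcond=None)
        np.testing.assert_allclose(fit.beta_mean, ols, atol=0.05)


class TestChain:
    def test_residual_identity_audit(self):
        rng = np.random.default_rng(5)
        gm, phen, _, _ = _toy_data(rng, n=150, p=80)
        data = build_model_data(gm, phen)
        fit = run_chain(data, "bayesB", mcmc=MCMCConfig(n_iter=800, burn_in=100, seed=6))
        Xc = data.XT.T.astype(np.float64)
        e_fresh = data.y - data.Xf @ fit.final_beta - Xc @ fit.final_alpha
        denom = max(np.abs(fit.final_residual).max(), 1.0)
        assert np.abs(e_fresh - fit.final_residual).max() / denom < 1e-8

    def test_single_stored_sample_bookkeeping(self):
        rng = np.random.default_rng(7)
        gm, phen, _, _ = _toy_data(rng, n=50, p=20)
        data = build_model_data(gm, phen)
        fit = run_chain(data, "bayesC", mcmc=MCMCConfig(n_iter=101, burn_in=100, seed=8))
        assert fit.n_stored == 1
        assert fit.window_samples.shape[0] == 1
        assert np.all((fit.inclusion_prob >= 0) & (fit.inclusion_prob <= 1))

    def test_ridge_oracle_small(self):
        """pi = 0 chain with fixed variances agrees with the joint solve."""
        rng = np.random.default_rng(9)
        gm, phen, _, _ = _toy_data(rng, n=100, p=50)
        data = build_model_data(gm, phen)
        s2a, s2e = 0.01, 0.5
        fit = run_chain(data, "gblup",
                        mcmc=MCMCConfig(n_iter=8000, burn_in=1000, seed=10),
                        fix_variances=True, sigma2_alpha=s2a, sigma2_e=s2e)
        Xc = data.XT.T.astype(np.float64)
        W = np.hstack([data.Xf, Xc])
        lam = np.zeros(W.shape[1])
        lam[data.Xf.shape[1]:] = s2e / s2a
        sol = np.linalg.solve(W.T @ W + np.diag(lam), W.T @ data.y)
        alpha_direct = sol[data.Xf.shape[1]:]
        corr = np.corrcoef(fit.alpha_mean, alpha_direct)[0, 1]
        assert corr > 0.995

    def test_pure_noise_residual_variance_recovery(self):
        rng = np.random.default_rng(11)
        n, sigma2 = 500, 1.7
        y = rng.normal(0, np.sqrt(sigma2), size=n)
        gm = GenotypeMatrix([f"a{i}" for i in range(n)], [],
                            np.zeros((n, 0)), pd.DataFrame(columns=["snp", "chrom", "bp"]))
        phen = PhenotypeTable(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                          "generation": 1, "hatch": "h1", "y": y})
        )
        data = build_model_data(gm, phen)
        prior = PriorSpec(pi=0.0, nu_alpha=4.0, nu_e=10.0,
                          target_genetic_variance=1e-6, target_residual_variance=1.0)
        fit = run_chain(data, "bayesC0", prior=prior,
                        mcmc=MCMCConfig(n_iter=4000, burn_in=500, seed=12))
        assert fit.sigma2_e_samples.mean() == pytest.approx(np.var(y), rel=0.10)

    def test_snp_order_exchangeable(self):
        rng = np.random.default_rng(13)
        gm, phen, _, _ = _toy_data(rng, n=120, p=100)
        data = build_model_data(gm, phen)
        fit1 = run_chain(data, "bayesC", mcmc=MCMCConfig(n_iter=4000, burn_in=1000, seed=14))
        perm = rng.permutation(gm.n_snps)
        gm2 = gm.subset_snps(perm)
        data2 = build_model_data(gm2, phen)
        fit2 = run_chain(data2, "bayesC", mcmc=MCMCConfig(n_iter=4000, burn_in=1000, seed=14))
        g1 = gebv(fit1, gm)
        g2 = gebv(fit2, gm2)
        assert np.corrcoef(g1.to_numpy(), g2.to_numpy())[0, 1] > 0.98

    def test_qtl_window_enriched_on_simdata(self, small_pop):
        from bayesqtl.io_formats import qc_filter

        filt, _ = qc_filter(small_pop.genotypes, small_pop.pedigree)
        data = build_model_data(filt, small_pop.phenotypes)
        fit = run_chain(data, "bayesB", mcmc=MCMCConfig(n_iter=3000, burn_in=500, seed=15))
        wa = fit.window_assignment
        chrom, mb = small_pop.true_window
        label = f"{chrom}_{mb}"
        in_win = [s in set(wa.snps_in_window(label, fit.snp_ids)) for s in fit.snp_ids]
        in_win = np.array(in_win)
        assert in_win.any()
        assert fit.inclusion_prob[in_win].max() > np.median(fit.inclusion_prob)


class TestGEBV:
    def _fitted(self):
        rng = np.random.default_rng(20)
        gm, phen, _, _ = _toy_data(rng, n=80, p=40)
        data = build_model_data(gm, phen)
        fit = run_chain(data, "bayesC", mcmc=MCMCConfig(n_iter=1500, burn_in=500, seed=21))
        return gm, fit

    def test_empty_subset_is_zero(self):
        gm, fit = self._fitted()
        assert (gebv(fit, gm, snp_subset=[]) == 0).all()

    def test_window_additivity(self):
        gm, fit = self._fitted()
        full = gebv(fit, gm)
        half1 = gebv(fit, gm, snp_subset=fit.snp_ids[:20])
        half2 = gebv(fit, gm, snp_subset=fit.snp_ids[20:])
        np.testing.assert_allclose(full, half1 + half2, atol=1e-10)

    def test_identical_genotypes_identical_gebv(self):
        gm, fit = self._fitted()
        twin = GenotypeMatrix(["t1", "t2"], gm.snp_ids,
                              np.vstack([gm.dosages[0], gm.dosages[0]]), gm.map)
        vals = gebv(fit, twin)
        assert vals.iloc[0] == vals.iloc[1]

    def test_unknown_snp_rejected(self):
        gm, fit = self._fitted()
        with pytest.raises(KeyError):
            gebv(fit, gm, snp_subset=["nonexistent"])


def test_default_priors_match_model_conventions():
    assert default_prior("bayesB").pi == 0.99
    assert default_prior("bayesC0").pi == 0.0
    g = default_prior("gblup")
    assert g.nu_alpha == 100.0 and g.nu_e == 100.0
    with pytest.raises(ValueError):
        default_prior("bayesA")
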