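"""Interaction-regression engine vs dense linear-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gweiskit.gweis import (
    DesignSpec,
    RankDeficientError,
    UnderDeterminedError,
    build_design,
    fit_gweis,
    model_cov,
    ols_fit,
    run_gwas,
    run_gweis,
    sandwich_cov,
)
from gweiskit.gweis import test_interaction as interaction_test
from gweiskit.io_genetics import GenotypeMatrix
from gweiskit.simulate import EnvironmentSpec, SimulationConfig, simulate_cohort


def brute_force_sandwich(X, e):
    """Element-wise triple product (X'X)^-1 X' diag(e^2) X (X'X)^-1."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = np.zeros((p, p))
    for i in range(n):
        xi = X[i][:, None]
        meat += e[i] ** 2 * (xi @ xi.T)
    return xtx_inv @ meat @ xtx_inv


class TestBuildDesign:
    def test_column_count_and_order(self, rng):
        n = 30
        y, g, e = rng.normal(size=n), rng.integers(0, 3, n).astype(float), rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        spec = DesignSpec("env", covariates=["c1", "c2"])
        X, yv, mask = build_design(y, g, e, C, spec)
        assert X.shape == (n, 10)  # 4 + 3k with k=2
        assert mask.all()
        np.testing.assert_array_equal(X[:, 3], g * e)
        np.testing.assert_array_equal(X[:, 4:6], C)
        np.testing.assert_array_equal(X[:, 6:8], C * g[:, None])

    def test_listwise_deletion(self, rng):
        n = 25
        y, g = rng.normal(size=n), rng.integers(0, 3, n).astype(float)
        e = rng.normal(size=n)
        e[3] = np.nan
        X, yv, mask = build_design(y, g, e, None, DesignSpec("env"))
        assert X.shape[0] == n - 1 and not mask[3]

    def test_under_determined(self, rng):
        with pytest.raises(UnderDeterminedError):
            build_design(rng.normal(size=3), [0, 1, 2], rng.normal(size=3), None,
                         DesignSpec("env"))


class TestOlsAndSandwich:
    def test_ols_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        beta, resid = ols_fit(X, y)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(beta, oracle, atol=1e-8)
        np.testing.assert_allclose(X.T @ resid, 0, atol=1e-8)  # orthogonality

    def test_exact_fit_gives_zero_residuals(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        _, resid = ols_fit(X, y)
        np.testing.assert_allclose(resid, 0, atol=1e-10)
        np.testing.assert_allclose(sandwich_cov(X, resid), 0, atol=1e-20)

    def test_monomorphic_snp_raises_rank_error(self, rng):
        n = 20
        g = np.zeros(n)
        X, yv, _ = build_design(rng.normal(size=n), g + 1, rng.normal(size=n), None,
                                DesignSpec("env"))
        X[:, 1] = 0.0
        with pytest.raises(RankDeficientError):
            ols_fit(X, yv)

    def test_sandwich_matches_brute_force(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=(15, 3))])
        e = rng.normal(size=15)
        np.testing.assert_allclose(sandwich_cov(X, e), brute_force_sandwich(X, e), atol=1e-10)

    def test_intercept_only_closed_form(self, rng):
        n = 40
        e = rng.normal(size=n)
        X = np.ones((n, 1))
        cov = sandwich_cov(X, e)
        assert cov[0, 0] == pytest.approx((e**2).sum() / n**2, rel=1e-12)

    def test_hc1_scaling(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        e = rng.normal(size=30)
        np.testing.assert_allclose(
            sandwich_cov(X, e, hc1=True), sandwich_cov(X, e) * 30 / 27, atol=1e-12
        )

    def test_agrees_with_statsmodels_hc0(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        beta, resid = ols_fit(X, y)
        smfit = sm.OLS(y, X).fit(cov_type="HC0")
        np.testing.assert_allclose(sandwich_cov(X, resid), smfit.cov_params(), atol=1e-10)
        np.testing.assert_allclose(model_cov(X, resid), sm.OLS(y, X).fit().cov_params(),
                                   atol=1e-10)


class TestInteractionTest:
    def _fit(self, rng, n=200):
        g = rng.integers(0, 3, n).astype(float)
        e = rng.normal(size=n)
        y = 0.2 * g + 0.1 * e + 0.15 * g * e + rng.normal(size=n)
        return fit_gweis(y, g, e, None, DesignSpec("env"), snp="s"), (y, g, e)

    def test_zero_interaction_coefficient_gives_p_one(self, rng):
        fit, _ = self._fit(rng)
        fit.beta[fit.names.index("GxE")] = 0.0
        t, p = interaction_test(fit, DesignSpec("env"))
        assert t == 0.0 and p == 1.0

    def test_allele_flip_preserves_abs_t(self):
        a, (y, g, e) = self._fit(np.random.default_rng(77))
        b = fit_gweis(y, 2.0 - g, e, None, DesignSpec("env"), snp="s")
        assert a.t_gxe == pytest.approx(-b.t_gxe, rel=1e-9)
        assert a.p_gxe == pytest.approx(b.p_gxe, rel=1e-9)

    def test_robust_and_model_p_agree_under_homoscedasticity(self, rng):
        n = 30_000
        g = rng.integers(0, 3, n).astype(float)
        e = rng.normal(size=n)
        y = 0.05 * g * e + rng.normal(size=n)
        fit = fit_gweis(y, g, e, None, DesignSpec("env"))
        t_r, p_r = interaction_test(fit, DesignSpec("env", robust=True))
        t_m, p_m = interaction_test(fit, DesignSpec("env", robust=False))
        assert p_r == pytest.approx(p_m, rel=0.1)

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        n = 300
        g = rng.integers(0, 3, n).astype(float)
        e = rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        y = 0.1 * g * e + C @ [0.3, -0.2] + rng.normal(size=n)
        spec = DesignSpec("env", covariates=["c1", "c2"])
        t1, _ = interaction_test(fit_gweis(y, g, e, C, spec), spec)
        t2, _ = interaction_test(fit_gweis(y, g, e, 10.0 * C + 3.0, spec), spec)
        assert abs(t1) == pytest.approx(abs(t2), abs=1e-6)


class TestScans:
    def _cohort(self, seed=12, **kw):
        cfg = SimulationConfig(
            n_samples=1200, n_snps=100, seed=seed, n_pcs=1, n_centres=2,
            environments=[EnvironmentSpec("e")], **kw,
        )
        return cfg, *simulate_cohort(cfg)

    def test_null_scan_calibration_and_row_count(self):
        cfg, gm, cohort = self._cohort()
        spec = DesignSpec("e", covariates=cfg.covariate_names)
        res = run_gweis(gm, cohort, spec)
        assert len(res) == gm.n_snps
        hits = (res["P_GXE"] < 0.05).sum()
        # binomial(100, 0.05) 99.9% envelope
        assert 0 <= hits <= 13

    def test_sample_order_invariance(self):
        cfg, gm, cohort = self._cohort(seed=21)
        spec = DesignSpec("e", covariates=cfg.covariate_names)
        res1 = run_gweis(gm, cohort, spec)
        perm = np.random.default_rng(0).permutation(cohort.n_samples)
        shuffled = cohort.data.iloc[perm].reset_index(drop=True)
        cohort2 = type(cohort)(shuffled, cohort.phenotype, cohort.environments,
                               list(cohort.covariates), cohort.holdout)
        res2 = run_gweis(gm, cohort2, spec)
        np.testing.assert_allclose(res1["STAT_GXE"], res2["STAT_GXE"], atol=1e-9)

    def test_monomorphic_snp_skipped_not_fatal(self):
        cfg, gm, cohort = self._cohort(seed=5)
        gm.dosages[:, 7] = 1.0
        res = run_gweis(gm, cohort, DesignSpec("e"))
        assert len(res) == gm.n_snps - 1
        assert gm.snps.loc[7, "id"] not in set(res["SNP"])

    def test_missing_environment_column_raises(self):
        _, gm, cohort = self._cohort(seed=6)
        with pytest.raises(KeyError, match="nope"):
            run_gweis(gm, cohort, DesignSpec("nope"))

    def test_gwas_recovers_causal_snp_and_flips_sign(self):
        cfg = SimulationConfig(n_samples=30_000, n_snps=12, seed=33,
                               maf_range=(0.2, 0.5), beta_g={3: 0.08})
        gm, cohort = simulate_cohort(cfg)
        causal = gm.snps.loc[3, "id"]
        res = run_gwas(gm, cohort, [])
        assert res.loc[res["SNP"] == causal, "P_G"].iloc[0] < 5e-8
        null_p = res.loc[res["SNP"] != causal, "P_G"]
        assert (null_p < 0.05).sum() <= 4
        flipped = GenotypeMatrix(gm.sample_ids, 2.0 - gm.dosages, gm.snps.copy(), sex=gm.sex)
        res_f = run_gwas(flipped, cohort, [])
        b1 = res.loc[res["SNP"] == causal, "BETA_G"].iloc[0]
        b2 = res_f.loc[res_f["SNP"] == causal, "BETA_G"].iloc[0]
        assert b1 == pytest.approx(-b2, rel=1e-9)
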