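"""Polygenic score construction, grids, and hold-out evaluation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gweiskit.gweis import RankDeficientError
from gweiskit.io_genetics import CohortTable
from gweiskit.postprocess import ClumpParams
from gweiskit.prs import (
    PrsEvaluation,
    PrsModel,
    adjusted_r2,
    build_threshold_grid,
    evaluate_prs,
    score_iprs,
    score_prs,
    select_best_threshold,
)
from tests.conftest import make_genotypes


def _model(gm, betas, kind="PRS", a1=None, **kw):
    weights = pd.DataFrame({
        "SNP": gm.snps["id"][: len(betas)],
        "A1": a1 if a1 is not None else gm.snps["a1"][: len(betas)],
        "BETA": betas,
        "EAF": np.nanmean(gm.dosages[:, : len(betas)], axis=0) / 2.0,
    })
    return PrsModel(kind=kind, weights=weights, p_threshold=1.0, **kw)


class TestScoring:
    def test_matches_hand_computed_dot_product(self, rng):
        dos = rng.integers(0, 3, size=(4, 5)).astype(float)
        gm = make_genotypes(dos)
        betas = np.array([0.5, -1.0, 0.25, 0.0, 2.0])
        expected = np.array([sum(dos[i, j] * betas[j] for j in range(5)) for i in range(4)])
        np.testing.assert_allclose(score_prs(gm, _model(gm, betas)), expected)

    def test_zero_betas_zero_scores(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(6, 3)).astype(float))
        assert not score_prs(gm, _model(gm, [0.0, 0.0, 0.0])).any()

    def test_single_snp_unit_beta_is_dosage(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(8, 2)).astype(float))
        np.testing.assert_allclose(score_prs(gm, _model(gm, [1.0])), gm.dosages[:, 0])

    def test_allele_mismatch_flips_dosage(self, rng):
        dos = rng.integers(0, 3, size=(5, 1)).astype(float)
        gm = make_genotypes(dos)  # a1='A' counted, a2='G'
        flipped = _model(gm, [1.0], a1=["G"])
        np.testing.assert_allclose(score_prs(gm, flipped), 2.0 - dos[:, 0])
        with pytest.raises(ValueError, match="neither"):
            score_prs(gm, _model(gm, [1.0], a1=["T"]))

    def test_missing_dosage_imputed_at_twice_allele_frequency(self):
        dos = np.array([[0.0], [2.0], [2.0], [np.nan]])
        gm = make_genotypes(dos)
        model = _model(gm, [1.0])  # EAF from non-missing = 4/6
        scores = score_prs(gm, model)
        assert scores[3] == pytest.approx(2.0 * 4 / 6)

    def test_iprs_identities(self, rng):
        dos = rng.integers(0, 3, size=(6, 4)).astype(float)
        gm = make_genotypes(dos)
        betas = rng.normal(size=4)
        E = rng.normal(size=6)
        gxe = _model(gm, betas, kind="iPRS_GxE")
        np.testing.assert_allclose(score_iprs(gm, E, gxe), E * (dos @ betas))
        assert score_iprs(gm, np.zeros(6), gxe)[0] == 0.0
        np.testing.assert_allclose(
            score_iprs(gm, np.ones(6), gxe),
            score_prs(gm, _model(gm, betas)),
        )
        ig = _model(gm, betas, kind="iPRS_G")
        np.testing.assert_allclose(score_iprs(gm, E, ig), score_prs(gm, _model(gm, betas)) * E)

    def test_iprs_g_plus_gxe_adds_main_effect_term(self, rng):
        dos = rng.integers(0, 3, size=(5, 3)).astype(float)
        gm = make_genotypes(dos)
        b_gxe, b_g = rng.normal(size=3), rng.normal(size=3)
        E = rng.normal(size=5)
        model = _model(gm, b_gxe, kind="iPRS_G_plus_GxE")
        model.weights["BETA_G"] = b_g
        np.testing.assert_allclose(
            score_iprs(gm, E, model), E * (dos @ b_gxe) + dos @ b_g
        )


class TestThresholdGrid:
    def _stats(self, gm, p):
        return pd.DataFrame({
            "SNP": gm.snps["id"], "CHR": gm.snps["chr"], "BP": gm.snps["bp"],
            "A1": gm.snps["a1"], "A2": gm.snps["a2"], "ENV": "e", "N": gm.n_samples,
            "BETA_G": 0.05, "SE_G": 0.01, "BETA_E": 0.0, "BETA_GXE": 0.1,
            "SE_GXE": 0.05, "STAT_GXE": 2.0, "P_GXE": p,
        })

    def test_nested_and_complete(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(500, 8)).astype(float))
        p = [0.0005, 0.03, 0.08, 0.15, 0.45, 0.65, 0.85, 0.95]
        models = build_threshold_grid(self._stats(gm, p), gm, kind="iPRS_GxE",
                                      clump_params=ClumpParams(0.2, 250.0))
        assert models[1.0].n_snps == 8  # threshold 1 keeps every index SNP
        sets = [set(models[t].weights["SNP"]) for t in sorted(models)]
        for small, big in zip(sets, sets[1:]):
            assert small <= big
        assert models[0.001].n_snps == 1

    def test_empty_model_at_stringent_threshold(self, rng):
        gm = make_genotypes(rng.integers(0, 3, size=(200, 3)).astype(float))
        models = build_threshold_grid(self._stats(gm, [0.2, 0.4, 0.9]), gm)
        assert models[0.001].n_snps == 0


class TestAdjustedR2:
    def test_closed_forms(self):
        assert adjusted_r2(1.0, 50, 5) == pytest.approx(1.0)
        assert adjusted_r2(0.5, 101, 10) == pytest.approx(1 - 0.5 * 100 / 90)
        assert adjusted_r2(0.3, 60, 0) == pytest.approx(0.3)  # intercept-only penalty


class TestEvaluation:
    def _holdout(self, rng, n=800, score_effect=0.0):
        C = rng.normal(size=(n, 2))
        score = rng.normal(size=n)
        y = C @ [0.3, -0.1] + score_effect * score + rng.normal(size=n)
        data = pd.DataFrame({
            "sample_id": [f"H{i}" for i in range(n)],
            "phenotype": y, "c1": C[:, 0], "c2": C[:, 1],
        })
        table = CohortTable(data, covariates=["c1", "c2"])
        return table, score

    def test_f_test_matches_statsmodels_t_square(self, rng):
        table, score = self._holdout(rng, score_effect=0.1)
        ev = evaluate_prs(table, score, "PRS")
        X = sm.add_constant(np.column_stack([
            table.data[["c1", "c2"]].to_numpy(), score]))
        smfit = sm.OLS(table.data["phenotype"], X).fit()
        assert ev.f_stat == pytest.approx(smfit.tvalues.iloc[-1] ** 2, rel=1e-9)
        assert ev.p_value == pytest.approx(smfit.pvalues.iloc[-1], rel=1e-6)

    def test_delta_matches_partial_correlation_identity(self, rng):
        table, score = self._holdout(rng, score_effect=0.15)
        ev = evaluate_prs(table, score, "PRS")
        y = table.data["phenotype"].to_numpy()
        base = sm.add_constant(table.data[["c1", "c2"]].to_numpy())
        ry = y - base @ np.linalg.lstsq(base, y, rcond=None)[0]
        rs = score - base @ np.linalg.lstsq(base, score, rcond=None)[0]
        partial_r2 = np.corrcoef(ry, rs)[0, 1] ** 2
        n, p0, p1 = len(y), 2, 3
        delta_oracle = (
            adjusted_r2(1 - (1 - partial_r2) * (ry @ ry) / ((y - y.mean()) @ (y - y.mean())), n, p1)
            - adjusted_r2(1 - (ry @ ry) / ((y - y.mean()) @ (y - y.mean())), n, p0)
        )
        assert ev.delta_adj_r2 == pytest.approx(delta_oracle, abs=1e-10)

    def test_score_duplicating_covariate_raises(self, rng):
        table, _ = self._holdout(rng)
        with pytest.raises(RankDeficientError):
            evaluate_prs(table, table.data["c1"].to_numpy(), "PRS")

    def test_leakage_guard(self, rng):
        table, score = self._holdout(rng)
        gm = make_genotypes(rng.integers(0, 3, size=(3, 1)).astype(float))
        model = _model(gm, [0.1], train_fingerprint=frozenset(table.sample_ids[:5]))
        with pytest.raises(ValueError, match="leak"):
            evaluate_prs(table, score, "PRS", model=model)

    def test_iprs_needs_environment_and_main_prs(self, rng):
        table, score = self._holdout(rng)
        with pytest.raises(ValueError, match="main-effect"):
            evaluate_prs(table, score, "iPRS_GxE")


class TestSelectBestThreshold:
    def _ev(self, t, delta):
        return PrsEvaluation(env="e", kind="PRS", p_threshold=t, n_snps=1,
                             delta_adj_r2=delta, f_stat=1.0, p_value=0.5, n=100)

    def test_argmax_with_tie_toward_smaller_threshold(self, rng):
        evs = [self._ev(t, d) for t, d in
               [(0.05, 0.01), (0.1, 0.03), (0.5, 0.03), (1.0, 0.02)]]
        best = select_best_threshold(evs)
        assert best.p_threshold == 0.1
        # randomized fixture vs argmax oracle
        deltas = rng.normal(size=12)
        grid = np.linspace(0.01, 1.0, 12)
        evs = [self._ev(t, d) for t, d in zip(grid, deltas)]
        assert select_best_threshold(evs).p_threshold == grid[np.argmax(deltas)]

    def test_single_point_returns_itself(self):
        ev = self._ev(0.5, -0.002)
        assert select_best_threshold([ev]) is ev
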