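"""Per-SNP interaction regression with heteroscedasticity-robust inference.

For every SNP G and a chosen environment E the engine fits

    Y = b0 + G bG + E bE + G*E bGxE + C' bC + C'G bCxG + C'E bCxE + eps

by ordinary least squares and tests bGxE with a t-statistic whose standard
error comes from the Huber-White sandwich estimator

    (X'X)^-1 X' diag(e_i^2) X (X'X)^-1          (HC0; HC1 = HC0 * n/(n-p))

which permits a distinct residual variance per observation.  Interaction
tests are notoriously sensitive to heteroscedastic residuals -- the
model-based (constant-variance) standard error is anti-conservative there --
and the sandwich form restores type-I error control.  Covariate-by-SNP and
covariate-by-environment product terms are included by default because
covariate *main* effects alone do not stop a confounding covariate
interaction from loading onto the G*E term.

A main-effect GWAS mode (Y ~ 1 + G + C, model-based errors) is provided for
building the comparison polygenic score.

Missing data are handled by per-SNP listwise deletion, so the complete-case n
may differ across SNPs and environments.  Monomorphic or otherwise
rank-deficient design matrices skip the SNP with a logged reason rather than
aborting the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from gweiskit.io_genetics import CohortTable, GenotypeMatrix

__all__ = [
    "RankDeficientError",
    "UnderDeterminedError",
    "DesignSpec",
    "GweisFit",
    "build_design",
    "ols_fit",
    "sandwich_cov",
    "model_cov",
    "fit_gweis",
    "test_interaction",
    "run_gweis",
    "run_gwas",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-8


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full column rank (e.g. monomorphic SNP)."""


class UnderDeterminedError(ValueError):
    """Fewer complete cases than design columns."""


@dataclass
class DesignSpec:
    """What goes into the per-SNP model and how the interaction is tested.

    With k covariates and ``include_covariate_interactions`` the design has
    p = 4 + 3k columns ordered [1, G, E, G*E, C..., C*G..., C*E...]; without
    them p = 4 + k.  ``robust`` selects the sandwich standard error for the
    interaction test (HC0 by default, HC1 with ``hc1``); the reference
    distribution is t with n - p degrees of freedom.
    """

    environment: str
    covariates: Sequence[str] = field(default_factory=list)
    include_covariate_interactions: bool = True
    robust: bool = True
    hc1: bool = False

    def n_columns(self) -> int:
        k = len(self.covariates)
        return 4 + (3 * k if self.include_covariate_interactions else k)

    def column_names(self) -> list[str]:
        names = ["const", "G", "E", "GxE"] + list(self.covariates)
        if self.include_covariate_interactions:
            names += [f"{c}xG" for c in self.covariates]
            names += [f"{c}xE" for c in self.covariates]
        return names


@dataclass
class GweisFit:
    """One fitted SNP-by-environment model.

    Carries all coefficients in design-column order, both the sandwich and
    the model-based coefficient covariance, and the interaction test chosen
    by the spec.
    """

    snp: str
    env: str
    n: int
    names: list
    beta: np.ndarray
    cov_robust: np.ndarray
    cov_model: np.ndarray
    t_gxe: float = np.nan
    p_gxe: float = np.nan

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def se(self, name: str, robust: bool = True) -> float:
        i = self.names.index(name)
        cov = self.cov_robust if robust else self.cov_model
        return float(np.sqrt(cov[i, i]))


def build_design(y, g, e, C, spec: DesignSpec):
    """Assemble (X, y, complete-case mask) for one SNP.

    Rows with any missing value in y, G, E, or the covariates are dropped
    listwise.  Columns are ordered [1, G, E, G*E, C..., C*G..., C*E...].
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    C = np.asarray(C, dtype=float) if C is not None else np.empty((len(y), 0))
    if C.ndim == 1:
        C = C[:, None]
    if not (len(y) == len(g) == len(e) == len(C)):
        raise ValueError("column length mismatch")

    mask = ~(np.isnan(y) | np.isnan(g) | np.isnan(e) | np.isnan(C).any(axis=1))
    yv, gv, ev, Cv = y[mask], g[mask], e[mask], C[mask]
    cols = [np.ones(mask.sum()), gv, ev, gv * ev, Cv]
    if spec.include_covariate_interactions and Cv.shape[1]:
        cols += [Cv * gv[:, None], Cv * ev[:, None]]
    X = np.column_stack(cols)
    if X.shape[0] <= X.shape[1]:
        raise UnderDeterminedError(
            f"{X.shape[0]} complete cases for {X.shape[1]} design columns"
        )
    return X, yv, mask


def ols_fit(X, y):
    """Least-squares coefficients and residuals; raises on rank deficiency."""
    beta, _res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1] or sv[-1] < _RANK_TOL * sv[0]:
        raise RankDeficientError(
            f"design rank {rank} < {X.shape[1]} columns (constant or collinear column)"
        )
    return beta, y - X @ beta


def sandwich_cov(X, residuals, hc1: bool = False) -> np.ndarray:
    """Huber-White covariance (X'X)^-1 X' diag(e^2) X (X'X)^-1.

    HC0 uses raw squared residuals; ``hc1`` rescales by n/(n-p), a
    finite-sample correction that matters only at small n.
    """
    n, p = X.shape
    bread = linalg.inv(X.T @ X)
    Xe = X * residuals[:, None]
    cov = bread @ (Xe.T @ Xe) @ bread
    if hc1:
        cov = cov * n / (n - p)
    return (cov + cov.T) / 2.0


def model_cov(X, residuals) -> np.ndarray:
    """Classical OLS covariance sigma^2 (X'X)^-1 with sigma^2 = RSS/(n-p)."""
    n, p = X.shape
    sigma2 = residuals @ residuals / (n - p)
    return sigma2 * linalg.inv(X.T @ X)


def fit_gweis(y, g, e, C, spec: DesignSpec, snp: str = "", env: str = "") -> GweisFit:
    """Fit the interaction model for one SNP and attach the chosen test."""
    X, yv, _mask = build_design(y, g, e, C, spec)
    beta, resid = ols_fit(X, yv)
    fit = GweisFit(
        snp=snp,
        env=env or spec.environment,
        n=X.shape[0],
        names=spec.column_names(),
        beta=beta,
        cov_robust=sandwich_cov(X, resid, hc1=spec.hc1),
        cov_model=model_cov(X, resid),
    )
    fit.t_gxe, fit.p_gxe = test_interaction(fit, spec)
    return fit


def test_interaction(fit: GweisFit, spec: DesignSpec) -> tuple[float, float]:
    """Two-sided t-test of the G*E coefficient, df = n - p.

    Uses the sandwich standard error when ``spec.robust``, else the
    model-based one.
    """
    se = fit.se("GxE", robust=spec.robust)
    t = fit.coef("GxE") / se
    df = fit.n - len(fit.names)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _aligned_arrays(gm: GenotypeMatrix, cohort: CohortTable):
    """Intersect samples and align cohort rows to genotype order.

    Returns (genotype matrix restricted to shared samples, cohort rows in the
    same order).  Samples outside the cohort (e.g. the hold-out set when
    scanning the training split) are simply dropped.
    """
    order = pd.Index(cohort.data["sample_id"]).get_indexer(gm.sample_ids)
    keep = order >= 0
    if not keep.any():
        raise ValueError("no overlap between genotype and cohort samples")
    if not keep.all():
        gm = gm.subset_samples(np.where(keep)[0])
    return gm, cohort.data.iloc[order[keep]].reset_index(drop=True)


def run_gweis(gm: GenotypeMatrix, cohort: CohortTable, spec: DesignSpec) -> pd.DataFrame:
    """Scan every SNP against one environment; one summary row per SNP.

    Deterministic given inputs and invariant to sample order.  SNPs whose
    design is rank deficient (monomorphic genotype, constant interaction
    column) are skipped with a logged reason.
    """
    gm, table = _aligned_arrays(gm, cohort)
    y = table[cohort.phenotype].to_numpy(dtype=float)
    if spec.environment not in table.columns:
        raise KeyError(f"environment column {spec.environment!r} absent from cohort table")
    e = table[spec.environment].to_numpy(dtype=float)
    C = table[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else None

    a_eff = "a1" if gm.effect_allele == "a1" else "a2"
    a_oth = "a2" if gm.effect_allele == "a1" else "a1"
    rows, skipped = [], 0
    for j in range(gm.n_snps):
        meta = gm.snps.iloc[j]
        try:
            fit = fit_gweis(y, gm.dosages[:, j], e, C, spec, snp=meta["id"])
        except (RankDeficientError, UnderDeterminedError) as err:
            skipped += 1
            logger.info("skipping %s: %s", meta["id"], err)
            continue
        rows.append({
            "SNP": meta["id"], "CHR": meta["chr"], "BP": int(meta["bp"]),
            "A1": meta[a_eff], "A2": meta[a_oth],
            "ENV": spec.environment, "N": fit.n,
            "BETA_G": fit.coef("G"), "SE_G": fit.se("G", robust=spec.robust),
            "BETA_E": fit.coef("E"),
            "BETA_GXE": fit.coef("GxE"), "SE_GXE": fit.se("GxE", robust=spec.robust),
            "STAT_GXE": fit.t_gxe, "P_GXE": fit.p_gxe,
        })
    logger.info("gweis(%s): %d SNPs analysed, %d skipped", spec.environment, len(rows), skipped)
    return pd.DataFrame(rows, columns=[
        "SNP", "CHR", "BP", "A1", "A2", "ENV", "N",
        "BETA_G", "SE_G", "BETA_E", "BETA_GXE", "SE_GXE", "STAT_GXE", "P_GXE",
    ])


def run_gwas(
    gm: GenotypeMatrix,
    cohort: CohortTable,
    covariates: Optional[Sequence[str]] = None,
    robust: bool = False,
) -> pd.DataFrame:
    """Main-effect scan Y ~ 1 + G + C with model-based errors by default."""
    covariates = list(covariates if covariates is not None else cohort.covariates)
    gm, table = _aligned_arrays(gm, cohort)
    y = table[cohort.phenotype].to_numpy(dtype=float)
    C = table[covariates].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))

    a_eff = "a1" if gm.effect_allele == "a1" else "a2"
    a_oth = "a2" if gm.effect_allele == "a1" else "a1"
    rows, skipped = [], 0
    for j in range(gm.n_snps):
        meta = gm.snps.iloc[j]
        g = gm.dosages[:, j]
        mask = ~(np.isnan(y) | np.isnan(g) | np.isnan(C).any(axis=1))
        X = np.column_stack([np.ones(mask.sum()), g[mask], C[mask]])
        try:
            if X.shape[0] <= X.shape[1]:
                raise UnderDeterminedError(f"{X.shape[0]} cases, {X.shape[1]} columns")
            beta, resid = ols_fit(X, y[mask])
        except (RankDeficientError, UnderDeterminedError) as err:
            skipped += 1
            logger.info("skipping %s: %s", meta["id"], err)
            continue
        cov = sandwich_cov(X, resid) if robust else model_cov(X, resid)
        se = float(np.sqrt(cov[1, 1]))
        t = float(beta[1] / se)
        p = 2.0 * stats.t.sf(abs(t), X.shape[0] - X.shape[1])
        rows.append({
            "SNP": meta["id"], "CHR": meta["chr"], "BP": int(meta["bp"]),
            "A1": meta[a_eff], "A2": meta[a_oth], "N": X.shape[0],
            "BETA_G": float(beta[1]), "SE_G": se, "STAT_G": t, "P_G": float(p),
        })
    logger.info("gwas: %d SNPs analysed, %d skipped", len(rows), skipped)
    return pd.DataFrame(rows, columns=[
        "SNP", "CHR", "BP", "A1", "A2", "N", "BETA_G", "SE_G", "STAT_G", "P_G",
    ])
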