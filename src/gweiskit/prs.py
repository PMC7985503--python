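"""Main-effect and interaction-based polygenic scores (PRS / iPRS).

Four scores over a clumped, p-value-thresholded SNP set with per-SNP weights:

    PRS_i            = sum_j G_ij b_j^G           (GWAS main-effect betas)
    iPRS_i^G         = PRS_i * E_i                (main-effect score times E)
    iPRS_i^GxE       = E_i * sum_j G_ij b_j^GxE   (interaction betas)
    iPRS_i^{G+GxE}   = sum_j G_ij (E_i b_j^GxE + b_j^G)

Predictive ability is the increment in *adjusted* R2 of a full over a nested
covariate-only linear model in a hold-out sample, with the nested comparison
tested by an F-test.  For the interaction scores the covariate-only model
already contains the environment, the main-effect PRS, and their interactions
with the base covariates, so the iPRS is credited only with signal beyond
every main effect; the main-effect PRS used there comes from the GWAS, not
from the interaction scan's main-effect betas, because a SNP set pruned on
interaction p-values underestimates the genome-wide main-effect contribution.

Weights carry a fingerprint of the training samples they were estimated in;
evaluating in a hold-out set that overlaps training is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gweiskit.gweis import ols_fit
from gweiskit.io_genetics import CohortTable, GenotypeMatrix
from gweiskit.postprocess import ClumpParams, clump

__all__ = [
    "PRS_KINDS",
    "DEFAULT_GRID",
    "PrsModel",
    "PrsEvaluation",
    "score_prs",
    "score_iprs",
    "build_threshold_grid",
    "adjusted_r2",
    "evaluate_prs",
    "select_best_threshold",
]

PRS_KINDS = ("PRS", "iPRS_G", "iPRS_GxE", "iPRS_G_plus_GxE")

# p-value threshold grid for score construction: .001, .05, .1, .2, ..., .9, 1
DEFAULT_GRID = (0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass
class PrsModel:
    """A weighted SNP set at one p-value threshold.

    ``weights`` columns: SNP, A1 (effect allele of the beta), BETA (the
    scoring weight: b^G for kind 'PRS', b^GxE for the interaction kinds),
    BETA_G (additionally, for 'iPRS_G_plus_GxE'), EAF (training effect-allele
    frequency, used to mean-impute missing dosages as PLINK --score does).
    """

    kind: str
    weights: pd.DataFrame
    p_threshold: float
    source: str = ""
    train_fingerprint: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.kind not in PRS_KINDS:
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.weights["SNP"].duplicated().any():
            raise ValueError("duplicate SNP ids in score weights")
        if not np.isfinite(self.weights["BETA"]).all():
            raise ValueError("non-finite scoring weight")

    @property
    def n_snps(self) -> int:
        return len(self.weights)


@dataclass
class PrsEvaluation:
    """Nested-model comparison of one score in the hold-out sample."""

    env: Optional[str]
    kind: str
    p_threshold: float
    n_snps: int
    delta_adj_r2: float
    f_stat: float
    p_value: float
    n: int


def _aligned_dosages(gm: GenotypeMatrix, model: PrsModel) -> tuple[np.ndarray, np.ndarray]:
    """Dosage columns of the model SNPs, flipped onto the model's effect allele.

    Missing genotypes are imputed with twice the training effect-allele
    frequency.  Returns (n_samples x n_model_snps dosages, beta-sign flip
    mask is already applied to the dosages, not the betas).
    """
    col = {sid: j for j, sid in enumerate(gm.snps["id"])}
    a_eff = "a1" if gm.effect_allele == "a1" else "a2"
    a_oth = "a2" if gm.effect_allele == "a1" else "a1"
    out = np.empty((gm.n_samples, len(model.weights)))
    eaf = model.weights["EAF"].to_numpy(dtype=float) if "EAF" in model.weights else np.full(len(model.weights), np.nan)
    for k, row in enumerate(model.weights.itertuples(index=False)):
        if row.SNP not in col:
            raise KeyError(f"score SNP {row.SNP!r} absent from genotypes")
        j = col[row.SNP]
        counted = gm.snps.iloc[j][a_eff]
        other = gm.snps.iloc[j][a_oth]
        d = gm.dosages[:, j]
        if row.A1 == counted:
            pass
        elif row.A1 == other:
            d = 2.0 - d
        else:
            raise ValueError(
                f"SNP {row.SNP!r}: model effect allele {row.A1!r} matches "
                f"neither genotype allele ({counted!r}/{other!r})"
            )
        if np.isnan(d).any():
            fill = 2.0 * eaf[k] if np.isfinite(eaf[k]) else np.nanmean(d)
            d = np.where(np.isnan(d), fill, d)
        out[:, k] = d
    return out, model.weights["BETA"].to_numpy(dtype=float)


def score_prs(gm: GenotypeMatrix, model: PrsModel) -> np.ndarray:
    """Per-sample weighted allele count sum_j G_ij beta_j."""
    if model.n_snps == 0:
        return np.zeros(gm.n_samples)
    D, beta = _aligned_dosages(gm, model)
    return D @ beta


def score_iprs(gm: GenotypeMatrix, E, model: PrsModel) -> np.ndarray:
    """Interaction-based scores; ``E`` is the per-sample environment value."""
    E = np.asarray(E, dtype=float)
    if len(E) != gm.n_samples:
        raise ValueError("environment length mismatch")
    if model.kind == "iPRS_G":
        return score_prs(gm, model) * E
    if model.kind == "iPRS_GxE":
        return E * score_prs(gm, model)  # BETA are the interaction betas
    if model.kind == "iPRS_G_plus_GxE":
        if model.n_snps == 0:
            return np.zeros(gm.n_samples)
        D, beta_gxe = _aligned_dosages(gm, model)
        beta_g = model.weights["BETA_G"].to_numpy(dtype=float)
        return (D * E[:, None]) @ beta_gxe + D @ beta_g
    raise ValueError(f"{model.kind!r} is not an interaction score kind")


def build_threshold_grid(
    stats_df: pd.DataFrame,
    gm: GenotypeMatrix,
    kind: str = "PRS",
    grid: Sequence[float] = DEFAULT_GRID,
    clump_params: ClumpParams = ClumpParams(r2_threshold=0.2, window_kb=250.0),
    source: str = "",
) -> dict[float, PrsModel]:
    """One :class:`PrsModel` per grid threshold, from clumped index SNPs.

    ``gm`` must be the *training* genotype matrix: it supplies the LD for
    clumping, the effect-allele frequencies for missing-dosage imputation,
    and the leakage fingerprint.  Interaction kinds weight by BETA_GXE/P_GXE,
    the main-effect kind by BETA_G and its test.  Models are nested along
    the grid.
    """
    interaction = kind in ("iPRS_GxE", "iPRS_G_plus_GxE")
    p_col = "P_GXE" if interaction else ("P_GXE" if "P_GXE" in stats_df else "P_G")
    beta_col = "BETA_GXE" if interaction else "BETA_G"
    index_ids = clump(stats_df, gm, clump_params, p_column=p_col)
    idx = stats_df.set_index("SNP").loc[index_ids]

    with np.errstate(invalid="ignore"):
        eaf_all = np.nanmean(gm.dosages, axis=0) / 2.0
    eaf = dict(zip(gm.snps["id"], eaf_all))
    fingerprint = frozenset(gm.sample_ids)

    models = {}
    for t in grid:
        sub = idx.loc[idx[p_col] <= t]
        weights = pd.DataFrame({
            "SNP": sub.index,
            "A1": sub["A1"].to_numpy(),
            "BETA": sub[beta_col].to_numpy(dtype=float),
            "EAF": [eaf[s] for s in sub.index],
        })
        if kind == "iPRS_G_plus_GxE":
            weights["BETA_G"] = sub["BETA_G"].to_numpy(dtype=float)
        models[t] = PrsModel(
            kind=kind, weights=weights.reset_index(drop=True),
            p_threshold=t, source=source, train_fingerprint=fingerprint,
        )
    return models


def adjusted_r2(r2: float, n: int, p_predictors: int) -> float:
    """Adjusted R2 = 1 - (1 - R2)(n - 1)/(n - p - 1), p excluding the intercept."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_predictors - 1)


def _fit_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(adjusted R2, residual sum of squares) of an OLS fit with intercept."""
    _beta, resid = ols_fit(X, y)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return adjusted_r2(r2, X.shape[0], X.shape[1] - 1), rss


def evaluate_prs(
    holdout: CohortTable,
    score: np.ndarray,
    kind: str,
    env: Optional[str] = None,
    covariates: Optional[Sequence[str]] = None,
    prs_main: Optional[np.ndarray] = None,
    model: Optional[PrsModel] = None,
    p_threshold: float = np.nan,
    n_snps: int = 0,
) -> PrsEvaluation:
    """Incremental adjusted R2 of a score over its covariate-only model.

    For kind 'PRS' the covariate-only model is Y ~ 1 + C.  For the iPRS kinds
    it is Y ~ 1 + C + PRS + E + C*PRS + C*E (``prs_main`` required), so the
    score is tested strictly beyond gene and environment main effects and
    their covariate interactions.  Complete cases only; the F-test of the
    nested comparison has (1, n - p_full) degrees of freedom.
    """
    if kind not in PRS_KINDS:
        raise ValueError(f"unknown score kind {kind!r}")
    if model is not None and model.train_fingerprint:
        overlap = model.train_fingerprint & set(holdout.sample_ids)
        if overlap:
            raise ValueError(
                f"hold-out overlaps the score's training samples ({len(overlap)} ids): "
                "evaluation would leak training information"
            )
    covariates = list(covariates if covariates is not None else holdout.covariates)
    y = holdout.data[holdout.phenotype].to_numpy(dtype=float)
    C = holdout.data[covariates].to_numpy(dtype=float)
    score = np.asarray(score, dtype=float)

    parts = [C]
    if kind != "PRS":
        if env is None or prs_main is None:
            raise ValueError("iPRS evaluation needs the environment and the main-effect PRS")
        E = holdout.data[env].to_numpy(dtype=float)
        prs_main = np.asarray(prs_main, dtype=float)
        parts += [prs_main[:, None], E[:, None], C * prs_main[:, None], C * E[:, None]]
    base = np.column_stack([np.ones(len(y))] + parts)
    full = np.column_stack([base, score])

    mask = ~(np.isnan(y) | np.isnan(full).any(axis=1))
    yv, base_v, full_v = y[mask], base[mask], full[mask]
    n = int(mask.sum())
    if n <= full_v.shape[1]:
        raise ValueError("too few complete hold-out cases for the full model")

    adj0, rss0 = _fit_r2(base_v, yv)
    adj1, rss1 = _fit_r2(full_v, yv)  # raises RankDeficientError if score is collinear
    df2 = n - full_v.shape[1]
    f = (rss0 - rss1) / (rss1 / df2)
    p = float(stats.f.sf(f, 1, df2))
    return PrsEvaluation(
        env=env, kind=kind, p_threshold=p_threshold, n_snps=n_snps,
        delta_adj_r2=adj1 - adj0, f_stat=float(f), p_value=p, n=n,
    )


def select_best_threshold(evaluations: Sequence[PrsEvaluation]) -> PrsEvaluation:
    """The grid point with the greatest incremental adjusted R2.

    Ties break toward the smallest p-value threshold (the sparser score).
    """
    if not evaluations:
        raise ValueError("no evaluations to select from")
    return min(evaluations, key=lambda ev: (-ev.delta_adj_r2, ev.p_threshold))
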