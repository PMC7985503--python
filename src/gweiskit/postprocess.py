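"""QC filtering, LD clumping, inflation diagnostics, layered Bonferroni.

The multiple-testing arithmetic is layered the way a multi-environment scan
needs it: a per-analysis correction (genome-wide 5e-8 for SNPs, 0.05 / number
of tests for gene-level counts), an extra division by the number of
environments scanned, and 0.05 / environments / 2 for the two families of
interaction-based polygenic scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gweiskit.io_genetics import GenotypeMatrix

__all__ = [
    "ClumpParams",
    "ThresholdScheme",
    "qc_filter",
    "ld_r2",
    "clump",
    "genomic_lambda",
    "bonferroni_threshold",
    "qq_table",
]

logger = logging.getLogger(__name__)

# median of the chi-square(1 df) distribution, the null genomic-control anchor
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


@dataclass(frozen=True)
class ClumpParams:
    """Greedy clumping parameters: r2 < 0.2 within 250 kb is the score-building
    default; r2 < 0.8 is the looser criterion for reporting independent hits."""

    r2_threshold: float = 0.2
    window_kb: float = 250.0
    p_threshold: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass(frozen=True)
class ThresholdScheme:
    """Inputs to the layered Bonferroni arithmetic."""

    base_alpha: float = 0.05
    n_tests: int = 1
    n_environments: int = 25
    n_models: int = 2

    def __post_init__(self):
        if min(self.n_tests, self.n_environments, self.n_models) < 1:
            raise ValueError("all counts must be >= 1")


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    info_min: float = 0.9,
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= 1%, missingness <= 5%, imputation info >= 0.9.

    SNPs without an info score (genotyped or synthetic data) pass the info
    filter trivially; that is logged.  Idempotent by construction.
    """
    maf = gm.maf()
    miss = gm.missingness()
    info = gm.snps["info"].to_numpy(dtype=float)
    no_info = np.isnan(info)
    if no_info.any():
        logger.info("qc_filter: %d SNPs lack an info score; info filter waived", no_info.sum())
    keep = (maf >= maf_min) & (miss <= miss_max) & (no_info | (info >= info_min))
    logger.info(
        "qc_filter: kept %d / %d SNPs (maf>=%g, miss<=%g, info>=%g)",
        keep.sum(), gm.n_snps, maf_min, miss_max, info_min,
    )
    return gm.subset_snps(np.where(keep)[0])


def ld_r2(dosage_i, dosage_j) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete samples; invariant to allele flips
    (x -> 2 - x).  Returns NaN when either column is constant, where r2 is
    undefined.
    """
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    stats_df: pd.DataFrame,
    gm: GenotypeMatrix,
    params: ClumpParams,
    p_column: str = "P_GXE",
) -> list[str]:
    """Greedy LD clumping; returns index-SNP ids ordered by ascending p.

    Repeatedly takes the lowest-p unassigned SNP with p <= p_threshold as an
    index SNP, then assigns to it every unassigned SNP on the same chromosome
    within +-window_kb whose dosage r2 with the index is >= r2_threshold.
    Index SNPs therefore mutually satisfy r2 < r2_threshold within the
    window.  Ties in p break on (chr, bp), then id, so the output is
    invariant to input row order.
    """
    missing = set(stats_df["SNP"]) - set(gm.snps["id"])
    if missing:
        raise KeyError(f"SNPs in summary stats absent from genotypes: {sorted(missing)[:5]}")
    col = {sid: j for j, sid in enumerate(gm.snps["id"])}

    cand = stats_df.loc[stats_df[p_column] <= params.p_threshold].copy()
    cand["_chrord"] = [23 if c == "X" else int(c) for c in cand["CHR"].astype(str)]
    cand = cand.sort_values(
        by=[p_column, "_chrord", "BP", "SNP"], kind="mergesort"
    ).reset_index(drop=True)

    window_bp = params.window_kb * 1000.0
    assigned = np.zeros(len(cand), dtype=bool)
    index_snps: list[str] = []
    for i in range(len(cand)):
        if assigned[i]:
            continue
        idx_row = cand.iloc[i]
        index_snps.append(idx_row["SNP"])
        assigned[i] = True
        gi = gm.dosages[:, col[idx_row["SNP"]]]
        near = (
            ~assigned
            & (cand["_chrord"].to_numpy() == idx_row["_chrord"])
            & (np.abs(cand["BP"].to_numpy() - idx_row["BP"]) <= window_bp)
        )
        for k in np.where(near)[0]:
            r2 = ld_r2(gi, gm.dosages[:, col[cand.iloc[k]["SNP"]]])
            if not np.isnan(r2) and r2 >= params.r2_threshold:
                assigned[k] = True
    return index_snps


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed chi2(1) over the null median.

    p-values are transformed to chi-square(1 df) quantiles; lambda near 1
    indicates a calibrated scan, lambda > 1 inflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_table(p_values, n_points: int = 200) -> pd.DataFrame:
    """Expected vs observed -log10 p at evenly spaced order-statistic ranks."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    n = len(p)
    ranks = np.unique(np.linspace(0, n - 1, min(n_points, n)).astype(int))
    expected = (ranks + 0.5) / n
    return pd.DataFrame({
        "expected_neglog10p": -np.log10(expected),
        "observed_neglog10p": -np.log10(np.maximum(p[ranks], np.finfo(float).tiny)),
    })


def bonferroni_threshold(scheme: ThresholdScheme, layer: str) -> float:
    """Layered Bonferroni thresholds.

    'per-analysis'      : base_alpha / n_tests (e.g. 0.05 over the gene count;
                          for SNPs use base_alpha = 5e-8 with n_tests = 1).
    'cross-environment' : the per-analysis value further divided by the number
                          of environments scanned.
    'iprs'              : 0.05 / n_environments / n_models, correcting the
                          polygenic-score evaluations for environments and for
                          the two interaction-score families.
    """
    per_analysis = scheme.base_alpha / scheme.n_tests
    if layer == "per-analysis":
        return per_analysis
    if layer == "cross-environment":
        return per_analysis / scheme.n_environments
    if layer == "iprs":
        return 0.05 / scheme.n_environments / scheme.n_models
    raise ValueError(f"unknown correction layer {layer!r}")
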