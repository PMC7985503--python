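"""Synthetic cohort generator for the interaction-scan pipeline.

Generates, from a single master seed, the pieces the analysis assumes:

* genotypes in Hardy-Weinberg equilibrium with tunable block LD -- each SNP is
  the sum of two haplotype alleles obtained by thresholding latent Gaussians
  at the minor-allele-frequency quantile; within an LD block the latents share
  a common factor with loading sqrt(rho), across blocks they are independent;
* typed environments (continuous, ordinal with k levels, bounded counts),
  optionally heritable: a configurable fraction h2_E of the latent environment
  variance comes from a causal SNP set, so an apparent GxE can be made partly
  GxG on purpose;
* covariates shaped like a biobank's: an age analogue, a sex indicator,
  PC-like standard normals, and assessment-centre indicator columns;
* a phenotype built term by term from the interaction regression model
  Y = b0 + G bG + E bE + G*E bGxE + C'bC + C'G bCxG + C'E bCxE + eps,
  with homoscedastic noise or multiplicative heteroscedasticity
  sigma_i^2 = sigma^2 * exp(theta * E_i), and optionally rank-binned onto the
  0-12 sum-score scale of the questionnaire phenotype;
* a reproducible train / hold-out split.

Everything is deterministic given ``SimulationConfig.seed``: the master seed
spawns independent named substreams per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gweiskit.io_genetics import CohortTable, GenotypeMatrix

__all__ = [
    "EnvironmentSpec",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_phenotype",
    "simulate_cohort",
    "split_holdout",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """One environment column: its measurement type and genetic architecture.

    ``kind`` is 'continuous', 'ordinal' (with ``levels`` in 2-7), or 'count'
    (integers 0..``max_count``); ordinal/count values come from equal-frequency
    quantile binning of the latent continuous environment.  ``h2`` in [0, 1)
    is the fraction of latent variance explained by ``causal_snps``.
    """

    name: str
    kind: str = "continuous"
    levels: int = 5
    max_count: int = 3
    h2: float = 0.0
    causal_snps: tuple = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "count"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.h2 > 0 and not self.causal_snps:
            raise ValueError("heritable environment needs a causal SNP set")


@dataclass
class SimulationConfig:
    """Generative model for one synthetic cohort.

    Effect sizes are sparse mappings: ``beta_g[snp_index]``,
    ``beta_e[env_name]``, ``beta_gxe[(snp_index, env_name)]``,
    ``beta_c[cov_name]``, ``beta_cxg[(cov_name, snp_index)]``,
    ``beta_cxe[(cov_name, env_name)]``.  Unlisted terms are zero, so the
    default configuration is a global null.  ``theta`` > 0 switches on
    multiplicative heteroscedasticity driven by ``het_env`` (first
    environment when unset).
    """

    n_samples: int = 2000
    n_snps: int = 200
    maf_range: tuple = (0.01, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    bp_spacing: int = 10_000
    missing_rate: float = 0.0
    environments: Sequence[EnvironmentSpec] = field(
        default_factory=lambda: (EnvironmentSpec("env1"),)
    )
    n_pcs: int = 2
    n_centres: int = 3
    beta_g: Mapping = field(default_factory=dict)
    beta_e: Mapping = field(default_factory=dict)
    beta_gxe: Mapping = field(default_factory=dict)
    beta_c: Mapping = field(default_factory=dict)
    beta_cxg: Mapping = field(default_factory=dict)
    beta_cxe: Mapping = field(default_factory=dict)
    intercept: float = 0.0
    sigma: float = 1.0
    theta: float = 0.0
    het_env: Optional[str] = None
    phenotype_kind: str = "linear"  # or "likert12"
    holdout_n: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for idx in self.beta_g:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")
        for idx, _env in self.beta_gxe:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")

    @property
    def covariate_names(self) -> list[str]:
        names = ["age", "sex"]
        names += [f"pc{i + 1}" for i in range(self.n_pcs)]
        names += [f"centre_{i + 2}" for i in range(self.n_centres - 1)]
        return names

    def streams(self) -> dict:
        """Named independent RNG substreams spawned from the master seed."""
        names = ["genotypes", "environments", "covariates", "phenotype", "holdout"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypeMatrix:
    """Draw a HWE genotype matrix with equicorrelated block LD.

    One minor-allele frequency is drawn per LD block (uniform over
    ``maf_range``) and shared within it, so rho = 1 yields identical dosage
    columns.  A haplotype allele at SNP j of sample i is
    1{ sqrt(rho) u_i + sqrt(1-rho) z_ij < Phi^-1(maf) }, giving marginal
    Bernoulli(maf) alleles in HWE and pairwise latent correlation rho within
    the block.  The counted (effect) allele is the minor allele.
    """
    rng = rng or config.streams()["genotypes"]
    n, m = config.n_samples, config.n_snps
    block = max(1, config.ld_block_size)
    rho = config.ld_rho
    dosages = np.empty((n, m))
    mafs = np.empty(m)
    for start in range(0, m, block):
        width = min(block, m - start)
        maf = rng.uniform(*config.maf_range)
        mafs[start : start + width] = maf
        thresh = stats.norm.ppf(maf)
        haps = []
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            indep = rng.standard_normal((n, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
            haps.append((latent < thresh).astype(float))
        dosages[:, start : start + width] = haps[0] + haps[1]
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    width_id = len(str(m))
    snps = pd.DataFrame({
        "id": [f"snp{i + 1:0{width_id}d}" for i in range(m)],
        "chr": "1",
        "bp": 1_000_000 + np.arange(m) * config.bp_spacing,
        "a1": "A",
        "a2": "G",
    })
    sample_ids = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)
    sex = np.array(["unknown"] * n, dtype=object)
    return GenotypeMatrix(sample_ids, dosages, snps, sex=sex, effect_allele="a1")


def _filled(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages (generative use only, never in analysis)."""
    if not np.isnan(dosages).any():
        return dosages
    col_mean = np.nanmean(dosages, axis=0)
    out = dosages.copy()
    idx = np.where(np.isnan(out))
    out[idx] = np.take(col_mean, idx[1])
    return out


def simulate_environment(spec: EnvironmentSpec, G: GenotypeMatrix, rng) -> np.ndarray:
    """Draw one environment column, optionally heritable.

    The latent environment is s*(X gamma) + e with gamma standard normal on
    the causal dosages, s chosen so Var(genetic)/Var(latent) = h2 and the
    latent has unit variance.  Continuous environments return the latent;
    ordinal/count environments are equal-frequency quantile-binned onto their
    integer code range (first level 0).
    """
    n = G.n_samples
    e = rng.standard_normal(n)
    if spec.h2 > 0:
        X = _filled(G.dosages[:, list(spec.causal_snps)])
        gamma = rng.standard_normal(X.shape[1])
        g = X @ gamma
        sd = g.std()
        if sd == 0:
            raise ValueError("causal SNPs for the environment are constant")
        latent = np.sqrt(spec.h2) * (g - g.mean()) / sd + np.sqrt(1 - spec.h2) * e
    else:
        latent = e
    if spec.kind == "continuous":
        return latent
    k = spec.levels if spec.kind == "ordinal" else spec.max_count + 1
    # equal-frequency binning by rank: codes 0..k-1
    ranks = stats.rankdata(latent, method="ordinal") - 1
    return np.floor(ranks * k / n).astype(int).astype(float)


def simulate_phenotype(
    config: SimulationConfig,
    G: GenotypeMatrix,
    E: Mapping[str, np.ndarray],
    C: pd.DataFrame,
    rng=None,
) -> np.ndarray:
    """Build the phenotype from the interaction model, term by term.

    Noise is N(0, sigma^2) when theta = 0, otherwise
    N(0, sigma^2 exp(theta * E_het)).  With ``phenotype_kind='likert12'`` the
    linear phenotype is rank-binned into 13 equal-frequency integer levels
    0-12, the sum-score scale of a 12-item dichotomous questionnaire.
    """
    rng = rng or config.streams()["phenotype"]
    n = config.n_samples
    dos = _filled(G.dosages)
    y = np.full(n, config.intercept, dtype=float)
    for j, b in config.beta_g.items():
        y += dos[:, j] * b
    for env, b in config.beta_e.items():
        y += E[env] * b
    for (j, env), b in config.beta_gxe.items():
        y += dos[:, j] * E[env] * b
    for cov, b in config.beta_c.items():
        y += C[cov].to_numpy() * b
    for (cov, j), b in config.beta_cxg.items():
        y += C[cov].to_numpy() * dos[:, j] * b
    for (cov, env), b in config.beta_cxe.items():
        y += C[cov].to_numpy() * E[env] * b

    if config.theta != 0.0:
        het = config.het_env or config.environments[0].name
        sd = config.sigma * np.exp(0.5 * config.theta * E[het])
    else:
        sd = config.sigma
    y = y + rng.standard_normal(n) * sd

    if config.phenotype_kind == "likert12":
        ranks = stats.rankdata(y, method="ordinal") - 1
        y = np.floor(ranks * 13 / n).astype(float)
    elif config.phenotype_kind != "linear":
        raise ValueError(f"unknown phenotype kind {config.phenotype_kind!r}")
    return y


def _simulate_covariates(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_samples
    cols = {
        "age": rng.normal(57.0, 8.0, n).round(1),
        "sex": rng.integers(0, 2, n).astype(float),
    }
    for i in range(config.n_pcs):
        cols[f"pc{i + 1}"] = rng.standard_normal(n)
    centre = rng.integers(0, config.n_centres, n)
    for i in range(config.n_centres - 1):
        cols[f"centre_{i + 2}"] = (centre == i + 1).astype(float)
    return pd.DataFrame(cols)


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, CohortTable]:
    """Generate the full cohort: genotypes plus a phenotype/environment table.

    The returned :class:`CohortTable` carries the hold-out flag for
    ``config.holdout_n`` randomly chosen samples.
    """
    streams = config.streams()
    G = simulate_genotypes(config, streams["genotypes"])
    C = _simulate_covariates(config, streams["covariates"])
    E = {
        spec.name: simulate_environment(spec, G, streams["environments"])
        for spec in config.environments
    }
    y = simulate_phenotype(config, G, E, C, streams["phenotype"])

    data = pd.DataFrame({"sample_id": G.sample_ids, "phenotype": y})
    for name, col in E.items():
        data[name] = col
    data = pd.concat([data, C], axis=1)
    data["holdout"] = False
    if config.holdout_n:
        pick = streams["holdout"].choice(config.n_samples, config.holdout_n, replace=False)
        data.loc[pick, "holdout"] = True

    env_schemas = {}
    for spec in config.environments:
        if spec.kind == "ordinal":
            env_schemas[spec.name] = {"kind": "ordinal", "levels": spec.levels}
        elif spec.kind == "count":
            env_schemas[spec.name] = {"kind": "count", "max": spec.max_count}
        else:
            env_schemas[spec.name] = {"kind": "continuous"}
    cohort = CohortTable(
        data=data,
        phenotype="phenotype",
        environments=env_schemas,
        covariates=config.covariate_names,
        holdout="holdout",
    )
    return G, cohort


def split_holdout(cohort: CohortTable, holdout_n: int, seed: int) -> tuple[CohortTable, CohortTable]:
    """Disjoint, exhaustive, seed-reproducible train / hold-out split."""
    n = cohort.n_samples
    if holdout_n > n:
        raise ValueError("holdout_n exceeds cohort size")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n, holdout_n, replace=False)
    flag = np.zeros(n, dtype=bool)
    flag[pick] = True
    data = cohort.data.copy()
    data[cohort.holdout] = flag
    flagged = CohortTable(
        data=data,
        phenotype=cohort.phenotype,
        environments=cohort.environments,
        covariates=list(cohort.covariates),
        holdout=cohort.holdout,
    )
    return flagged.training(), flagged.holdout_set()
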