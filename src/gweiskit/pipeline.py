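"""End-to-end orchestration: simulate -> QC -> scans -> clump -> scores -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML), writes every
stage output into a run directory, and records a manifest with the config
hash, master seed, package version, and per-stage row counts.  All randomness
descends from the single master seed, so re-running an identical config
reproduces every output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import gweiskit
from gweiskit.gweis import DesignSpec, run_gwas, run_gweis
from gweiskit.io_genetics import (
    CohortTable,
    GenotypeMatrix,
    write_cohort,
    write_plink,
    write_summary_stats,
)
from gweiskit.postprocess import (
    ClumpParams,
    ThresholdScheme,
    bonferroni_threshold,
    clump,
    genomic_lambda,
    qc_filter,
    qq_table,
)
from gweiskit.prs import (
    DEFAULT_GRID,
    build_threshold_grid,
    evaluate_prs,
    score_iprs,
    score_prs,
    select_best_threshold,
)
from gweiskit.simulate import EnvironmentSpec, SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    environments: Sequence[str] = field(default_factory=list)
    covariates: Sequence[str] = field(default_factory=list)
    robust: bool = True
    hc1: bool = False
    clump_r2: float = 0.2
    clump_kb: float = 250.0
    prs_grid: Sequence[float] = DEFAULT_GRID
    prs_kinds: Sequence[str] = ("PRS", "iPRS_G", "iPRS_GxE")
    scheme: ThresholdScheme = field(default_factory=ThresholdScheme)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, default_out=str(Path(path).with_suffix("")) + "_run")

    @classmethod
    def from_dict(cls, raw: dict, default_out: str = "run") -> "RunConfig":
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            envs = [EnvironmentSpec(**e) for e in s.pop("environments", [])]
            for key in ("beta_gxe", "beta_cxg", "beta_cxe"):
                if key in s:
                    s[key] = {_pair_key(k): v for k, v in s[key].items()}
            if "beta_g" in s:
                s["beta_g"] = {int(k): v for k, v in s["beta_g"].items()}
            sim = SimulationConfig(
                environments=envs or (EnvironmentSpec("env1"),),
                seed=raw.get("seed", 0),
                **s,
            )
        scheme_raw = raw.get("thresholds", {})
        return cls(
            out_dir=raw.get("out_dir", default_out),
            seed=raw.get("seed", 0),
            simulation=sim,
            environments=raw.get("environments", [e.name for e in sim.environments] if sim else []),
            covariates=raw.get("covariates", sim.covariate_names if sim else []),
            robust=raw.get("robust", True),
            hc1=raw.get("hc1", False),
            clump_r2=raw.get("clump", {}).get("r2", 0.2),
            clump_kb=raw.get("clump", {}).get("kb", 250.0),
            prs_grid=tuple(raw.get("prs", {}).get("grid", DEFAULT_GRID)),
            prs_kinds=tuple(raw.get("prs", {}).get("kinds", ("PRS", "iPRS_G", "iPRS_GxE"))),
            scheme=ThresholdScheme(
                base_alpha=scheme_raw.get("base_alpha", 5e-8),
                n_tests=scheme_raw.get("n_tests", 1),
                n_environments=scheme_raw.get("n_environments", 25),
                n_models=scheme_raw.get("n_models", 2),
            ),
        )

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pair_key(key: str):
    """'3|env1' -> (3, 'env1') for SNPxENV betas; 'age|3' / 'age|env1' for CxG/CxE."""
    a, b = str(key).split("|")
    try:
        return (int(a), b)
    except ValueError:
        try:
            return (a, int(b))
        except ValueError:
            return (a, b)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def run_pipeline(
    config: RunConfig,
    genotypes: Optional[GenotypeMatrix] = None,
    cohort: Optional[CohortTable] = None,
) -> Path:
    """Execute every stage; returns the run directory.

    Inputs come either from ``config.simulation`` or as pre-loaded
    ``genotypes``/``cohort``.  Any stage failure halts the run with the stage
    name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": gweiskit.__version__,
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        if config.simulation is not None:
            rec = stage("simulate")
            genotypes, cohort = simulate_cohort(config.simulation)
            write_plink(genotypes, out / "genotypes")
            write_cohort(cohort, out / "cohort.tsv")
            rec.update(n_samples=genotypes.n_samples, n_snps=genotypes.n_snps)
        if genotypes is None or cohort is None:
            raise ValueError("no input: provide a simulation config or genotypes+cohort")

        rec = stage("qc")
        genotypes = qc_filter(genotypes)
        rec.update(n_snps_pass=genotypes.n_snps)

        train = cohort.training()
        holdout = cohort.holdout_set()
        train_ids = pd.Index(genotypes.sample_ids).isin(set(train.sample_ids))
        gm_train = genotypes.subset_samples(np.where(train_ids)[0])
        gm_holdout = genotypes.subset_samples(np.where(~train_ids)[0])

        rec = stage("gweis")
        gweis_stats = {}
        for env in config.environments:
            spec = DesignSpec(
                environment=env, covariates=config.covariates,
                robust=config.robust, hc1=config.hc1,
            )
            res = run_gweis(gm_train, train, spec)
            write_summary_stats(res, out / f"gweis_{env}.tsv")
            gweis_stats[env] = res
            rec[env] = len(res)

        rec = stage("gwas")
        gwas_stats = run_gwas(gm_train, train, config.covariates)
        write_summary_stats(gwas_stats, out / "gwas.tsv")
        rec["n_rows"] = len(gwas_stats)

        rec = stage("clump")
        cp = ClumpParams(r2_threshold=config.clump_r2, window_kb=config.clump_kb)
        for env, res in gweis_stats.items():
            ids = clump(res, gm_train, cp, p_column="P_GXE")
            pd.Series(ids, name="SNP").to_csv(out / f"clump_{env}.tsv", sep="\t", index=False)
            rec[env] = len(ids)

        if len(holdout.data) and config.prs_kinds:
            rec = stage("prs")
            evals = _prs_stage(config, gm_train, gm_holdout, holdout, gwas_stats, gweis_stats)
            evals.to_csv(out / "prs_evaluations.tsv", sep="\t", index=False)
            rec["n_evaluations"] = len(evals)

        rec = stage("report")
        report_text = report(out, config, gweis_stats, gwas_stats)
        rec["written"] = True
    except Exception as err:
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else "init"
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        raise RuntimeError(f"pipeline halted at stage {manifest['failed_stage']!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return out


def _prs_stage(config, gm_train, gm_holdout, holdout, gwas_stats, gweis_stats) -> pd.DataFrame:
    cp = ClumpParams(r2_threshold=config.clump_r2, window_kb=config.clump_kb)
    rows = []

    prs_models = build_threshold_grid(
        gwas_stats, gm_train, kind="PRS", grid=config.prs_grid, clump_params=cp, source="GWAS",
    )
    prs_evals = {}
    for t, model in prs_models.items():
        if model.n_snps == 0:
            logger.info("PRS threshold %g: empty model, skipped", t)
            continue
        sc = score_prs(gm_holdout, model)
        ev = evaluate_prs(holdout, sc, "PRS", covariates=config.covariates,
                          model=model, p_threshold=t, n_snps=model.n_snps)
        prs_evals[t] = (model, sc, ev)
        rows.append(_eval_row(ev))
    if not prs_evals:
        return pd.DataFrame(rows)
    best = select_best_threshold([ev for _, _, ev in prs_evals.values()])
    best_model, best_prs_scores, _ = prs_evals[best.p_threshold]

    for env in config.environments:
        E = holdout.data[env].to_numpy(dtype=float)
        for kind in config.prs_kinds:
            if kind == "PRS":
                continue
            if kind == "iPRS_G":
                sc = best_prs_scores * E
                ev = evaluate_prs(holdout, sc, kind, env=env, covariates=config.covariates,
                                  prs_main=best_prs_scores, model=best_model,
                                  p_threshold=best.p_threshold, n_snps=best_model.n_snps)
                rows.append(_eval_row(ev))
                continue
            models = build_threshold_grid(
                gweis_stats[env], gm_train, kind=kind, grid=config.prs_grid,
                clump_params=cp, source=f"GWEIS({env})",
            )
            kind_evals = []
            for t, model in models.items():
                if model.n_snps == 0:
                    logger.info("%s(%s) threshold %g: empty model, skipped", kind, env, t)
                    continue
                sc = score_iprs(gm_holdout, E, model)
                ev = evaluate_prs(holdout, sc, kind, env=env, covariates=config.covariates,
                                  prs_main=best_prs_scores, model=model,
                                  p_threshold=t, n_snps=model.n_snps)
                kind_evals.append(ev)
                rows.append(_eval_row(ev))
    return pd.DataFrame(rows)


def _eval_row(ev) -> dict:
    return {
        "kind": ev.kind, "env": ev.env if ev.env else "-",
        "p_threshold": ev.p_threshold, "n_snps": ev.n_snps,
        "delta_adj_r2": ev.delta_adj_r2, "F": ev.f_stat, "p": ev.p_value, "n": ev.n,
    }


def report(run_dir: Path, config: RunConfig, gweis_stats: dict, gwas_stats: pd.DataFrame) -> str:
    """Summarise a run: significant SNPs at both correction layers, lambda,
    QQ tables, and the score-evaluation grid.  Idempotent."""
    run_dir = Path(run_dir)
    per_analysis = bonferroni_threshold(config.scheme, "per-analysis")
    cross_env = bonferroni_threshold(config.scheme, "cross-environment")
    lines = [
        "# Run report",
        f"config hash: {config.config_hash()}  seed: {config.seed}",
        "",
        f"Thresholds: per-analysis {per_analysis:.3g}; "
        f"cross-environment {cross_env:.3g}; "
        f"iPRS {bonferroni_threshold(config.scheme, 'iprs'):.3g}",
        "",
        "| environment | n SNPs | lambda | sig @ per-analysis | sig @ cross-env |",
        "|---|---|---|---|---|",
    ]
    sig_rows = []
    for env, res in gweis_stats.items():
        lam = genomic_lambda(res["P_GXE"])
        n1 = int((res["P_GXE"] < per_analysis).sum())
        n2 = int((res["P_GXE"] < cross_env).sum())
        lines.append(f"| {env} | {len(res)} | {lam:.3f} | {n1} | {n2} |")
        qq_table(res["P_GXE"]).to_csv(run_dir / f"qq_{env}.tsv", sep="\t", index=False)
        sig = res.loc[res["P_GXE"] < per_analysis]
        for _, r in sig.iterrows():
            sig_rows.append({**r[["SNP", "CHR", "BP", "ENV", "BETA_GXE", "P_GXE"]].to_dict()})
    pd.DataFrame(sig_rows, columns=["SNP", "CHR", "BP", "ENV", "BETA_GXE", "P_GXE"]).to_csv(
        run_dir / "significant_snps.tsv", sep="\t", index=False
    )
    lam_gwas = genomic_lambda(gwas_stats["P_G"]) if len(gwas_stats) else float("nan")
    lines += ["", f"GWAS: {len(gwas_stats)} SNPs, lambda {lam_gwas:.3f}"]
    ev_path = run_dir / "prs_evaluations.tsv"
    if ev_path.exists():
        lines += ["", "Score evaluations: see prs_evaluations.tsv"]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
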