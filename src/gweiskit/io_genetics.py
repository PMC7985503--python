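"""Genotype, cohort, and summary-statistics I/O.

Genotypes live in PLINK 1 binary triples (.bed/.bim/.fam, SNP-major).  The
in-memory container is :class:`GenotypeMatrix`: a samples x SNPs matrix of
additive allele counts (dosages) with per-SNP metadata.  Missing genotypes are
``NaN`` -- an out-of-band sentinel, never a numeric code that could leak into
arithmetic.

The dosage of a SNP counts a configurable *effect allele*.  By default we count
bim A1 (00 in the 2-bit code means homozygous A1, hence dosage 2).  The counted
allele is always recorded in summary-statistic output, so sign conventions are
explicit rather than implied.  Interaction p-values are invariant to an allele
flip; coefficient signs are not.

Cohort tables (phenotype, typed environments, covariates, hold-out flag) and
summary statistics travel as tab-separated text with a header row, '.' decimal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlinkFormatError",
    "SchemaError",
    "SnpRecord",
    "GenotypeMatrix",
    "CohortTable",
    "read_plink",
    "write_plink",
    "read_cohort",
    "write_cohort",
    "SUMMARY_COLUMNS",
    "GWAS_COLUMNS",
    "write_summary_stats",
    "read_summary_stats",
]

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit genotype codes (PLINK 1 .bed): dosage of A1 for codes 0b00..0b11.
# 00 -> hom A1 (2 copies), 01 -> missing, 10 -> het, 11 -> hom A2 (0 copies).
_CODE_TO_A1_COUNT = np.array([2.0, np.nan, 1.0, 0.0])

_SEX_TO_FAM = {"male": 1, "female": 2, "unknown": 0}
_FAM_TO_SEX = {1: "male", 2: "female"}


class PlinkFormatError(ValueError):
    """Raised when a .bed file violates the binary format contract."""


class SchemaError(ValueError):
    """Raised when a cohort table does not conform to its declared schema."""


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one SNP: map position, alleles, and QC statistics."""

    id: str
    chr: str
    bp: int
    effect_allele: str
    other_allele: str
    maf: float = np.nan
    missingness: float = np.nan
    info: float = np.nan


def _normalise_chrom(c) -> str:
    """Chromosome labels: 1-22 as digits, X accepted as '23' or 'X'."""
    s = str(c).strip()
    return "X" if s in ("23", "X", "x") else s


def _chrom_order(c: str) -> int:
    return 23 if c == "X" else int(c)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids : array of str, unique, ordered as rows of ``dosages``.
    dosages : float array (n_samples, n_snps); non-missing autosomal entries
        are in {0, 1, 2}, male X entries in {0, 2}; missing is NaN.
    snps : DataFrame with columns id, chr, bp, a1, a2, info (NaN when the
        imputation quality score is absent, as for array or synthetic data).
    sex : array of {'male', 'female', 'unknown'} per sample.
    effect_allele : which bim allele the dosage counts ('a1' or 'a2').
    """

    sample_ids: np.ndarray
    dosages: np.ndarray
    snps: pd.DataFrame
    sex: np.ndarray = None
    effect_allele: str = "a1"

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.sex is None:
            self.sex = np.full(len(self.sample_ids), "unknown", dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} snps"
            )
        self.snps = self.snps.reset_index(drop=True)
        self.snps["chr"] = [_normalise_chrom(c) for c in self.snps["chr"]]
        if "info" not in self.snps.columns:
            self.snps["info"] = np.nan

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency from non-missing dosages.

        The effect-allele frequency is mean(dosage)/2 over non-missing calls
        (male X calls contribute a single allele coded 0/2, consistent with
        the haploid coding convention); the MAF folds it onto (0, 0.5].
        """
        with np.errstate(invalid="ignore"):
            eaf = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(eaf, 1.0 - eaf)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def records(self) -> list[SnpRecord]:
        maf, miss = self.maf(), self.missingness()
        a_eff = "a1" if self.effect_allele == "a1" else "a2"
        a_oth = "a2" if self.effect_allele == "a1" else "a1"
        return [
            SnpRecord(
                id=row.id,
                chr=row.chr,
                bp=int(row.bp),
                effect_allele=getattr(row, a_eff),
                other_allele=getattr(row, a_oth),
                maf=maf[i],
                missingness=miss[i],
                info=row.info,
            )
            for i, row in enumerate(self.snps.itertuples(index=False))
        ]

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            dosages=self.dosages[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            sex=self.sex,
            effect_allele=self.effect_allele,
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[index],
            dosages=self.dosages[index, :],
            snps=self.snps.copy(),
            sex=self.sex[index],
            effect_allele=self.effect_allele,
        )


# ---------------------------------------------------------------------------
# PLINK binary triple
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None, effect_allele="a1") -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam triple into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to ``bed_path`` with the extension
    swapped.  The .bed must be SNP-major (mode byte 0x01).  Dosages count
    ``effect_allele`` ('a1', the PLINK/bim default here, or 'a2').
    """
    bed_path = os.fspath(bed_path)
    stem = bed_path[:-4] if bed_path.endswith(".bed") else bed_path
    bim_path = bim_path or stem + ".bim"
    fam_path = fam_path or stem + ".fam"

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chr", "id", "cm", "bp", "a1", "a2"],
        dtype={"chr": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)

    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not SNP-major (mode {raw[2:3]!r})")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size {len(raw)} != expected {expected} "
            f"for {n} samples x {m} snps"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # Expand each byte into four 2-bit codes, sample order from the LSB pair up.
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_A1_COUNT[codes[:, :n]].T  # (n, m), counts A1
    if effect_allele == "a2":
        dosages = 2.0 - dosages
    elif effect_allele != "a1":
        raise ValueError("effect_allele must be 'a1' or 'a2'")

    sex = np.array([_FAM_TO_SEX.get(s, "unknown") for s in fam["sex"]], dtype=object)
    snps = bim[["id", "chr", "bp", "a1", "a2"]].copy()
    return GenotypeMatrix(
        sample_ids=fam["iid"].to_numpy(dtype=object),
        dosages=dosages,
        snps=snps,
        sex=sex,
        effect_allele=effect_allele,
    )


def write_plink(gm: GenotypeMatrix, prefix) -> tuple[str, str, str]:
    """Write ``gm`` as ``prefix``.bed/.bim/.fam; returns the three paths.

    Inverse of :func:`read_plink` on (dosages, sample ids, snp metadata).
    """
    prefix = os.fspath(prefix)
    bed_path, bim_path, fam_path = (prefix + e for e in (".bed", ".bim", ".fam"))

    a1_counts = gm.dosages if gm.effect_allele == "a1" else 2.0 - gm.dosages
    valid = np.isnan(a1_counts) | np.isin(a1_counts, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("dosages must be hard calls in {0,1,2} or missing")

    n, m = a1_counts.shape
    # dosage-of-A1 -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    codes = np.where(
        np.isnan(a1_counts), 1, np.where(a1_counts == 2, 0, np.where(a1_counts == 1, 2, 3))
    ).astype(np.uint8).T  # (m, n)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        body |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR + body.tobytes())

    bim = gm.snps.copy()
    bim_out = pd.DataFrame({
        "chr": ["23" if c == "X" else c for c in bim["chr"]],
        "id": bim["id"], "cm": 0, "bp": bim["bp"],
        "a1": bim["a1"], "a2": bim["a2"],
    })
    bim_out.to_csv(bim_path, sep="\t", header=False, index=False)

    fam = pd.DataFrame({
        "fid": gm.sample_ids, "iid": gm.sample_ids, "pat": 0, "mat": 0,
        "sex": [_SEX_TO_FAM.get(s, 0) for s in gm.sex], "pheno": -9,
    })
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_ENV_KINDS = ("continuous", "ordinal", "count")


@dataclass
class CohortTable:
    """Per-sample phenotype, typed environments, covariates, hold-out flag.

    ``data`` holds one row per sample; ``environments`` maps each environment
    column to its declared type, e.g. ``{"kind": "ordinal", "levels": 5}`` or
    ``{"kind": "count", "max": 3}``.  Ordinal and count environments carry
    integer codes (first level 0) but are *analysed* as continuous.
    """

    data: pd.DataFrame
    phenotype: str = "phenotype"
    environments: Mapping[str, Mapping] = field(default_factory=dict)
    covariates: Sequence[str] = field(default_factory=list)
    holdout: str = "holdout"

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        if self.data["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample ids in cohort table")
        for name, spec in self.environments.items():
            kind = spec.get("kind")
            if kind not in _ENV_KINDS:
                raise SchemaError(f"environment {name!r}: unknown type {kind!r}")
            col = self.data[name]
            vals = col.dropna()
            if kind == "ordinal":
                hi = spec["levels"] - 1
            elif kind == "count":
                hi = spec["max"]
            else:
                continue
            if len(vals) and not np.array_equal(vals, vals.astype(int)):
                raise SchemaError(f"environment {name!r}: non-integer codes")
            if len(vals) and (vals.min() < 0 or vals.max() > hi):
                raise SchemaError(
                    f"environment {name!r}: codes outside declared range [0, {hi}]"
                )
        if self.holdout not in self.data.columns:
            self.data[self.holdout] = False

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy(dtype=object)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def training(self) -> "CohortTable":
        return self._mask(~self.data[self.holdout].astype(bool))

    def holdout_set(self) -> "CohortTable":
        return self._mask(self.data[self.holdout].astype(bool))

    def _mask(self, mask) -> "CohortTable":
        return CohortTable(
            data=self.data.loc[np.asarray(mask)].reset_index(drop=True),
            phenotype=self.phenotype,
            environments=self.environments,
            covariates=list(self.covariates),
            holdout=self.holdout,
        )


def read_cohort(path, schema: Mapping) -> CohortTable:
    """Read a tab-separated cohort table under an explicit column schema.

    ``schema`` keys: ``sample_id``, ``phenotype``, ``environments`` (name ->
    type spec), ``covariates`` (list), optional ``holdout``.  Blank cells
    become missing.  A column present in the file but absent from the schema
    is an error: every analysed column must have a declared type.
    """
    df = pd.read_csv(path, sep="\t", dtype={schema["sample_id"]: str})
    declared = (
        {schema["sample_id"], schema["phenotype"]}
        | set(schema.get("environments", {}))
        | set(schema.get("covariates", []))
        | {schema.get("holdout", "holdout")}
    )
    undeclared = set(df.columns) - declared
    if undeclared:
        raise SchemaError(f"columns without a declared type: {sorted(undeclared)}")
    df = df.rename(columns={schema["sample_id"]: "sample_id"})
    return CohortTable(
        data=df,
        phenotype=schema["phenotype"],
        environments=schema.get("environments", {}),
        covariates=list(schema.get("covariates", [])),
        holdout=schema.get("holdout", "holdout"),
    )


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "ENV", "N",
    "BETA_G", "SE_G", "BETA_E", "BETA_GXE", "SE_GXE", "STAT_GXE", "P_GXE",
]
GWAS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "N", "BETA_G", "SE_G", "STAT_G", "P_G"]


def _format_p(p: float) -> str:
    """At least 3 significant digits; scientific notation below 1e-4."""
    if pd.isna(p):
        return "NA"
    return f"{p:.3e}" if 0 < p < 1e-4 else f"{p:.4g}"


def write_summary_stats(results: pd.DataFrame, path) -> None:
    """Write per-SNP results as TSV in the fixed column order.

    The GWEIS dialect carries the environment name and interaction test; the
    GWAS dialect (detected by the absence of an ENV column) drops the
    interaction columns and carries the main-effect test instead.
    """
    cols = SUMMARY_COLUMNS if "ENV" in results.columns else GWAS_COLUMNS
    out = results.reindex(columns=cols).copy()
    pcol = "P_GXE" if "ENV" in results.columns else "P_G"
    out[pcol] = [_format_p(p) for p in out[pcol]]
    for c in out.columns:
        if c.startswith(("BETA", "SE", "STAT")):
            out[c] = [("NA" if pd.isna(v) else f"{v:.6g}") for v in out[c]]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    if "ENV" in df.columns:
        df["ENV"] = df["ENV"].astype(str)
    return df
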