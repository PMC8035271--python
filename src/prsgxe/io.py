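"""File readers/writers, cohort assembly, and pipeline configuration.

Formats: uncompressed VCF 4.2 (GT or DS) or dosage TSV for genotypes;
tab-delimited summary statistics with configurable column names (an OR column
is log-transformed when no beta column is present); tab-delimited cohort and
result tables with "NA" as the missing token.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import GenotypeMatrix, PE_ITEMS

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CohortAssemblyReport",
    "read_sumstats",
    "read_genotypes",
    "read_cohort",
    "write_cohort",
    "assemble_cohort",
    "write_prs_model",
    "write_scores",
]

SUMSTATS_DEFAULT_COLUMNS = {
    "snp": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2",
    "beta": "BETA", "odds_ratio": "OR", "p": "P",
    "freq": "FRQ_A1", "info": "INFO",
}


@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end pipeline."""

    sumstats_path: str = ""
    genotypes_path: str = ""
    variants_path: str = ""
    cohort_path: str = ""
    output_dir: str = "results"
    min_call_rate: float = 0.95
    min_hwe_p: float = 1e-10
    min_af: float = 0.001
    min_info: float = 0.8
    p_thresholds: tuple[float, ...] = (0.05, 0.005, 0.0005, 0.00005)
    prune_r2: float = 0.5
    prune_window: int = 500_000
    exposures: tuple[str, ...] = ("ever_binary", "risk_units")
    covariate_names: tuple[str, ...] = ("sex", "pc1")
    categorical_covariates: tuple[str, ...] = ()
    joint_fdr: bool = False
    include_covariate_interactions: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_call_rate", "min_hwe_p", "min_af", "min_info", "prune_r2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"config key {name} must be in [0, 1]")
        if not self.p_thresholds:
            raise ValueError("config key p_thresholds must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("p_thresholds", "exposures", "covariate_names", "categorical_covariates"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class CohortAssemblyReport:
    n_input: int = 0
    n_excluded_dx: int = 0
    n_missing_exposure: int = 0
    n_missing_all_outcomes: int = 0
    n_final: int = 0

    def check(self) -> None:
        total = (self.n_excluded_dx + self.n_missing_exposure
                 + self.n_missing_all_outcomes + self.n_final)
        if total != self.n_input:
            raise AssertionError("assembly report counts do not reconcile")


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(
    path: str | Path, column_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a tab-delimited GWAS summary-statistic file into typed records.

    ``column_map`` maps canonical roles (snp, chrom, pos, effect_allele,
    other_allele, beta, odds_ratio, p, freq, info) to the file's column names.
    When no beta column exists the OR column is log-transformed.  Rows with
    unparseable or out-of-domain numerics (p outside (0, 1]) are dropped and
    counted.
    """
    cmap = {**SUMSTATS_DEFAULT_COLUMNS, **(column_map or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    have_beta = cmap["beta"] in raw.columns
    have_or = cmap["odds_ratio"] in raw.columns
    if not have_beta and not have_or:
        raise ValueError("sumstats must contain a beta or an odds-ratio column")

    n_in = len(raw)
    df = pd.DataFrame(
        {
            "SNP": raw[cmap["snp"]],
            "CHR": pd.to_numeric(raw[cmap["chrom"]], errors="coerce"),
            "BP": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "A1": raw[cmap["effect_allele"]].str.upper(),
            "A2": raw[cmap["other_allele"]].str.upper(),
            "P": pd.to_numeric(raw[cmap["p"]], errors="coerce"),
        }
    )
    if have_beta:
        df["BETA"] = pd.to_numeric(raw[cmap["beta"]], errors="coerce")
    else:
        or_vals = pd.to_numeric(raw[cmap["odds_ratio"]], errors="coerce")
        df["BETA"] = np.log(or_vals.where(or_vals > 0))
    df["FRQ_A1"] = (
        pd.to_numeric(raw[cmap["freq"]], errors="coerce")
        if cmap["freq"] in raw.columns else np.nan
    )
    df["INFO"] = (
        pd.to_numeric(raw[cmap["info"]], errors="coerce")
        if cmap["info"] in raw.columns else 1.0
    )
    ok = (
        df["CHR"].notna() & df["BP"].notna() & df["BETA"].notna()
        & df["P"].notna() & (df["P"] > 0) & (df["P"] <= 1)
    )
    dropped = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    df["CHR"] = df["CHR"].astype(int)
    df["BP"] = df["BP"].astype(int)
    df["OR"] = np.exp(df["BETA"])
    return df, {"n_input": n_in, "n_dropped": dropped, "n_kept": len(df)}


# ---------------------------------------------------------------------------
# genotypes


def _read_vcf(path: str | Path) -> tuple[GenotypeMatrix, dict[str, int]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    meta_rows = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        ds = None
        try:
            raw = var.format("DS")
            if raw is not None:
                ds = np.asarray(raw, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None:
            gts = var.genotype.array()  # (n, ploidy+1): alleles..., phased flag
            alleles = gts[:, :-1]
            miss = (alleles < 0).any(axis=1)
            ds = alleles.clip(min=0).sum(axis=1).astype(float)
            ds[miss] = np.nan
        else:
            ds = np.where(ds < 0, np.nan, ds)
            # cyvcf2 encodes missing DS as huge sentinel in some files
            ds = np.where(ds > 2.5, np.nan, ds)
        info = var.INFO.get("R2")
        if info is None:
            info = var.INFO.get("INFO", 1.0)
        chrom = var.CHROM.removeprefix("chr")
        meta_rows.append(
            {
                "id": var.ID or f"{chrom}:{var.POS}",
                "chrom": chrom, "pos": var.POS,
                "ref": var.REF, "alt": var.ALT[0], "info": float(info),
            }
        )
        dosage_cols.append(ds)
    if not meta_rows:
        raise ValueError("VCF contains no usable biallelic records")
    meta = pd.DataFrame(meta_rows)
    try:
        meta["chrom"] = pd.to_numeric(meta["chrom"])
    except (ValueError, TypeError):
        pass  # non-numeric contigs (X, MT) stay as strings
    geno = GenotypeMatrix(
        dosages=np.column_stack(dosage_cols), variants=meta, samples=samples
    )
    return geno, {"n_multiallelic_skipped": n_multiallelic, "n_variants": len(meta)}


def _read_dosage_tsv(
    path: str | Path, variants_path: str | Path
) -> tuple[GenotypeMatrix, dict[str, int]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    meta = pd.read_csv(variants_path, sep="\t")
    if list(df.columns) != list(meta["id"]):
        raise ValueError("dosage TSV columns do not match variant metadata ids")
    geno = GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        variants=meta,
        samples=[str(s) for s in df.index],
    )
    return geno, {"n_variants": len(meta)}


def read_genotypes(
    path: str | Path, variants_path: str | Path | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Read genotypes from an uncompressed VCF (GT or DS) or a dosage TSV.

    Dosage TSVs need a companion variant-metadata TSV (id, chrom, pos, ref,
    alt, info) since the matrix alone carries no coordinates.
    """
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return _read_vcf(path)
    if variants_path is None:
        raise ValueError("dosage TSV input requires variants_path metadata")
    return _read_dosage_tsv(path, variants_path)


# ---------------------------------------------------------------------------
# cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA", ""])


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def assemble_cohort(
    raw: pd.DataFrame,
) -> tuple[pd.DataFrame, CohortAssemblyReport]:
    """Apply inclusion rules and exposure recoding to a raw phenotype table.

    Exclusions in fixed order, each row attributed to its first failing rule:
    psychotic-disorder diagnosis flag, missing ever-use answer, all four
    psychotic-experience items missing.  Never-users with a missing frequency
    answer get frequency 0 (they are never asked the frequency question);
    per-item outcome missingness is preserved for per-outcome models.
    """
    report = CohortAssemblyReport(n_input=len(raw))
    df = raw.copy()

    dx = df.get("excluded_dx")
    dx_mask = (dx == 1) if dx is not None else pd.Series(False, index=df.index)
    report.n_excluded_dx = int(dx_mask.sum())
    df = df[~dx_mask]

    exp_missing = df["cannabis_ever"].isna()
    report.n_missing_exposure = int(exp_missing.sum())
    df = df[~exp_missing]

    items = [c for c in PE_ITEMS if c in df.columns]
    all_missing = df[items].isna().all(axis=1)
    report.n_missing_all_outcomes = int(all_missing.sum())
    df = df[~all_missing].copy()

    never = df["cannabis_ever"] == 0
    df.loc[never & df["cannabis_freq"].isna(), "cannabis_freq"] = 0
    bad = never & (df["cannabis_freq"] != 0)
    if bad.any():
        raise ValueError("never-users must have cannabis frequency 0")

    any_pos = (df[items] == 1).any(axis=1)
    has_obs = df[items].notna().any(axis=1)
    df["pe_any"] = np.where(has_obs, any_pos.astype(float), np.nan)

    report.n_final = len(df)
    report.check()
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# results


def write_prs_model(model, path: str | Path, provenance_path: str | Path | None = None) -> None:
    model.entries.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if provenance_path is not None:
        payload = {
            "p_threshold": model.p_threshold,
            "prune_r2": model.prune_r2,
            "prune_window": model.prune_window,
            "drop_counts": model.provenance,
        }
        Path(provenance_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_scores(scores: pd.Series, path: str | Path) -> None:
    scores.rename_axis("sample_id").to_frame().to_csv(
        path, sep="\t", float_format="%.10g"
    )
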