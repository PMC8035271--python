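"""Synthetic cohort generator.

Emulates the three inputs the analysis pipeline consumes, with the statistical
structure the method assumes:

1. a panel of biallelic autosomal SNP dosages in Hardy-Weinberg equilibrium,
   with block LD, configurable missingness and imputation-info metadata;
2. GWAS summary statistics from an "independent cohort" — noisy estimates of
   spike-and-slab true effects, reported on a randomized allele orientation
   (swaps and strand flips) to exercise harmonization;
3. a phenotyped cohort: a liability-threshold schizophrenia label, an ordinal
   cannabis-use exposure (never/ever/monthly/weekly/daily), four binary
   self-reported psychotic-experience items generated from a logistic model
   with exposure, genetic-liability and exposure-by-liability terms, plus
   onset-age / distress / help-seeking qualities.

Determinism: one integer seed feeds named substreams (genotypes, sumstats,
phenotypes) derived via ``numpy.random.SeedSequence``, so each stage can be
regenerated independently and serialized outputs are byte-identical per seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "SimulationParams",
    "GenotypeMatrix",
    "PE_ITEMS",
    "simulate_genotypes",
    "simulate_gwas_sumstats",
    "simulate_cohort_phenotypes",
    "generate_fixture_bundle",
    "PRESETS",
]

#: the four self-reported psychotic-experience items
PE_ITEMS = ("pe_auditory", "pe_visual", "pe_persecutory", "pe_reference")

# Cannabis use-frequency category counts observed in the study population the
# generator emulates (never / ever / monthly / weekly / daily out of 109,308).
_EXPOSURE_COUNTS = (87010, 14642, 2671, 3582, 1403)

# Never-user prevalence of each psychotic-experience item in that population.
_ITEM_BASE_PREVALENCE = {
    "pe_auditory": 0.013,
    "pe_visual": 0.028,
    "pe_persecutory": 0.006,
    "pe_reference": 0.006,
}

# Per-risk-unit log odds ratios for each item (adjusted estimates of the
# emulated population; used as generative slopes).
_ITEM_EXPOSURE_BETA = {
    "pe_auditory": float(np.log(1.21)),
    "pe_visual": float(np.log(1.21)),
    "pe_persecutory": float(np.log(1.24)),
    "pe_reference": float(np.log(1.18)),
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _default_exposure_probs() -> tuple[float, ...]:
    total = float(sum(_EXPOSURE_COUNTS))
    probs = [c / total for c in _EXPOSURE_COUNTS]
    probs[0] += 1.0 - sum(probs)  # force exact unit sum in float arithmetic
    return tuple(probs)


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generative model.

    Defaults are the study conditions the pipeline targets: the exposure
    distribution and per-item baseline prevalences mirror the population the
    analysis emulates; GWAS architecture and interaction effects are
    generator choices documented in the methods note.
    """

    n_individuals: int = 5000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.6
    missing_rate: float = 0.01
    causal_fraction: float = 0.3
    effect_sd: float = 0.02
    gwas_n: int = 100_000
    scz_prevalence: float = 0.01
    exposure_probs: tuple[float, ...] = field(default_factory=_default_exposure_probs)
    beta0: dict[str, float] = field(
        default_factory=lambda: {
            k: float(logit(v)) for k, v in _ITEM_BASE_PREVALENCE.items()
        }
    )
    beta_exposure: dict[str, float] = field(
        default_factory=lambda: dict(_ITEM_EXPOSURE_BETA)
    )
    beta_prs: float = float(np.log(1.3))
    beta_gxe: float = 0.05
    gec_rho: float = 0.0
    # (name, kind, effect); kind in {"continuous", "binary", "categorical:K"}
    covariate_spec: tuple[tuple[str, str, float], ...] = (
        ("sex", "binary", -0.10),
        ("pc1", "continuous", 0.05),
    )
    pe_missing_rate: float = 0.005
    excluded_dx_fraction: float = 0.005
    onset_age_range: tuple[float, float] = (12.0, 65.0)
    palindromic_fraction: float = 0.10
    strand_flip_fraction: float = 0.20
    allele_swap_fraction: float = 0.30
    low_info_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_individuals > 0 and self.n_variants > 0):
            raise ValueError("n_individuals and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        for name in ("missing_rate", "causal_fraction", "scz_prevalence",
                     "pe_missing_rate", "excluded_dx_fraction",
                     "palindromic_fraction", "strand_flip_fraction",
                     "allele_swap_fraction", "low_info_fraction"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 <= v <= 1):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not (0 < self.scz_prevalence < 1):
            raise ValueError("scz_prevalence must be in (0, 1)")
        p = np.asarray(self.exposure_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("exposure_probs must be 5 probabilities summing to 1")
        if not -1 <= self.gec_rho <= 1:
            raise ValueError("gec_rho must be in [-1, 1]")
        if self.effect_sd < 0 or not np.isfinite(self.effect_sd):
            raise ValueError("effect_sd must be non-negative and finite")
        if self.gwas_n < 10:
            raise ValueError("gwas_n must be >= 10")
        for coll in (self.beta0, self.beta_exposure):
            if set(coll) != set(PE_ITEMS):
                raise ValueError(f"per-item betas must cover exactly {PE_ITEMS}")

    def substream(self, name: str) -> np.random.Generator:
        """Named, order-independent child RNG stream."""
        key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class GenotypeMatrix:
    """Individuals x variants alt-allele dosage matrix with variant metadata.

    ``dosages`` is float with NaN for missing entries; ``variants`` has columns
    id, chrom, pos, ref, alt, info with positions strictly increasing within a
    chromosome and unique ids.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage matrix shape does not match sample/variant counts")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant IDs")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )


# ---------------------------------------------------------------------------
# genotypes


def _variant_metadata(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    m = params.n_variants
    n_blocks = -(-m // params.ld_block_size)
    # distribute LD blocks over autosomes so no block spans a chromosome
    n_chroms = min(22, n_blocks)
    block_chrom = np.repeat(np.arange(n_chroms), -(-n_blocks // n_chroms))[:n_blocks] + 1
    chrom = np.repeat(block_chrom, params.ld_block_size)[:m]
    # 2-20 kb spacing: a default-size block spans well under the 500 kb window
    spacing = rng.integers(2_000, 20_000, size=m)
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = 10_000 + np.cumsum(spacing[mask])
    bases = np.array(list("ACGT"))
    palindromic = rng.random(m) < params.palindromic_fraction
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.empty(m, dtype="<U1")
    for j in range(m):
        if palindromic[j]:
            alt[j] = _COMPLEMENT[ref[j]]
        else:
            choices = [b for b in "ACGT" if b not in (ref[j], _COMPLEMENT[ref[j]])]
            alt[j] = choices[rng.integers(0, len(choices))]
    info = np.round(rng.uniform(0.85, 1.0, size=m), 4)
    low = rng.random(m) < params.low_info_fraction
    info[low] = np.round(rng.uniform(0.5, 0.8, size=m), 4)[low]
    return pd.DataFrame(
        {
            "id": [f"rs{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom.astype(int),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "info": info,
        }
    )


def simulate_genotypes(params: SimulationParams) -> GenotypeMatrix:
    """Draw an HWE dosage panel with block-AR(1) linkage disequilibrium.

    Each individual carries two independent haplotypes; within an LD block the
    latent Gaussian of haplotype ``j+1`` is ``rho * z_j + sqrt(1-rho^2) * eps``
    and the allele is the indicator ``z < Phi^{-1}(maf)``.  Independence of the
    two haplotypes gives exact Hardy-Weinberg genotype proportions per variant;
    the realized dosage correlation of adjacent variants is the tetrachoric
    attenuation of ``ld_rho`` (about ``(2/pi) asin(rho)`` at MAF 0.5).
    """
    params.validate()
    rng = params.substream("genotypes")
    meta = _variant_metadata(params, rng)
    n, m = params.n_individuals, params.n_variants
    maf = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)
    thresh = norm.ppf(maf)

    block = np.arange(m) // params.ld_block_size
    new_block = np.concatenate([[True], block[1:] != block[:-1]])
    rho = params.ld_rho
    dosages = np.zeros((n, m))
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0:
            for j in range(1, m):
                if not new_block[j]:
                    z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * z[:, j]
        dosages += (z < thresh).astype(float)

    if params.missing_rate > 0:
        miss = rng.random((n, m)) < params.missing_rate
        dosages[miss] = np.nan

    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=meta, samples=samples)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_sumstats(
    genotype_meta: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate an independent-cohort GWAS over the panel's variants.

    True per-alt-allele log odds ratios are spike-and-slab: zero with
    probability ``1 - causal_fraction``, else Normal(0, effect_sd).  The
    reported estimate adds Normal(0, se) noise with the Wald standard error
    ``se = 1 / sqrt(2 f (1-f) gwas_n)`` implied by the study size and allele
    frequency, and the p-value is the two-sided Wald test.  Allele orientation
    is randomized record-by-record: a fraction are reported with effect/other
    alleles swapped (effect sign follows the effect allele) and a fraction on
    the opposite strand, so harmonization is actually exercised.

    Returns the summary-statistic table (columns SNP, CHR, BP, A1, A2, BETA,
    OR, P, FRQ_A1, INFO, oriented to the reported A1) and the vector of true
    per-alt-allele effects in panel order.
    """
    if len(genotype_meta) == 0:
        raise ValueError("variant records must be non-empty")
    if params.gwas_n < 10:
        raise ValueError("gwas_n must be >= 10")
    rng = params.substream("sumstats")
    m = len(genotype_meta)

    causal = rng.random(m) < params.causal_fraction
    true_beta = np.where(causal, rng.normal(0.0, params.effect_sd or 1.0, size=m), 0.0)
    if params.effect_sd == 0:
        true_beta = np.zeros(m)

    freq = rng.uniform(params.maf_range[0], params.maf_range[1], size=m)
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * params.gwas_n)
    beta_hat = true_beta + rng.normal(0.0, se)
    z = beta_hat / se
    pvals = 2.0 * norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    a1 = genotype_meta["alt"].to_numpy().copy()
    a2 = genotype_meta["ref"].to_numpy().copy()
    rep_beta = beta_hat.copy()
    rep_freq = freq.copy()
    swap = rng.random(m) < params.allele_swap_fraction
    a1[swap], a2[swap] = a2[swap].copy(), a1[swap].copy()
    rep_beta[swap] *= -1.0
    rep_freq[swap] = 1.0 - rep_freq[swap]
    flip = rng.random(m) < params.strand_flip_fraction
    comp = np.vectorize(_COMPLEMENT.get)
    a1[flip] = comp(a1[flip])
    a2[flip] = comp(a2[flip])

    table = pd.DataFrame(
        {
            "SNP": genotype_meta["id"].to_numpy(),
            "CHR": genotype_meta["chrom"].to_numpy(),
            "BP": genotype_meta["pos"].to_numpy(),
            "A1": a1,
            "A2": a2,
            "BETA": rep_beta,
            "OR": np.exp(rep_beta),
            "P": pvals,
            "FRQ_A1": rep_freq,
            "INFO": genotype_meta["info"].to_numpy(),
        }
    )
    return table, true_beta


# ---------------------------------------------------------------------------
# phenotypes


def _genetic_liability(genotypes: GenotypeMatrix, true_effects: np.ndarray) -> np.ndarray:
    d = genotypes.dosages
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    filled = np.where(np.isnan(d), col_mean, d)
    raw = filled @ np.asarray(true_effects, dtype=float)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def _draw_covariates(
    params: SimulationParams, n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    categorical: list[str] = []
    for name, kind, effect in params.covariate_spec:
        if kind == "continuous":
            x = rng.standard_normal(n)
            cols[name] = x
            eta += effect * x
        elif kind == "binary":
            x = (rng.random(n) < 0.5).astype(int)
            cols[name] = x
            eta += effect * x
        elif kind.startswith("categorical:"):
            k = int(kind.split(":", 1)[1])
            x = rng.integers(0, k, size=n)
            cols[name] = x
            # level 0 is reference; effect scales linearly with level index
            eta += effect * x
            categorical.append(name)
        else:
            raise ValueError(f"unknown covariate kind: {kind!r}")
    return pd.DataFrame(cols), eta, categorical


def simulate_cohort_phenotypes(
    genotypes: GenotypeMatrix,
    true_effects: np.ndarray,
    params: SimulationParams,
) -> pd.DataFrame:
    """Generate the phenotype/covariate table from genotypes and true effects.

    Genetic liability is the standardized true-weight score. The schizophrenia
    label is a liability-threshold draw: liability plus standard-normal noise
    exceeding the (1 - prevalence) quantile of that sum. The ordinal cannabis
    exposure comes from ordered thresholds on a latent normal correlated with
    liability at ``gec_rho``; each psychotic-experience item is Bernoulli with
    logit ``beta0 + beta_exposure*X + beta_prs*L + beta_gxe*X*L + covariates``
    where X is the risk-unit coding (0-4) of the exposure.  ``pe_any`` is
    derived from the items; onset age, distress and help-seeking are generated
    only where ``pe_any`` is 1.  The table carries the true standardized
    liability as ``prs_true``.
    """
    params.validate()
    if len(set(genotypes.samples)) != len(genotypes.samples):
        raise ValueError("genotype sample IDs must be unique")
    true_effects = np.asarray(true_effects, dtype=float)
    if true_effects.shape != (genotypes.n_variants,):
        raise ValueError("true_effects length must match variant count")
    rng = params.substream("phenotypes")
    n = genotypes.n_individuals

    liability = _genetic_liability(genotypes, true_effects)
    lia_var = float(liability.var())
    total = liability + rng.standard_normal(n)
    tau = norm.ppf(1.0 - params.scz_prevalence) * np.sqrt(lia_var + 1.0)
    scz = (total > tau).astype(int)

    # ordered-threshold latent exposure, optionally correlated with liability
    g = params.gec_rho
    latent = g * liability + np.sqrt(max(0.0, 1.0 - g * g)) * rng.standard_normal(n)
    cuts = norm.ppf(np.cumsum(params.exposure_probs)[:-1])
    freq = np.searchsorted(cuts, latent, side="left").astype(int)
    ever = (freq > 0).astype(int)

    cov_df, cov_eta, _cat = _draw_covariates(params, n, rng)

    out = pd.DataFrame({"sample_id": genotypes.samples})
    out["scz_status"] = scz
    out["cannabis_ever"] = ever
    out["cannabis_freq"] = freq
    out["prs_true"] = liability
    for c in cov_df.columns:
        out[c] = cov_df[c]

    x = freq.astype(float)
    for item in PE_ITEMS:
        eta = (
            params.beta0[item]
            + params.beta_exposure[item] * x
            + params.beta_prs * liability
            + params.beta_gxe * x * liability
            + cov_eta
        )
        y = (rng.random(n) < expit(eta)).astype(float)
        if params.pe_missing_rate > 0:
            y[rng.random(n) < params.pe_missing_rate] = np.nan
        out[item] = y

    items = out[list(PE_ITEMS)].to_numpy()
    any_pos = np.nansum(items == 1, axis=1) > 0
    all_missing = np.isnan(items).all(axis=1)
    pe_any = np.where(all_missing, np.nan, any_pos.astype(float))
    out["pe_any"] = pe_any

    has_pe = pe_any == 1
    onset = np.full(n, np.nan)
    lo, hi = params.onset_age_range
    onset[has_pe] = np.round(rng.uniform(lo, hi, size=int(has_pe.sum())), 1)
    out["onset_age"] = onset
    distress = np.full(n, np.nan)
    distress[has_pe] = (rng.random(int(has_pe.sum())) < 0.5).astype(float)
    out["distressing"] = distress
    help_seek = np.full(n, np.nan)
    help_seek[has_pe] = (rng.random(int(has_pe.sum())) < 0.35).astype(float)
    out["help_seeking"] = help_seek

    out["excluded_dx"] = (rng.random(n) < params.excluded_dx_fraction).astype(int)
    return out


# ---------------------------------------------------------------------------
# fixture bundles

PRESETS: dict[str, SimulationParams] = {
    "tiny": SimulationParams(n_individuals=200, n_variants=50, ld_block_size=5),
    "default": SimulationParams(n_individuals=5000, n_variants=2000),
    "power": SimulationParams(n_individuals=20000, n_variants=2000, beta_gxe=0.25),
}


def _fmt(x: float) -> str:
    return "NA" if (isinstance(x, float) and np.isnan(x)) else f"{x:g}"


def write_vcf(genotypes: GenotypeMatrix, path: Path) -> None:
    """Write the panel as an uncompressed VCF 4.2 with GT and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        d = genotypes.dosages
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in genotypes.variants.iterrows():
            fields = [
                str(v["chrom"]), str(v["pos"]), v["id"], v["ref"], v["alt"],
                ".", "PASS", f"R2={v['info']:g}", "GT:DS",
            ]
            col = d[:, j]
            cells = []
            for x in col:
                if np.isnan(x):
                    cells.append("./.:.")
                else:
                    gt = gt_map.get(int(round(x)), "./.") if abs(x - round(x)) < 1e-9 else "./."
                    cells.append(f"{gt}:{x:g}")
            fh.write("\t".join(fields + cells) + "\n")


def write_dosage_tsv(genotypes: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.samples, columns=genotypes.variants["id"]
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def generate_fixture_bundle(preset_name: str, seed: int, outdir: str | Path) -> dict:
    """Simulate a complete input bundle and write it to ``outdir``.

    Writes genotype VCF + dosage TSV + variant metadata TSV, GWAS sumstats
    TSV, cohort TSV, and a JSON manifest with the generating parameters.
    Byte-identical across runs for a fixed seed.
    """
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
    params = replace(PRESETS[preset_name], seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    geno = simulate_genotypes(params)
    sumstats, true_beta = simulate_gwas_sumstats(geno.variants, params)
    cohort = simulate_cohort_phenotypes(geno, true_beta, params)

    paths = {
        "genotypes_vcf": outdir / "genotypes.vcf",
        "dosages_tsv": outdir / "dosages.tsv",
        "variants_tsv": outdir / "variants.tsv",
        "sumstats_tsv": outdir / "sumstats.tsv",
        "cohort_tsv": outdir / "cohort.tsv",
        "true_effects_tsv": outdir / "true_effects.tsv",
        "manifest_json": outdir / "manifest.json",
    }
    write_vcf(geno, paths["genotypes_vcf"])
    write_dosage_tsv(geno, paths["dosages_tsv"])
    geno.variants.to_csv(paths["variants_tsv"], sep="\t", index=False, float_format="%g")
    sumstats.to_csv(paths["sumstats_tsv"], sep="\t", index=False, na_rep="NA",
                    float_format="%.10g")
    cohort.to_csv(paths["cohort_tsv"], sep="\t", index=False, na_rep="NA",
                  float_format="%.10g")
    pd.DataFrame({"id": geno.variants["id"], "true_beta": true_beta}).to_csv(
        paths["true_effects_tsv"], sep="\t", index=False, float_format="%.10g"
    )

    manifest = {
        "preset": preset_name,
        "seed": seed,
        "n_individuals": params.n_individuals,
        "n_variants": params.n_variants,
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in params.__dict__.items()
            if not isinstance(v, dict)
        },
        "files": {k: p.name for k, p in paths.items() if k != "manifest_json"},
    }
    with open(paths["manifest_json"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(p) for k, p in paths.items()}
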