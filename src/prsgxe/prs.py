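"""Polygenic risk score construction by pruning and thresholding (P+T).

The score is built in five steps: (1) variant QC on the cohort panel —
non-duplicate autosomal SNPs with call rate > 95%, exact Hardy-Weinberg
p > 1e-10, minor allele frequency > 0.1% and imputation info > 0.8; (2)
harmonization of external GWAS summary statistics to the panel's ref/alt
orientation and strand, dropping palindromic (A/T, C/G) and unmatched
variants; (3) p-value thresholding, with the cutoff chosen by case/control
AUC over a candidate grid; (4) greedy LD pruning to r^2 < 0.5 within a 500 kb
window; (5) scoring each individual as the weighted sum of effect-allele
dosages with per-variant mean imputation of missing genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import GenotypeMatrix, _COMPLEMENT

logger = logging.getLogger(__name__)

__all__ = [
    "QcThresholds",
    "PrsModel",
    "AucResult",
    "qc_filter_variants",
    "hwe_exact_test",
    "harmonize_sumstats",
    "ld_prune",
    "score_individuals",
    "concordance_auc",
    "choose_threshold",
    "select_p_threshold",
    "DEFAULT_P_THRESHOLDS",
]

#: candidate p-value cutoffs, least strict first
DEFAULT_P_THRESHOLDS = (0.05, 0.005, 0.0005, 0.00005)

#: |dosage - round(dosage)| above this exempts a variant from HWE filtering
HWE_ROUNDING_TOL = 0.1


@dataclass(frozen=True)
class QcThresholds:
    """Strict lower bounds for per-variant QC (a value exactly at a bound fails)."""

    min_call_rate: float = 0.95
    min_hwe_p: float = 1e-10
    min_af: float = 0.001
    min_info: float = 0.8

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_hwe_p", "min_af", "min_info"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PrsModel:
    """Harmonized, thresholded, pruned weight set in cohort orientation.

    ``entries`` columns: variant_id, chrom, pos, weight (log-OR per alt-allele
    dose), offset (constant contribution from ref-oriented effect alleles), p.
    """

    entries: pd.DataFrame
    p_threshold: float
    prune_r2: float = 0.5
    prune_window: int = 500_000
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries["variant_id"].duplicated().any():
            raise ValueError("duplicate variant IDs in PRS model")


@dataclass(frozen=True)
class AucResult:
    auc: float
    n_cases: int
    n_controls: int


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE test p-value from genotype counts.

    Sums, over all heterozygote counts with the observed allele margins and
    parity, the conditional probabilities no larger than the observed one
    (the standard exact SNP-HWE formulation). Monomorphic variants give 1.0.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("genotype counts must not all be zero")
    n_a = 2 * n_aa + n_ab  # copies of allele a
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    obs_het = n_ab
    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[obs_het]
    total = sum(math.exp(v) for v in logs.values())
    p = sum(math.exp(v) for v in logs.values() if v <= obs + 1e-12) / total
    return min(1.0, p)


def _dosage_genotype_counts(col: np.ndarray) -> tuple[int, int, int] | None:
    """Round dosages to hard calls; None when any call is too fractional."""
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return None
    rounded = np.round(obs)
    if np.any(np.abs(obs - rounded) > HWE_ROUNDING_TOL):
        return None
    counts = [int((rounded == g).sum()) for g in (0, 1, 2)]
    if sum(counts) != obs.size:  # dosages outside [0, 2]
        return None
    return counts[2], counts[1], counts[0]  # (alt-hom, het, ref-hom)


# ---------------------------------------------------------------------------
# variant QC


def qc_filter_variants(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the five-step variant QC; returns the subset and per-step drops.

    Filters are evaluated in a fixed order (duplicate id, non-autosomal,
    non-SNP, call rate, allele frequency, info score, HWE) and each dropped
    variant is tallied under its first failing rule.  Allele frequency is the
    alt-dose mean over non-missing entries divided by 2, compared as a minor
    allele frequency; all numeric bounds are strict.
    """
    if genotypes.n_variants == 0:
        raise ValueError("genotype matrix has no variants")
    thr = thresholds or QcThresholds()
    meta = genotypes.variants
    drops = {
        "duplicate": 0, "non_autosomal": 0, "non_snp": 0,
        "call_rate": 0, "allele_freq": 0, "info": 0, "hwe": 0,
    }
    keep: list[int] = []
    seen_ids: set[str] = set()
    d = genotypes.dosages
    for j in range(genotypes.n_variants):
        row = meta.iloc[j]
        if row["id"] in seen_ids:
            drops["duplicate"] += 1
            continue
        seen_ids.add(row["id"])
        try:
            chrom = int(row["chrom"])
        except (TypeError, ValueError):
            chrom = -1
        if not 1 <= chrom <= 22:
            drops["non_autosomal"] += 1
            continue
        if not (
            str(row["ref"]) in "ACGT" and str(row["alt"]) in "ACGT"
            and len(str(row["ref"])) == 1 and len(str(row["alt"])) == 1
            and row["ref"] != row["alt"]
        ):
            drops["non_snp"] += 1
            continue
        col = d[:, j]
        n_obs = int(np.sum(~np.isnan(col)))
        call_rate = n_obs / len(col)
        if not call_rate > thr.min_call_rate:
            drops["call_rate"] += 1
            continue
        af = float(np.nanmean(col)) / 2.0 if n_obs else 0.0
        if not min(af, 1.0 - af) > thr.min_af:
            drops["allele_freq"] += 1
            continue
        if not float(row["info"]) > thr.min_info:
            drops["info"] += 1
            continue
        counts = _dosage_genotype_counts(col)
        if counts is not None:
            if not hwe_exact_test(*counts) > thr.min_hwe_p:
                drops["hwe"] += 1
                continue
        else:
            logger.info("variant %s exempt from HWE (fractional dosages)", row["id"])
        keep.append(j)
    if not keep:
        logger.warning("QC removed every variant")
    return genotypes.subset_variants(keep), drops


# ---------------------------------------------------------------------------
# harmonization


def harmonize_sumstats(
    sumstats: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Orient GWAS records to the cohort panel's ref/alt alleles.

    Matching key is chrom:pos with allele verification; IDs are labels only.
    Per record, in priority order: exact allele match (effect allele = alt
    gives weight +beta; effect allele = ref gives weight -beta with a
    per-variant offset of 2*beta, the algebraic identity beta*(2 - d) =
    -beta*d + 2*beta); strand-complemented match; otherwise dropped.
    Palindromic records (A/T, C/G) are dropped unconditionally — strand is
    unresolvable from the alleles.  Returns oriented entries (variant_id,
    chrom, pos, weight, offset, p) and drop tallies.
    """
    panel_idx: dict[tuple, dict] = {}
    ambiguous_keys: set[tuple] = set()
    for row in panel.itertuples(index=False):
        key = (int(row.chrom), int(row.pos))
        rec = {"id": row.id, "ref": str(row.ref).upper(), "alt": str(row.alt).upper()}
        if key in panel_idx and (
            panel_idx[key]["ref"] != rec["ref"] or panel_idx[key]["alt"] != rec["alt"]
        ):
            ambiguous_keys.add(key)
        panel_idx[key] = panel_idx.get(key, rec)

    drops = {
        "absent": 0, "palindromic": 0, "mismatch": 0,
        "ambiguous_mapping": 0, "duplicate": 0,
    }
    out = []
    used: set[str] = set()
    for row in sumstats.itertuples(index=False):
        key = (int(row.CHR), int(row.BP))
        if key in ambiguous_keys:
            drops["ambiguous_mapping"] += 1
            continue
        rec = panel_idx.get(key)
        if rec is None:
            drops["absent"] += 1
            continue
        a1, a2 = str(row.A1).upper(), str(row.A2).upper()
        beta = float(row.BETA)
        if _COMPLEMENT.get(a1) == a2 or _COMPLEMENT.get(rec["alt"]) == rec["ref"]:
            drops["palindromic"] += 1
            continue
        if rec["id"] in used:
            drops["duplicate"] += 1
            continue
        resolved = None
        for ea, oa in ((a1, a2), (_COMPLEMENT.get(a1, "?"), _COMPLEMENT.get(a2, "?"))):
            if ea == rec["alt"] and oa == rec["ref"]:
                resolved = (beta, 0.0)
                break
            if ea == rec["ref"] and oa == rec["alt"]:
                resolved = (-beta, 2.0 * beta)
                break
        if resolved is None:
            drops["mismatch"] += 1
            continue
        used.add(rec["id"])
        out.append(
            {
                "variant_id": rec["id"], "chrom": key[0], "pos": key[1],
                "weight": resolved[0], "offset": resolved[1], "p": float(row.P),
            }
        )
    cols = ["variant_id", "chrom", "pos", "weight", "offset", "p"]
    return pd.DataFrame(out, columns=cols), drops


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        return 0.0
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0  # constant dosage: correlation undefined, treated as no LD
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: GenotypeMatrix,
    candidates: pd.DataFrame,
    r2_max: float = 0.5,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Greedy genome-order LD pruning of PRS candidate variants.

    Scans candidates sorted by (chrom, pos); for every conflicting pair — same
    chromosome, |Δpos| <= window (inclusive), r^2 >= r2_max — the member with
    the larger GWAS p-value is dropped (ties drop the larger position).  The
    retained set therefore contains no within-window pair at or above r2_max.
    """
    if candidates.empty:
        return candidates.copy()
    id_to_col = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    cand = candidates.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    d = genotypes.dosages
    retained: list[int] = []  # row indices into cand
    for i in range(len(cand)):
        ci = cand.iloc[i]
        conflicts = []
        drop_candidate = False
        for r in retained:
            cr = cand.iloc[r]
            if cr["chrom"] != ci["chrom"] or ci["pos"] - cr["pos"] > window_bp:
                continue
            r2 = _pairwise_r2(d[:, id_to_col[ci["variant_id"]]],
                              d[:, id_to_col[cr["variant_id"]]])
            if r2 >= r2_max:
                # candidate has the later position, so it loses ties
                if ci["p"] >= cr["p"]:
                    drop_candidate = True
                    break
                conflicts.append(r)
        if drop_candidate:
            continue
        for r in conflicts:
            retained.remove(r)
        retained.append(i)
    return cand.iloc[sorted(retained)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# scoring and AUC


def score_individuals(genotypes: GenotypeMatrix, model: PrsModel) -> pd.Series:
    """Apply PRS weights: sum of weight x alt dosage plus orientation offsets.

    Missing dosages are mean-imputed per variant over the scoring cohort's
    non-missing individuals; variants entirely missing in the cohort are
    dropped with a warning.
    """
    id_to_col = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    missing_ids = [v for v in model.entries["variant_id"] if v not in id_to_col]
    if missing_ids:
        raise KeyError(f"PRS variants absent from panel: {missing_ids[:5]}")
    scores = np.zeros(genotypes.n_individuals)
    n_dropped = 0
    for row in model.entries.itertuples(index=False):
        col = genotypes.dosages[:, id_to_col[row.variant_id]]
        mean = np.nanmean(col) if np.any(~np.isnan(col)) else np.nan
        if np.isnan(mean):
            n_dropped += 1
            continue
        filled = np.where(np.isnan(col), mean, col)
        scores += row.weight * filled + row.offset
    if n_dropped:
        logger.warning("%d PRS variants entirely missing in cohort; dropped", n_dropped)
    return pd.Series(scores, index=genotypes.samples, name="prs")


def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> AucResult:
    """Case/control concordance: P(random case score > random control score).

    Computed by the rank formula with average ranks, which equals the
    all-pairs count with ties worth one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(scores)  # average ranks handle ties
    auc = (ranks[labels == 1].sum() - n_cases * (n_cases + 1) / 2.0) / (
        n_cases * n_controls
    )
    return AucResult(auc=float(auc), n_cases=n_cases, n_controls=n_controls)


# ---------------------------------------------------------------------------
# threshold selection


def build_prs_model(
    harmonized: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float,
    r2_max: float = 0.5,
    window_bp: int = 500_000,
    prune: bool = True,
    provenance: dict[str, int] | None = None,
) -> PrsModel:
    """Threshold harmonized entries at ``p < p_threshold`` and optionally prune."""
    subset = harmonized[harmonized["p"] < p_threshold].reset_index(drop=True)
    prov = dict(provenance or {})
    prov["after_threshold"] = len(subset)
    if prune:
        subset = ld_prune(genotypes, subset, r2_max=r2_max, window_bp=window_bp)
    prov["after_prune"] = len(subset)
    return PrsModel(
        entries=subset, p_threshold=p_threshold,
        prune_r2=r2_max, prune_window=window_bp, provenance=prov,
    )


def choose_threshold(auc_map: dict[float, float | None]) -> float:
    """Argmax-AUC selection with ties going to the less strict threshold."""
    best: tuple[float, float] | None = None
    for t in sorted(auc_map, reverse=True):  # least strict first
        auc = auc_map[t]
        if auc is None:
            continue
        if best is None or auc > best[1]:
            best = (t, auc)
    if best is None:
        raise ValueError("no candidate threshold retained any variants")
    return best[0]


def select_p_threshold(
    harmonized: pd.DataFrame,
    genotypes: GenotypeMatrix,
    scz_labels: np.ndarray,
    candidates: tuple[float, ...] = DEFAULT_P_THRESHOLDS,
    r2_max: float = 0.5,
    window_bp: int = 500_000,
    prune_before_auc: bool = True,
) -> tuple[float, dict[float, float | None]]:
    """Pick the p cutoff maximizing schizophrenia AUC over a candidate grid.

    For each candidate the entries are thresholded, (by default) LD-pruned,
    scored and evaluated by AUC against the case/control labels.  Ties go to
    the less strict threshold; candidates retaining zero variants record a
    missing AUC and are skipped.
    """
    if not candidates:
        raise ValueError("candidate threshold set must be non-empty")
    auc_map: dict[float, float | None] = {}
    for t in sorted(candidates, reverse=True):  # least strict first
        model = build_prs_model(
            harmonized, genotypes, t, r2_max=r2_max, window_bp=window_bp,
            prune=prune_before_auc,
        )
        if model.entries.empty:
            auc_map[t] = None
            continue
        scores = score_individuals(genotypes, model)
        auc_map[t] = concordance_auc(scores.to_numpy(), scz_labels).auc
    return choose_threshold(auc_map), auc_map
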