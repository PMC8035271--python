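"""Simulation experiments that calibrate and power-check the pipeline.

These are the package's own verification studies: type-I error of the
interaction likelihood-ratio test under a null generator, recovery of a known
interaction coefficient, the AUC-vs-threshold profile under a dense weak
polygenic architecture, and detection power at a population-biobank scale.
Each experiment takes an integer seed and derives per-replicate seeds from
it, so runs are reproducible end to end.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .interaction import run_interaction_suite
from .prs import (
    harmonize_sumstats,
    qc_filter_variants,
    score_individuals,
    select_p_threshold,
    build_prs_model,
)
from .simulate import (
    SimulationParams,
    simulate_cohort_phenotypes,
    simulate_genotypes,
    simulate_gwas_sumstats,
)

__all__ = [
    "interaction_null_rejection_rate",
    "interaction_recovery",
    "threshold_ordering_experiment",
    "power_detection_rate",
    "DENSE_WEAK_PARAMS",
]

# Small panel for phenotype-level replicate studies: the LRT operates on the
# cohort table, so the variant panel only has to furnish a genetic liability.
_REPLICATE_PANEL_KW = dict(
    n_variants=150, ld_block_size=5, missing_rate=0.0, pe_missing_rate=0.0
)

# Dense weak polygenic architecture: per-variant effects comparable to the
# GWAS standard error, so stricter p cutoffs discard real signal and the AUC
# profile falls as the threshold tightens.  The schizophrenia AUC is evaluated
# on a case-enriched panel (prevalence 0.2) so its Monte-Carlo error is small
# relative to the between-threshold differences.
DENSE_WEAK_PARAMS = SimulationParams(
    n_individuals=5000,
    n_variants=2000,
    causal_fraction=0.3,
    effect_sd=0.008,
    gwas_n=50_000,
    scz_prevalence=0.2,
    missing_rate=0.0,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1]


def _one_interaction_fit(
    seed: int, beta_gxe: float, n_individuals: int, outcome: str = "pe_visual"
) -> pd.Series:
    params = replace(
        SimulationParams(seed=seed, beta_gxe=beta_gxe, n_individuals=n_individuals),
        **_REPLICATE_PANEL_KW,
    )
    geno = simulate_genotypes(params)
    _, true_beta = simulate_gwas_sumstats(geno.variants, params)
    cohort = simulate_cohort_phenotypes(geno, true_beta, params)
    suite = run_interaction_suite(
        cohort, [outcome], exposures=("risk_units",),
        covariate_names=("sex", "pc1"), prs_col="prs_true",
    )
    return suite.iloc[0]


def interaction_null_rejection_rate(
    n_reps: int = 1000, n_individuals: int = 2000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical type-I error of the interaction LRT with no true interaction.

    Each replicate simulates a fresh cohort with ``beta_gxe = 0`` and tests
    the exposure-by-liability product term; returns the rejection rate at
    ``alpha`` and the collected p-values.
    """
    pvals = []
    for s in _child_seeds(seed, n_reps):
        row = _one_interaction_fit(s, beta_gxe=0.0, n_individuals=n_individuals)
        pvals.append(row["p"])
    pvals = np.array(pvals)
    return {
        "n_reps": n_reps,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "pvalues": pvals,
    }


def interaction_recovery(
    beta_gxe: float = 0.25,
    n_reps: int = 100,
    n_individuals: int = 5000,
    seed: int = 0,
) -> dict:
    """Parameter recovery for a known exposure-by-liability log odds ratio.

    Returns the mean estimated interaction coefficient and the fraction of
    replicates whose Wald 95% CI covers the generative value.
    """
    est, covered = [], []
    for s in _child_seeds(seed, n_reps):
        row = _one_interaction_fit(s, beta_gxe=beta_gxe, n_individuals=n_individuals)
        b, se = row["beta_gxe"], row["se_gxe"]
        est.append(b)
        covered.append(b - 1.96 * se <= beta_gxe <= b + 1.96 * se)
    return {
        "n_reps": n_reps,
        "truth": beta_gxe,
        "mean_estimate": float(np.mean(est)),
        "ci_coverage": float(np.mean(covered)),
        "estimates": np.array(est),
    }


def threshold_ordering_experiment(n_seeds: int = 10, seed: int = 0) -> dict:
    """AUC-by-threshold profile under the dense weak polygenic architecture.

    For each seed the full PRS path (QC, harmonization, threshold selection
    with pruning) runs and the selected cutoff plus the AUC map are recorded.
    Returns the count of seeds selecting the least strict candidate and the
    count with a non-increasing AUC profile as the cutoff tightens.
    """
    n_selected_least_strict = 0
    n_monotone = 0
    maps = []
    for s in _child_seeds(seed, n_seeds):
        params = replace(DENSE_WEAK_PARAMS, seed=s)
        geno = simulate_genotypes(params)
        sumstats, true_beta = simulate_gwas_sumstats(geno.variants, params)
        cohort = simulate_cohort_phenotypes(geno, true_beta, params)
        geno_qc, _ = qc_filter_variants(geno)
        harmonized, _ = harmonize_sumstats(sumstats, geno_qc.variants)
        chosen, auc_map = select_p_threshold(
            harmonized, geno_qc, cohort["scz_status"].to_numpy()
        )
        thresholds = sorted(auc_map, reverse=True)
        n_selected_least_strict += chosen == thresholds[0]
        aucs = [auc_map[t] for t in thresholds if auc_map[t] is not None]
        n_monotone += all(a >= b - 1e-12 for a, b in zip(aucs, aucs[1:]))
        maps.append({str(t): auc_map[t] for t in thresholds})
    return {
        "n_seeds": n_seeds,
        "n_selected_least_strict": n_selected_least_strict,
        "n_monotone": n_monotone,
        "auc_maps": maps,
    }


def power_detection_rate(
    n_reps: int = 20,
    params: SimulationParams | None = None,
    fdr_level: float = 0.10,
    seed: int = 0,
) -> dict:
    """Detection rate of a true interaction at biobank scale.

    One genotype panel is simulated at the given (power-scale) parameters; the
    PRS is constructed once from the GWAS summary statistics; then ``n_reps``
    phenotype replicates are drawn over the fixed panel (fresh phenotype seed
    per replicate) and the full outcome-by-exposure interaction suite runs on
    each.  A replicate counts as a detection when any test reaches
    BH-adjusted FDR <= ``fdr_level``.
    """
    from .simulate import PRESETS

    params = params or PRESETS["power"]
    params = replace(params, seed=seed)
    geno = simulate_genotypes(params)
    sumstats, true_beta = simulate_gwas_sumstats(geno.variants, params)
    geno_qc, _ = qc_filter_variants(geno)
    harmonized, _ = harmonize_sumstats(sumstats, geno_qc.variants)

    cohort0 = simulate_cohort_phenotypes(geno, true_beta, params)
    chosen, _ = select_p_threshold(
        harmonized, geno_qc, cohort0["scz_status"].to_numpy()
    )
    model = build_prs_model(harmonized, geno_qc, chosen)
    scores = score_individuals(geno_qc, model)

    outcomes = ["pe_auditory", "pe_visual", "pe_persecutory", "pe_reference", "pe_any"]
    detections = 0
    min_fdrs = []
    for s in _child_seeds(seed + 1, n_reps):
        cohort = simulate_cohort_phenotypes(geno, true_beta, replace(params, seed=s))
        cohort["prs"] = scores.to_numpy()
        suite = run_interaction_suite(
            cohort, outcomes, exposures=("ever_binary", "risk_units"),
            covariate_names=("sex", "pc1"), prs_col="prs",
        )
        min_fdr = float(suite["fdr"].min())
        min_fdrs.append(min_fdr)
        detections += min_fdr <= fdr_level
    return {
        "n_reps": n_reps,
        "detection_rate": detections / n_reps,
        "p_threshold": chosen,
        "prs_liability_corr": float(
            np.corrcoef(scores.to_numpy(), cohort0["prs_true"])[0, 1]
        ),
        "min_fdrs": np.array(min_fdrs),
    }
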