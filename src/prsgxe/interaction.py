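"""Gene-by-environment interaction testing.

Tests whether schizophrenia polygenic risk modulates the cannabis-psychotic
experience association: a full logistic model with an exposure-by-PRS product
term is compared to the nested model without it by a 1-df likelihood-ratio
chi-square test.  Covariate-by-exposure and covariate-by-PRS products are
included in BOTH models (the Keller adjustment) so that confounder
interactions cannot masquerade as the genetic one.  P-values across the five
outcomes are Benjamini-Hochberg adjusted within each exposure coding, and
PRS-quintile stratified AORs are provided for interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .assoc import (
    ExposureCoding,
    FitResult,
    estimate_aor,
    expand_covariates,
    fit_logistic,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionSpec",
    "LrtResult",
    "build_interaction_designs",
    "lrt",
    "bh_adjust",
    "quintile_stratify",
    "stratified_aor_table",
    "run_interaction_suite",
]

RANK_TOL = 1e-8


@dataclass(frozen=True)
class InteractionSpec:
    """One interaction test: exposure coding, outcome and adjustment set."""

    exposure: ExposureCoding
    outcome: str
    covariate_names: tuple[str, ...] = ()
    categorical: frozenset[str] = field(default_factory=frozenset)
    include_covariate_interactions: bool = True
    prs_col: str = "prs"

    def __post_init__(self) -> None:
        if self.exposure.kind not in ("ever_binary", "risk_units"):
            raise ValueError("interaction exposure must be ever_binary or risk_units")


@dataclass(frozen=True)
class LrtResult:
    chi2: float
    df: int
    p: float
    fdr: float | None = None


# ---------------------------------------------------------------------------
# design assembly


def _rank_filter(design: pd.DataFrame, protected: str) -> pd.DataFrame:
    """Drop collinear columns by incremental Gram-Schmidt, keeping earlier
    columns; the ``protected`` column is orthogonalized first among the
    product terms so a covariate duplicating it is dropped instead."""
    order = [c for c in design.columns if c != protected]
    # place the protected term right after intercept/exposure/PRS base terms
    base_len = min(3, len(order))
    order = order[:base_len] + [protected] + order[base_len:]
    kept: list[str] = []
    basis: list[np.ndarray] = []
    for c in order:
        v = design[c].to_numpy(dtype=float).copy()
        norm0 = np.linalg.norm(v)
        for b in basis:
            v -= (v @ b) * b
        if np.linalg.norm(v) > RANK_TOL * max(norm0, 1.0):
            kept.append(c)
            basis.append(v / np.linalg.norm(v))
        else:
            logger.info("dropping collinear design column %s", c)
    return design[[c for c in design.columns if c in kept]]


def build_interaction_designs(
    cohort: pd.DataFrame, spec: InteractionSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Assemble nested designs for the interaction LRT.

    Reduced: intercept + exposure + PRS + covariates + covariate-by-exposure +
    covariate-by-PRS.  Full: reduced + exposure-by-PRS.  The PRS column is
    standardized to mean 0 / SD 1 over the analysis rows before any products
    are formed; both designs share one row mask (listwise over outcome,
    exposure, PRS and covariates).  Collinear columns are dropped identically
    from both designs, with the exposure-by-PRS term protected so the test
    keeps 1 df.
    """
    exp_cols = spec.exposure.columns(cohort)
    xname = exp_cols.columns[0]
    cov = expand_covariates(cohort, spec.covariate_names, set(spec.categorical))
    needed = pd.concat(
        [exp_cols, cohort[[spec.prs_col, spec.outcome]], cov], axis=1
    )
    mask = needed.notna().all(axis=1)
    sub = needed[mask]

    x = sub[xname].to_numpy(dtype=float)
    prs = sub[spec.prs_col].to_numpy(dtype=float)
    sd = prs.std()
    if sd == 0:
        raise ValueError("PRS has zero variance on analysis rows")
    prs = (prs - prs.mean()) / sd

    cols: dict[str, np.ndarray] = {"intercept": np.ones(mask.sum())}
    cols[xname] = x
    cols["prs"] = prs
    cols[f"{xname}:prs"] = x * prs
    for c in cov.columns:
        cv = sub[c].to_numpy(dtype=float)
        cols[c] = cv
        if spec.include_covariate_interactions:
            cols[f"{c}:{xname}"] = cv * x
            cols[f"{c}:prs"] = cv * prs

    full = _rank_filter(pd.DataFrame(cols, index=sub.index), protected=f"{xname}:prs")
    if f"{xname}:prs" not in full.columns:
        raise ValueError("exposure-by-PRS term is collinear with the base model")
    reduced = full.drop(columns=[f"{xname}:prs"])
    return full, reduced, mask


def lrt(full_fit: FitResult, reduced_fit: FitResult, df: int = 1) -> LrtResult:
    """Likelihood-ratio chi-square for nested logistic fits."""
    if full_fit.n_used != reduced_fit.n_used:
        raise ValueError("nested fits must use identical rows")
    chi2 = 2.0 * (full_fit.loglik - reduced_fit.loglik)
    if chi2 < -1e-6:
        raise ValueError(f"negative LRT statistic ({chi2:.3g}): convergence failure")
    chi2 = max(chi2, 0.0)
    if df < 1:
        return LrtResult(chi2=chi2, df=0, p=1.0)
    return LrtResult(chi2=float(chi2), df=df, p=float(chi2_dist.sf(chi2, df)))


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * n / j over the ascending order statistics,
    capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# quintile stratification


def quintile_stratify(prs: np.ndarray | pd.Series) -> np.ndarray:
    """Assign quintile labels 1-5 by empirical 20/40/60/80 percentiles.

    Ties are broken by stable input order, so bin sizes always differ by at
    most one; for distinct values this coincides with percentile cuts."""
    values = np.asarray(prs, dtype=float)
    n = values.size
    if n < 5:
        raise ValueError("quintile stratification needs at least 5 individuals")
    if np.any(~np.isfinite(values)):
        raise ValueError("PRS values must be finite")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    bounds = [round(k * n / 5) for k in range(6)]
    for q in range(5):
        labels[order[bounds[q]:bounds[q + 1]]] = q + 1
    return labels


def stratified_aor_table(
    cohort: pd.DataFrame,
    outcomes: list[str],
    covariate_names: tuple[str, ...] = (),
    categorical: set[str] | None = None,
    prs_col: str = "prs",
) -> pd.DataFrame:
    """Ever-use AOR within each PRS quintile for each outcome.

    Within a stratum the PRS (and any interaction with it) is omitted — it is
    the stratifier — and the usual covariate adjustment applies.  Cells where
    the fit fails or does not converge are flagged.
    """
    from .assoc import fit_outcome  # deferred to keep module import light

    work = cohort.copy()
    work["prs_quintile"] = quintile_stratify(work[prs_col].to_numpy())
    exposure = ExposureCoding("ever_binary")
    rows = []
    for q in range(1, 6):
        sub = work[work["prs_quintile"] == q]
        for out in outcomes:
            obs = sub[[out, "cannabis_ever"]].dropna()
            prev_ever = 100.0 * obs.loc[obs["cannabis_ever"] == 1, out].mean()
            prev_never = 100.0 * obs.loc[obs["cannabis_ever"] == 0, out].mean()
            row: dict = {
                "quintile": q, "outcome": out,
                "prev_ever_pct": prev_ever, "prev_never_pct": prev_never,
            }
            try:
                fit = fit_outcome(sub, out, exposure, covariate_names, categorical)
                aor = estimate_aor(fit, "cannabis_ever")
                row.update(
                    {
                        "aor": aor.aor, "ci_low": aor.ci_low, "ci_high": aor.ci_high,
                        "p": aor.p, "n": fit.n_used, "converged": fit.converged,
                    }
                )
            except ValueError as exc:
                logger.warning("quintile %d outcome %s fit failed: %s", q, out, exc)
                row.update({"aor": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "p": np.nan, "n": len(obs), "converged": False})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full suite


def test_interaction(cohort: pd.DataFrame, spec: InteractionSpec) -> tuple[LrtResult, FitResult]:
    """Run one full-vs-reduced interaction LRT; returns the test and the full fit."""
    full_X, reduced_X, mask = build_interaction_designs(cohort, spec)
    y = cohort.loc[mask, spec.outcome].to_numpy(dtype=float)
    full_fit = fit_logistic(full_X, y)
    reduced_fit = fit_logistic(reduced_X, y)
    df = full_X.shape[1] - reduced_X.shape[1]
    return lrt(full_fit, reduced_fit, df=df), full_fit


# hands off: pytest must not collect the function above as a test
test_interaction.__test__ = False


def run_interaction_suite(
    cohort: pd.DataFrame,
    outcomes: list[str],
    exposures: tuple[str, ...] = ("ever_binary", "risk_units"),
    covariate_names: tuple[str, ...] = (),
    categorical: set[str] | None = None,
    prs_col: str = "prs",
    include_covariate_interactions: bool = True,
    joint_fdr: bool = False,
) -> pd.DataFrame:
    """LRT per outcome x exposure with BH-FDR within each exposure's family.

    ``joint_fdr=True`` instead adjusts all outcome-by-exposure tests as one
    family.  Columns: outcome, exposure, interaction term estimate and SE,
    chi2, df, p, fdr.
    """
    rows = []
    for exp_kind in exposures:
        for out in outcomes:
            spec = InteractionSpec(
                exposure=ExposureCoding(exp_kind),
                outcome=out,
                covariate_names=tuple(covariate_names),
                categorical=frozenset(categorical or ()),
                include_covariate_interactions=include_covariate_interactions,
                prs_col=prs_col,
            )
            try:
                result, full_fit = test_interaction(cohort, spec)
            except ValueError as exc:  # degenerate outcome at small n
                logger.warning("interaction %s/%s not fit: %s", exp_kind, out, exc)
                rows.append({"outcome": out, "exposure": exp_kind,
                             "beta_gxe": np.nan, "se_gxe": np.nan,
                             "chi2": np.nan, "df": 0, "p": np.nan,
                             "n": 0, "converged": False})
                continue
            term = [c for c in full_fit.params.index if c.endswith(":prs")
                    and c.startswith("cannabis")][0]
            rows.append(
                {
                    "outcome": out, "exposure": exp_kind,
                    "beta_gxe": float(full_fit.params[term]),
                    "se_gxe": float(full_fit.bse[term]),
                    "chi2": result.chi2, "df": result.df, "p": result.p,
                    "n": full_fit.n_used, "converged": full_fit.converged,
                }
            )
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    valid = table["p"].notna()
    if joint_fdr:
        if valid.any():
            table.loc[valid, "fdr"] = bh_adjust(table.loc[valid, "p"].to_numpy())
    else:
        for exp_kind in exposures:
            m = (table["exposure"] == exp_kind) & valid
            if m.any():
                table.loc[m, "fdr"] = bh_adjust(table.loc[m, "p"].to_numpy())
    return table
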