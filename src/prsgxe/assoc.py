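"""Covariate-adjusted logistic association of cannabis use with psychotic
experiences.

Exposure codings: ever/never binary; ordinal "risk units" (never=0, ever=1,
monthly=2, weekly=3, daily=4); or per-category indicators against never-use.
Effects are reported as adjusted odds ratios (AOR = exp(beta)) with Wald 95%
confidence intervals exp(beta +/- 1.96 SE).  Pairs of log odds ratios are
compared with a Z-test whose standard error is the root sum of squares of the
two coefficient SEs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureCoding",
    "FitResult",
    "AorEstimate",
    "CoefficientDifferenceResult",
    "build_design",
    "fit_logistic",
    "fit_outcome",
    "estimate_aor",
    "prevalence_table",
    "outcome_dichotomies",
    "coef_difference_test",
    "quality_contrast_analysis",
    "sex_stratified_analysis",
]

Z_95 = 1.96                      # Wald CI multiplier
SEPARATION_BETA_LIMIT = 15.0     # |beta| beyond this flags (quasi-)separation
RISK_UNIT_LEVELS = ("never", "ever", "monthly", "weekly", "daily")


@dataclass(frozen=True)
class ExposureCoding:
    """How cannabis use enters the design matrix.

    ``ever_binary``: one 0/1 column (any use).  ``risk_units``: one ordinal
    column, never=0 ... daily=4.  ``category_indicators``: four indicator
    columns for ever/monthly/weekly/daily against never-use.
    """

    kind: str = "ever_binary"

    def __post_init__(self) -> None:
        if self.kind not in ("ever_binary", "risk_units", "category_indicators"):
            raise ValueError(f"unknown exposure coding {self.kind!r}")

    def columns(self, cohort: pd.DataFrame) -> pd.DataFrame:
        if self.kind == "ever_binary":
            return pd.DataFrame({"cannabis_ever": cohort["cannabis_ever"].astype(float)})
        if self.kind == "risk_units":
            return pd.DataFrame({"cannabis_risk_units": cohort["cannabis_freq"].astype(float)})
        freq = cohort["cannabis_freq"]
        return pd.DataFrame(
            {
                f"cannabis_{lvl}": (freq == k).astype(float).where(freq.notna())
                for k, lvl in enumerate(RISK_UNIT_LEVELS)
                if k > 0
            }
        )


@dataclass
class FitResult:
    """Coefficients, SEs and log-likelihood for one logistic model."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    n_used: int
    converged: bool


@dataclass(frozen=True)
class AorEstimate:
    aor: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class CoefficientDifferenceResult:
    d: float
    se_d: float
    z: float
    p: float


# ---------------------------------------------------------------------------
# design construction


def expand_covariates(
    cohort: pd.DataFrame,
    covariate_names: list[str] | tuple[str, ...],
    categorical: set[str] | None = None,
) -> pd.DataFrame:
    """Continuous covariates pass through; categoricals become k-1 indicators
    against their most frequent level. Single-level covariates are dropped with
    a warning."""
    categorical = set(categorical or ())
    cols: dict[str, pd.Series] = {}
    for name in covariate_names:
        if name not in cohort.columns:
            raise KeyError(f"covariate {name!r} not in cohort")
        col = cohort[name]
        is_cat = name in categorical or not pd.api.types.is_numeric_dtype(col)
        if not is_cat:
            cols[name] = col.astype(float)
            continue
        levels = col.dropna().value_counts()  # sorted by frequency, stable
        if len(levels) < 2:
            logger.warning("covariate %s has a single level; dropped", name)
            continue
        ref = levels.index[0]
        for lvl in levels.index[1:]:
            cols[f"{name}[{lvl}]"] = (col == lvl).astype(float).where(col.notna())
    return pd.DataFrame(cols, index=cohort.index)


def build_design(
    cohort: pd.DataFrame,
    exposure: ExposureCoding,
    covariate_names: list[str] | tuple[str, ...] = (),
    categorical: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Intercept + exposure column(s) + expanded covariates.

    Returns the design restricted to complete rows and the boolean row mask
    that was applied (listwise deletion over every required column).
    """
    exp_cols = exposure.columns(cohort)
    if exp_cols.isna().all().any():
        raise ValueError("exposure column is entirely missing")
    cov_cols = expand_covariates(cohort, covariate_names, categorical)
    design = pd.concat([exp_cols, cov_cols], axis=1)
    design.insert(0, "intercept", 1.0)
    mask = design.notna().all(axis=1)
    return design[mask], mask


# ---------------------------------------------------------------------------
# fitting


def fit_logistic(design: pd.DataFrame, outcome: np.ndarray | pd.Series) -> FitResult:
    """Maximum-likelihood logistic fit (Newton IRLS, tol 1e-8, <=100 iters).

    SEs come from the inverse observed information.  Non-convergence or
    apparent separation (any |beta| > 15) is flagged via ``converged`` rather
    than raised; estimates are still returned.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(design):
        raise ValueError("outcome length does not match design")
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or len(uniq) < 2:
        raise ValueError("outcome must contain both classes, coded 0/1")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # perfect separation raises in some statsmodels paths
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=200, disp=0)
            converged = False
    params = pd.Series(res.params, index=design.columns)
    if np.any(np.abs(params) > SEPARATION_BETA_LIMIT):
        converged = False
    return FitResult(
        params=params,
        bse=pd.Series(res.bse, index=design.columns),
        loglik=float(res.llf),
        n_used=len(y),
        converged=converged,
    )


def fit_outcome(
    cohort: pd.DataFrame,
    outcome_col: str,
    exposure: ExposureCoding,
    covariate_names: list[str] | tuple[str, ...] = (),
    categorical: set[str] | None = None,
) -> FitResult:
    """Build the design for one outcome and fit, with listwise deletion over
    the outcome, exposure and covariates jointly."""
    design, mask = build_design(cohort, exposure, covariate_names, categorical)
    y = cohort.loc[mask, outcome_col]
    keep = y.notna()
    return fit_logistic(design[keep.to_numpy()], y[keep])


def estimate_aor(fit: FitResult, term: str) -> AorEstimate:
    """Adjusted odds ratio with Wald 95% CI and two-sided p for one term."""
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fit")
    b, se = float(fit.params[term]), float(fit.bse[term])
    z = b / se
    with np.errstate(over="ignore"):  # separated fits give infinite CI bounds
        return AorEstimate(
            aor=float(np.exp(b)),
            ci_low=float(np.exp(b - Z_95 * se)),
            ci_high=float(np.exp(b + Z_95 * se)),
            p=float(2.0 * norm.sf(abs(z))),
        )


# ---------------------------------------------------------------------------
# tabulation and derived outcomes


def prevalence_table(
    cohort: pd.DataFrame, outcomes: list[str], strata_col: str
) -> pd.DataFrame:
    """Raw percent prevalence of each outcome within each stratum.

    Missing outcome values are excluded from the denominator; an empty stratum
    yields a missing cell.  Columns: outcome, stratum, n_cases, n_nonmissing,
    percent.
    """
    rows = []
    for stratum, grp in cohort.groupby(strata_col, dropna=True):
        for out in outcomes:
            obs = grp[out].dropna()
            rows.append(
                {
                    "outcome": out,
                    "stratum": stratum,
                    "n_cases": int((obs == 1).sum()),
                    "n_nonmissing": len(obs),
                    "percent": 100.0 * (obs == 1).mean() if len(obs) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def outcome_dichotomies(cohort: pd.DataFrame, onset_cutoff: float = 18.0) -> pd.DataFrame:
    """Derive quality-split outcome columns with complementary exclusion.

    ``pe_early_onset`` is 1 for experiences starting strictly before the
    cutoff (18 years); individuals whose experience started at or after the
    cutoff are excluded (missing) from that analysis, and vice versa for
    ``pe_adult_onset``.  ``pe_distressing`` / ``pe_nondistressing`` and
    ``pe_help_seeking`` / ``pe_no_help_seeking`` are built the same way.
    Individuals with no psychotic experience are controls (0) everywhere.
    """
    pe = cohort["pe_any"]
    if ((pe != 1) & cohort["onset_age"].notna()).any():
        raise ValueError("onset_age present for individuals without psychotic experiences")
    out = pd.DataFrame(index=cohort.index)

    def split(flag: pd.Series, name_pos: str, name_neg: str) -> None:
        pos = pd.Series(np.nan, index=cohort.index)
        neg = pd.Series(np.nan, index=cohort.index)
        controls = pe == 0
        pos[controls] = 0.0
        neg[controls] = 0.0
        with_pe = pe == 1
        pos[with_pe & (flag == 1)] = 1.0   # complementary cases stay missing
        neg[with_pe & (flag == 0)] = 1.0
        out[name_pos] = pos
        out[name_neg] = neg

    early = (cohort["onset_age"] < onset_cutoff).astype(float).where(
        cohort["onset_age"].notna()
    )
    split(early, "pe_early_onset", "pe_adult_onset")
    split(cohort["distressing"], "pe_distressing", "pe_nondistressing")
    split(cohort["help_seeking"], "pe_help_seeking", "pe_no_help_seeking")
    return out


def coef_difference_test(
    b1: float, se1: float, b2: float, se2: float
) -> CoefficientDifferenceResult:
    """Z-test for the difference of two log odds ratios.

    D = b1 - b2 with SE sqrt(se1^2 + se2^2); two-sided normal p-value."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    d = b1 - b2
    se_d = float(np.sqrt(se1 * se1 + se2 * se2))
    z = d / se_d
    return CoefficientDifferenceResult(
        d=float(d), se_d=se_d, z=float(z), p=float(2.0 * norm.sf(abs(z)))
    )


QUALITY_CONTRASTS = (
    ("early_vs_adult_onset", "pe_early_onset", "pe_adult_onset"),
    ("distressing_vs_not", "pe_distressing", "pe_nondistressing"),
    ("help_seeking_vs_not", "pe_help_seeking", "pe_no_help_seeking"),
)


def quality_contrast_analysis(
    cohort: pd.DataFrame,
    covariate_names: list[str] | tuple[str, ...] = (),
    categorical: set[str] | None = None,
    exposure: ExposureCoding | None = None,
) -> pd.DataFrame:
    """Ever-use AORs for quality-split outcomes with paired difference tests.

    Builds the early/adult-onset, distressing/non-distressing and
    help-seeking/non-help-seeking outcome pairs (each side excluding the
    complementary cases), fits the exposure AOR for each side, and compares
    the pair's log odds ratios with the Z-test; the three difference
    p-values are BH-adjusted together.
    """
    from .interaction import bh_adjust  # local import avoids a cycle

    exposure = exposure or ExposureCoding("ever_binary")
    term = exposure.columns(cohort).columns[0]
    derived = outcome_dichotomies(cohort)
    work = pd.concat([cohort, derived], axis=1)
    rows = []
    for name, pos_col, neg_col in QUALITY_CONTRASTS:
        entry: dict = {"contrast": name}
        fits = {}
        for side, col in (("with_quality", pos_col), ("without_quality", neg_col)):
            try:
                fit = fit_outcome(work, col, exposure, covariate_names, categorical)
                aor = estimate_aor(fit, term)
                fits[side] = fit
                entry.update(
                    {
                        f"{side}_aor": aor.aor, f"{side}_ci_low": aor.ci_low,
                        f"{side}_ci_high": aor.ci_high, f"{side}_n": fit.n_used,
                        f"{side}_converged": fit.converged,
                    }
                )
            except ValueError as exc:
                logger.warning("quality contrast %s/%s not fit: %s", name, col, exc)
                entry.update({f"{side}_aor": np.nan, f"{side}_ci_low": np.nan,
                              f"{side}_ci_high": np.nan, f"{side}_n": 0,
                              f"{side}_converged": False})
        if len(fits) == 2:
            diff = coef_difference_test(
                float(fits["with_quality"].params[term]),
                float(fits["with_quality"].bse[term]),
                float(fits["without_quality"].params[term]),
                float(fits["without_quality"].bse[term]),
            )
            entry.update({"diff_z": diff.z, "diff_p": diff.p})
        else:
            entry.update({"diff_z": np.nan, "diff_p": np.nan})
        rows.append(entry)
    table = pd.DataFrame(rows)
    table["diff_fdr"] = np.nan
    ok = table["diff_p"].notna()
    if ok.any():
        table.loc[ok, "diff_fdr"] = bh_adjust(table.loc[ok, "diff_p"].to_numpy())
    return table


def sex_stratified_analysis(
    cohort: pd.DataFrame,
    outcomes: list[str],
    covariate_names: list[str] | tuple[str, ...] = (),
    categorical: set[str] | None = None,
    exposure: ExposureCoding | None = None,
) -> pd.DataFrame:
    """Per-sex AORs for each outcome plus a between-sex difference test.

    Sex is removed from the within-stratum covariates; the five difference
    p-values are jointly Benjamini-Hochberg adjusted.  Rows where a stratum
    fit does not converge are flagged.
    """
    from .interaction import bh_adjust  # local import avoids a cycle

    exposure = exposure or ExposureCoding("ever_binary")
    covs = [c for c in covariate_names if c != "sex"]
    term = exposure.columns(cohort).columns[0]
    rows = []
    for out in outcomes:
        entry: dict = {"outcome": out}
        fits = {}
        for sex_val, label in ((0, "sex0"), (1, "sex1")):
            sub = cohort[cohort["sex"] == sex_val]
            try:
                fit = fit_outcome(sub, out, exposure, covs, categorical)
            except ValueError as exc:  # stratum too sparse to fit
                logger.warning("sex stratum %s outcome %s not fit: %s", label, out, exc)
                entry.update({f"{label}_aor": np.nan, f"{label}_ci_low": np.nan,
                              f"{label}_ci_high": np.nan, f"{label}_n": 0,
                              f"{label}_converged": False})
                continue
            fits[label] = fit
            aor = estimate_aor(fit, term)
            entry.update(
                {
                    f"{label}_aor": aor.aor, f"{label}_ci_low": aor.ci_low,
                    f"{label}_ci_high": aor.ci_high, f"{label}_n": fit.n_used,
                    f"{label}_converged": fit.converged,
                }
            )
        if len(fits) == 2:
            diff = coef_difference_test(
                float(fits["sex0"].params[term]), float(fits["sex0"].bse[term]),
                float(fits["sex1"].params[term]), float(fits["sex1"].bse[term]),
            )
            entry.update({"diff_z": diff.z, "diff_p": diff.p})
        else:
            entry.update({"diff_z": np.nan, "diff_p": np.nan})
        rows.append(entry)
    table = pd.DataFrame(rows)
    table["diff_fdr"] = np.nan
    ok = table["diff_p"].notna()
    if ok.any():
        table.loc[ok, "diff_fdr"] = bh_adjust(table.loc[ok, "diff_p"].to_numpy())
    return table
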