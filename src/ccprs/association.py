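"""Crude and covariate-adjusted odds ratios under standard inheritance models.

Models
------
codominant    two indicator regressors (heterozygote, risk homozygote)
dominant      1{g >= 1}
recessive     1{g == 2}
log_additive  per-allele dosage g
allelic_2x2   allele-level 2x2 table (no regression, crude only)

Crude odds ratios for the 2x2-representable models come from the contingency
table (Woolf confidence interval, Haldane-Anscombe 0.5 correction when a cell
is empty); codominant and log-additive crude estimates, and all adjusted
estimates, come from maximum-likelihood logistic regression. P-values for
logistic models are likelihood-ratio tests of the genotype term(s) against
the covariate-only (or intercept-only) null; confidence intervals are Wald.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALCOHOL_LEVELS, Cohort
from .errors import ConfigError, SeparationWarning, UndefinedStatisticError
from .freq_hwe import GenotypeCounts, genotype_counts

MODELS = ("codominant", "dominant", "recessive", "log_additive", "allelic_2x2")
DEFAULT_COVARIATES = ("sex", "age", "diet", "alcohol", "smoking")

_SEPARATION_BOUND = 15.0  # |beta| on the log-odds scale


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation: bool = False
    names: tuple[str, ...] = ()

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class MultipleTesting:
    alpha: float
    m: int

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("number of comparisons must be >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.m

    @property
    def display(self) -> str:
        from .report import round_half_away
        return f"{round_half_away(self.threshold, 4):.4f}"


@dataclass
class EffectEstimate:
    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    reference: bool = False


@dataclass
class AssociationResult:
    locus_id: str
    model: str
    estimates: list[EffectEstimate]
    p_value: float
    adjusted: bool
    covariates: tuple[str, ...] = ()
    significant_raw: bool | None = None
    significant_bonferroni: bool | None = None
    notes: list[str] = field(default_factory=list)


def bonferroni(alpha: float, m: int) -> MultipleTesting:
    """Family-wise Bonferroni correction: per-test threshold alpha / m."""
    return MultipleTesting(alpha, m)


# -- contingency-table odds ratios ---------------------------------------------


def contingency_or(table) -> tuple[EffectEstimate, float, bool]:
    """Odds ratio, Woolf 95% CI and chi-square p for a 2x2 table.

    ``table`` is ((a, b), (c, d)) with rows = case/control and columns =
    exposed/unexposed, so OR = ad / bc. Returns (estimate, p_value,
    haldane_corrected).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("a margin of the 2x2 table is zero; OR undefined")
    corrected = bool((arr == 0).any())
    work = arr + 0.5 if corrected else arr
    (a, b), (c, d) = work
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = or_ * math.exp(-1.96 * se), or_ * math.exp(1.96 * se)
    chi2_stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return EffectEstimate("exposed", float(or_), float(lo), float(hi)), float(p), corrected


def model_tables(case: GenotypeCounts, control: GenotypeCounts, model: str):
    """Collapse per-group genotype counts into the model's contingency table.

    Rows are (case, control); for 2x2 models the first column is the
    'exposed' class. Codominant returns the full 2x3 (columns g = 0, 1, 2).
    """
    c0, c1, c2 = case.as_tuple
    k0, k1, k2 = control.as_tuple
    if model == "dominant":
        return ((c1 + c2, c0), (k1 + k2, k0))
    if model == "recessive":
        return ((c2, c0 + c1), (k2, k0 + k1))
    if model == "allelic_2x2":
        return ((c1 + 2 * c2, 2 * c0 + c1), (k1 + 2 * k2, 2 * k0 + k1))
    if model == "codominant":
        return ((c0, c1, c2), (k0, k1, k2))
    raise ConfigError(f"unknown inheritance model {model!r}")


# -- logistic regression -------------------------------------------------------


def fit_logistic(outcome, design, max_iter: int = 100,
                 score_tol: float = 1e-8, ll_tol: float = 1e-10,
                 names: Sequence[str] = ()) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton-Raphson).

    Converges when the largest score component falls below ``score_tol`` or
    the relative log-likelihood change falls below ``ll_tol``. Complete or
    quasi-complete separation (|beta| > 15) is flagged with a
    ``SeparationWarning``; the partial fit is still returned.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be 2-d with one row per outcome")
    if y.min() == y.max():
        raise UndefinedStatisticError("outcome has a single class")

    beta = np.zeros(X.shape[1])
    loglik = -np.inf
    separation = converged = False
    n_iter = 0
    cov = np.full((X.shape[1], X.shape[1]), np.nan)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        score = X.T @ (y - mu)
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        new_loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if np.abs(beta).max() > _SEPARATION_BOUND:
            separation = True
            warnings.warn(
                "complete or quasi-complete separation detected; estimates unreliable",
                SeparationWarning,
            )
            loglik = new_loglik
            break
        score_now = X.T @ (y - mu)
        rel_change = abs(new_loglik - loglik) / (abs(loglik) + 1e-300)
        loglik = new_loglik
        if np.abs(score_now).max() < score_tol or rel_change < ll_tol:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return LogisticFit(beta, cov, loglik, n_iter, converged and not separation,
                       separation, tuple(names))


def _intercept_only_loglik(y: np.ndarray) -> float:
    p = y.mean()
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def likelihood_ratio_test(full: LogisticFit, null_loglik: float, df: int) -> float:
    lr = max(0.0, 2.0 * (full.loglik - null_loglik))
    return float(stats.chi2.sf(lr, df=df))


def _wald_estimate(fit: LogisticFit, index: int, label: str) -> EffectEstimate:
    beta = fit.params[index]
    se = fit.se()[index]
    return EffectEstimate(label, math.exp(beta),
                          math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))


# -- covariate handling --------------------------------------------------------

_ALCOHOL_SCORE = {level: float(i) for i, level in enumerate(ALCOHOL_LEVELS)}


def covariate_design(samples: pd.DataFrame, covariates: Iterable[str]):
    """Build the covariate part of a logistic design matrix.

    Codings: sex -> male indicator; age -> years (linear); diet -> two
    indicators with 'mixed' as reference; alcohol -> ordinal score 0-3;
    smoking -> 'ever' indicator. Covariates that are wholly missing are
    dropped with a warning. Returns (matrix, names, complete_row_mask,
    dropped_names); rows with any missing retained covariate are masked out.
    """
    columns: list[np.ndarray] = []
    names: list[str] = []
    dropped: list[str] = []
    n = len(samples)
    for cov in covariates:
        if cov not in samples.columns or samples[cov].isna().all():
            dropped.append(cov)
            warnings.warn(f"covariate {cov!r} is wholly missing and was dropped")
            continue
        if cov == "age":
            columns.append(pd.to_numeric(samples["age"]).to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            s = samples["sex"]
            columns.append(np.where(s.isna(), np.nan, (s == "male").astype(float)))
            names.append("sex_male")
        elif cov == "diet":
            s = samples["diet"]
            for level in ("vegetarian", "mostly_meat"):
                columns.append(np.where(s.isna(), np.nan, (s == level).astype(float)))
                names.append(f"diet_{level}")
        elif cov == "alcohol":
            columns.append(samples["alcohol"].map(_ALCOHOL_SCORE).to_numpy(dtype=float))
            names.append("alcohol_score")
        elif cov == "smoking":
            s = samples["smoking"]
            columns.append(np.where(s.isna(), np.nan, (s == "ever").astype(float)))
            names.append("smoking_ever")
        else:
            raise ConfigError(f"unknown covariate {cov!r}")
    if not columns:
        return np.empty((n, 0)), [], np.ones(n, dtype=bool), dropped
    matrix = np.column_stack(columns)
    mask = np.isfinite(matrix).all(axis=1)
    return matrix, names, mask, dropped


# -- model regressors ----------------------------------------------------------


def _genotype_regressors(g: np.ndarray, model: str):
    """Genotype regressor column(s) and labels for a logistic model."""
    if model == "codominant":
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)]), \
            ["het", "hom_risk"]
    if model == "dominant":
        return (g >= 1).astype(float)[:, None], ["carrier"]
    if model == "recessive":
        return (g == 2).astype(float)[:, None], ["hom_risk"]
    if model == "log_additive":
        return g.astype(float)[:, None], ["per_allele"]
    raise ConfigError(f"model {model!r} has no regression coding")


def _logistic_association(y, g, model, cov_matrix, cov_names, locus_id, adjusted) -> AssociationResult:
    G, labels = _genotype_regressors(g, model)
    n = len(y)
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, G, cov_matrix])
    names = ["intercept", *labels, *cov_names]
    full = fit_logistic(y, X_full, names=names)
    if cov_matrix.shape[1]:
        null = fit_logistic(y, np.hstack([intercept, cov_matrix]))
        null_ll = null.loglik
    else:
        null_ll = _intercept_only_loglik(np.asarray(y, dtype=float))
    p = likelihood_ratio_test(full, null_ll, df=G.shape[1])
    estimates = [EffectEstimate("reference", 1.0, 1.0, 1.0, reference=True)] \
        if model == "codominant" else []
    for k, label in enumerate(labels):
        estimates.append(_wald_estimate(full, 1 + k, label))
    notes = ["separation"] if full.separation else []
    return AssociationResult(locus_id, model, estimates, p, adjusted,
                             covariates=tuple(cov_names), notes=notes)


def _table_association(case: GenotypeCounts, control: GenotypeCounts,
                       model: str, locus_id: str) -> AssociationResult:
    table = model_tables(case, control, model)
    estimate, p, corrected = contingency_or(table)
    label = {"dominant": "carrier", "recessive": "hom_risk",
             "allelic_2x2": "risk_allele"}[model]
    estimate = EffectEstimate(label, estimate.odds_ratio, estimate.ci_low, estimate.ci_high)
    notes = ["haldane_corrected"] if corrected else []
    return AssociationResult(locus_id, model, [estimate], p, adjusted=False, notes=notes)


def association_scan(cohort: Cohort, models: Sequence[str] = MODELS,
                     covariates: Sequence[str] = DEFAULT_COVARIATES,
                     alpha: float = 0.05, m: int | None = None) -> list[AssociationResult]:
    """Crude and adjusted association results for every locus x model.

    Individuals are excluded locus-wise when their genotype is missing, and
    additionally (adjusted analyses only) when a retained covariate is
    missing. The allelic 2x2 model is crude-only by construction. Bonferroni
    flags use threshold ``alpha / m`` with ``m`` defaulting to the number of
    loci scanned.
    """
    for model in models:
        if model not in MODELS:
            raise ConfigError(f"unknown inheritance model {model!r}")
    m = m if m is not None else len(cohort.loci)
    threshold = bonferroni(alpha, m).threshold
    y_all = cohort.is_case.astype(float)
    cov_matrix, cov_names, cov_mask, _ = covariate_design(cohort.samples, covariates) \
        if covariates else (np.empty((cohort.n_individuals, 0)), [],
                            np.ones(cohort.n_individuals, dtype=bool), [])
    empty_cov = np.empty((cohort.n_individuals, 0))

    results: list[AssociationResult] = []
    for locus in cohort.loci:
        g = cohort.dosage(locus.locus_id)
        geno_mask = np.isfinite(g)
        case = genotype_counts(cohort, locus.locus_id, "case")
        control = genotype_counts(cohort, locus.locus_id, "control")
        for model in models:
            # crude
            if model in ("dominant", "recessive", "allelic_2x2"):
                crude = _table_association(case, control, model, locus.locus_id)
            else:
                crude = _logistic_association(
                    y_all[geno_mask], g[geno_mask], model,
                    empty_cov[geno_mask], [], locus.locus_id, adjusted=False)
            crude.significant_raw = crude.p_value < alpha
            crude.significant_bonferroni = crude.p_value < threshold
            results.append(crude)
            # adjusted
            if model == "allelic_2x2" or not cov_names:
                continue
            mask = geno_mask & cov_mask
            adj = _logistic_association(
                y_all[mask], g[mask], model, cov_matrix[mask], cov_names,
                locus.locus_id, adjusted=True)
            adj.significant_raw = adj.p_value < alpha
            adj.significant_bonferroni = adj.p_value < threshold
            results.append(adj)
    return results


def scan_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for est in r.estimates:
            rows.append(
                {
                    "locus": r.locus_id,
                    "model": r.model,
                    "adjusted": r.adjusted,
                    "level": est.label,
                    "odds_ratio": est.odds_ratio,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_value": r.p_value,
                    "significant_raw": r.significant_raw,
                    "significant_bonferroni": r.significant_bonferroni,
                    "notes": ";".join(r.notes),
                }
            )
    return pd.DataFrame(rows)


# -- covariate comparison table ------------------------------------------------


def covariate_table(cohort: Cohort) -> pd.DataFrame:
    """Case/control comparison of covariates: pooled-variance t-test for age,
    Pearson chi-square (no continuity correction) for categorical variables.

    Covariates with a single observed level are skipped with a note.
    """
    is_case = cohort.is_case
    rows = []
    if "age" in cohort.samples.columns and not cohort.samples["age"].isna().all():
        age = pd.to_numeric(cohort.samples["age"]).to_numpy(dtype=float)
        a, b = age[is_case], age[~is_case]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            if np.isnan(t) and np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0  # zero pooled variance, equal means
            rows.append({"covariate": "age", "test": "t", "statistic": float(t),
                         "p_value": float(p), "case_summary": float(np.mean(a)),
                         "control_summary": float(np.mean(b)), "note": ""})
    for cov in ("sex", "diet", "alcohol", "smoking"):
        if cov not in cohort.samples.columns or cohort.samples[cov].isna().all():
            continue
        series = cohort.samples[cov]
        table = pd.crosstab(series, is_case)
        if table.shape != (table.shape[0], 2) or table.shape[0] < 2:
            rows.append({"covariate": cov, "test": "chi_square", "statistic": np.nan,
                         "p_value": np.nan, "case_summary": np.nan,
                         "control_summary": np.nan, "note": "single level; skipped"})
            continue
        chi2_stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"covariate": cov, "test": "chi_square", "statistic": float(chi2_stat),
                     "p_value": float(p), "case_summary": np.nan,
                     "control_summary": np.nan, "note": ""})
    return pd.DataFrame(rows)
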