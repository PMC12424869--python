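"""Covariate-adjusted association of variant frequencies with traits.

Quantitative traits are tested with ordinary least squares, disease
indicators with maximum-likelihood logistic regression (statsmodels),
controlling for age, sex, age x sex, age^2, rDNA copy number, the first
genetic principal components and one-hot sequencing batches.  The
logistic path z-scores the predictor and continuous covariates; the
linear path fits on the raw scale.  Non-converged fits are flagged and
excluded, never reported as zero effects.  Multiple testing uses
Bonferroni over (number of variants) x (number of independent traits);
QQ data with the genomic-control lambda summarizes calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CASES = 30_000  # "at least 30,000 cases" at biobank scale
DEFAULT_MIN_PREVALENCE = 0.06  # equivalent 6% prevalence for smaller cohorts

CONTINUOUS_COVARIATES = ("age", "age_sex", "age_sq", "rdna_cn")


class DesignError(ValueError):
    pass


def build_design(
    covariates: pd.DataFrame,
    predictor: pd.Series,
    standardize: bool = False,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """Assemble the regression design matrix.

    Expects covariate columns ``age``, ``sex`` (0/1), ``rdna_cn``,
    ``pc1..pcN`` and categorical ``batch``.  Adds intercept, the
    predictor, age x sex and age^2; one-hot encodes batch dropping the
    lexicographically first level as reference.  ``standardize=True``
    z-scores the predictor, the continuous covariates and the PCs (the
    logistic-path convention).  Complete cases only.
    """
    pred_name = predictor.name or "predictor"
    df = covariates.copy()
    df[pred_name] = predictor
    df = df.dropna()
    if df.empty:
        raise DesignError("no complete cases")
    if df[pred_name].nunique() <= 1:
        raise DesignError("constant predictor")
    out = pd.DataFrame(index=df.index)
    out["const"] = 1.0
    out[pred_name] = df[pred_name].astype(float)
    out["age"] = df["age"].astype(float)
    out["sex"] = df["sex"].astype(float)
    out["age_sex"] = out["age"] * out["sex"]
    out["age_sq"] = out["age"] ** 2
    out["rdna_cn"] = df["rdna_cn"].astype(float)
    pc_cols = [f"pc{i}" for i in range(1, n_pcs + 1) if f"pc{i}" in df.columns]
    for c in pc_cols:
        out[c] = df[c].astype(float)
    if "batch" in df.columns:
        levels = sorted(df["batch"].astype(str).unique())
        for level in levels[1:]:  # first level is the reference
            out[f"batch_{level}"] = (df["batch"].astype(str) == level).astype(float)
    if standardize:
        for c in [pred_name, *CONTINUOUS_COVARIATES, *pc_cols]:
            sd = out[c].std(ddof=0)
            if sd > 0:
                out[c] = (out[c] - out[c].mean()) / sd
    rank = np.linalg.matrix_rank(out.to_numpy())
    if rank < out.shape[1]:
        logger.warning(
            "design is rank-deficient (rank %d of %d columns)", rank, out.shape[1]
        )
    return out


@dataclass
class AssociationResult:
    predictor: str
    trait: str
    model: str  # "linear" or "logistic"
    beta: float | None
    se: float | None
    p_value: float | None
    n: int
    converged: bool

    @property
    def reportable(self) -> bool:
        return self.converged and self.p_value is not None


def fit_linear(
    trait: pd.Series, design: pd.DataFrame, predictor: str
) -> AssociationResult:
    """OLS of a quantitative trait on the design; two-sided Wald p-value."""
    shared = design.index.intersection(trait.dropna().index)
    X = design.loc[shared]
    y = trait.loc[shared].astype(float)
    name = trait.name or "trait"
    if len(shared) <= X.shape[1]:
        return AssociationResult(predictor, name, "linear", None, None, None,
                                 len(shared), converged=False)
    try:
        fit = sm.OLS(y, X).fit()
        beta = float(fit.params[predictor])
        se = float(fit.bse[predictor])
        p = float(fit.pvalues[predictor])
        if not np.isfinite(p):
            raise ValueError("non-finite p-value (singular design)")
    except Exception as exc:  # singular design etc.
        logger.warning("linear fit failed for %s ~ %s: %s", name, predictor, exc)
        return AssociationResult(predictor, name, "linear", None, None, None,
                                 len(shared), converged=False)
    return AssociationResult(predictor, name, "linear", beta, se, p,
                             int(len(shared)), converged=True)


def fit_logistic(
    cases: pd.Series, design: pd.DataFrame, predictor: str, maxiter: int = 100
) -> AssociationResult:
    """ML logistic regression of a 0/1 case indicator on the design.

    Complete separation and other convergence failures yield a
    non-converged result (excluded downstream), never a silent zero.
    """
    shared = design.index.intersection(cases.dropna().index)
    X = design.loc[shared]
    y = cases.loc[shared].astype(float)
    name = cases.name or "disease"
    if y.nunique() < 2:
        return AssociationResult(predictor, name, "logistic", None, None, None,
                                 len(shared), converged=False)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, warn_convergence=False)
        if not fit.mle_retvals.get("converged", False):
            raise ValueError("did not converge")
        beta = float(fit.params[predictor])
        se = float(fit.bse[predictor])
        p = float(fit.pvalues[predictor])
        if not (np.isfinite(beta) and np.isfinite(se) and np.isfinite(p)):
            raise ValueError("non-finite estimates")
    except Exception as exc:
        logger.warning("logistic fit failed for %s ~ %s: %s", name, predictor, exc)
        return AssociationResult(predictor, name, "logistic", None, None, None,
                                 len(shared), converged=False)
    return AssociationResult(predictor, name, "logistic", beta, se, p,
                             int(len(shared)), converged=True)


def filter_diseases(
    case_counts: Mapping[str, int],
    cohort_n: int | None = None,
    min_cases: int | None = None,
) -> list[str]:
    """ICD10 codes with enough cases to be worth testing.

    Default threshold is 30,000 cases; when ``cohort_n`` is given and no
    explicit ``min_cases``, the equivalent 6% prevalence is used so the
    rule scales to smaller cohorts.  'At least': >= is retained.
    """
    if min_cases is None:
        if cohort_n is not None:
            min_cases = int(np.ceil(DEFAULT_MIN_PREVALENCE * cohort_n))
        else:
            min_cases = DEFAULT_MIN_CASES
    return sorted(code for code, n in case_counts.items() if n >= min_cases)


def bonferroni_threshold(
    alpha: float, n_variants: int, n_independent_traits: int
) -> float:
    """alpha / (variants x independent traits); significance is strict <."""
    if n_variants < 1 or n_independent_traits < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_variants * n_independent_traits)


def effective_trait_count(traits: pd.DataFrame, method: str = "raw") -> float:
    """Number of independent traits for the Bonferroni denominator.

    ``raw`` (default) simply counts trait columns — the maximally
    conservative choice.  ``eigen`` estimates an effective number from
    the eigenvalues of the trait correlation matrix (Li-Ji style:
    sum over eigenvalues of I(lambda >= 1) + frac(lambda)); it equals the
    raw count for mutually independent traits and 1 when all traits are
    perfectly correlated.
    """
    k = traits.shape[1]
    if method == "raw":
        return float(k)
    if method != "eigen":
        raise ValueError(f"unknown method {method!r}")
    if k < 2:
        return float(k)
    if len(traits) < 3:
        raise ValueError("need >= 3 participants for the eigen method")
    corr = traits.corr().fillna(0.0).to_numpy()
    np.fill_diagonal(corr, 1.0)
    eig = np.linalg.eigvalsh(corr)
    eig = np.clip(eig, 0.0, None)
    # snap eigenvalues to integers where round-off would flip floor()
    near = np.isclose(eig, np.round(eig), atol=1e-9)
    eig = np.where(near, np.round(eig), eig)
    meff = float(np.sum((eig >= 1).astype(float) + (eig - np.floor(eig))))
    return min(meff, float(k))


def significance_flags(
    results: Sequence[AssociationResult], threshold: float
) -> pd.DataFrame:
    """Tabulate results with the Bonferroni verdict; non-converged excluded."""
    rows = []
    for r in results:
        rows.append(
            {
                "predictor": r.predictor,
                "trait": r.trait,
                "model": r.model,
                "beta": r.beta,
                "se": r.se,
                "p_value": r.p_value,
                "n": r.n,
                "converged": r.converged,
                "significant": bool(
                    r.reportable and r.p_value < threshold
                ),
            }
        )
    return pd.DataFrame(rows)


def qq_data(p_values: Sequence[float]) -> dict:
    """Expected vs observed -log10 p quantiles plus genomic-control lambda.

    expected_i = -log10((i - 0.5) / m) for ascending sorted p; lambda_GC
    is the median chi-square(1) statistic implied by the p-values over its
    null median.  Zero p-values are clamped to the smallest positive
    float (with a warning).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any():
        logger.warning("clamping %d non-positive p-values", int((p <= 0).sum()))
        p = np.clip(p, np.finfo(float).tiny, None)
    p = np.sort(p)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p)
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    return {"expected": expected, "observed": observed, "lambda_gc": lam}
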