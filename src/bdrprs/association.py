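"""Adjusted association models for the PRS-BDR analysis.

Three primary models, all with the same adjustment set (age, sex, BMI
category, doctor visits, genotype PCs 1-6):

* linear regression of continuous BDR % on the z-scored PRS;
* logistic regression of the responder flag (BDR >= 12%) on the z-scored
  PRS, reported as an odds ratio per SD;
* the same logistic model at the 8% threshold (sensitivity analysis).

Inference is Wald-based throughout — estimate +/- 1.959964 * SE, with the
interval exponentiated onto the odds-ratio scale for logistic models —
matching the symmetric confidence-interval style of the reported effects.
Interaction tests add modifier x PRS product terms and return the Wald
p-value (joint, for the multi-indicator BMI modifier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .phenotypes import CohortTable, dichotomize_bdr, encode_covariates
from .prs import PrsResult

Z_975 = 1.959964  # two-sided 95% normal quantile
MAX_ABS_COEF = 50.0  # beyond this a logistic fit is treated as separated


class ModelError(ValueError):
    """Raised for rank deficiency, separation, or degenerate outcomes."""


@dataclass
class AssociationResult:
    """Per-SD effect estimate with Wald inference and model metadata."""

    model: str  # "linear" | "logistic"
    outcome: str
    estimate: float  # BDR % per SD (linear) or log-odds per SD (logistic)
    se: float
    ci_low: float  # estimate scale for linear, OR scale for logistic
    ci_high: float
    p_value: float
    n: int
    odds_ratio: float | None = None
    covariate_estimates: dict[str, float] = field(default_factory=dict)
    formula: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "outcome": self.outcome,
            "estimate": self.estimate,
            "odds_ratio": self.odds_ratio,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
            "covariate_estimates": self.covariate_estimates,
            "formula": self.formula,
        }


def _design(cohort: CohortTable, prs: PrsResult) -> pd.DataFrame:
    if prs.z_score is None:
        raise ModelError("PRS must be standardized before model fitting")
    if list(cohort.sample_ids) != list(prs.sample_ids):
        raise ModelError("cohort and PRS sample ids do not align")
    X = encode_covariates(cohort).copy()
    X.insert(0, "prs_z", np.asarray(prs.z_score, dtype=float))
    X.insert(0, "const", 1.0)
    return X

def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: the columns pivoted past the numerical rank are the
        # linearly dependent ones
        _, _, piv = linalg.qr(arr, mode="economic", pivoting=True)
        culprits = [X.columns[j] for j in piv[rank:]]
        raise ModelError(f"design matrix rank-deficient; collinear column(s): {', '.join(culprits)}")
    if arr.shape[0] <= arr.shape[1]:
        raise ModelError("more parameters than observations")


def _wald(est: float, se: float) -> tuple[float, float, float]:
    lo, hi = est - Z_975 * se, est + Z_975 * se
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return lo, hi, max(p, np.nextafter(0, 1))


def fit_linear_adjusted(cohort: CohortTable, prs: PrsResult) -> AssociationResult:
    """OLS of continuous BDR % on the z-scored PRS plus the adjustment set."""
    X = _design(cohort, prs)
    _check_full_rank(X)
    y = cohort.bdr_percent
    res = sm.OLS(y, X).fit()
    est, se = float(res.params["prs_z"]), float(res.bse["prs_z"])
    lo, hi, p = _wald(est, se)
    return AssociationResult(
        model="linear",
        outcome="bdr_percent",
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n=len(y),
        covariate_estimates={k: float(v) for k, v in res.params.items() if k != "prs_z"},
        formula="bdr_percent ~ prs_z + " + " + ".join(c for c in X.columns if c not in ("const", "prs_z")),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    if y.min() == y.max():
        raise ModelError("outcome has a single class; logistic model undefined")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise ModelError(f"logistic fit failed (separation or singular Hessian): {exc}")
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise ModelError("perfect separation detected in logistic model")
    if np.abs(res.params.to_numpy()).max() > MAX_ABS_COEF:
        raise ModelError("diverging coefficient: outcome (quasi-)separated by a predictor")
    return res


def fit_logistic_threshold(
    cohort: CohortTable, prs: PrsResult, threshold: float = 12.0
) -> AssociationResult:
    """Adjusted logistic model for responder status at ``threshold`` % BDR.

    The outcome is BDR >= threshold (inclusive); cohorts generated directly
    in threshold mode may instead carry a precomputed binary ``responder``
    column, which is used as-is.
    """
    X = _design(cohort, prs)
    _check_full_rank(X)
    if "bdr_percent" in cohort.data.columns:
        y = dichotomize_bdr(cohort.bdr_percent, threshold).astype(float)
    else:
        y = cohort.data["responder"].to_numpy(dtype=float)
    res = _fit_logit(y, X)
    est, se = float(res.params["prs_z"]), float(res.bse["prs_z"])
    lo, hi, p = _wald(est, se)
    thr_label = int(threshold) if float(threshold).is_integer() else threshold
    return AssociationResult(
        model="logistic",
        outcome=f"responder_{thr_label}",
        estimate=est,
        se=se,
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=p,
        n=len(y),
        odds_ratio=float(np.exp(est)),
        covariate_estimates={k: float(v) for k, v in res.params.items() if k != "prs_z"},
        formula=f"responder_{thr_label} ~ prs_z + "
        + " + ".join(c for c in X.columns if c not in ("const", "prs_z")),
    )


def test_interaction(
    cohort: CohortTable,
    prs: PrsResult,
    modifier: str,
    threshold: float | None = None,
) -> float:
    """Wald p-value for a modifier x PRS interaction.

    ``modifier`` is ``sex``, ``age`` or ``bmi_category``; BMI contributes
    three product terms tested jointly.  ``threshold=None`` fits the linear
    model, otherwise the logistic model at that BDR cut.
    """
    X = _design(cohort, prs)
    if modifier == "sex":
        terms = ["male:prs_z"]
        X["male:prs_z"] = X["male"] * X["prs_z"]
        if cohort.data["sex"].nunique() < 2:
            raise ModelError("modifier 'sex' is constant in this cohort")
    elif modifier == "age":
        if cohort.data["age_years"].nunique() < 2:
            raise ModelError("modifier 'age' is constant in this cohort")
        terms = ["age_years:prs_z"]
        X["age_years:prs_z"] = X["age_years"] * X["prs_z"]
    elif modifier == "bmi_category":
        if cohort.data["bmi_category"].nunique() < 2:
            raise ModelError("modifier 'bmi_category' is constant in this cohort")
        terms = []
        for cat in ("underweight", "overweight", "obese"):
            col = f"bmi_{cat}:prs_z"
            X[col] = X[f"bmi_{cat}"] * X["prs_z"]
            terms.append(col)
        # a category absent from the cohort leaves an all-zero product column
        terms = [t for t in terms if X[t].abs().sum() > 0]
    else:
        raise ValueError(f"unknown modifier {modifier!r}")
    _check_full_rank(X)

    if threshold is None:
        res = sm.OLS(cohort.bdr_percent, X).fit()
    else:
        if "bdr_percent" in cohort.data.columns:
            y = dichotomize_bdr(cohort.bdr_percent, threshold).astype(float)
        else:
            y = cohort.data["responder"].to_numpy(dtype=float)
        res = _fit_logit(y, X)
    if len(terms) == 1:
        _, _, p = _wald(float(res.params[terms[0]]), float(res.bse[terms[0]]))
        return float(p)
    wt = res.wald_test(np.array([[1.0 if c == t else 0.0 for c in X.columns] for t in terms]),
                       use_f=False, scalar=True)
    return float(wt.pvalue)
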