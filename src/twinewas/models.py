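"""Logistic covariate models and ANOVA variance explained.

Per-bin and joint logistic regressions of CWP status on standardized bin
methylation with epidemiological covariates: age, BMI, cotwin affection
status (absorbing familial dependence — the only "modification" the twin
design needs at this stage), smoking (coded ever/never) and the four
measured white-blood-cell subtype counts. Complete-case per model, with the
n actually used reported (smoking and WBC counts are known only for
subsets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InputError

__all__ = ["LogisticFit", "logistic_cwp", "joint_logistic", "anova_variance_explained"]

KNOWN_COVARIATES = ("age", "bmi", "cotwin_status", "smoking", "wbc4")
_WBC = ("neut", "eos", "mono", "lymph")


@dataclass
class LogisticFit:
    """Per-term results of a maximum-likelihood logistic fit."""

    terms: pd.DataFrame  # columns: estimate, se, z, p
    n_used: int
    converged: bool
    loglik: float

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise InputError("constant predictor: coefficient undefined")
    return (x - x.mean()) / s


def _covariate_frame(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    unknown = set(covariates) - set(KNOWN_COVARIATES)
    if unknown:
        raise InputError(f"unknown covariates: {sorted(unknown)}")
    out = pd.DataFrame(index=cohort.index)
    if "age" in covariates:
        out["age"] = cohort["age"].astype(float)
    if "bmi" in covariates:
        out["bmi"] = cohort["bmi"].astype(float)
    if "cotwin_status" in covariates:
        out["cotwin_status"] = cohort["cotwin_cwp"].astype(float)
    if "smoking" in covariates:
        smk = cohort["smoking"].astype(str)
        ever = smk.isin(["ex", "current"]).astype(float)
        ever[~smk.isin(["ex", "current", "never"])] = np.nan
        out["smoking_ever"] = ever
    if "wbc4" in covariates:
        for c in _WBC:
            out[c] = cohort[c].astype(float)
    return out


def _fit_logit(y: np.ndarray, x: pd.DataFrame) -> LogisticFit:
    design = sm.add_constant(x, has_constant="add")
    mat = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient (collinear or constant predictors)"
        )
    model = sm.Logit(y, design)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-10)
            converged = bool(res.mle_retvals.get("converged", False))
            # perfect separation shows up as exploding coefficients
            if np.any(np.abs(res.params) > 1e3):
                converged = False
        except Exception:
            raise InputError("logistic fit failed (possible perfect separation)")
    terms = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )
    return LogisticFit(
        terms=terms, n_used=int(len(y)), converged=converged, loglik=float(res.llf)
    )


def _prepare(
    bin_values: pd.DataFrame, cohort: pd.DataFrame, covariates, standardize=True
) -> tuple[np.ndarray, pd.DataFrame]:
    cohort = cohort[cohort["visit"] == 1].set_index("sample_id")
    common = bin_values.index.intersection(cohort.index)
    cohort = cohort.loc[common]
    x = _covariate_frame(cohort, covariates)
    for name in bin_values.columns:
        x.insert(0, name, bin_values.loc[common, name].to_numpy(dtype=float))
    y = cohort["cwp"].to_numpy(dtype=float)
    keep = ~(x.isna().any(axis=1).to_numpy() | np.isnan(y))
    x, y = x.loc[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise InputError("outcome has a single class")
    n_params = x.shape[1] + 1
    if len(y) < 10 * n_params:
        warnings.warn(
            f"only {len(y)} complete cases for {n_params} parameters", stacklevel=3
        )
    # standardize methylation so coefficients are per SD
    for name in bin_values.columns:
        if standardize:
            x[name] = _standardize(x[name].to_numpy())
        elif x[name].std() == 0:
            raise InputError("constant predictor: coefficient undefined")
    return y, x


def logistic_cwp(
    bin_values: pd.Series | pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=("age", "bmi", "cotwin_status"),
    standardize: bool = True,
) -> LogisticFit:
    """Logistic regression of CWP (0/1) on one bin's standardized methylation
    plus covariates; Wald z tests per term; complete-case.

    ``standardize=False`` keeps methylation on its raw scale (coefficients
    per unit rather than per SD)."""
    if isinstance(bin_values, pd.Series):
        bin_values = bin_values.to_frame()
    y, x = _prepare(bin_values, cohort, covariates, standardize)
    return _fit_logit(y, x)


def joint_logistic(
    bin_matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=("age", "bmi", "cotwin_status"),
    standardize: bool = True,
) -> LogisticFit:
    """One logistic model containing all listed bins (<= 4 recommended) plus
    covariates; every bin term is retained regardless of significance."""
    if bin_matrix.columns.duplicated().any():
        raise CollinearityError("duplicated bins in joint model")
    y, x = _prepare(bin_matrix, cohort, covariates, standardize)
    return _fit_logit(y, x)


def anova_variance_explained(bin_values, cwp_status) -> float:
    """One-way-ANOVA eta^2: fraction of methylation variance attributable to
    affection status, SS_between / SS_total. Invariant to affine rescaling."""
    y = np.asarray(bin_values, dtype=float)
    g = np.asarray(cwp_status)
    if len(np.unique(g)) < 2:
        raise InputError("both affection groups must be non-empty")
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    if ss_total == 0:
        raise InputError("zero total variance: eta^2 undefined")
    ss_between = sum(
        len(y[g == lev]) * (y[g == lev].mean() - grand) ** 2 for lev in np.unique(g)
    )
    return float(ss_between / ss_total)
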