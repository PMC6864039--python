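"""Inclusion-weighted binary logistic regression per outcome.

Each of the four microscopic outcomes is regressed on the five normalized
contrasts.  Rows are weighted by the inverse of their class's sample fraction
to counter the heavy voxel-level class imbalance, the joint predictive power
of the contrasts is summarized by a 5-df Wald chi-square on the contrast
coefficients with a Huber-White (HC0) sandwich covariance, and goodness of fit
by McFadden's pseudo R^2 = 1 - ll_full / ll_null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .volumes import CONTRAST_COLUMNS, OUTCOMES


class SeparationWarning(UserWarning):
    """Fit looks perfectly separated or failed to converge cleanly."""


def inclusion_weights(flags: np.ndarray) -> np.ndarray:
    """Weight each row by 1 / p(class), so weighted class masses are equal."""
    y = np.asarray(flags)
    if y.ndim != 1 or len(y) == 0:
        raise ValueError("flags must be a non-empty 1-D binary vector")
    p_pos = float((y == 1).mean())
    if p_pos in (0.0, 1.0):
        raise ValueError("both classes must be present to compute inclusion weights")
    return np.where(y == 1, 1.0 / p_pos, 1.0 / (1.0 - p_pos))


@dataclass
class LogitFit:
    outcome: str
    coefficients: np.ndarray  # intercept first, then 5 contrast terms
    robust_se: np.ndarray
    cov_robust: np.ndarray
    loglik_full: float
    loglik_null: float
    pseudo_r2: float
    wald_chi2: float
    wald_p: float
    n_obs: int
    converged: bool


def fit_weighted_logit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    outcome: str = "",
) -> LogitFit:
    """Maximum-likelihood weighted logit with HC0 sandwich standard errors.

    The null model (intercept only, same weights) provides ``loglik_null`` for
    McFadden's pseudo R^2.  A fit with runaway coefficients or failed
    convergence is flagged (``converged=False``) with a
    :class:`SeparationWarning` rather than silently truncated.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if w is None:
        w = np.ones(len(y))
    w = np.asarray(w, dtype=np.float64)
    # refuse a constant predictor column; the intercept is added here
    if np.any(X.std(axis=0) == 0):
        raise ValueError("X contains a constant column; the intercept is added internally")
    Xc = sm.add_constant(X, has_constant="raise")

    model = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w)
    res = model.fit(maxiter=100, tol=1e-8, cov_type="HC0")
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), var_weights=w)
    res0 = null.fit(maxiter=100, tol=1e-10)

    converged = bool(res.converged) and float(np.max(np.abs(res.params))) < 50.0
    if not converged:
        warnings.warn(
            f"logit fit for outcome {outcome or '?'} did not converge cleanly "
            "(possible perfect separation)",
            SeparationWarning,
            stacklevel=2,
        )

    cov = np.asarray(res.cov_params())
    llf = float(res.llf)
    lln = float(res0.llf)
    fit = LogitFit(
        outcome=outcome,
        coefficients=np.asarray(res.params),
        robust_se=np.sqrt(np.diag(cov)),
        cov_robust=cov,
        loglik_full=llf,
        loglik_null=lln,
        pseudo_r2=1.0 - llf / lln,
        wald_chi2=np.nan,
        wald_p=np.nan,
        n_obs=len(y),
        converged=converged,
    )
    fit.wald_chi2, fit.wald_p = wald_chi2(fit)
    return fit


def wald_chi2(fit: LogitFit, terms: slice = slice(1, None)) -> tuple[float, float]:
    """Joint Wald test b' V^-1 b of the selected coefficients (default: all 5 contrasts)."""
    b = np.atleast_1d(fit.coefficients[terms])
    V = np.atleast_2d(fit.cov_robust[terms, :][:, terms])
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular robust covariance; Wald statistic undefined") from exc
    stat = max(stat, 0.0)
    df = len(b)
    return stat, float(stats.chi2.sf(stat, df))


def robust_se(fit: LogitFit) -> np.ndarray:
    """Huber-White sandwich standard errors of the fitted coefficients."""
    return fit.robust_se


def screen_outcomes(fm: pd.DataFrame, outcomes=OUTCOMES) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the weighted logit for each outcome on the pooled feature matrix.

    Returns a per-outcome summary table (n, Wald chi2, p, pseudo R^2) and a
    long coefficient table (outcome x contrast, estimate and robust SE).
    """
    X = fm[list(CONTRAST_COLUMNS)].to_numpy()
    summary_rows, coef_rows = [], []
    for o in outcomes:
        y = fm[o].to_numpy()
        fit = fit_weighted_logit(X, y, inclusion_weights(y), outcome=o)
        summary_rows.append(
            {
                "outcome": o,
                "n": fit.n_obs,
                "wald_chi2": fit.wald_chi2,
                "p": fit.wald_p,
                "pseudo_r2": fit.pseudo_r2,
                "converged": fit.converged,
            }
        )
        for name, b, se in zip(CONTRAST_COLUMNS, fit.coefficients[1:], fit.robust_se[1:]):
            coef_rows.append({"outcome": o, "contrast": name, "coef": b, "robust_se": se})
    return pd.DataFrame(summary_rows), pd.DataFrame(coef_rows)
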