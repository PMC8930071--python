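"""Thin wrappers around the regression fits used throughout the pipeline.

Logistic fits go through statsmodels GLM (IRLS); the wrapper normalises the
failure modes the scan has to survive unattended — non-convergence, perfect
separation, rank deficiency — into a ``converged`` flag and a reason string
instead of exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm


@dataclass
class GLMFit:
    """A fitted logistic model (or a record of why it could not be fitted)."""

    params: pd.Series | None
    bse: pd.Series | None
    llf: float
    deviance: float
    df_resid: float
    n_params: int
    converged: bool
    reason: str = ""

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_params

    def wald(self, term: str) -> tuple[float, float, float]:
        """(beta, se, two-sided p) for one coefficient."""
        b = float(self.params[term])
        se = float(self.bse[term])
        z = b / se
        return b, se, max(2.0 * float(scipy.stats.norm.sf(abs(z))), 1e-300)


def drop_dependent_columns(x: pd.DataFrame, tol: float = 1e-8) -> tuple[pd.DataFrame, list[str]]:
    """Remove linearly dependent columns (QR with pivoting); returns kept df + dropped names."""
    arr = x.to_numpy(dtype=float)
    if arr.shape[1] == 0:
        return x, []
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = tol * (diag[0] if diag.size else 1.0)
    rank = int((diag > thresh).sum())
    keep = sorted(piv[:rank])
    dropped = [x.columns[j] for j in range(arr.shape[1]) if j not in keep]
    return x.iloc[:, keep], dropped


def fit_logistic(
    y: np.ndarray,
    x: pd.DataFrame,
    add_const: bool = True,
    drop_collinear: bool = False,
) -> GLMFit:
    """Logistic regression of binary y on the columns of x."""
    if add_const:
        x = sm.add_constant(x, has_constant="add")
    dropped: list[str] = []
    if drop_collinear:
        x, dropped = drop_dependent_columns(x)
    try:
        res = sm.GLM(np.asarray(y, float), x, family=sm.families.Binomial()).fit(
            maxiter=200
        )
    except Exception as exc:  # separation / singularity inside IRLS
        return GLMFit(None, None, np.nan, np.nan, np.nan, x.shape[1], False, str(exc))
    ok = bool(np.isfinite(res.params).all() and np.isfinite(res.bse).all())
    # absurd standard errors signal quasi-separation
    if ok and np.max(np.abs(res.bse.to_numpy())) > 1e3:
        ok = False
    reason = "" if ok else "non-convergence or separation"
    if dropped:
        reason = (reason + "; " if reason else "") + f"dropped collinear: {dropped}"
    return GLMFit(
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        deviance=float(res.deviance),
        df_resid=float(res.df_resid),
        n_params=x.shape[1],
        converged=ok,
        reason=reason,
    )


def fit_ols(y: np.ndarray, x: pd.DataFrame, add_const: bool = True):
    """OLS fit returning the statsmodels results object."""
    if add_const:
        x = sm.add_constant(x, has_constant="add")
    return sm.OLS(np.asarray(y, float), x).fit()


def likelihood_ratio_test(
    fit_full: GLMFit, fit_reduced: GLMFit
) -> tuple[float, int, float]:
    """(statistic, df, p) for nested GLMs; statistic clipped at 0."""
    if not (fit_full.converged and fit_reduced.converged):
        return np.nan, 0, np.nan
    stat = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    df = int(round(fit_reduced.df_resid - fit_full.df_resid))
    if df <= 0:
        raise ValueError("models are not strictly nested (df difference <= 0)")
    return stat, df, float(scipy.stats.chi2.sf(stat, df))
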