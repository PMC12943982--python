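"""Least-squares machinery with truncated-SVD fitting and robust inference.

Slopes are the minimum-norm least-squares solution computed from a
singular value decomposition in which singular values below a relative
threshold are treated as zero.  The same effective pseudo-inverse feeds
the leverage values, the predicted (leave-one-out, PRESS) residuals and
the HC3 heteroskedasticity-consistent covariance of the slopes:

    S = (X'X)^+ X' diag(e_i^2 / (1 - h_ii)^2) X (X'X)^+

where e are ordinary residuals and h_ii hat-matrix diagonals.  Because
e_i/(1-h_ii) is exactly the predicted residual, HC3 is the sandwich
built from predicted rather than ordinary residuals.

Holdout performance measures (RMSE_HO, MAE_HO, R2_HO) are computed from
the predicted residuals, so every fit carries its own leave-one-out
cross-validation for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .dataset import DesignMatrix, Term

__all__ = [
    "FitError",
    "LeverageError",
    "FitResult",
    "Measures",
    "fit_design",
    "predicted_residuals",
    "hc3_covariance",
    "performance_measures",
    "adequacy_anova",
    "error_nullity_test",
]

#: Default relative truncation threshold for singular values.
DEFAULT_REL_TOL = 1e-10

TssConvention = Literal["auto", "centered", "uncentered"]


class FitError(ValueError):
    """The design cannot be fitted (empty, all-zero, degenerate dof)."""


class LeverageError(FitError):
    """A leverage of (numerically) 1 makes a holdout quantity undefined."""


@dataclass
class FitResult:
    """Everything downstream inference needs from one least-squares fit."""

    terms: list[Term]
    slopes: np.ndarray          # aligned with terms
    fitted: np.ndarray
    resid: np.ndarray           # ordinary residuals e
    hat: np.ndarray             # leverages h_ii
    singular_values: np.ndarray
    rank: int                   # effective rank after truncation
    n: int
    p: int
    rel_tol: float
    design: DesignMatrix = field(repr=False)

    # populated lazily
    _pred_resid: np.ndarray | None = field(default=None, repr=False)
    _hc3: np.ndarray | None = field(default=None, repr=False)

    @property
    def dof(self) -> int:
        return self.n - self.p

    @property
    def resid_sd(self) -> float:
        """sqrt(SSE / (n - p)); the residual-standard-deviation slot."""
        if self.dof <= 0:
            return float("nan")
        return float(np.sqrt(self.resid @ self.resid / self.dof))

    @property
    def pred_resid(self) -> np.ndarray:
        return predicted_residuals(self)

    @property
    def hc3_cov(self) -> np.ndarray:
        return hc3_covariance(self)

    @property
    def slope_sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.hc3_cov))

    def to_dict(self) -> dict:
        """JSON-ready summary of the fit."""
        return {
            "terms": [t.name for t in self.terms],
            "slopes": self.slopes.tolist(),
            "slope_sds_hc3": self.slope_sds.tolist(),
            "hc3_cov": self.hc3_cov.tolist(),
            "resid_sd": self.resid_sd,
            "n": self.n,
            "p": self.p,
            "dof": self.dof,
            "rank": self.rank,
        }


@dataclass
class Measures:
    """Goodness-of-fit summary; the *_ho members come from holdout residuals."""

    rmse_ho: float
    mae_ho: float
    r2_adj: float
    r2_ho: float
    r2: float
    tss_convention: str

    def to_dict(self) -> dict:
        return {
            "rmse_ho": self.rmse_ho,
            "mae_ho": self.mae_ho,
            "r2_adj": self.r2_adj,
            "r2_ho": self.r2_ho,
            "r2": self.r2,
            "tss_convention": self.tss_convention,
        }


def fit_design(design: DesignMatrix, rel_tol: float = DEFAULT_REL_TOL) -> FitResult:
    """Minimum-norm least squares via SVD with relative truncation.

    Singular values below ``rel_tol * s_max`` are treated as zero, which
    keeps rank-deficient designs (duplicated or collinear columns)
    well-defined without ever forming normal equations.
    """
    X, y = design.values, design.response
    if X.size == 0 or X.shape[0] == 0:
        raise FitError("empty design matrix")
    if not np.any(X):
        raise FitError("all-zero design matrix")
    n, p = X.shape

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > rel_tol * s[0]
    rank = int(np.count_nonzero(keep))
    Ur, sr, Vr = U[:, keep], s[keep], Vt[keep].T

    slopes = Vr @ ((Ur.T @ y) / sr)
    fitted = X @ slopes
    resid = y - fitted
    hat = np.einsum("ij,ij->i", Ur, Ur)  # diag(U_r U_r')

    return FitResult(
        terms=list(design.terms),
        slopes=slopes,
        fitted=fitted,
        resid=resid,
        hat=np.clip(hat, 0.0, 1.0),
        singular_values=s,
        rank=rank,
        n=n,
        p=p,
        rel_tol=rel_tol,
        design=design,
    )


def predicted_residuals(fit: FitResult) -> np.ndarray:
    """Predicted (holdout) residuals e_i / (1 - h_ii).

    Each entry equals the prediction error on record i of the model
    refitted with record i left out (the PRESS identity).
    """
    if fit._pred_resid is None:
        bad = np.flatnonzero(fit.hat >= 1.0 - fit.rel_tol)
        if bad.size:
            ids = [fit.design.record_ids[i] if fit.design.record_ids else int(i) for i in bad]
            raise LeverageError(
                f"leverage ~ 1 for record(s) {ids}: holdout prediction undefined"
            )
        fit._pred_resid = fit.resid / (1.0 - fit.hat)
    return fit._pred_resid


def hc3_covariance(fit: FitResult) -> np.ndarray:
    """HC3 sandwich covariance of the slopes (symmetrized)."""
    if fit._hc3 is None:
        X = fit.design.values
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        keep = s > fit.rel_tol * s[0]
        Vr, sr = Vt[keep].T, s[keep]
        xtx_inv = (Vr / sr**2) @ Vr.T  # pseudo-inverse of X'X
        omega = predicted_residuals(fit) ** 2
        bread = xtx_inv @ X.T
        S = (bread * omega) @ bread.T
        fit._hc3 = (S + S.T) / 2.0
    return fit._hc3


def _tss(fit: FitResult, convention: TssConvention) -> tuple[float, int, str]:
    """Total sum of squares and the centering constant c.

    ``auto`` centers when an intercept term is present and uses the raw
    (uncentered) sum of squares otherwise, so that R2 compares the model
    against its natural null (mean-only vs zero).
    """
    y = fit.design.response
    if convention == "auto":
        convention = "centered" if fit.design.has_intercept else "uncentered"
    if convention == "centered":
        return float(np.sum((y - y.mean()) ** 2)), 1, "centered"
    return float(np.sum(y**2)), 0, "uncentered"


def performance_measures(fit: FitResult, tss: TssConvention = "auto") -> Measures:
    """Holdout RMSE/MAE and the two coefficients of determination."""
    e = fit.resid
    e_tilde = predicted_residuals(fit)
    tss_val, c, used = _tss(fit, tss)
    if tss_val <= 0:
        raise FitError("total sum of squares is zero: R2 undefined")
    r2 = 1.0 - float(e @ e) / tss_val
    if fit.dof <= 0:
        raise FitError("n <= p: adjusted R2 undefined")
    r2_adj = 1.0 - (1.0 - r2) * (fit.n - c) / fit.dof
    return Measures(
        rmse_ho=float(np.sqrt(np.mean(e_tilde**2))),
        mae_ho=float(np.mean(np.abs(e_tilde))),
        r2_adj=r2_adj,
        r2_ho=1.0 - float(e_tilde @ e_tilde) / tss_val,
        r2=r2,
        tss_convention=used,
    )


def adequacy_anova(fit: FitResult, tss: TssConvention = "auto") -> float:
    """Overall-F p-value of the fitted model against its null model.

    Without an intercept the null model predicts zero and the numerator
    has p degrees of freedom; with an intercept the null is the mean-only
    model and the numerator has p - 1.
    """
    tss_val, c, _ = _tss(fit, tss)
    sse = float(fit.resid @ fit.resid)
    df_num = fit.p - c
    df_den = fit.dof
    if df_num <= 0 or df_den <= 0:
        raise FitError("degenerate degrees of freedom for the adequacy test")
    if sse <= 0:
        return 0.0
    f = ((tss_val - sse) / df_num) / (sse / df_den)
    return float(stats.f.sf(f, df_num, df_den))


def error_nullity_test(fit: FitResult) -> float:
    """Two-sided one-sample t-test that the mean predicted residual is zero."""
    e_tilde = predicted_residuals(fit)
    if fit.n < 2:
        raise FitError("need n >= 2 for the nullity test")
    if np.std(e_tilde, ddof=1) == 0:
        return 1.0 if np.mean(e_tilde) == 0 else 0.0
    return float(stats.ttest_1samp(e_tilde, 0.0).pvalue)
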