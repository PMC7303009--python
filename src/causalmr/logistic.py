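"""Logistic regression via iteratively reweighted least squares.

The association analyses (family history, genetic risk score, per-variant
scan) all reduce to logistic fits with Wald standard errors.  The fitter is
deliberately small and explicit: convergence is declared on the relative
change in log-likelihood (tolerance 1e-8, at most 25 iterations), standard
errors come from the inverse observed information, and the two common
failure modes — rank-deficient designs and complete separation — are
reported rather than silently returning arbitrary coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = ["LogisticFit", "fit_logistic", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; message names the offending column."""


@dataclass
class LogisticFit:
    """Coefficients on the log-odds scale with Wald inference."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    converged: bool
    separation: bool
    n_iterations: int
    llf: float
    nobs: int
    cov: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def conf_int(self, name: str, z: float = 1.959964) -> tuple[float, float]:
        i = self.names.index(name)
        return (float(self.params[i] - z * self.bse[i]), float(self.params[i] + z * self.bse[i]))

    def odds_ratio(self, name: str, z: float = 1.959964) -> tuple[float, float, float]:
        """(point, lower, upper) odds ratio for one term at the 95% level."""
        lo, hi = self.conf_int(name, z)
        return (float(np.exp(self.coef(name))), float(np.exp(lo)), float(np.exp(hi)))

    def summary(self) -> str:
        lines = [f"Logistic regression ({self.nobs} obs, "
                 f"{'converged' if self.converged else 'NOT converged'}"
                 f"{', separation detected' if self.separation else ''})",
                 f"{'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'p':>12}"]
        for i, name in enumerate(self.names):
            lines.append(f"{name:<16}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                         f"{self.zvalues[i]:>8.2f}{self.pvalues[i]:>12.3g}")
        return "\n".join(lines)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted QR exposes which column is linearly dependent on the others
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise RankDeficientError(
            f"design matrix is rank deficient: column {names[piv[bad[0]]]!r} "
            "is collinear with the others"
        )


def fit_logistic(
    y,
    X,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Fit ``P(y=1) = expit(X beta)`` by IRLS.

    ``X`` must already contain the intercept column.  Complete separation
    (all fitted probabilities numerically 0 or 1) is flagged and the fit
    marked non-converged instead of reporting diverging coefficients.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("one name per design column required")
    if y.shape[0] != n:
        raise ValueError("y and X must have the same number of rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than predictors ({p})")
    _check_rank(X, list(names))

    beta = np.zeros(p)
    # starting intercept from the marginal prevalence speeds convergence
    const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
    ybar = y.mean()
    if const_cols.size and 0.0 < ybar < 1.0:
        c = const_cols[0]
        beta[c] = np.log(ybar / (1.0 - ybar)) / X[0, c]

    llf = -np.inf
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # complete separation: every fitted probability is numerically 0/1
        if np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            separation = True
            break
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        xtwx = X.T @ wx
        xtwz = wx.T @ z
        try:
            beta = linalg.solve(xtwx, xtwz, assume_a="pos")
        except linalg.LinAlgError:
            break
        eta_new = np.clip(X @ beta, -30.0, 30.0)
        mu_new = 1.0 / (1.0 + np.exp(-eta_new))
        llf_new = float(np.sum(y * np.log(mu_new + 1e-300) + (1 - y) * np.log(1 - mu_new + 1e-300)))
        if np.isfinite(llf) and abs(llf_new - llf) <= tol * (abs(llf) + 1e-12):
            llf = llf_new
            converged = True
            break
        llf = llf_new

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if not converged and np.all((mu < 1e-6) | (mu > 1 - 1e-6)):
        separation = True
    w = mu * (1.0 - mu)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = linalg.inv(xtwx)
    except linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if separation:
        converged = False
    bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zv = np.where(bse > 0, beta / bse, np.nan)
    pv = 2.0 * stats.norm.sf(np.abs(zv))
    return LogisticFit(
        names=list(names), params=beta, bse=bse, zvalues=zv, pvalues=pv,
        converged=converged, separation=separation, n_iterations=it,
        llf=llf, nobs=n, cov=cov,
    )
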