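"""Two-sample Mendelian randomization estimators.

Given per-variant associations with an exposure (beta_X, se_X) and an
outcome (beta_Y, se_Y), each variant supplies a Wald ratio
theta_j = beta_Yj / beta_Xj, and the estimators combine them:

* ``IVW`` — inverse-variance weighted average of the ratios, identical to
  weighted regression of beta_Y on beta_X through the origin with weights
  1/se_Y^2.  Fixed-effects SE is (sum w_j)^(-1/2); the default multiplicative
  random-effects model inflates it by max(1, sqrt(Q/(J-1))) where Q is
  Cochran's heterogeneity statistic.
* ``CorrelatedIVW`` — generalized least squares for correlated (cis)
  instruments: with Omega_ij = se_Yi se_Yj rho_ij,
  theta = (x' Omega^-1 x)^-1 x' Omega^-1 y.
* ``MREgger`` — the same weighted regression with an unconstrained
  intercept after orienting every variant to a positive exposure
  association; the intercept estimates average directional pleiotropy and
  its test is the standard check of the exclusion restriction.
* ``WeightedMedian`` — the weighted median of the ratio estimates,
  consistent when valid instruments carry at least half the weight; its SE
  comes from a seeded parametric bootstrap.
* ``MultivariableIVW`` — joint weighted regression of beta_Y on several
  exposures' beta_X columns, attributing effects among correlated
  risk factors (e.g. the lipid fractions) that share instruments.

Every ``fit`` returns an :class:`MREstimate` carrying the log-odds causal
effect, its SE, the 95% CI and p-value on the odds-ratio scale, and method
diagnostics (heterogeneity Q, Egger intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .sumstats import HarmonizedInstrumentSet, MVInstrumentSet

__all__ = [
    "MREstimate",
    "IVW",
    "CorrelatedIVW",
    "MREgger",
    "WeightedMedian",
    "MultivariableIVW",
    "ratio_estimates",
    "ivw",
    "ivw_correlated",
    "egger",
    "weighted_median",
    "multivariable_ivw",
    "to_odds_scale",
    "se_from_or_ci",
    "Z95",
]

#: 97.5% normal quantile, hard-coded so CI digits are reproducible.
Z95 = 1.959964


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float, float]:
    """Map (log-odds effect, SE) to (OR, 95% LCL, 95% UCL, two-sided p)."""
    if se <= 0:
        raise ValueError("se must be positive")
    or_point = float(np.exp(beta))
    lcl = float(np.exp(beta - Z95 * se))
    ucl = float(np.exp(beta + Z95 * se))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return or_point, lcl, ucl, max(p, np.nextafter(0, 1))


def se_from_or_ci(or_point: float, lcl: float, ucl: float) -> tuple[float, float]:
    """Invert a printed OR (CI) back to (beta, se); round-trip of to_odds_scale."""
    beta = float(np.log(or_point))
    se = float((np.log(ucl) - np.log(lcl)) / (2.0 * Z95))
    return beta, se


@dataclass
class MREstimate:
    """A causal-effect estimate with odds-ratio-scale reporting.

    ``beta`` is the log odds of the outcome per unit of the exposure;
    ``egger_*`` fields are populated for the Egger method only, where the
    intercept is also reported exponentiated (``egger_intercept_or``) to
    match the convention of printing intercepts as OR-scale values near 1.
    """

    method: str
    beta: float
    se: float
    n_variants: int
    or_point: float = field(init=False)
    or_lcl: float = field(init=False)
    or_ucl: float = field(init=False)
    pvalue: float = field(init=False)
    exposure: str = "exposure"
    outcome: str = "outcome"
    heterogeneity_Q: float | None = None
    Q_df: int | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    variant_id: str | None = None  # for single-variant / ratio reporting

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        self.or_point, self.or_lcl, self.or_ucl, self.pvalue = to_odds_scale(self.beta, self.se)

    @property
    def egger_intercept_or(self) -> float | None:
        if self.egger_intercept is None:
            return None
        return float(np.exp(self.egger_intercept))

    def set_pvalue(self, p: float) -> None:
        """Override the normal-tail p (used for bootstrap-based methods)."""
        self.pvalue = float(min(max(p, np.nextafter(0, 1)), 1.0))

    def summary(self) -> str:
        lines = [
            f"Method: {self.method}  ({self.exposure} -> {self.outcome}, "
            f"J={self.n_variants})",
            f"  log-odds effect: {self.beta:.4f} (SE {self.se:.4f})",
            f"  OR (95% CI): {self.or_point:.2f} ({self.or_lcl:.2f}-{self.or_ucl:.2f})",
            f"  p-value: {self.pvalue:.3g}",
        ]
        if self.heterogeneity_Q is not None:
            lines.append(f"  heterogeneity Q: {self.heterogeneity_Q:.2f} on {self.Q_df} df")
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept: {self.egger_intercept:.4f} "
                f"(SE {self.egger_intercept_se:.4f}, p {self.egger_intercept_p:.3g}; "
                f"OR scale {self.egger_intercept_or:.2f})"
            )
        return "\n".join(lines)


class _MRModel:
    """Base class: holds the harmonized instrument set."""

    min_variants = 1

    def __init__(self, data: HarmonizedInstrumentSet):
        if data.n_variants < self.min_variants:
            raise ValueError(
                f"{type(self).__name__} requires at least {self.min_variants} variants, "
                f"got {data.n_variants}"
            )
        self.data = data


class IVW(_MRModel):
    """Inverse-variance weighted estimator for independent instruments."""

    def fit(self, effects_model: str = "random") -> MREstimate:
        if effects_model not in ("fixed", "random"):
            raise ValueError("effects_model must be 'fixed' or 'random'")
        d = self.data
        nz = d.beta_exposure != 0
        if not nz.any():
            raise ValueError("all exposure effects are zero; IVW undefined")
        bx, by, sy = d.beta_exposure[nz], d.beta_outcome[nz], d.se_outcome[nz]
        w = bx**2 / sy**2
        theta_j = by / bx
        theta = float(np.sum(w * theta_j) / np.sum(w))
        se_fixed = float(np.sum(w)) ** -0.5
        J = bx.size
        Q = float(np.sum(w * (theta_j - theta) ** 2))
        se = se_fixed
        if effects_model == "random" and J > 1:
            se = se_fixed * max(1.0, np.sqrt(Q / (J - 1)))
        return MREstimate(
            method=f"ivw_{'fe' if effects_model == 'fixed' else 're'}",
            beta=theta, se=se, n_variants=J,
            exposure=d.exposure_label, outcome=d.outcome_label,
            heterogeneity_Q=Q, Q_df=max(J - 1, 0),
        )


class CorrelatedIVW(_MRModel):
    """GLS-based IVW for correlated (cis-region) instruments.

    The outcome covariance is Omega_ij = se_Yi se_Yj rho_ij with rho the
    signed LD correlation; the estimate is the GLS slope of beta_Y on beta_X
    through the origin.  Near-singular correlation matrices are eigenvalue-
    clipped at 1e-8; a condition number above 1e8 after that is an error
    advising instrument pruning.
    """

    max_condition = 1e8

    def fit(self) -> MREstimate:
        d = self.data
        rho = d.correlation if d.correlation is not None else np.eye(d.n_variants)
        evals, evecs = linalg.eigh(rho)
        if evals.min() < 1e-8:
            evals = np.clip(evals, 1e-8, None)
            rho = evecs @ np.diag(evals) @ evecs.T
        omega = np.outer(d.se_outcome, d.se_outcome) * rho
        cond = np.linalg.cond(omega)
        if cond > self.max_condition:
            raise ValueError(
                f"outcome covariance is ill-conditioned (condition number {cond:.2e} "
                f"> {self.max_condition:.0e}); prune highly correlated instruments"
            )
        x, y = d.beta_exposure, d.beta_outcome
        oi_x = linalg.solve(omega, x, assume_a="pos")
        precision = float(x @ oi_x)
        theta = float(oi_x @ y) / precision
        se = precision**-0.5
        return MREstimate(
            method="ivw_correlated", beta=theta, se=se, n_variants=d.n_variants,
            exposure=d.exposure_label, outcome=d.outcome_label,
        )


class MREgger(_MRModel):
    """MR-Egger regression: causal slope plus directional-pleiotropy intercept."""

    min_variants = 3

    def fit(self, constrain_intercept: bool = False) -> MREstimate:
        d = self.data
        sign = np.where(d.beta_exposure < 0, -1.0, 1.0)
        bx = sign * d.beta_exposure
        by = sign * d.beta_outcome
        sy = d.se_outcome
        if np.ptp(bx) == 0:
            raise ValueError("all exposure effects equal after orientation; Egger slope unidentified")
        w = 1.0 / sy**2
        if constrain_intercept:
            X = bx[:, None]
            names = ["slope"]
        else:
            X = np.column_stack([np.ones_like(bx), bx])
            names = ["intercept", "slope"]
        xtwx = X.T @ (X * w[:, None])
        coef = linalg.solve(xtwx, X.T @ (w * by), assume_a="pos")
        resid = by - X @ coef
        J, k = X.shape
        Q = float(np.sum(w * resid**2))
        phi = max(1.0, Q / (J - k)) if J > k else 1.0
        cov = linalg.inv(xtwx) * phi
        i_slope = names.index("slope")
        est = MREstimate(
            method="egger", beta=float(coef[i_slope]), se=float(np.sqrt(cov[i_slope, i_slope])),
            n_variants=J, exposure=d.exposure_label, outcome=d.outcome_label,
            heterogeneity_Q=Q, Q_df=J - k,
        )
        if not constrain_intercept:
            a, sa = float(coef[0]), float(np.sqrt(cov[0, 0]))
            est.egger_intercept = a
            est.egger_intercept_se = sa
            est.egger_intercept_p = float(2.0 * stats.norm.sf(abs(a) / sa))
        return est


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative-midpoint quantile at 1/2."""
    order = np.argsort(theta)
    th = theta[order]
    wn = w[order] / w.sum()
    p = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, p, th))


class WeightedMedian(_MRModel):
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratio estimates are ordered and the weighted median taken at cumulative
    weight 1/2 with linear interpolation, using normalized inverse-variance
    weights w_j = beta_Xj^2 / se_Yj^2.  The SE resamples beta_X and beta_Y
    from their reported normal sampling distributions; the seed is mandatory
    so results are reproducible.
    """

    min_variants = 3

    def fit(self, n_boot: int = 10_000, seed: int | None = None) -> MREstimate:
        if seed is None:
            raise ValueError("weighted median requires an explicit bootstrap seed")
        d = self.data
        if np.any(d.se_exposure <= 0):
            raise ValueError("se_exposure required for the parametric bootstrap")
        theta_j = d.beta_outcome / d.beta_exposure
        w = d.beta_exposure**2 / d.se_outcome**2
        point = _weighted_median_point(theta_j, w)

        rng = np.random.default_rng(seed)
        bx = rng.normal(d.beta_exposure, d.se_exposure, size=(n_boot, d.n_variants))
        by = rng.normal(d.beta_outcome, d.se_outcome, size=(n_boot, d.n_variants))
        th = by / bx
        wb = bx**2 / d.se_outcome**2
        order = np.argsort(th, axis=1)
        th = np.take_along_axis(th, order, axis=1)
        wb = np.take_along_axis(wb, order, axis=1)
        wb = wb / wb.sum(axis=1, keepdims=True)
        p = np.cumsum(wb, axis=1) - wb / 2.0
        # vectorized linear interpolation of each row's quantile at 0.5
        idx = np.sum(p < 0.5, axis=1)
        boots = np.empty(n_boot)
        lo_edge = idx == 0
        hi_edge = idx == d.n_variants
        mid = ~(lo_edge | hi_edge)
        boots[lo_edge] = th[lo_edge, 0]
        boots[hi_edge] = th[hi_edge, -1]
        rows = np.nonzero(mid)[0]
        i1 = idx[mid]
        i0 = i1 - 1
        p0, p1 = p[rows, i0], p[rows, i1]
        t0, t1 = th[rows, i0], th[rows, i1]
        frac = np.where(p1 > p0, (0.5 - p0) / (p1 - p0), 0.0)
        boots[rows] = t0 + frac * (t1 - t0)
        se = float(np.std(boots, ddof=1))
        return MREstimate(
            method="weighted_median", beta=point, se=se, n_variants=d.n_variants,
            exposure=d.exposure_label, outcome=d.outcome_label,
        )


class MultivariableIVW:
    """Multivariable MR: joint weighted regression on K exposures, no intercept."""

    def __init__(self, data: MVInstrumentSet):
        if data.n_variants <= data.n_exposures:
            raise ValueError("multivariable MR needs more variants than exposures (J > K)")
        self.data = data

    def fit(self) -> list[MREstimate]:
        d = self.data
        X = d.beta_exposures
        w = 1.0 / d.se_outcome**2
        xtwx = X.T @ (X * w[:, None])
        evals = linalg.eigvalsh(xtwx)
        if evals.min() <= evals.max() * 1e-10:
            # identify a collinear column by pivoted QR on the weighted design
            _, r, piv = linalg.qr(X * np.sqrt(w)[:, None], mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            bad = int(piv[np.argmin(diag)])
            raise ValueError(
                f"exposure matrix is rank deficient: column {d.exposure_labels[bad]!r} "
                "is collinear with the others"
            )
        coef = linalg.solve(xtwx, X.T @ (w * d.beta_outcome), assume_a="pos")
        resid = d.beta_outcome - X @ coef
        J, K = X.shape
        Q = float(np.sum(w * resid**2))
        phi = max(1.0, Q / (J - K))
        cov = linalg.inv(xtwx) * phi
        out = []
        for k, label in enumerate(d.exposure_labels):
            out.append(MREstimate(
                method="multivariable", beta=float(coef[k]), se=float(np.sqrt(cov[k, k])),
                n_variants=J, exposure=label, outcome=d.outcome_label,
                heterogeneity_Q=Q, Q_df=J - K,
            ))
        return out


# ---------------------------------------------------------------------------
# Functional wrappers


def ratio_estimates(data: HarmonizedInstrumentSet) -> tuple[list[MREstimate], list[str]]:
    """Per-variant Wald ratios with first-order SEs.

    Variants with a zero exposure effect are skipped; their IDs come back in
    the second element.
    """
    out: list[MREstimate] = []
    skipped: list[str] = []
    for j, vid in enumerate(data.variant_ids):
        bx = data.beta_exposure[j]
        if bx == 0:
            skipped.append(vid)
            continue
        out.append(MREstimate(
            method="ratio",
            beta=float(data.beta_outcome[j] / bx),
            se=float(data.se_outcome[j] / abs(bx)),
            n_variants=1,
            exposure=data.exposure_label, outcome=data.outcome_label,
            variant_id=vid,
        ))
    return out, skipped


def ivw(data: HarmonizedInstrumentSet, effects_model: str = "random") -> MREstimate:
    return IVW(data).fit(effects_model=effects_model)


def ivw_correlated(data: HarmonizedInstrumentSet) -> MREstimate:
    return CorrelatedIVW(data).fit()


def egger(data: HarmonizedInstrumentSet) -> MREstimate:
    return MREgger(data).fit()


def weighted_median(data: HarmonizedInstrumentSet, n_boot: int = 10_000,
                    seed: int | None = None) -> MREstimate:
    return WeightedMedian(data).fit(n_boot=n_boot, seed=seed)


def multivariable_ivw(data: MVInstrumentSet) -> list[MREstimate]:
    return MultivariableIVW(data).fit()


def single_variant_estimate(data: HarmonizedInstrumentSet) -> MREstimate:
    """Per-allele outcome association for a single-instrument exposure."""
    if data.n_variants != 1:
        raise ValueError("single_variant_estimate requires exactly one variant")
    est = MREstimate(
        method="single_variant",
        beta=float(data.beta_outcome[0]), se=float(data.se_outcome[0]),
        n_variants=1, exposure=data.exposure_label, outcome=data.outcome_label,
        variant_id=data.variant_ids[0],
    )
    return est


def plot_instruments(data: HarmonizedInstrumentSet, estimate: MREstimate | None = None,
                     ax=None):
    """Scatter of per-variant outcome vs exposure associations with the fitted line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(data.beta_exposure, data.beta_outcome,
                xerr=Z95 * data.se_exposure, yerr=Z95 * data.se_outcome,
                fmt="o", ms=3, lw=0.6, alpha=0.7, color="tab:blue")
    if estimate is not None:
        xs = np.linspace(min(0, data.beta_exposure.min()), data.beta_exposure.max(), 50)
        ax.plot(xs, estimate.beta * xs, color="tab:red",
                label=f"{estimate.method}: {estimate.or_point:.2f}")
        ax.legend(frameon=False)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"association with {data.exposure_label}")
    ax.set_ylabel(f"association with {data.outcome_label} (log odds)")
    return ax
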