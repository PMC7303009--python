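"""Synthetic two-sample MR summary statistics and individual-level cohorts.

The summary-statistics generator draws per-variant true exposure effects
beta_Xj ~ N(0, instrument_strength^2) and forms the outcome associations

    beta_Y_hat_j = theta * beta_Xj + alpha_j + eps_Yj,
    beta_X_hat_j = beta_Xj + eps_Xj,

where theta is the causal effect, alpha_j the pleiotropic (direct) effect
of variant j on the outcome, eps_X ~ N(0, se_exposure^2), and eps_Y drawn
jointly with covariance se_Yi se_Yj rho_ij under the LD model.  Directional
pleiotropy is defined relative to the exposure-increasing allele:
alpha_j = sign(beta_Xj) * a_j with a_j ~ N(mu_alpha, sigma_alpha^2), so a
positive mu_alpha biases every Wald ratio upward regardless of how the
variant happens to be coded — exactly the violation the Egger intercept is
designed to detect, and invariant to the estimators' own re-orientation.
Violation of the InSIDE assumption is controlled explicitly:
a_j = mu_alpha + rho_I * sigma_alpha * standardize(|beta_Xj|)
    + sqrt(1 - rho_I^2) * sigma_alpha * z_j, correlating pleiotropy with
instrument strength.

Default parameters emulate the scale of a 51-variant triglycerides panel
against a ~15k-case depression outcome: instrument effects with SD 0.05 per
exposure SD, exposure SEs of 0.004 (a ~190k-sample GWAS) and outcome SEs of
0.013, which put the IVW standard error near 0.037.

The cohort generator draws genotypes Binomial(2, freq), builds a
standardized weighted risk score, and draws depression from a logistic
model; questionnaire answers are then generated *consistently with* the
drawn phenotype, so the phenotype classifier re-derives it exactly — cases
receive answers satisfying every criterion of their severity level, and
controls fail at least one criterion chosen uniformly at random.

All randomness flows from one seed through named `numpy` SeedSequence
substreams (one per generated quantity), so outputs are bit-reproducible
and adding a new stream never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import CohortTable, build_grs, compute_pcs
from .phenotype import HEART_DISEASE
from .sumstats import HarmonizedInstrumentSet, MVInstrumentSet, SummaryStatRecord

__all__ = [
    "ScenarioConfig",
    "CohortConfig",
    "simulate_sumstats",
    "simulate_mv_sumstats",
    "simulate_cohort",
    "hset_to_records",
    "questionnaire_for_status",
]

_STREAMS = {"beta_x": 0, "alpha": 1, "eps_x": 2, "eps_y": 3, "meta": 4}
_COHORT_STREAMS = {"genotypes": 0, "phenotype": 1, "questionnaire": 2, "sex": 3,
                   "famhist": 4, "config": 5}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class ScenarioConfig:
    """Generative parameters for a two-sample MR scenario.

    ``true_effect`` (theta) is the causal log-odds of outcome per exposure
    unit; ``ld_correlation`` is either an exchangeable scalar rho in [0, 1)
    or a full positive-semi-definite matrix.
    """

    n_variants: int = 51
    true_effect: float = 0.0
    instrument_strength: float = 0.05
    se_exposure: float | np.ndarray = 0.004
    se_outcome: float | np.ndarray = 0.013
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    ld_correlation: float | np.ndarray = 0.0
    seed: int = 0
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.instrument_strength <= 0:
            raise ValueError("instrument_strength must be positive")
        for name in ("se_exposure", "se_outcome"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if abs(self.inside_violation) > 1:
            raise ValueError("|inside_violation| must be <= 1")

    def ld_matrix(self) -> np.ndarray:
        J = self.n_variants
        ld = self.ld_correlation
        if np.isscalar(ld):
            rho = float(ld)
            if not 0 <= rho < 1:
                raise ValueError("exchangeable ld_correlation must be in [0, 1)")
            m = np.full((J, J), rho)
            np.fill_diagonal(m, 1.0)
            return m
        m = np.asarray(ld, dtype=float)
        if m.shape != (J, J):
            raise ValueError(f"ld matrix must be {J}x{J}")
        lam_min = float(np.linalg.eigvalsh(m).min())
        if lam_min < -1e-10:
            raise ValueError(f"ld matrix is not positive semi-definite "
                             f"(smallest eigenvalue {lam_min:.3e})")
        return m


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_sumstats(config: ScenarioConfig) -> HarmonizedInstrumentSet:
    """Draw one two-sample summary-statistics replicate.

    The returned set carries the generating truth in ``.truth`` (theta, the
    true instrument effects, the pleiotropic effects) for test assertions;
    its ``correlation`` attribute is set to the LD matrix when LD is
    present, as a GLS consumer would receive it from a reference panel.
    """
    J = config.n_variants
    sx = np.broadcast_to(np.asarray(config.se_exposure, dtype=float), (J,)).copy()
    sy = np.broadcast_to(np.asarray(config.se_outcome, dtype=float), (J,)).copy()
    ld = config.ld_matrix()

    beta_x_true = _rng(config.seed, _STREAMS["beta_x"]).normal(
        0.0, config.instrument_strength, J)

    z = _rng(config.seed, _STREAMS["alpha"]).standard_normal(J)
    rho_i = config.inside_violation
    a = (config.pleiotropy_mean
         + rho_i * config.pleiotropy_sd * _standardize(np.abs(beta_x_true))
         + np.sqrt(1.0 - rho_i**2) * config.pleiotropy_sd * z)
    alpha = np.sign(beta_x_true) * a

    eps_x = _rng(config.seed, _STREAMS["eps_x"]).standard_normal(J) * sx

    rng_y = _rng(config.seed, _STREAMS["eps_y"])
    if np.isscalar(config.ld_correlation) and float(config.ld_correlation) == 0.0:
        eps_y = rng_y.standard_normal(J) * sy
        corr_out = None
    else:
        cov = np.outer(sy, sy) * ld
        # PSD guaranteed by ld_matrix(); small jitter guards exact semidefiniteness
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(J))
        eps_y = chol @ rng_y.standard_normal(J)
        corr_out = ld

    ids = [f"rs{j + 1:06d}" for j in range(J)]
    return HarmonizedInstrumentSet(
        variant_ids=ids,
        beta_exposure=beta_x_true + eps_x,
        se_exposure=sx,
        beta_outcome=config.true_effect * beta_x_true + alpha + eps_y,
        se_outcome=sy,
        correlation=corr_out,
        exposure_label=config.exposure_label,
        outcome_label=config.outcome_label,
        truth={
            "theta": config.true_effect,
            "beta_x_true": beta_x_true,
            "alpha": alpha,
            "config": config,
        },
    )


def simulate_mv_sumstats(
    n_variants: int,
    true_effects,
    instrument_strength: float = 0.05,
    se_outcome: float | np.ndarray = 0.013,
    seed: int = 0,
    exposure_labels: list[str] | None = None,
    outcome_label: str = "outcome",
) -> MVInstrumentSet:
    """Simulate a shared-instrument panel for multivariable MR.

    Each of K exposures gets independent true instrument effects
    beta_X[:, k] ~ N(0, instrument_strength^2); the outcome association is
    beta_Y_hat = beta_X @ theta + eps_Y.  The returned set carries the truth
    for test assertions.
    """
    theta = np.asarray(true_effects, dtype=float).ravel()
    K = theta.size
    J = n_variants
    if J <= K:
        raise ValueError("need more variants than exposures")
    sy = np.broadcast_to(np.asarray(se_outcome, dtype=float), (J,)).copy()
    bx = _rng(seed, _STREAMS["beta_x"]).normal(0.0, instrument_strength, (J, K))
    eps_y = _rng(seed, _STREAMS["eps_y"]).standard_normal(J) * sy
    mv = MVInstrumentSet(
        variant_ids=[f"rs{j + 1:06d}" for j in range(J)],
        beta_exposures=bx,
        beta_outcome=bx @ theta + eps_y,
        se_outcome=sy,
        exposure_labels=exposure_labels or [f"exposure_{k + 1}" for k in range(K)],
        outcome_label=outcome_label,
    )
    mv.truth = {"theta": theta, "beta_x_true": bx}
    return mv


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]  # non-palindromic


def hset_to_records(
    hset: HarmonizedInstrumentSet,
    n_exposure: int = 190_000,
    n_outcome: int = 367_703,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Render a harmonized set as exposure and outcome record lists.

    Allele labels cycle through non-palindromic pairs and EAFs are derived
    deterministically from the variant index, so the round trip through
    ``harmonize`` is exact.
    """
    from scipy import stats

    expo, outc = [], []
    for j, vid in enumerate(hset.variant_ids):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        eaf = 0.1 + 0.8 * ((j * 37) % 100) / 100.0
        for (records, beta, se, n) in (
            (expo, hset.beta_exposure[j], hset.se_exposure[j], n_exposure),
            (outc, hset.beta_outcome[j], hset.se_outcome[j], n_outcome),
        ):
            z = abs(beta) / se
            records.append(SummaryStatRecord(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=float(beta), se=float(se), eaf=eaf,
                pvalue=float(max(2 * stats.norm.sf(z), np.nextafter(0, 1))),
                n=n,
            ))
    return expo, outc


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortConfig:
    """Generative parameters for a toy individual-level cohort.

    ``grs_effect`` is the log-odds of depression per SD of the risk score;
    ``famhist_effect`` the log-odds for parental heart disease (the emulated
    observational effect is OR 1.20); ``depression_base_rate`` the
    prevalence at score 0 without family history (4% in the emulated
    cohort).  ``severe_fraction`` splits cases into severe vs moderate
    (6228/14701 in the emulated cohort).
    """

    n_individuals: int = 10_000
    n_variants: int = 20
    allele_freqs: float | np.ndarray | None = None
    grs_weights: np.ndarray | None = None
    grs_effect: float = 0.0
    famhist_prevalence: float = 0.12
    famhist_effect: float = 0.0
    depression_base_rate: float = 0.04
    severe_fraction: float = 6228 / 14701
    male_fraction: float = 0.459
    n_pcs: int = 10
    seed: int = 0
    questionnaire: bool = True

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0 < self.depression_base_rate < 1:
            raise ValueError("depression_base_rate must be in (0,1)")
        if not 0 <= self.famhist_prevalence < 1:
            raise ValueError("famhist_prevalence must be in [0,1)")
        if not 0 <= self.severe_fraction <= 1:
            raise ValueError("severe_fraction must be in [0,1]")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if np.any(f <= 0) or np.any(f >= 1):
                raise ValueError("allele frequencies must be in (0,1)")


def questionnaire_for_status(status: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Questionnaire answers consistent with a given depression status vector.

    Cases receive answers satisfying every criterion of their level (severe
    cases answer yes to the psychiatrist item; moderate cases yes to the GP
    item and no to the psychiatrist item).  Controls fail at least one
    criterion, chosen uniformly among: no core low-mood/anhedonia week,
    longest episode under two weeks, fewer than two episodes, or no
    GP/psychiatrist contact.
    """
    n = status.shape[0]
    is_case = status != "none"
    is_severe = status == "severe"

    dep = rng.random(n) < 0.7
    anh = rng.random(n) < 0.5
    weeks = rng.integers(2, 53, n)
    periods = rng.integers(2, 10, n)
    gp = rng.random(n) < 0.4
    psych = rng.random(n) < 0.15

    # cases: enforce every needed criterion
    dep = np.where(is_case & ~anh, True, dep)
    weeks = np.where(is_case, np.maximum(weeks, 2), weeks)
    periods = np.where(is_case, np.maximum(periods, 2), periods)
    psych = np.where(is_severe, True, psych)
    psych = np.where(is_case & ~is_severe, False, psych)
    gp = np.where(is_case & ~is_severe, True, gp)

    # controls: break one criterion chosen uniformly
    broken = rng.integers(0, 4, n)
    ctrl = ~is_case
    dep = np.where(ctrl & (broken == 0), False, dep)
    anh = np.where(ctrl & (broken == 0), False, anh)
    weeks = np.where(ctrl & (broken == 1), rng.integers(0, 2, n), weeks)
    periods = np.where(ctrl & (broken == 2), rng.integers(0, 2, n), periods)
    gp = np.where(ctrl & (broken == 3), False, gp)
    psych = np.where(ctrl & (broken == 3), False, psych)
    # a control must not accidentally satisfy a full case path
    core = (dep | anh) & (weeks >= 2) & (periods >= 2)
    accidental = ctrl & core & (gp | psych)
    gp = np.where(accidental, False, gp)
    psych = np.where(accidental, False, psych)

    yn = np.array(["no", "yes"])
    return pd.DataFrame({
        "ever_depressed_week": yn[dep.astype(int)],
        "ever_anhedonia_week": yn[anh.astype(int)],
        "longest_weeks": weeks.astype(int),
        "n_periods": periods.astype(int),
        "seen_gp": yn[gp.astype(int)],
        "seen_psychiatrist": yn[psych.astype(int)],
    })


def simulate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a toy cohort with genotypes, risk score, and derived phenotypes."""
    n, m = config.n_individuals, config.n_variants
    rng_cfg = _rng(config.seed, _COHORT_STREAMS["config"])
    if config.allele_freqs is None:
        freqs = rng_cfg.uniform(0.1, 0.9, m)
    else:
        freqs = np.broadcast_to(np.asarray(config.allele_freqs, dtype=float), (m,)).copy()
    if config.grs_weights is None:
        weights = rng_cfg.standard_normal(m)
    else:
        weights = np.asarray(config.grs_weights, dtype=float)
        if weights.shape != (m,):
            raise ValueError("grs_weights must have one entry per variant")

    geno = _rng(config.seed, _COHORT_STREAMS["genotypes"]).binomial(2, freqs, (n, m)).astype(float)
    variant_ids = [f"rs{j + 1:06d}" for j in range(m)]

    try:
        grs, raw_mean, raw_sd = build_grs(geno, weights)
    except ValueError:
        # degenerate single-row or monomorphic draws: score carries no information
        grs, raw_mean, raw_sd = np.zeros(n), float((geno @ weights).mean()), 0.0

    rng_ph = _rng(config.seed, _COHORT_STREAMS["phenotype"])
    famhist = _rng(config.seed, _COHORT_STREAMS["famhist"]).random(n) < config.famhist_prevalence
    intercept = float(np.log(config.depression_base_rate / (1 - config.depression_base_rate)))
    eta = intercept + config.grs_effect * grs + config.famhist_effect * famhist.astype(float)
    p_dep = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng_ph.random(n) < p_dep
    severe = is_case & (rng_ph.random(n) < config.severe_fraction)
    status = np.where(severe, "severe", np.where(is_case, "moderate", "none"))

    sex = np.where(_rng(config.seed, _COHORT_STREAMS["sex"]).random(n) < config.male_fraction,
                   "male", "female")

    k = min(config.n_pcs, max(n - 1, 0), m)
    try:
        pcs = compute_pcs(geno, k) if k > 0 else np.empty((n, 0))
    except ValueError:
        pcs = np.empty((n, 0))
        k = 0

    ids = [f"id{i + 1:07d}" for i in range(n)]
    ind = pd.DataFrame(index=pd.Index(ids, name="individual_id"))
    ind["sex"] = sex
    ind["famhist"] = famhist
    # parental condition lists consistent with the famhist indicator
    rng_q = _rng(config.seed, _COHORT_STREAMS["questionnaire"])
    side = rng_q.integers(0, 3, n)  # 0 father, 1 mother, 2 both
    father = np.where(famhist & (side != 1), HEART_DISEASE, "")
    mother = np.where(famhist & (side != 0), HEART_DISEASE, "")
    ind["father_conditions"] = father
    ind["mother_conditions"] = mother
    ind["depression_status"] = status
    if config.questionnaire:
        q = questionnaire_for_status(status, rng_q)
        for col in q.columns:
            ind[col] = q[col].to_numpy()
    ind["grs"] = grs
    for i in range(k):
        ind[f"PC{i + 1}"] = pcs[:, i]

    genotypes = pd.DataFrame(geno, index=ind.index, columns=variant_ids)
    return CohortTable(
        individuals=ind, genotypes=genotypes,
        grs_raw_mean=raw_mean, grs_raw_sd=raw_sd,
        truth={
            "config": config, "allele_freqs": freqs, "grs_weights": weights,
            "p_depression": p_dep,
        },
    )
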