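"""Genetic risk scores, principal components, and association scans.

A genetic risk score is the weighted sum of risk-allele dosages,
standardized on the analysis sample so effects are reported per 1 SD of
score.  Ancestry structure is summarized by the leading principal
components of the column-standardized dosage matrix; association models
adjust for the first ``n_pcs`` of them.  The per-variant scan fits one
logistic model per variant (dosage + PCs) and emits records in the
summary-statistics dialect so the MR estimators can consume the output
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logistic import LogisticFit, fit_logistic
from .sumstats import SummaryStatRecord

__all__ = [
    "CohortTable",
    "build_grs",
    "compute_pcs",
    "grs_association",
    "variant_scan",
]

_SELECTORS = {
    "moderate+severe": ("moderate", "severe"),
    "moderate": ("moderate",),
    "severe": ("severe",),
}


@dataclass
class CohortTable:
    """Individual-level cohort: phenotypes/covariates plus a dosage matrix.

    ``individuals`` is indexed by individual ID and carries sex, family
    history, derived depression status, questionnaire answers, principal
    components (``PC1..PCk``) and the standardized risk score (``grs``).
    ``genotypes`` shares the index, one column per variant, dosages in
    [0, 2] with NaN for missing.
    """

    individuals: pd.DataFrame
    genotypes: pd.DataFrame
    grs_raw_mean: float | None = None
    grs_raw_sd: float | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.individuals.index.equals(self.genotypes.index):
            raise ValueError("individuals and genotypes must share the same index")
        g = self.genotypes.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(g, initial=0) < 0 or np.nanmax(g, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.individuals.columns if c.startswith("PC") and c[2:].isdigit()]

    def to_tsv(self, path) -> None:
        merged = self.individuals.join(self.genotypes)
        merged.to_csv(path, sep="\t", na_rep="NA", index_label="individual_id")

    @classmethod
    def from_tsv(cls, path, variant_prefix: str = "rs") -> "CohortTable":
        df = pd.read_csv(path, sep="\t", index_col="individual_id",
                         na_values=["NA"], keep_default_na=True)
        geno_cols = [c for c in df.columns if c.startswith(variant_prefix)]
        return cls(individuals=df.drop(columns=geno_cols), genotypes=df[geno_cols])


def build_grs(
    dosages: pd.DataFrame | np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Weighted dosage score, standardized to sample mean 0 and SD 1.

    Missing dosages are mean-imputed (to twice the observed allele
    frequency) before scoring, a deterministic convention that leaves the
    imputed individual at the variant's average contribution.  Returns
    (standardized scores, raw mean, raw SD) so the raw scale is auditable.
    """
    G = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if G.ndim != 2 or G.shape[1] != w.size:
        raise ValueError(f"need one weight per variant column; got {G.shape} vs {w.size}")
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])
    raw = G @ w
    mean = float(raw.mean())
    sd = float(raw.std(ddof=0))
    if sd == 0:
        raise ValueError("risk score has zero variance; cannot standardize")
    return (raw - mean) / sd, mean, sd


def compute_pcs(dosages: pd.DataFrame | np.ndarray, k: int) -> np.ndarray:
    """Leading k principal-component scores of the standardized dosage matrix.

    Columns are standardized to mean 0, SD 1 (monomorphic columns are
    excluded — they carry no variance).  Components are ordered by
    decreasing variance explained, with the sign convention that each
    component's largest-magnitude loading is positive.
    """
    G = np.asarray(dosages, dtype=float)
    if G.ndim != 2:
        raise ValueError("dosage matrix must be 2-D")
    n = G.shape[0]
    if k == 0:
        return np.empty((n, 0))
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_mean, idx[1])
    sd = G.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Z.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but standardized matrix has rank {rank}")
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            scores[:, i] *= -1
    return scores


def pc_variance_explained(dosages) -> np.ndarray:
    """Fraction of standardized variance carried by each component."""
    G = np.asarray(dosages, dtype=float)
    sd = G.std(axis=0, ddof=0)
    Z = (G[:, sd > 0] - G[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    s = np.linalg.svd(Z, compute_uv=False)
    lam = s**2
    return lam / lam.sum()


def _case_control(individuals: pd.DataFrame, selector: str) -> tuple[np.ndarray, np.ndarray]:
    if selector not in _SELECTORS:
        raise ValueError(f"unknown outcome selector {selector!r}; use one of {sorted(_SELECTORS)}")
    status = individuals["depression_status"].astype(str)
    case_levels = _SELECTORS[selector]
    is_case = status.isin(case_levels).to_numpy()
    # the severity level excluded by the selector is removed entirely
    in_analysis = is_case | (status == "none").to_numpy()
    return is_case, in_analysis


def grs_association(
    cohort: CohortTable,
    selector: str = "moderate+severe",
    stratum: str = "all",
    adjust_pcs: bool = True,
) -> LogisticFit:
    """Logistic association of depression with the standardized risk score.

    ``selector`` picks the case definition (individuals with the excluded
    severity level are dropped, not treated as controls); ``stratum``
    restricts to ``male``/``female``.  The score stays standardized on the
    full sample so per-SD units are comparable across strata.  PCs are
    adjusted for by default.
    """
    ind = cohort.individuals
    is_case, keep = _case_control(ind, selector)
    if stratum != "all":
        if stratum not in ("male", "female"):
            raise ValueError("stratum must be 'all', 'male' or 'female'")
        keep = keep & (ind["sex"].astype(str) == stratum).to_numpy()
    y = is_case[keep].astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    cols = [np.ones(keep.sum()), ind.loc[keep, "grs"].to_numpy(dtype=float)]
    names = ["intercept", "grs"]
    if adjust_pcs:
        for pc in cohort.pc_columns:
            cols.append(ind.loc[keep, pc].to_numpy(dtype=float))
            names.append(pc)
    X = np.column_stack(cols)
    return fit_logistic(y, X, names=names)


def variant_scan(
    cohort: CohortTable,
    variant_ids: list[str] | None = None,
    selector: str = "moderate+severe",
    adjust_pcs: bool = True,
    effect_alleles: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[SummaryStatRecord], list[str]]:
    """Per-variant logistic scan of the depression outcome.

    Each variant is fitted as dosage + intercept (+ PCs); results are
    emitted as summary-statistic records (effect per dosage allele on the
    log-odds scale).  Monomorphic variants produce a missing-beta record and
    a log entry.  ``effect_alleles`` optionally maps variant -> (effect,
    other) allele labels; synthetic defaults (A/G) are used otherwise.
    """
    ind = cohort.individuals
    is_case, keep = _case_control(ind, selector)
    y = is_case[keep].astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    ids = variant_ids if variant_ids is not None else list(cohort.genotypes.columns)
    base_cols = [np.ones(int(keep.sum()))]
    base_names = ["intercept"]
    if adjust_pcs:
        for pc in cohort.pc_columns:
            base_cols.append(ind.loc[keep, pc].to_numpy(dtype=float))
            base_names.append(pc)
    records: list[SummaryStatRecord] = []
    log: list[str] = []
    n_eff = int(keep.sum())
    for vid in ids:
        g = cohort.genotypes.loc[keep, vid].to_numpy(dtype=float)
        if np.isnan(g).any():
            g = np.where(np.isnan(g), np.nanmean(g), g)
        ea, oa = (effect_alleles or {}).get(vid, ("A", "G"))
        eaf = float(g.mean() / 2.0)
        if np.ptp(g) == 0:
            log.append(f"{vid}: monomorphic, no association estimated")
            records.append(SummaryStatRecord(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=None, se=None, eaf=eaf, n=n_eff,
            ))
            continue
        X = np.column_stack([base_cols[0], g] + base_cols[1:])
        names = ["intercept", "dosage"] + base_names[1:]
        fit = fit_logistic(y, X, names=names)
        records.append(SummaryStatRecord(
            variant_id=vid, effect_allele=ea, other_allele=oa,
            beta=fit.coef("dosage"), se=fit.se("dosage"),
            eaf=eaf, pvalue=min(max(fit.pvalue("dosage"), np.nextafter(0, 1)), 1.0),
            n=n_eff,
        ))
    return records, log
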