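"""Genotype and sample quality control.

The QC cascade mirrors standard biobank practice: variants are dropped for
low call rate (more than ``sd_multiplier`` standard deviations below the
mean call rate, one-sided) or Hardy-Weinberg disequilibrium at
MAF-stratified thresholds (1e-6 for common variants with MAF > 1%, 1e-12
for rare ones); individuals are then dropped for low call rate, outlying
heterozygosity (two-sided, 3 SD), or genetic/reported sex mismatch; finally
relatedness is pruned so that exactly one member of each kinship-connected
family remains (the lexicographically smallest ID, a deterministic
tie-break).  Every exclusion is logged with the rule, the observed statistic
and the threshold that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QCThresholds", "QCResult", "hwe_test", "qc_filter"]


@dataclass
class QCThresholds:
    """Thresholds for the QC cascade (defaults follow common practice)."""

    sd_multiplier: float = 3.0
    hwe_p_common: float = 1e-6
    hwe_p_rare: float = 1e-12
    maf_cut: float = 0.01

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        for name in ("hwe_p_common", "hwe_p_rare"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if not 0 < self.maf_cut < 0.5:
            raise ValueError("maf_cut must be in (0, 0.5)")


@dataclass
class QCResult:
    retained_variants: list[str]
    retained_individuals: list[str]
    log: pd.DataFrame  # columns: entity, id, rule, statistic, threshold


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts are computed from the estimated allele
    frequency.  Monomorphic variants carry no testable departure and return
    p = 1.  An exact test is not used: the thresholds applied downstream
    (1e-6 / 1e-12) are extreme enough that the asymptotic test suffices at
    the sample sizes simulated here.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    g = np.rint(col[~np.isnan(col)]).astype(int)
    return int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2))


def qc_filter(
    genotypes: pd.DataFrame,
    sex: pd.DataFrame | None = None,
    kinship_pairs: list[tuple[str, str]] | None = None,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Run the full QC cascade on an individuals x variants genotype table.

    ``genotypes`` holds 0/1/2 calls with NaN for missing, indexed by
    individual ID.  ``sex``, when given, is indexed likewise with
    ``reported_sex`` and ``genetic_sex`` columns.  ``kinship_pairs`` lists
    related pairs (third-degree or closer); one individual per connected
    family is retained.

    Order is fixed: variant filters, then individual filters (statistics
    recomputed on the retained variants), then relatedness pruning.
    """
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    thr = thresholds or QCThresholds()
    log_rows: list[dict] = []
    G = genotypes.astype(float)

    # --- variant filters -------------------------------------------------
    callrate_v = G.notna().mean(axis=0)
    mean_v, sd_v = float(callrate_v.mean()), float(callrate_v.std(ddof=0))
    cut_v = mean_v - thr.sd_multiplier * sd_v
    keep_variants = []
    for vid in G.columns:
        cr = float(callrate_v[vid])
        if sd_v > 0 and cr < cut_v:
            log_rows.append(dict(entity="variant", id=vid, rule="low_call_rate",
                                 statistic=cr, threshold=cut_v))
            continue
        n_aa, n_ab, n_bb = _genotype_counts(G[vid].to_numpy())
        total = n_aa + n_ab + n_bb
        if total == 0:
            log_rows.append(dict(entity="variant", id=vid, rule="all_missing",
                                 statistic=0.0, threshold=np.nan))
            continue
        freq = (2 * n_aa + n_ab) / (2 * total)
        maf = min(freq, 1 - freq)
        p_hwe = hwe_test(n_aa, n_ab, n_bb)
        p_cut = thr.hwe_p_common if maf > thr.maf_cut else thr.hwe_p_rare
        if p_hwe < p_cut:
            log_rows.append(dict(entity="variant", id=vid, rule="hwe_failure",
                                 statistic=p_hwe, threshold=p_cut))
            continue
        keep_variants.append(vid)
    G = G[keep_variants]
    if not keep_variants:
        raise ValueError("no variants remain after variant QC")

    # --- individual filters ----------------------------------------------
    callrate_i = G.notna().mean(axis=1)
    het_i = (G == 1).sum(axis=1) / G.notna().sum(axis=1).replace(0, np.nan)
    mean_cr, sd_cr = float(callrate_i.mean()), float(callrate_i.std(ddof=0))
    mean_het, sd_het = float(het_i.mean()), float(het_i.std(ddof=0))
    cut_cr = mean_cr - thr.sd_multiplier * sd_cr
    keep_individuals = []
    for iid in G.index:
        cr = float(callrate_i[iid])
        if sd_cr > 0 and cr < cut_cr:
            log_rows.append(dict(entity="individual", id=iid, rule="low_call_rate",
                                 statistic=cr, threshold=cut_cr))
            continue
        het = float(het_i[iid]) if np.isfinite(het_i[iid]) else np.nan
        if sd_het > 0 and np.isfinite(het) and abs(het - mean_het) > thr.sd_multiplier * sd_het:
            log_rows.append(dict(entity="individual", id=iid, rule="heterozygosity_outlier",
                                 statistic=het, threshold=thr.sd_multiplier * sd_het))
            continue
        if sex is not None and iid in sex.index:
            rep, gen = sex.loc[iid, "reported_sex"], sex.loc[iid, "genetic_sex"]
            if pd.notna(rep) and pd.notna(gen) and rep != gen:
                log_rows.append(dict(entity="individual", id=iid, rule="sex_mismatch",
                                     statistic=np.nan, threshold=np.nan))
                continue
        keep_individuals.append(iid)

    # --- relatedness pruning ---------------------------------------------
    keep_set = set(keep_individuals)
    if kinship_pairs:
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b in kinship_pairs
                         if a in keep_set and b in keep_set)
        for comp in nx.connected_components(g):
            survivor = min(comp, key=str)
            for iid in comp:
                if iid != survivor:
                    keep_set.discard(iid)
                    log_rows.append(dict(entity="individual", id=iid, rule="relatedness",
                                         statistic=np.nan, threshold=np.nan))
        keep_individuals = [i for i in keep_individuals if i in keep_set]

    log = pd.DataFrame(log_rows, columns=["entity", "id", "rule", "statistic", "threshold"])
    return QCResult(retained_variants=list(keep_variants),
                    retained_individuals=list(keep_individuals),
                    log=log)
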