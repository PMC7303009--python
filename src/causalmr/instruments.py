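"""Instrument selection and LD correlation matrices from a reference panel.

Cis-region analyses (e.g. variants in the *IL6R* or *CRP* gene regions) use
instruments that are only moderately correlated; candidates are filtered to
genome-wide significance and greedily pruned so no retained pair exceeds an
r-squared ceiling.  The signed pairwise correlation matrix, estimated from
a reference dosage panel, feeds the GLS-based IVW estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import SummaryStatRecord

__all__ = ["SelectionRule", "select_instruments", "correlation_matrix"]


@dataclass
class SelectionRule:
    """Significance, correlation and region constraints for selection."""

    gw_significance: float = 5e-8
    r2_max: float = 0.6
    region: tuple[str, int, int] | None = None  # (chromosome, start, end)

    def __post_init__(self) -> None:
        if not 0 < self.gw_significance <= 1:
            raise ValueError("gw_significance must be in (0,1]")
        if not 0 <= self.r2_max < 1:
            raise ValueError("r2_max must be in [0,1)")


def select_instruments(
    records: list[SummaryStatRecord],
    rule: SelectionRule,
    reference: pd.DataFrame,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Select instruments by significance then greedy LD pruning.

    Candidates are restricted to ``p <= gw_significance`` (and the region,
    when given), then visited by ascending p-value with variant-ID
    tie-break; each visited variant is retained unless its r-squared with an
    already retained variant strictly exceeds ``r2_max``.  Deterministic
    given the inputs.  Returns retained IDs plus a (variant, reason) log of
    every exclusion.
    """
    log: list[tuple[str, str]] = []
    candidates: list[SummaryStatRecord] = []
    for rec in records:
        if rec.pvalue is None:
            log.append((rec.variant_id, "missing p-value"))
            continue
        if rec.pvalue > rule.gw_significance:
            log.append((rec.variant_id, "not genome-wide significant"))
            continue
        if rule.region is not None:
            chrom, start, end = rule.region
            if rec.chromosome != str(chrom) or rec.position is None or \
                    not (start <= rec.position <= end):
                log.append((rec.variant_id, "outside region"))
                continue
        if rec.variant_id not in reference.columns:
            log.append((rec.variant_id, "absent from reference panel"))
            continue
        candidates.append(rec)

    candidates.sort(key=lambda r: (r.pvalue, r.variant_id))
    retained: list[str] = []
    for rec in candidates:
        pruned = False
        for kept in retained:
            r = _pearson(reference[rec.variant_id].to_numpy(dtype=float),
                         reference[kept].to_numpy(dtype=float))
            if r * r > rule.r2_max:
                log.append((rec.variant_id, f"r2 {r * r:.3f} with {kept} exceeds {rule.r2_max}"))
                pruned = True
                break
        if not pruned:
            retained.append(rec.variant_id)
    return retained, log


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance dosage vector in reference panel")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def correlation_matrix(
    reference: pd.DataFrame,
    variant_ids: list[str],
    psd_clip: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Signed pairwise Pearson correlation of dosage vectors.

    Missing dosages are handled pairwise-complete, which can leave the
    matrix indefinite; eigenvalues are then clipped at ``psd_clip`` and the
    repair reported via the second return value.  Requires at least two
    individuals; zero-variance variants are an error.
    """
    if len(reference) < 2:
        raise ValueError("reference panel needs at least 2 individuals")
    missing = [v for v in variant_ids if v not in reference.columns]
    if missing:
        raise KeyError(f"variants absent from reference panel: {missing}")
    J = len(variant_ids)
    mat = np.eye(J)
    for i in range(J):
        for j in range(i + 1, J):
            r = _pearson(reference[variant_ids[i]].to_numpy(dtype=float),
                         reference[variant_ids[j]].to_numpy(dtype=float))
            mat[i, j] = mat[j, i] = r
    repaired = False
    evals, evecs = np.linalg.eigh(mat)
    if evals.min() < psd_clip:
        evals = np.clip(evals, psd_clip, None)
        mat = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
        mat = (mat + mat.T) / 2.0
        repaired = True
    return mat, repaired
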