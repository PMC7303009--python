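"""Config-driven orchestration of the full analysis plan.

A plan lists exposures (each backed by summary-statistics files or a
simulation scenario), an outcome source, the estimators to run per
exposure, optional multivariable groups, and the multiplicity correction.
``run_plan`` executes every exposure — harmonize, estimate with each method
in its set, flag significance against the Bonferroni threshold — and
collects one report row per estimate plus Egger intercept rows.  Failures
abort the affected exposure with a logged reason, never the whole run.

Method routing follows the analysis design: polygenic instrument sets get
IVW, MR-Egger and the weighted median; cis-region sets with two or more
variants get the correlation-adjusted IVW using their reference panel; a
single-variant exposure is reported per allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import mr
from .assoc import CohortTable, variant_scan
from .instruments import correlation_matrix
from .simulate import ScenarioConfig, hset_to_records, simulate_mv_sumstats, simulate_sumstats
from .sumstats import (
    HarmonizedInstrumentSet,
    MVInstrumentSet,
    SummaryStatRecord,
    harmonize,
    read_sumstats,
)

__all__ = [
    "AnalysisPlan",
    "ExposureSpec",
    "ReportBundle",
    "bonferroni_threshold",
    "run_plan",
    "render_report",
    "format_pvalue",
    "format_or_ci",
]


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Family-wise threshold alpha/m, with its 1-significant-figure rounding.

    Returns ``(exact, rounded)``; e.g. (0.05, 15) -> (0.003333..., 0.003).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    exponent = math.floor(math.log10(exact))
    rounded = round(exact, -exponent)
    return exact, float(f"{rounded:.{max(-exponent, 0)}f}")


@dataclass
class ExposureSpec:
    """One exposure in the plan: data source, method set, LD panel."""

    label: str
    sumstats: str | None = None
    scenario: dict | None = None
    methods: list[str] = field(default_factory=list)
    cis: bool = False
    panel: str | None = None
    dialect: dict | None = None

    def __post_init__(self) -> None:
        if (self.sumstats is None) == (self.scenario is None):
            raise ValueError(f"exposure {self.label!r}: exactly one of sumstats/scenario required")
        if self.cis and self.panel is None and self.sumstats is not None:
            raise ValueError(f"cis exposure {self.label!r} requires a correlation panel")
        if not self.methods:
            self.methods = ["ivw_correlated"] if self.cis else ["ivw", "egger", "weighted_median"]


@dataclass
class AnalysisPlan:
    exposures: list[ExposureSpec]
    outcome_sumstats: str | None = None
    outcome_cohort: str | None = None
    outcome_dialect: dict | None = None
    multivariable: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    n_exposures_for_bonferroni: int = 15
    outcome_levels: list[str] = field(default_factory=lambda: ["moderate+severe"])
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [e.label for e in self.exposures]
        if len(set(labels)) != len(labels):
            raise ValueError("exposure labels must be unique")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisPlan":
        d = dict(d)
        exposures = [ExposureSpec(**e) for e in d.pop("exposures", [])]
        return cls(exposures=exposures, **d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """Full-precision results plus the run log."""

    results: pd.DataFrame
    threshold_exact: float
    threshold_rounded: float
    log: list[str]
    seed: int

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False, na_rep="NA")


def _method_seed(seed: int, label: str) -> int:
    import zlib

    return int((seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1))


def _load_outcome(plan: AnalysisPlan, log: list[str]) -> list[SummaryStatRecord] | None:
    if plan.outcome_sumstats is not None:
        return read_sumstats(plan.outcome_sumstats, dialect=plan.outcome_dialect)
    if plan.outcome_cohort is not None:
        cohort = CohortTable.from_tsv(plan.outcome_cohort)
        records, scan_log = variant_scan(cohort, selector=plan.outcome_levels[0])
        log.extend(scan_log)
        return [r for r in records if r.beta is not None]
    return None


def _exposure_hset(
    spec: ExposureSpec,
    outcome: list[SummaryStatRecord] | None,
    plan: AnalysisPlan,
    log: list[str],
) -> HarmonizedInstrumentSet:
    if spec.scenario is not None:
        cfg = ScenarioConfig(**{**spec.scenario, "exposure_label": spec.label,
                                "seed": spec.scenario.get("seed", _method_seed(plan.seed, spec.label))})
        hset = simulate_sumstats(cfg)
        if outcome is not None:
            log.append(f"{spec.label}: scenario carries its own outcome; plan outcome ignored")
        return hset
    if outcome is None:
        raise ValueError("file-based exposures require an outcome source in the plan")
    exp_records = read_sumstats(spec.sumstats, dialect=spec.dialect)
    hset, exclusions = harmonize(exp_records, outcome,
                                 palindrome_eaf_limit=plan.palindrome_eaf_limit,
                                 exposure_label=spec.label)
    for vid, reason in exclusions:
        log.append(f"{spec.label}: excluded {vid} ({reason})")
    return hset


def _estimate_rows(spec: ExposureSpec, hset: HarmonizedInstrumentSet,
                   plan: AnalysisPlan, log: list[str]) -> list[mr.MREstimate]:
    ests: list[mr.MREstimate] = []
    if hset.n_variants == 1:
        log.append(f"{spec.label}: single instrument; reporting per-allele association")
        ests.append(mr.single_variant_estimate(hset))
        return ests
    methods = list(spec.methods)
    if spec.cis and "ivw_correlated" not in methods:
        methods.append("ivw_correlated")
    for method in methods:
        try:
            if method == "ivw":
                ests.append(mr.ivw(hset))
            elif method == "ivw_fixed":
                ests.append(mr.ivw(hset, effects_model="fixed"))
            elif method == "egger":
                ests.append(mr.egger(hset))
            elif method == "weighted_median":
                ests.append(mr.weighted_median(hset, n_boot=plan.n_boot,
                                               seed=_method_seed(plan.seed, spec.label)))
            elif method == "ivw_correlated":
                data = hset
                if data.correlation is None and spec.panel is not None:
                    panel = pd.read_csv(spec.panel, sep="\t", index_col=0, na_values=["NA"])
                    corr, repaired = correlation_matrix(panel, hset.variant_ids)
                    if repaired:
                        log.append(f"{spec.label}: correlation matrix repaired to PSD")
                    data = HarmonizedInstrumentSet(
                        variant_ids=hset.variant_ids, beta_exposure=hset.beta_exposure,
                        se_exposure=hset.se_exposure, beta_outcome=hset.beta_outcome,
                        se_outcome=hset.se_outcome, correlation=corr,
                        exposure_label=hset.exposure_label, outcome_label=hset.outcome_label)
                ests.append(mr.ivw_correlated(data))
            else:
                log.append(f"{spec.label}: unknown method {method!r} skipped")
        except ValueError as exc:
            log.append(f"{spec.label}: method {method} failed: {exc}")
    return ests


def _rows_from_estimate(est: mr.MREstimate, threshold: float) -> list[dict]:
    rows = [dict(
        exposure=est.exposure, method=est.method, beta=est.beta, se=est.se,
        or_point=est.or_point, or_lcl=est.or_lcl, or_ucl=est.or_ucl,
        pvalue=est.pvalue, n_variants=est.n_variants,
        significant=bool(est.pvalue < threshold),
        heterogeneity_Q=est.heterogeneity_Q,
        Q_df=est.Q_df,
    )]
    if est.egger_intercept is not None:
        a, sa = est.egger_intercept, est.egger_intercept_se
        rows.append(dict(
            exposure=est.exposure, method="egger_intercept", beta=a, se=sa,
            or_point=float(np.exp(a)), or_lcl=float(np.exp(a - mr.Z95 * sa)),
            or_ucl=float(np.exp(a + mr.Z95 * sa)), pvalue=est.egger_intercept_p,
            n_variants=est.n_variants, significant=bool(est.egger_intercept_p < threshold),
            heterogeneity_Q=None, Q_df=None,
        ))
    return rows


def run_plan(plan: AnalysisPlan) -> ReportBundle:
    """Execute the analysis plan and return the report bundle."""
    log: list[str] = [f"seed={plan.seed}",
                      f"bonferroni alpha={plan.alpha} m={plan.n_exposures_for_bonferroni}"]
    exact, rounded = bonferroni_threshold(plan.alpha, plan.n_exposures_for_bonferroni)
    outcome = _load_outcome(plan, log)
    rows: list[dict] = []
    for spec in plan.exposures:
        try:
            hset = _exposure_hset(spec, outcome, plan, log)
            for est in _estimate_rows(spec, hset, plan, log):
                rows.extend(_rows_from_estimate(est, exact))
        except Exception as exc:  # per-exposure isolation
            log.append(f"{spec.label}: exposure aborted: {exc}")
    for group in plan.multivariable:
        try:
            mv = _build_mv(group, plan, outcome, log)
            for est in mr.multivariable_ivw(mv):
                rows.extend(_rows_from_estimate(est, exact))
        except Exception as exc:
            log.append(f"multivariable {group.get('label', '?')}: aborted: {exc}")
    results = pd.DataFrame(rows, columns=[
        "exposure", "method", "beta", "se", "or_point", "or_lcl", "or_ucl",
        "pvalue", "n_variants", "significant", "heterogeneity_Q", "Q_df",
    ])
    return ReportBundle(results=results, threshold_exact=exact,
                        threshold_rounded=rounded, log=log, seed=plan.seed)


def _build_mv(group: dict, plan: AnalysisPlan,
              outcome: list[SummaryStatRecord] | None, log: list[str]) -> MVInstrumentSet:
    if "scenario" in group:
        sc = dict(group["scenario"])
        sc.setdefault("seed", _method_seed(plan.seed, group.get("label", "multivariable")))
        return simulate_mv_sumstats(
            exposure_labels=group.get("exposure_labels"), **sc)
    member_labels = group["exposures"]
    specs = {s.label: s for s in plan.exposures}
    members = [specs[lbl] for lbl in member_labels]
    if outcome is None:
        raise ValueError("file-based multivariable group requires an outcome source")
    out_by_id = {r.variant_id: r for r in outcome if r.beta is not None}
    member_records = []
    for spec in members:
        if spec.sumstats is None:
            raise ValueError("multivariable members must be file-based exposures")
        recs = {r.variant_id: r for r in read_sumstats(spec.sumstats, dialect=spec.dialect)
                if r.beta is not None}
        member_records.append(recs)
    shared = set(out_by_id)
    for recs in member_records:
        shared &= set(recs)
    ids = sorted(shared)
    if len(ids) <= len(members):
        raise ValueError("too few shared variants for the multivariable model")
    log.append(f"multivariable {group.get('label', '?')}: {len(ids)} shared variants")
    bx = np.array([[member_records[k][v].beta for k in range(len(members))] for v in ids])
    return MVInstrumentSet(
        variant_ids=ids, beta_exposures=bx,
        beta_outcome=np.array([out_by_id[v].beta for v in ids]),
        se_outcome=np.array([out_by_id[v].se for v in ids]),
        exposure_labels=member_labels,
    )


# ---------------------------------------------------------------------------
# Report rendering


def format_pvalue(p: float) -> str:
    """Format p-values the way epidemiology tables print them.

    Two significant figures down to 0.001, one below that, scientific
    notation (one significant figure) below 1e-4; e.g. 0.00029 -> '0.0003',
    2.2e-5 -> '2e-05'.
    """
    if not 0 < p <= 1:
        return "NA"
    if p < 1e-4:
        return f"{p:.0e}"
    if p < 1e-3:
        return f"{p:.1g}"
    return f"{p:.2g}"


def format_or_ci(or_point: float, lcl: float, ucl: float) -> str:
    """e.g. '1.18 (1.09–1.27)' — ORs to two decimals, en-dash CI."""
    return f"{or_point:.2f} ({lcl:.2f}–{ucl:.2f})"


def render_report(bundle: ReportBundle) -> str:
    """Human-readable grouped table; full precision lives in the TSV."""
    if bundle.results.empty:
        raise ValueError("no results to render")
    lines = [
        f"{'Risk factor':<22}{'Method':<18}{'Odds ratio (95% CI)':<24}{'p-value':<10}{'sig.':<5}",
        "-" * 79,
    ]
    for exposure, grp in bundle.results.groupby("exposure", sort=False):
        for _, row in grp.iterrows():
            method = "(intercept)" if row["method"] == "egger_intercept" else row["method"]
            lines.append(
                f"{exposure:<22}{method:<18}"
                f"{format_or_ci(row['or_point'], row['or_lcl'], row['or_ucl']):<24}"
                f"{format_pvalue(row['pvalue']):<10}"
                f"{'*' if row['significant'] else '':<5}"
            )
    lines.append("-" * 79)
    lines.append(f"* p < {bundle.threshold_rounded} "
                 f"(Bonferroni 0.05-level across {bundle.results['exposure'].nunique()} "
                 f"reported exposures; threshold {bundle.threshold_exact:.6g})")
    return "\n".join(lines)
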