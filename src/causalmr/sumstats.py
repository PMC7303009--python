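"""GWAS summary statistics: records, file I/O, and allele harmonization.

Summary statistics are exchanged as tab-separated text with one header row
and ``NA`` for missing values.  Each row describes one variant's association
with one trait: effect/other allele, effect-allele frequency, effect size on
the log-odds or SD scale, its standard error, p-value and sample size.

Two-sample Mendelian randomization needs the exposure and outcome
associations expressed per the *same* allele of each variant; ``harmonize``
aligns the two sides, flipping swapped alleles, resolving strand flips, and
dropping palindromic (A/T, C/G) variants whose strand cannot be inferred
from allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "HarmonizedInstrumentSet",
    "MVInstrumentSet",
    "DialectError",
    "HarmonizationError",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "write_exclusion_report",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: Default column names; override per file via the ``dialect`` mapping.
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se")


class DialectError(ValueError):
    """A mandatory column cannot be resolved in the input header."""


class HarmonizationError(ValueError):
    """Exposure and outcome share no usable variants."""


@dataclass
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` on the log-odds
    scale (binary traits) or in SD units (quantitative traits).  ``beta``
    and ``se`` may be missing only for degenerate rows emitted by the
    variant scan (monomorphic variants); a present ``se`` must be positive.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float | None
    se: float | None
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    chromosome: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if self.se is not None and not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.variant_id}: pvalue {self.pvalue} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.variant_id}: n must be positive")
        if self.position is not None and self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in _PALINDROMIC


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effect vectors for one MR analysis.

    All vectors share length J.  ``correlation`` (signed LD r between
    instruments, estimated from a reference panel) is optional; when absent
    the instruments are treated as independent.  ``truth`` carries the
    generating parameters when the set was simulated, for test assertions
    only — estimators never read it.
    """

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    correlation: np.ndarray | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        j = len(self.variant_ids)
        if j < 1:
            raise ValueError("instrument set must contain at least one variant")
        if len(set(self.variant_ids)) != j:
            raise ValueError("variant_ids must be unique")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            v = getattr(self, name)
            if v.shape != (j,):
                raise ValueError(f"{name} must have shape ({j},), got {v.shape}")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be strictly positive")
        if self.correlation is not None:
            r = np.asarray(self.correlation, dtype=float)
            if r.shape != (j, j):
                raise ValueError(f"correlation must be {j}x{j}, got {r.shape}")
            if not np.allclose(r, r.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(r), 1.0, atol=1e-8):
                raise ValueError("correlation matrix must have unit diagonal")
            self.correlation = r

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset(self, idx: Sequence[int]) -> "HarmonizedInstrumentSet":
        idx = list(idx)
        return HarmonizedInstrumentSet(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            correlation=None if self.correlation is None else self.correlation[np.ix_(idx, idx)],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            truth=self.truth,
        )


@dataclass
class MVInstrumentSet:
    """Shared instruments for multivariable MR: J variants x K exposures."""

    variant_ids: list[str]
    beta_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_labels: list[str] = field(default_factory=list)
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, dtype=float))
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        j, k = self.beta_exposures.shape
        if not self.exposure_labels:
            self.exposure_labels = [f"exposure_{i + 1}" for i in range(k)]
        if len(self.exposure_labels) != k:
            raise ValueError("one label per exposure column required")
        if len(set(self.exposure_labels)) != k:
            raise ValueError("exposure labels must be unique")
        if j < k or k < 1:
            raise ValueError(f"need J >= K >= 1, got J={j}, K={k}")
        if self.beta_outcome.shape != (j,) or self.se_outcome.shape != (j,):
            raise ValueError("outcome vectors must have one entry per variant")
        if np.any(self.se_outcome <= 0):
            raise ValueError("se_outcome must be strictly positive")

    @property
    def n_variants(self) -> int:
        return self.beta_exposures.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]


# ---------------------------------------------------------------------------
# File I/O


def _parse_value(raw: str, kind: str):
    raw = raw.strip()
    if raw == "" or raw.upper() == "NA":
        return None
    if kind == "int":
        return int(float(raw))
    if kind == "float":
        return float(raw)
    return raw


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    return_errors: bool = False,
):
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names used in this file.  Malformed rows are rejected with
    row-indexed diagnostics; pass ``return_errors=True`` to receive them as a
    second return value (otherwise they are silently dropped from the result
    but still counted).

    Raises
    ------
    DialectError
        If a mandatory column (variant, alleles, beta, se) is absent.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in _MANDATORY:
        if names[key] not in df.columns:
            raise DialectError(
                f"mandatory column {key!r} (file column {names[key]!r}) missing from header "
                f"{list(df.columns)}"
            )
    records: list[SummaryStatRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = dict(zip(df.columns, row))

        def get(key, kind="str"):
            col = names[key]
            if col not in df.columns:
                return None
            return _parse_value(row[col], kind)

        try:
            rec = SummaryStatRecord(
                variant_id=str(get("variant_id")),
                effect_allele=str(get("effect_allele")),
                other_allele=str(get("other_allele")),
                beta=get("beta", "float"),
                se=get("se", "float"),
                eaf=get("eaf", "float"),
                pvalue=get("pvalue", "float"),
                n=get("n", "int"),
                chromosome=get("chromosome"),
                position=get("position", "int"),
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
            continue
        records.append(rec)
    if return_errors:
        return records, errors
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_sumstats(records: Iterable[SummaryStatRecord], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write records as TSV in the (possibly remapped) default dialect.

    Floats are written with ``repr`` so a write-then-read round trip is
    bit-exact for finite values.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    order = ["variant_id", "chromosome", "position", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pvalue", "n"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(names[k] for k in order) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(getattr(rec, k)) for k in order) + "\n")


def write_exclusion_report(exclusions: Sequence[tuple[str, str]], path) -> None:
    """Write dropped variants and their reasons as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_id\treason\n")
        for vid, reason in exclusions:
            fh.write(f"{vid}\t{reason}\n")


# ---------------------------------------------------------------------------
# Harmonization


def _minor_freq(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_eaf_limit: float = 0.42,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> tuple[HarmonizedInstrumentSet, list[tuple[str, str]]]:
    """Align outcome records to the exposure's effect alleles.

    For each variant shared by ID: if the outcome's alleles are swapped the
    outcome beta sign is flipped and its EAF complemented; a strand flip
    (complementary alleles) is resolved the same way.  Palindromic variants
    are kept only when both sides report an EAF whose minor-allele frequency
    is at most ``palindrome_eaf_limit`` (strand then inferred from frequency
    agreement); otherwise dropped as ambiguous.  Variants with incompatible
    allele pairs or missing effect sizes are dropped with a reason.

    Returns the harmonized set (in exposure order) and the exclusion report
    as ``(variant_id, reason)`` pairs.
    """
    if not exposure or not outcome:
        raise HarmonizationError("both exposure and outcome record lists must be non-empty")
    out_by_id = {r.variant_id: r for r in outcome}
    exclusions: list[tuple[str, str]] = []
    ids: list[str] = []
    bx, sx, by, sy = [], [], [], []
    seen: set[str] = set()
    for ex in exposure:
        vid = ex.variant_id
        if vid in seen:
            exclusions.append((vid, "duplicate exposure record"))
            continue
        seen.add(vid)
        if vid not in out_by_id:
            exclusions.append((vid, "absent from outcome"))
            continue
        ou = out_by_id[vid]
        if ex.beta is None or ex.se is None:
            exclusions.append((vid, "missing exposure effect"))
            continue
        if ou.beta is None or ou.se is None:
            exclusions.append((vid, "missing outcome effect"))
            continue

        pair_ex = (ex.effect_allele, ex.other_allele)
        pair_ou = (ou.effect_allele, ou.other_allele)
        flipped: bool | None = None
        if ex.is_palindromic or ou.is_palindromic:
            if pair_ou not in (pair_ex, pair_ex[::-1]):
                exclusions.append((vid, "allele mismatch"))
                continue
            if ex.eaf is None or ou.eaf is None:
                exclusions.append((vid, "palindromic, ambiguous strand"))
                continue
            if _minor_freq(ex.eaf) > palindrome_eaf_limit or _minor_freq(ou.eaf) > palindrome_eaf_limit:
                exclusions.append((vid, "palindromic, ambiguous strand"))
                continue
            # frequencies are informative: align by which allele is minor
            ou_eaf = ou.eaf if pair_ou == pair_ex else 1.0 - ou.eaf
            same_side = (ex.eaf < 0.5) == (ou_eaf < 0.5)
            if pair_ou == pair_ex:
                flipped = not same_side
            else:
                flipped = same_side
        else:
            comp_ou = (_COMPLEMENT[ou.effect_allele], _COMPLEMENT[ou.other_allele])
            if pair_ou == pair_ex or comp_ou == pair_ex:
                flipped = False
            elif pair_ou == pair_ex[::-1] or comp_ou == pair_ex[::-1]:
                flipped = True
            else:
                exclusions.append((vid, "allele mismatch"))
                continue
        ids.append(vid)
        bx.append(ex.beta)
        sx.append(ex.se)
        by.append(-ou.beta if flipped else ou.beta)
        sy.append(ou.se)
    if not ids:
        raise HarmonizationError(
            "no variants remain after harmonization; exclusions: "
            + "; ".join(f"{v} ({r})" for v, r in exclusions)
        )
    hset = HarmonizedInstrumentSet(
        variant_ids=ids,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
    )
    return hset, exclusions
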