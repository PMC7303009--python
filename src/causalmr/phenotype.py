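"""Derivation of the depression outcome and family-history exposure.

Probable lifetime major depression is derived from four touchscreen
questionnaire criteria: (1) ever feeling depressed/down, or anhedonic, for
at least a whole week; (2) longest such episode lasting two weeks or more;
(3) at least two such episodes; (4) having consulted a GP (moderate) or a
psychiatrist (severe) for nerves, anxiety, tension or depression.  Severe
requires criteria 1-3 plus the psychiatrist item and takes precedence over
moderate, so the two levels are disjoint.  Any answer that is missing is
treated as not satisfying its criterion, which classifies incomplete
responders as controls (a conservative, toward-the-null convention).

Family history of heart disease is a simple indicator: the participant
selected "heart disease" among the listed illnesses of father or mother.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QuestionnaireAnswers",
    "DepressionStatus",
    "classify_depression",
    "classify_depression_frame",
    "derive_family_history",
    "derive_family_history_frame",
    "HEART_DISEASE",
    "QUESTIONNAIRE_COLUMNS",
]

HEART_DISEASE = "heart disease"

DepressionStatus = str  # one of "none" | "moderate" | "severe"

#: Column names used for questionnaire fields in cohort tables.
QUESTIONNAIRE_COLUMNS = (
    "ever_depressed_week",
    "ever_anhedonia_week",
    "longest_weeks",
    "n_periods",
    "seen_gp",
    "seen_psychiatrist",
)


@dataclass
class QuestionnaireAnswers:
    """Raw answers feeding the depression classifier.

    Yes/no items are ``True``/``False`` with ``None`` for missing; counts are
    non-negative integers or ``None``.
    """

    ever_depressed_week: bool | None = None
    ever_anhedonia_week: bool | None = None
    longest_weeks: int | None = None
    n_periods: int | None = None
    seen_gp: bool | None = None
    seen_psychiatrist: bool | None = None
    father_conditions: set = field(default_factory=set)
    mother_conditions: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.longest_weeks is not None and self.longest_weeks < 0:
            raise ValueError("longest_weeks must be non-negative")
        if self.n_periods is not None and self.n_periods < 0:
            raise ValueError("n_periods must be non-negative")


def classify_depression(answers: QuestionnaireAnswers) -> DepressionStatus:
    """Classify one participant as ``none``, ``moderate`` or ``severe``."""
    core = (
        (answers.ever_depressed_week is True or answers.ever_anhedonia_week is True)
        and answers.longest_weeks is not None and answers.longest_weeks >= 2
        and answers.n_periods is not None and answers.n_periods >= 2
    )
    if not core:
        return "none"
    if answers.seen_psychiatrist is True:
        return "severe"
    if answers.seen_gp is True:
        return "moderate"
    return "none"


def _yes(col: pd.Series) -> np.ndarray:
    """Map a yes/no/missing column to a boolean 'answered yes' array."""
    if col.dtype == bool:
        return col.to_numpy()
    s = col.astype("string").str.strip().str.lower()
    return (s == "yes").fillna(False).to_numpy() | (s == "true").fillna(False).to_numpy()


def classify_depression_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorized classifier over a cohort table.

    Expects the :data:`QUESTIONNAIRE_COLUMNS`; yes/no items may be boolean or
    'yes'/'no'/'NA' strings, counts numeric with NaN for missing.
    """
    dep = _yes(df["ever_depressed_week"])
    anh = _yes(df["ever_anhedonia_week"])
    weeks = pd.to_numeric(df["longest_weeks"], errors="coerce").to_numpy()
    periods = pd.to_numeric(df["n_periods"], errors="coerce").to_numpy()
    gp = _yes(df["seen_gp"])
    psych = _yes(df["seen_psychiatrist"])
    core = (dep | anh) & (weeks >= 2) & (periods >= 2)
    status = np.where(core & psych, "severe", np.where(core & gp, "moderate", "none"))
    return pd.Series(status, index=df.index, name="depression_status")


def derive_family_history(answers: QuestionnaireAnswers) -> bool:
    """True iff 'heart disease' was selected for either parent."""
    return HEART_DISEASE in answers.father_conditions or HEART_DISEASE in answers.mother_conditions


def derive_family_history_frame(
    df: pd.DataFrame,
    father_col: str = "father_conditions",
    mother_col: str = "mother_conditions",
    sep: str = "|",
) -> pd.Series:
    """Vectorized family-history indicator over '|'-separated condition lists."""

    def has_hd(col: pd.Series) -> np.ndarray:
        s = col.astype("string").fillna("")
        return s.str.split(sep).apply(lambda items: HEART_DISEASE in [i.strip() for i in items]).to_numpy()

    return pd.Series(has_hd(df[father_col]) | has_hd(df[mother_col]),
                     index=df.index, name="famhist")
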