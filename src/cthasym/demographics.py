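"""Compound demographic scores and between-group homogeneity tests.

The two pedagogy groups (Montessori vs traditional) must be comparable on
everything except pedagogy for the asymmetry contrasts to be interpretable.
Continuous variables (age, SES, FIV, HEV) are compared with pooled-variance
Student t-tests and Cohen's d; categorical variables (sex, handedness) with
plain Pearson chi-squared on the 2x2 counts, df = 1, no continuity
correction.

Compound scores:

* SES — mean of parental education and profession levels, each on 0-4, over
  one or two parents; final score in [0, 4].
* HEV — equal-weight mean of four home-life components each expressed on
  [0, 100] (green-space access, weekly shared meals as n/7*100, parental
  interest in pedagogy, extracurricular activity); a percentage.
* FIV — count of correct answers over the 36 Raven progressive-matrices
  items; an integer in [0, 36].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

ALPHA_DEFAULT = 0.05

#: Default mapping of qualitative HEV items to percentages.
DEFAULT_HEV_SCORING: Mapping[str, float] = {
    "yes": 100.0,
    "high": 100.0,
    "no": 0.0,
    "low": 0.0,
}


def ses_score(parent_levels: Iterable[tuple[float, float]]) -> float:
    """Socioeconomic score: mean of (education, profession) levels, 0-4 each.

    ``parent_levels`` holds one or two parents.
    """
    levels = [v for pair in parent_levels for v in pair]
    if not levels:
        raise DomainError("ses_score of no parents")
    arr = np.asarray(levels, dtype=float)
    if ((arr < 0) | (arr > 4)).any():
        raise ValidationError("parental levels must lie in [0, 4]")
    return float(arr.mean())


def hev_score(components: Sequence[float]) -> float:
    """Home-environment score: equal-weight mean of four [0, 100] components."""
    arr = np.asarray(components, dtype=float)
    if arr.shape != (4,):
        raise ValidationError("hev_score expects exactly four components")
    if ((arr < 0) | (arr > 100)).any():
        raise ValidationError("HEV components must lie in [0, 100]")
    return float(arr.mean())


def meals_component(meals_per_week: int) -> float:
    """Weekly shared meals (0-7) rescaled to [0, 100]."""
    if not 0 <= meals_per_week <= 7:
        raise ValidationError("meals per week must lie in [0, 7]")
    return meals_per_week / 7 * 100


def fiv_score(answers: Sequence[bool]) -> int:
    """Fluid-intelligence score: number of correct answers over 36 items."""
    if len(answers) != 36:
        raise ValidationError(f"expected 36 items, got {len(answers)}")
    return int(sum(bool(a) for a in answers))


def pooled_t_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, Cohen's d) with df = n1 + n2 - 2 and d computed with
    the pooled SD.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise DomainError("group SDs must be positive")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    t = (m1 - m2) / (sp * np.sqrt(1 / n1 + 1 / n2))
    d = (m1 - m2) / sp
    return float(t), int(df), float(d)


def pearson_chi2_2x2(counts) -> tuple[float, int, float]:
    """Plain Pearson chi-squared on a 2x2 table, df = 1, no correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DomainError("zero marginal in the 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass(frozen=True)
class HomogeneityRow:
    variable: str
    kind: str  # "t" or "chi2"
    statistic: float | None
    df: int | None
    p: float | None
    effect_size: float | None  # Cohen's d for t rows, None for chi2 rows
    n1: int
    n2: int
    flagged: bool
    note: str = ""


_CONTINUOUS = ("age", "ses", "fiv", "hev")
_CATEGORICAL = (("sex", "female"), ("handedness", "left"))


def homogeneity_tests(
    cohort: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Between-pedagogy homogeneity table over the student cohort.

    t-tests (pooled variance, listwise per variable) on age/SES/FIV/HEV and
    Pearson chi-squared (df 1) on sex and handedness counts. Rows with
    p <= alpha are flagged. A variable entirely missing in one group is
    reported as not computable rather than raising.
    """
    students = cohort[cohort["group"] == "student"]
    groups = sorted(students["pedagogy"].dropna().unique())
    if len(groups) != 2:
        raise DomainError(f"expected two pedagogy groups, found {groups}")
    g1 = students[students["pedagogy"] == "montessori"]
    g2 = students[students["pedagogy"] == "traditional"]

    rows: list[HomogeneityRow] = []
    for var in _CONTINUOUS:
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x2 = g2[var].dropna().to_numpy(dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            rows.append(
                HomogeneityRow(var, "t", None, None, None, None,
                               len(x1), len(x2), False, "not computable")
            )
            continue
        res = stats.ttest_ind(x1, x2, equal_var=True)
        df = len(x1) + len(x2) - 2
        sp = np.sqrt(
            ((len(x1) - 1) * x1.var(ddof=1) + (len(x2) - 1) * x2.var(ddof=1)) / df
        )
        d = (x1.mean() - x2.mean()) / sp
        rows.append(
            HomogeneityRow(var, "t", float(res.statistic), df, float(res.pvalue),
                           float(d), len(x1), len(x2), res.pvalue <= alpha)
        )
    for var, positive in _CATEGORICAL:
        c1 = g1[var].dropna()
        c2 = g2[var].dropna()
        table = np.array(
            [
                [(c1 == positive).sum(), (c1 != positive).sum()],
                [(c2 == positive).sum(), (c2 != positive).sum()],
            ]
        ).T  # category x pedagogy
        try:
            chi2, df, p = pearson_chi2_2x2(table)
        except (DomainError, ValidationError):
            rows.append(
                HomogeneityRow(var, "chi2", None, None, None, None,
                               len(c1), len(c2), False, "not computable")
            )
            continue
        rows.append(
            HomogeneityRow(var, "chi2", chi2, df, p, None,
                           len(c1), len(c2), p <= alpha)
        )
    return pd.DataFrame([r.__dict__ for r in rows])
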