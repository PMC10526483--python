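"""Group comparison and hierarchical regression of asymmetry indices.

Three statistical layers:

* ``students_vs_adults`` — whole-brain AI of students vs adults: Shapiro-
  Wilk per group (descriptive), pooled-variance Student t (df n1+n2-2) and
  an ANCOVA of AI on group, age and their interaction (per-term F with
  (1, n-4) denominator df).
* ``fit_ai_mlr`` — the per-region multiple linear regression of AI on age,
  pedagogy (traditional - Montessori contrast, dummy coded M=0/T=1), sex
  (male - female, F=0/M=1), SES, and age x pedagogy, with listwise deletion
  of subjects missing any predictor.
* ``hierarchical_downscale`` — the down-scaling paradigm: the whole-brain
  model gates the four classical lobes; each lobe whose omnibus F-test is
  significant gates its own subregions. Per-term p-values are Benjamini-
  Hochberg adjusted within the family of sibling regions at the same level
  (family of 4 at the lobe stage, family of 9 for temporal subregions).
  Gating uses the raw omnibus p; both raw and adjusted p are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError

MAIN_LOBES = ("frontal", "parietal", "temporal", "occipital")
MLR_TERMS = ("intercept", "age", "pedagogy", "sex", "ses", "age_x_pedagogy")


# ---------------------------------------------------------------------------
# Model containers

@dataclass(frozen=True)
class TermResult:
    name: str
    beta: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class ModelResult:
    """One fitted per-region OLS model."""

    region: str
    level: str
    terms: tuple[TermResult, ...]
    f: float
    df_num: int
    df_den: int
    r2: float
    p_model: float
    n_used: int

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([t.__dict__ for t in self.terms])
        df.insert(0, "level", self.level)
        df.insert(0, "region", self.region)
        return df


@dataclass(frozen=True)
class StageResult:
    level: str
    models: tuple[ModelResult, ...]
    gate_open: Mapping[str, bool]
    gate_reason: Mapping[str, str]
    adjusted_p: pd.DataFrame  # columns: region, term, p_raw, p_fdr


@dataclass(frozen=True)
class HierarchicalResult:
    stages: tuple[StageResult, ...]
    alpha: float

    def stage(self, level: str) -> StageResult:
        for s in self.stages:
            if s.level == level:
                return s
        raise KeyError(level)

    def records(self) -> pd.DataFrame:
        """Flat machine-readable run record (one row per region x term)."""
        frames = []
        for s in self.stages:
            adj = s.adjusted_p.copy()
            adj["level"] = s.level
            adj["gate_open"] = adj["region"].map(dict(s.gate_open))
            frames.append(adj)
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Design matrix and OLS

def _design(merged: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(index=merged.index)
    x["intercept"] = 1.0
    x["age"] = merged["age"].astype(float)
    x["pedagogy"] = merged["pedagogy"].map({"montessori": 0.0, "traditional": 1.0})
    x["sex"] = merged["sex"].map({"female": 0.0, "male": 1.0})
    x["ses"] = merged["ses"].astype(float)
    x["age_x_pedagogy"] = x["age"] * x["pedagogy"]
    return x


def fit_ai_mlr(ai: pd.DataFrame, subjects: pd.DataFrame) -> ModelResult:
    """OLS of one region's AI on age + pedagogy + sex + SES + age x pedagogy.

    ``ai`` holds AI records for a single region (students only are used);
    subjects missing any predictor are dropped listwise, so the residual
    df is n_complete - 6.
    """
    regions = ai["region"].unique()
    if len(regions) != 1:
        raise ValidationError(f"expected one region, got {sorted(regions)}")
    level = ai["level"].iloc[0]
    students = subjects[subjects["group"] == "student"]
    merged = ai.merge(students, on="subject_id", how="inner")
    x = _design(merged)
    y = merged["ai"].astype(float)
    keep = x.notna().all(axis=1) & y.notna()
    x, y = x[keep], y[keep]
    n_used = len(x)
    if n_used <= x.shape[1]:
        raise DomainError(
            f"{regions[0]}: only {n_used} complete cases for {x.shape[1]} terms"
        )
    for col in x.columns[1:]:
        if x[col].nunique() <= 1:
            raise DomainError(f"{regions[0]}: predictor '{col}' is constant")
    fit = sm.OLS(y.to_numpy(), x.to_numpy()).fit()
    terms = tuple(
        TermResult(name, float(b), float(se), float(t), float(p))
        for name, b, se, t, p in zip(
            x.columns, fit.params, fit.bse, fit.tvalues, fit.pvalues
        )
    )
    return ModelResult(
        region=str(regions[0]),
        level=str(level),
        terms=terms,
        f=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        r2=float(fit.rsquared),
        p_model=float(fit.f_pvalue),
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# FDR

def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or ((arr < 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return adjusted


# ---------------------------------------------------------------------------
# Students vs adults

@dataclass(frozen=True)
class GroupComparison:
    n_students: int
    n_adults: int
    shapiro: Mapping[str, tuple[float, float]]  # group -> (W, p)
    t: float
    df: int
    p: float
    cohens_d: float
    group_means: Mapping[str, float]
    group_sds: Mapping[str, float]
    ancova: pd.DataFrame  # rows: group, age, group_x_age; cols F, df_num, df_den, p


def students_vs_adults(ai: pd.DataFrame, subjects: pd.DataFrame) -> GroupComparison:
    """Whole-brain AI comparison between students and adults.

    Pooled two-sample Student t (df = n1 + n2 - 2) plus an ANCOVA of AI on
    group + age + group x age (Type-III SS with sum-to-zero group coding);
    every ANCOVA term carries (1, n - 4) df. Shapiro-Wilk per group is
    reported descriptively and does not gate anything.
    """
    wb = ai[ai["level"] == "whole_brain"][["subject_id", "ai"]]
    merged = wb.merge(subjects[["subject_id", "group", "age"]], on="subject_id")
    merged = merged.dropna(subset=["ai", "group", "age"])
    x_s = merged.loc[merged["group"] == "student", "ai"].to_numpy()
    x_a = merged.loc[merged["group"] == "adult", "ai"].to_numpy()
    if len(x_s) < 3 or len(x_a) < 3:
        raise DomainError("each group needs at least 3 subjects")
    shapiro = {
        "student": tuple(map(float, stats.shapiro(x_s))),
        "adult": tuple(map(float, stats.shapiro(x_a))),
    }
    tt = stats.ttest_ind(x_s, x_a, equal_var=True)
    df = len(x_s) + len(x_a) - 2
    sp = np.sqrt(
        ((len(x_s) - 1) * x_s.var(ddof=1) + (len(x_a) - 1) * x_a.var(ddof=1)) / df
    )
    d = (x_s.mean() - x_a.mean()) / sp

    # Type-III ANCOVA with sum-to-zero group coding
    g = np.where(merged["group"] == "student", 1.0, -1.0)
    age = merged["age"].to_numpy(dtype=float)
    age_c = age - age.mean()
    x_full = np.column_stack([np.ones(len(g)), g, age_c, g * age_c])
    y = merged["ai"].to_numpy(dtype=float)
    full = sm.OLS(y, x_full).fit()
    rows = []
    names = ["group", "age", "group_x_age"]
    for j, name in enumerate(names, start=1):
        restricted = sm.OLS(y, np.delete(x_full, j, axis=1)).fit()
        f = (restricted.ssr - full.ssr) / (full.ssr / full.df_resid)
        p = stats.f.sf(f, 1, full.df_resid)
        rows.append({"term": name, "F": float(f), "df_num": 1,
                     "df_den": int(full.df_resid), "p": float(p)})
    return GroupComparison(
        n_students=len(x_s),
        n_adults=len(x_a),
        shapiro=shapiro,
        t=float(tt.statistic),
        df=df,
        p=float(tt.pvalue),
        cohens_d=float(d),
        group_means={"student": float(x_s.mean()), "adult": float(x_a.mean())},
        group_sds={"student": float(x_s.std(ddof=1)), "adult": float(x_a.std(ddof=1))},
        ancova=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Hierarchical down-scaling

def _adjust_family(models: Sequence[ModelResult]) -> pd.DataFrame:
    """BH-adjust each term's p across sibling regions (one family per term)."""
    rows = []
    names = [t.name for t in models[0].terms if t.name != "intercept"]
    for name in names:
        raw = [m.term(name).p for m in models]
        adj = bh_fdr(raw)
        for m, pr, pa in zip(models, raw, adj):
            rows.append({"region": m.region, "term": name,
                         "p_raw": pr, "p_fdr": float(pa)})
    for m in models:
        rows.append({"region": m.region, "term": "omnibus",
                     "p_raw": m.p_model, "p_fdr": np.nan})
    return pd.DataFrame(rows)


def hierarchical_downscale(
    ai_table: pd.DataFrame,
    subjects: pd.DataFrame,
    lobe_map=None,
    alpha: float = 0.05,
    fdr: str = "bh",
) -> HierarchicalResult:
    """Whole-brain -> lobe -> subregion gated regression cascade.

    Stage 1 fits the whole-brain MLR; the lobe stage runs only if its
    omnibus p <= alpha. Stage 2 fits the four classical lobes; per-term
    p-values are BH-adjusted within the family of four sibling lobes, and
    a lobe's subregions are fitted only if that lobe's raw omnibus
    p <= alpha. Stage 3 repeats per opened lobe with the sibling-subregion
    family size. ``fdr="none"`` reports raw p as adjusted.
    """
    from .atlas import default_lobe_map

    if lobe_map is None:
        lobe_map = default_lobe_map()
    if fdr not in ("bh", "none"):
        raise ValidationError(f"unknown fdr method {fdr!r}")
    for level in ("whole_brain", "lobe", "subregion"):
        if not (ai_table["level"] == level).any():
            raise DomainError(f"AI table lacks level '{level}'")

    def adjust(models):
        df = _adjust_family(models)
        if fdr == "none":
            df["p_fdr"] = df["p_raw"]
        return df

    # Stage 1 — whole brain
    wb_model = fit_ai_mlr(ai_table[ai_table["level"] == "whole_brain"], subjects)
    wb_open = wb_model.p_model <= alpha
    stage1 = StageResult(
        level="whole_brain",
        models=(wb_model,),
        gate_open={"whole_brain": wb_open},
        gate_reason={
            "whole_brain": f"omnibus p={wb_model.p_model:.4g} "
            f"{'<=' if wb_open else '>'} alpha={alpha}"
        },
        adjusted_p=adjust([wb_model]),
    )
    stages = [stage1]

    # Stage 2 — the four classical lobes
    opened_lobes: list[str] = []
    if wb_open:
        lobe_models = []
        for lobe in MAIN_LOBES:
            sel = ai_table[(ai_table["level"] == "lobe") & (ai_table["region"] == lobe)]
            lobe_models.append(fit_ai_mlr(sel, subjects))
        gate_open = {m.region: m.p_model <= alpha for m in lobe_models}
        gate_reason = {
            m.region: f"omnibus p={m.p_model:.4g} "
            f"{'<=' if gate_open[m.region] else '>'} alpha={alpha}"
            for m in lobe_models
        }
        stages.append(
            StageResult("lobe", tuple(lobe_models), gate_open, gate_reason,
                        adjust(lobe_models))
        )
        opened_lobes = [r for r, ok in gate_open.items() if ok]

    # Stage 3 — subregions of each opened lobe
    if opened_lobes:
        sub_models: list[ModelResult] = []
        gate_open = {}
        gate_reason = {}
        frames = []
        for lobe in opened_lobes:
            siblings = []
            for roi in lobe_map.rois_of(lobe):
                sel = ai_table[
                    (ai_table["level"] == "subregion") & (ai_table["region"] == roi)
                ]
                siblings.append(fit_ai_mlr(sel, subjects))
            frames.append(adjust(siblings))
            for m in siblings:
                gate_open[m.region] = m.p_model <= alpha
                gate_reason[m.region] = (
                    f"omnibus p={m.p_model:.4g} "
                    f"{'<=' if gate_open[m.region] else '>'} alpha={alpha} "
                    f"(family: {lobe})"
                )
            sub_models.extend(siblings)
        stages.append(
            StageResult("subregion", tuple(sub_models), gate_open, gate_reason,
                        pd.concat(frames, ignore_index=True))
        )

    return HierarchicalResult(stages=tuple(stages), alpha=alpha)
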