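"""Synthetic cohort generator with the study's statistical structure.

The generator emulates a cross-sectional schooling cohort: two pedagogy
groups of students (Montessori / traditional, ages 4-18) plus a young-adult
reference group (ages 20-30), with compound demographic scores (SES, FIV,
HEV) and a realistic missingness pattern, and bilateral regional
morphometry whose asymmetry carries configurable linear effects.

Effects are injected in AI space: each configured region model draws a
per-subject target AI from

    ai = b0 + b_age*age + b_ped*T + b_sex*M + b_ses*ses + b_int*age*T + N(0, sd)

with T the traditional-pedagogy dummy and M the male dummy. Every ROI then
resolves its target AI from the most specific model available (own ROI >
its lobe > whole brain > an independent null draw) and realizes bilateral
thicknesses around a per-subject ROI baseline as

    left = m*(1 + ai),   right = m*(1 - ai)

with surface area shared across hemispheres by default, so that the AI
recomputed by the analysis pipeline equals the drawn target exactly at the
level where it was injected (lobe AI is area-weighted, and a common factor
(1 +- ai) passes through the weighting unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import DK_LABELS, default_lobe_map
from .errors import DomainError, ValidationError
from .io import DEMOGRAPHIC_COLUMNS, MORPH_COLUMNS


@dataclass(frozen=True)
class AIModel:
    """Linear model generating one region's target asymmetry index."""

    intercept: float = 0.0
    beta_age: float = 0.0
    beta_pedagogy: float = 0.0  # traditional - Montessori contrast
    beta_sex: float = 0.0  # male - female contrast
    beta_ses: float = 0.0
    beta_age_pedagogy: float = 0.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# Published coefficient sets used as generator ground truth.
TEMPORAL_AI_MODEL = AIModel(
    intercept=-4.33e-3,
    beta_age=9.22e-4,
    beta_pedagogy=1.65e-2,
    beta_sex=-5.91e-4,
    beta_ses=-2.88e-3,
    beta_age_pedagogy=-2.04e-3,
    noise_sd=0.01,
)
PARAHIPPOCAMPAL_AI_MODEL = AIModel(
    intercept=1.23e-2,
    beta_age=4.16e-3,
    beta_pedagogy=5.31e-2,
    beta_sex=-7.55e-3,
    beta_ses=-1.35e-2,
    beta_age_pedagogy=-6.09e-3,
    noise_sd=0.01,
)

# Whole-brain AI group moments (mean, SD) reported for the study cohort.
STUDENT_WB_MOMENTS = (3.82e-3, 4.02e-3)
ADULT_WB_MOMENTS = (2.51e-3, 6.47e-3)

# Only the whole-brain age x pedagogy slope is published; the default
# structural model carries it with an intercept calibrated to the group mean.
WB_AGE_PEDAGOGY_BETA = -9.23e-4

#: Plausible per-ROI baselines (mean thickness mm, mean pial area mm^2).
#: Config data, not science: magnitudes in the range FreeSurfer reports for
#: healthy cortex; the AI analysis is invariant to them.
ROI_BASELINES: Mapping[str, tuple[float, float]] = {
    "superiorfrontal": (2.80, 7000.0),
    "rostralmiddlefrontal": (2.40, 6000.0),
    "caudalmiddlefrontal": (2.60, 2300.0),
    "parsopercularis": (2.60, 1700.0),
    "parstriangularis": (2.50, 1500.0),
    "parsorbitalis": (2.70, 700.0),
    "lateralorbitofrontal": (2.70, 2700.0),
    "medialorbitofrontal": (2.50, 2000.0),
    "precentral": (2.60, 5300.0),
    "paracentral": (2.50, 1500.0),
    "frontalpole": (2.80, 300.0),
    "superiorparietal": (2.20, 5500.0),
    "inferiorparietal": (2.50, 5200.0),
    "supramarginal": (2.60, 4000.0),
    "postcentral": (2.00, 4500.0),
    "precuneus": (2.40, 3800.0),
    "superiortemporal": (2.80, 4000.0),
    "middletemporal": (2.90, 3500.0),
    "inferiortemporal": (2.80, 3300.0),
    "bankssts": (2.50, 1000.0),
    "fusiform": (2.80, 3400.0),
    "transversetemporal": (2.40, 500.0),
    "entorhinal": (3.30, 400.0),
    "temporalpole": (3.70, 450.0),
    "parahippocampal": (2.70, 700.0),
    "lateraloccipital": (2.20, 5000.0),
    "lingual": (2.00, 3000.0),
    "cuneus": (1.90, 1500.0),
    "pericalcarine": (1.60, 1400.0),
    "rostralanteriorcingulate": (2.90, 800.0),
    "caudalanteriorcingulate": (2.70, 700.0),
    "posteriorcingulate": (2.50, 1200.0),
    "isthmuscingulate": (2.40, 900.0),
    "insula": (3.00, 2300.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort shape, demographic distributions and per-region AI models.

    Defaults mirror the study cohort: 56 Montessori + 55 traditional
    students aged 4-18, 51 adults aged 20-30, sex/handedness frequencies
    from the reported counts, SES ~ truncated normal(3.1, 0.6) on [0, 4],
    and the reported missingness pattern applied as exact per-variable
    counts (so 10-of-111 SES missing, 11 FIV, 13 HEV).
    """

    n_montessori: int = 56
    n_traditional: int = 55
    n_adults: int = 51
    student_age_range: tuple[float, float] = (4.0, 18.0)
    adult_age_range: tuple[float, float] = (20.0, 30.0)
    p_female_montessori: float = 27 / 56
    p_female_traditional: float = 35 / 55
    p_female_adult: float = 28 / 51
    p_left_handed: float = 9 / 111
    ses_mean: float = 3.1
    ses_sd: float = 0.6
    fiv_mean: float = 32.9
    fiv_sd: float = 3.8
    hev_mean: float = 92.7
    hev_sd: float = 10.7
    missing_ses: float = 10 / 111
    missing_fiv: float = 11 / 111
    missing_hev: float = 13 / 111
    student_ai_models: Mapping[str, AIModel] = field(default_factory=dict)
    adult_ai_models: Mapping[str, AIModel] = field(default_factory=dict)
    default_ai_model: AIModel = AIModel(intercept=0.0, noise_sd=0.01)
    rois: tuple[str, ...] = DK_LABELS
    roi_baselines: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ROI_BASELINES)
    )
    cth_subject_sd: float = 0.12
    csa_log_sd: float = 0.12
    csa_asymmetric: bool = False

    def __post_init__(self) -> None:
        for name in ("n_montessori", "n_traditional", "n_adults"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "p_female_montessori",
            "p_female_traditional",
            "p_female_adult",
            "p_left_handed",
            "missing_ses",
            "missing_fiv",
            "missing_hev",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("ses_sd", "fiv_sd", "hev_sd",
                     "cth_subject_sd", "csa_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lobe_map = default_lobe_map()
        known = set(lobe_map.rois) | set(lobe_map.lobes) | {"whole_brain"}
        for group_models in (self.student_ai_models, self.adult_ai_models):
            for region in group_models:
                if region not in known:
                    raise ValidationError(
                        f"AI model region {region!r} is neither an ROI, a lobe "
                        "nor 'whole_brain'"
                    )
        for roi in self.rois:
            if roi not in self.roi_baselines:
                raise ValidationError(f"ROI {roi!r} has no baseline entry")

    # -- canned configurations ------------------------------------------

    @classmethod
    def default(cls) -> "GeneratorConfig":
        """Study-shaped cohort with the published coefficient structure.

        Effects are injected where the study localized them — the temporal
        lobe and the parahippocampal subregion — while every other region
        carries a small uniform leftward asymmetry plus noise. The
        whole-brain signal then *emerges* from area-weighted aggregation
        instead of being painted onto every ROI.
        """
        return cls(
            student_ai_models={
                "temporal": TEMPORAL_AI_MODEL,
                "parahippocampal": PARAHIPPOCAMPAL_AI_MODEL,
            },
            adult_ai_models={
                "whole_brain": AIModel(
                    intercept=ADULT_WB_MOMENTS[0], noise_sd=ADULT_WB_MOMENTS[1]
                )
            },
            # diffuse leftward bias for uninjected regions, so the emergent
            # whole-brain mean sits near the reported student group mean
            default_ai_model=AIModel(intercept=5.0e-3, noise_sd=0.01),
        )

    @classmethod
    def whole_brain_structural(cls) -> "GeneratorConfig":
        """Whole-brain AI carrying the one published slope (age x pedagogy),
        with the intercept calibrated to the student group mean."""
        p_trad = 55 / 111
        mean_age = 11.0  # midpoint of the student age range
        wb = AIModel(
            intercept=STUDENT_WB_MOMENTS[0] - WB_AGE_PEDAGOGY_BETA * mean_age * p_trad,
            beta_age_pedagogy=WB_AGE_PEDAGOGY_BETA,
            noise_sd=3.8e-3,
        )
        return cls(
            student_ai_models={"whole_brain": wb},
            adult_ai_models={
                "whole_brain": AIModel(
                    intercept=ADULT_WB_MOMENTS[0], noise_sd=ADULT_WB_MOMENTS[1]
                )
            },
        )

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """No effects anywhere: every region's AI is pure noise."""
        return cls(**overrides)

    @classmethod
    def recovery(cls, region: str, model: AIModel,
                 n_per_group: int = 500) -> "GeneratorConfig":
        """Coefficient-recovery design: one injected region, no missingness,
        balanced pedagogy groups, no adults."""
        return cls(
            n_montessori=n_per_group,
            n_traditional=n_per_group,
            n_adults=0,
            p_female_montessori=0.5,
            p_female_traditional=0.5,
            missing_ses=0.0,
            missing_fiv=0.0,
            missing_hev=0.0,
            student_ai_models={region: model},
        )

    @classmethod
    def whole_brain_moments(cls, group: str, n: int = 5000) -> "GeneratorConfig":
        """Moment calibration: whole-brain AI ~ Normal(group mean, group SD)."""
        if group == "student":
            mean, sd = STUDENT_WB_MOMENTS
            return cls(
                n_montessori=n // 2,
                n_traditional=n - n // 2,
                n_adults=0,
                missing_ses=0.0,
                missing_fiv=0.0,
                missing_hev=0.0,
                student_ai_models={"whole_brain": AIModel(intercept=mean, noise_sd=sd)},
            )
        if group == "adult":
            mean, sd = ADULT_WB_MOMENTS
            return cls(
                n_montessori=0,
                n_traditional=0,
                n_adults=n,
                adult_ai_models={"whole_brain": AIModel(intercept=mean, noise_sd=sd)},
            )
        raise ValidationError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# Demographics


def _streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _complete_demographics(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    groups = [
        ("M", "student", "montessori", config.n_montessori,
         config.student_age_range, config.p_female_montessori),
        ("T", "student", "traditional", config.n_traditional,
         config.student_age_range, config.p_female_traditional),
        ("A", "adult", "not_applicable", config.n_adults,
         config.adult_age_range, config.p_female_adult),
    ]
    for prefix, group, pedagogy, n, age_range, p_female in groups:
        if n == 0:
            continue
        age = rng.uniform(age_range[0], age_range[1], n)
        female = rng.random(n) < p_female
        left = rng.random(n) < config.p_left_handed
        if group == "student":
            ses = _truncnorm(rng, config.ses_mean, config.ses_sd, 0, 4, n)
            fiv = np.rint(_truncnorm(rng, config.fiv_mean, config.fiv_sd, 0, 36, n))
            hev = _truncnorm(rng, config.hev_mean, config.hev_sd, 0, 100, n)
        else:
            ses = fiv = hev = np.full(n, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{prefix}{i + 1:04d}" for i in range(n)],
                    "group": group,
                    "pedagogy": pedagogy,
                    "age": age,
                    "sex": np.where(female, "female", "male"),
                    "handedness": np.where(left, "left", "right"),
                    "ses": ses,
                    "fiv": fiv,
                    "hev": hev,
                }
            )
        )
    if not rows:
        raise DomainError("config generates an empty cohort")
    return pd.concat(rows, ignore_index=True)[DEMOGRAPHIC_COLUMNS]


def _apply_missingness(demo: pd.DataFrame, config: GeneratorConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    out = demo.copy()
    students = out.index[out["group"] == "student"].to_numpy()
    n = len(students)
    for col, rate in (
        ("ses", config.missing_ses),
        ("fiv", config.missing_fiv),
        ("hev", config.missing_hev),
    ):
        k = int(round(rate * n))
        if k > 0:
            out.loc[rng.choice(students, size=k, replace=False), col] = np.nan
    return out


def generate_demographics(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Reproducible demographics table; missingness applied per variable
    at the configured rates as exact counts."""
    rng_demo, _, rng_miss = _streams(seed)
    return _apply_missingness(_complete_demographics(config, rng_demo), config, rng_miss)


# ---------------------------------------------------------------------------
# Morphometry


def ai_to_hemispheric_thickness(mean_cth, ai):
    """Invert the asymmetry index around a mean thickness.

    left = m*(1+ai), right = m*(1-ai); exact round trip through
    asymmetry_index. Accepts scalars or arrays.
    """
    m = np.asarray(mean_cth, dtype=float)
    a = np.asarray(ai, dtype=float)
    if (m <= 0).any():
        raise DomainError("mean thickness must be positive")
    if (np.abs(a) >= 1).any():
        raise DomainError("|ai| must be < 1")
    left, right = m * (1 + a), m * (1 - a)
    if left.ndim == 0:
        return float(left), float(right)
    return left, right


def _linear_predictor(model: AIModel, demo: pd.DataFrame,
                      config: GeneratorConfig) -> np.ndarray:
    age = demo["age"].to_numpy(dtype=float)
    trad = (demo["pedagogy"] == "traditional").to_numpy(dtype=float)
    male = (demo["sex"] == "male").to_numpy(dtype=float)
    ses = demo["ses"].to_numpy(dtype=float)
    # a missing covariate contributes its population mean (latent stand-in)
    ses = np.where(np.isnan(ses), config.ses_mean, ses)
    return (
        model.intercept
        + model.beta_age * age
        + model.beta_pedagogy * trad
        + model.beta_sex * male
        + model.beta_ses * ses
        + model.beta_age_pedagogy * age * trad
    )


def generate_morphometry(subjects: pd.DataFrame, config: GeneratorConfig,
                         seed: int) -> pd.DataFrame:
    """Bilateral per-ROI morphometry realizing the configured AI structure.

    Returns a morphometry long table (subject_id, hemisphere, roi, cth,
    csa). With all noise SDs zero and null coefficients every recomputed
    AI is exactly zero.
    """
    rng = np.random.default_rng(seed)
    lobe_map = default_lobe_map()
    n = len(subjects)
    if n == 0:
        raise DomainError("no subjects")

    is_adult = (subjects["group"] == "adult").to_numpy()
    model_sets = (config.student_ai_models, config.adult_ai_models)

    # one draw per configured model region per subject, per group's model set
    draws: dict[tuple[int, str], np.ndarray] = {}
    for gi, models in enumerate(model_sets):
        for region, model in models.items():
            mu = _linear_predictor(model, subjects, config)
            eps = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else 0.0
            draws[(gi, region)] = mu + eps

    def resolve(gi: int, roi: str) -> np.ndarray | None:
        models = model_sets[gi]
        for key in (roi, lobe_map.lobe_of(roi), "whole_brain"):
            if key in models:
                return draws[(gi, key)]
        return None

    frames = []
    subject_ids = subjects["subject_id"].to_numpy()
    for roi in config.rois:
        ai = np.empty(n)
        for gi, mask in enumerate((~is_adult, is_adult)):
            if not mask.any():
                continue
            resolved = resolve(gi, roi)
            if resolved is None:
                # uncovered ROI: independent draw from the default model
                default = config.default_ai_model
                resolved = _linear_predictor(default, subjects, config)
                if default.noise_sd > 0:
                    resolved = resolved + rng.normal(0.0, default.noise_sd, n)
            ai[mask] = resolved[mask]
        base_cth, base_csa = config.roi_baselines[roi]
        m = base_cth + rng.normal(0.0, config.cth_subject_sd, n)
        m = np.clip(m, 0.2 * base_cth, None)
        left, right = ai_to_hemispheric_thickness(m, ai)
        csa_l = base_csa * np.exp(rng.normal(0.0, config.csa_log_sd, n))
        if config.csa_asymmetric:
            csa_r = base_csa * np.exp(rng.normal(0.0, config.csa_log_sd, n))
        else:
            csa_r = csa_l
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.concatenate([subject_ids, subject_ids]),
                    "hemisphere": ["left"] * n + ["right"] * n,
                    "roi": roi,
                    "cth": np.concatenate([left, right]),
                    "csa": np.concatenate([csa_l, csa_r]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)[MORPH_COLUMNS]
    return out.sort_values(["subject_id", "hemisphere", "roi"], ignore_index=True)


def generate_cohort(config: GeneratorConfig,
                    seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Demographics (with observed missingness) plus matching morphometry.

    Morphometry is generated from the latent complete covariates before
    the missingness mask is applied, so masked subjects still carry the AI
    their true covariates imply (missingness hides data, it does not alter
    anatomy).
    """
    rng_demo, _, rng_miss = _streams(seed)
    morph_seed = int(np.random.SeedSequence(seed).spawn(3)[1].generate_state(1)[0] % (2**31))
    complete = _complete_demographics(config, rng_demo)
    morph = generate_morphometry(complete, config, morph_seed)
    observed = _apply_missingness(complete, config, rng_miss)
    return observed, morph
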