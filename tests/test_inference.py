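import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cthasym as c
from cthasym.inference import MAIN_LOBES, fit_ai_mlr
from cthasym.simulate import (
    AIModel,
    PARAHIPPOCAMPAL_AI_MODEL,
    TEMPORAL_AI_MODEL,
)


def _make_students(n, rng, ses_missing=0):
    demo = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": "student",
            "pedagogy": rng.choice(["montessori", "traditional"], n),
            "age": rng.uniform(4, 18, n),
            "sex": rng.choice(["female", "male"], n),
            "handedness": "right",
            "ses": rng.uniform(0.5, 4, n),
            "fiv": 30.0,
            "hev": 90.0,
        }
    )
    if ses_missing:
        demo.loc[demo.index[:ses_missing], "ses"] = np.nan
    return demo


def _ai_from(demo, coefs, noise, rng, region="temporal", level="lobe"):
    x = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": demo["age"],
            "pedagogy": (demo["pedagogy"] == "traditional").astype(float),
            "sex": (demo["sex"] == "male").astype(float),
            "ses": demo["ses"].fillna(2.5),
            "age_x_pedagogy": demo["age"]
            * (demo["pedagogy"] == "traditional").astype(float),
        }
    )
    y = x.to_numpy() @ np.asarray(coefs) + rng.normal(0, noise, len(demo))
    return pd.DataFrame(
        {
            "subject_id": demo["subject_id"],
            "level": level,
            "region": region,
            "ai": y,
            "wcth_left": 2.5,
            "wcth_right": 2.5,
        }
    )


class TestMlr:
    def test_noise_free_data_recovers_coefficients_exactly(self):
        rng = np.random.default_rng(0)
        demo = _make_students(60, rng)
        coefs = [-4e-3, 9e-4, 1.6e-2, -6e-4, -3e-3, -2e-3]
        ai = _ai_from(demo, coefs, noise=0.0, rng=rng)
        m = fit_ai_mlr(ai, demo)
        for term, truth in zip(m.terms, coefs):
            assert term.beta == pytest.approx(truth, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_df_bookkeeping_under_missingness(self):
        rng = np.random.default_rng(1)
        demo = _make_students(111, rng, ses_missing=10)
        ai = _ai_from(demo, [0, 0, 0, 0, 0, 0], noise=0.01, rng=rng)
        m = fit_ai_mlr(ai, demo)
        assert m.n_used == 101
        assert (m.df_num, m.df_den) == (5, 95)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_normal_equations_oracle(self, seed):
        """Betas, SEs and t equal the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        demo = _make_students(n, rng)
        ai = _ai_from(demo, rng.normal(0, 1e-2, 6), noise=0.02, rng=rng)
        m = fit_ai_mlr(ai, demo)
        x = np.column_stack(
            [
                np.ones(n),
                demo["age"],
                demo["pedagogy"] == "traditional",
                demo["sex"] == "male",
                demo["ses"],
                demo["age"] * (demo["pedagogy"] == "traditional"),
            ]
        ).astype(float)
        y = ai["ai"].to_numpy()
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y
        resid = y - x @ beta
        s2 = resid @ resid / (n - 6)
        se = np.sqrt(s2 * np.diag(xtx_inv))
        for j, term in enumerate(m.terms):
            assert term.beta == pytest.approx(beta[j], rel=1e-8, abs=1e-12)
            assert term.se == pytest.approx(se[j], rel=1e-8)
            assert term.t == pytest.approx(beta[j] / se[j], rel=1e-8)
        assert m.df_den == n - 6

    def test_constant_predictor_is_rank_error(self):
        rng = np.random.default_rng(2)
        demo = _make_students(40, rng)
        demo["pedagogy"] = "montessori"
        ai = _ai_from(demo, [0] * 6, noise=0.01, rng=rng)
        with pytest.raises(c.DomainError, match="pedagogy"):
            fit_ai_mlr(ai, demo)

    def test_too_few_complete_cases(self):
        rng = np.random.default_rng(3)
        demo = _make_students(6, rng)
        ai = _ai_from(demo, [0] * 6, noise=0.01, rng=rng)
        with pytest.raises(c.DomainError):
            fit_ai_mlr(ai, demo)

    def test_empirical_se_tracks_analytic_se(self):
        """Over replicates the spread of estimates matches the OLS SE."""
        model = AIModel(beta_age_pedagogy=-2e-3, beta_pedagogy=1.5e-2, noise_sd=0.01)
        cfg = c.GeneratorConfig.recovery("temporal", model, n_per_group=250)
        cfg = dataclasses.replace(
            cfg, rois=c.default_lobe_map().rois_of("temporal")
        )
        betas, analytic = [], []
        for seed in range(200):
            demo, morph = c.generate_cohort(cfg, 10_000 + seed)
            ai = c.compute_ai_table(morph)
            m = fit_ai_mlr(ai[(ai["level"] == "lobe") & (ai["region"] == "temporal")], demo)
            t = m.term("age_x_pedagogy")
            betas.append(t.beta)
            analytic.append(t.se)
        empirical = np.std(betas, ddof=1)
        assert empirical == pytest.approx(np.mean(analytic), rel=0.15)
        assert np.mean(betas) == pytest.approx(-2e-3, abs=3 * empirical / np.sqrt(200))


class TestBhFdr:
    def test_reported_family_of_four_adjustments(self):
        assert c.bh_fdr([0.030, 0.5, 0.6, 0.7])[0] == pytest.approx(0.12)
        assert c.bh_fdr([0.004, 0.5, 0.6, 0.7])[0] == pytest.approx(0.016)

    def test_all_equal_is_fixed_point(self):
        out = c.bh_fdr([0.2] * 7)
        assert np.allclose(out, 0.2)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20))
    def test_monotone_order_preserving_and_dominates_raw(self, pvals):
        adj = c.bh_fdr(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(c.ValidationError):
            c.bh_fdr([0.5, 1.5])


class TestStudentsVsAdults:
    @staticmethod
    def _cohort(rng, n_s=111, n_a=51, shift=0.0):
        ids = [f"x{i}" for i in range(n_s + n_a)]
        demo = pd.DataFrame(
            {
                "subject_id": ids,
                "group": ["student"] * n_s + ["adult"] * n_a,
                "pedagogy": ["montessori"] * n_s + ["not_applicable"] * n_a,
                "age": np.concatenate([rng.uniform(4, 18, n_s), rng.uniform(20, 30, n_a)]),
                "sex": "female",
                "handedness": "right",
                "ses": np.nan,
                "fiv": np.nan,
                "hev": np.nan,
            }
        )
        ai = pd.DataFrame(
            {
                "subject_id": ids,
                "level": "whole_brain",
                "region": "whole_brain",
                "ai": rng.normal(3e-3, 4e-3, n_s + n_a)
                + shift * np.r_[np.ones(n_s), np.zeros(n_a)],
                "wcth_left": 2.5,
                "wcth_right": 2.5,
            }
        )
        return ai, demo

    def test_reported_degrees_of_freedom(self):
        ai, demo = self._cohort(np.random.default_rng(0))
        comp = c.students_vs_adults(ai, demo)
        assert comp.df == 160  # 111 + 51 - 2
        assert (comp.ancova["df_den"] == 158).all()  # n - 4 at n = 162
        assert (comp.ancova["df_num"] == 1).all()
        assert set(comp.ancova["term"]) == {"group", "age", "group_x_age"}
        assert 0 <= comp.shapiro["student"][1] <= 1

    def test_detects_a_real_group_shift(self):
        ai, demo = self._cohort(np.random.default_rng(1), n_s=400, n_a=400, shift=2e-3)
        comp = c.students_vs_adults(ai, demo)
        assert comp.p < 1e-6 and comp.t > 0

    def test_null_simulation_calibration(self):
        """Same-distribution groups: t stays small and the ANCOVA rarely fires.

        Under the null each of the three F-tests fires ~5% of the time, so
        all three stay quiet in roughly 86% of runs; require >= 75% over
        100 seeds and a median |t| under 1.
        """
        quiet, tstats = 0, []
        for seed in range(100):
            ai, demo = self._cohort(np.random.default_rng(seed), n_s=300, n_a=150)
            comp = c.students_vs_adults(ai, demo)
            tstats.append(abs(comp.t))
            quiet += int((comp.ancova["p"] > 0.05).all())
        assert quiet >= 75
        assert np.median(tstats) < 1.0

    def test_tiny_group_is_domain_error(self):
        ai, demo = self._cohort(np.random.default_rng(2), n_s=10, n_a=2)
        with pytest.raises(c.DomainError):
            c.students_vs_adults(ai, demo)


class TestHierarchy:
    def test_designed_truth_opens_whole_brain_and_temporal(self):
        cfg = c.GeneratorConfig.recovery("temporal", TEMPORAL_AI_MODEL, n_per_group=500)
        cfg = dataclasses.replace(
            cfg,
            student_ai_models={
                "temporal": TEMPORAL_AI_MODEL,
                "parahippocampal": PARAHIPPOCAMPAL_AI_MODEL,
            },
        )
        demo, morph = c.generate_cohort(cfg, 1270)
        ai = c.compute_ai_table(morph)
        res = c.hierarchical_downscale(ai, demo)
        assert res.stage("whole_brain").gate_open["whole_brain"]
        assert res.stage("lobe").gate_open["temporal"]
        sub = res.stage("subregion")
        assert sub.gate_open["parahippocampal"]
        phc = [m for m in sub.models if m.region == "parahippocampal"][0]
        assert phc.term("age_x_pedagogy").p < 0.05

    def test_subregions_exist_only_for_opened_lobes(self):
        cfg = c.GeneratorConfig.recovery("temporal", TEMPORAL_AI_MODEL, n_per_group=500)
        demo, morph = c.generate_cohort(cfg, 99)
        ai = c.compute_ai_table(morph)
        res = c.hierarchical_downscale(ai, demo)
        if len(res.stages) == 3:
            opened = {r for r, ok in res.stage("lobe").gate_open.items() if ok}
            lm = c.default_lobe_map()
            fitted_lobes = {lm.lobe_of(m.region) for m in res.stage("subregion").models}
            assert fitted_lobes == opened

    def test_adjusted_p_dominates_raw_everywhere(self, default_cohort, default_ai):
        demo, _ = default_cohort
        res = c.hierarchical_downscale(default_ai, demo)
        rec = res.records()
        have = rec["p_fdr"].notna()
        assert (rec.loc[have, "p_fdr"] >= rec.loc[have, "p_raw"] - 1e-15).all()
        lobe_rec = rec[(rec["level"] == "lobe") & (rec["term"] != "omnibus")]
        assert set(lobe_rec["region"]) == set(MAIN_LOBES)

    def test_fdr_none_reports_raw(self, default_cohort, default_ai):
        demo, _ = default_cohort
        res = c.hierarchical_downscale(default_ai, demo, fdr="none")
        rec = res.records()
        have = rec["p_fdr"].notna()
        assert np.allclose(rec.loc[have, "p_fdr"], rec.loc[have, "p_raw"])

    def test_missing_level_is_domain_error(self, default_cohort, default_ai):
        demo, _ = default_cohort
        with pytest.raises(c.DomainError, match="subregion"):
            c.hierarchical_downscale(default_ai[default_ai["level"] != "subregion"], demo)
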