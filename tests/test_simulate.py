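import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cthasym as c
from cthasym.inference import fit_ai_mlr
from cthasym.simulate import (
    AIModel,
    PARAHIPPOCAMPAL_AI_MODEL,
    TEMPORAL_AI_MODEL,
)


class TestDemographics:
    def test_default_cohort_shape(self):
        demo = c.generate_demographics(c.GeneratorConfig.default(), seed=5)
        counts = demo.groupby(["group", "pedagogy"]).size()
        assert counts[("student", "montessori")] == 56
        assert counts[("student", "traditional")] == 55
        assert counts[("adult", "not_applicable")] == 51
        students = demo[demo["group"] == "student"]
        assert students["age"].between(4, 18).all()
        adults = demo[demo["group"] == "adult"]
        assert adults["age"].between(20, 30).all()
        assert adults[["ses", "fiv", "hev"]].isna().all().all()

    def test_missingness_matches_reported_pattern(self):
        demo = c.generate_demographics(c.GeneratorConfig.default(), seed=5)
        students = demo[demo["group"] == "student"]
        assert students["ses"].isna().sum() == 10
        assert students["fiv"].isna().sum() == 11
        assert students["hev"].isna().sum() == 13
        assert students["ses"].dropna().between(0, 4).all()
        assert students["fiv"].dropna().between(0, 36).all()
        assert students["hev"].dropna().between(0, 100).all()

    def test_same_seed_reproduces_identical_tables(self):
        cfg = c.GeneratorConfig.default()
        a = c.generate_demographics(cfg, seed=11)
        b = c.generate_demographics(cfg, seed=11)
        pd.testing.assert_frame_equal(a, b)
        d1, m1 = c.generate_cohort(cfg, seed=11)
        d2, m2 = c.generate_cohort(cfg, seed=11)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(m1, m2)
        # demographics alone and within the cohort entry point agree
        pd.testing.assert_frame_equal(a, d1)

    def test_invalid_config_names_field(self):
        with pytest.raises(c.ValidationError, match="p_left_handed"):
            c.GeneratorConfig(p_left_handed=1.5)
        with pytest.raises(c.ValidationError, match="n_adults"):
            c.GeneratorConfig(n_adults=-1)
        with pytest.raises(c.ValidationError, match="region"):
            c.GeneratorConfig(student_ai_models={"cerebellum": AIModel()})


class TestThicknessRealization:
    def test_examples(self):
        assert c.ai_to_hemispheric_thickness(2.5, 0.0) == (2.5, 2.5)
        left, right = c.ai_to_hemispheric_thickness(2.5, 0.04)
        assert (left, right) == pytest.approx((2.6, 2.4))
        with pytest.raises(c.DomainError):
            c.ai_to_hemispheric_thickness(2.5, 1.0)
        with pytest.raises(c.DomainError):
            c.ai_to_hemispheric_thickness(-1.0, 0.1)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.5, max_value=5, allow_nan=False),
        st.floats(min_value=-0.99, max_value=0.99, allow_nan=False),
    )
    def test_round_trip_through_asymmetry_index(self, m, a):
        left, right = c.ai_to_hemispheric_thickness(m, a)
        assert c.asymmetry_index(left, right) == pytest.approx(a, abs=1e-12)


class TestMorphometry:
    def test_null_noise_free_config_gives_all_zero_ai(self):
        cfg = c.GeneratorConfig.null(
            default_ai_model=AIModel(intercept=0.0, noise_sd=0.0), n_adults=0
        )
        demo, morph = c.generate_cohort(cfg, seed=2)
        ai = c.compute_ai_table(morph)
        assert np.allclose(ai["ai"], 0.0, atol=1e-15)
        assert len(ai) == 111 * 41

    def test_injected_lobe_target_reappears_exactly(self):
        """Generator/analyzer round trip: with shared CSA, the recomputed
        temporal-lobe AI equals the per-subject draw, which all nine
        temporal subregions share."""
        cfg = c.GeneratorConfig.recovery("temporal", TEMPORAL_AI_MODEL, n_per_group=30)
        demo, morph = c.generate_cohort(cfg, seed=3)
        ai = c.compute_ai_table(morph)
        lobe = ai[(ai["level"] == "lobe") & (ai["region"] == "temporal")]
        lobe = lobe.set_index("subject_id")["ai"]
        temporal_rois = c.default_lobe_map().rois_of("temporal")
        for roi in temporal_rois:
            sub = ai[(ai["level"] == "subregion") & (ai["region"] == roi)]
            sub = sub.set_index("subject_id")["ai"]
            assert np.allclose(sub.sort_index(), lobe.sort_index(), atol=1e-10)

    def test_asymmetric_csa_breaks_exact_equality_only_slightly(self):
        cfg = c.GeneratorConfig.recovery("temporal", TEMPORAL_AI_MODEL, n_per_group=30)
        cfg = dataclasses.replace(cfg, csa_asymmetric=True)
        demo, morph = c.generate_cohort(cfg, seed=3)
        left = morph[morph["hemisphere"] == "left"].set_index(["subject_id", "roi"])["csa"]
        right = morph[morph["hemisphere"] == "right"].set_index(["subject_id", "roi"])["csa"]
        assert not np.allclose(left, right)
        ai = c.compute_ai_table(morph)
        lobe = ai[(ai["level"] == "lobe") & (ai["region"] == "temporal")]["ai"]
        sub = ai[(ai["level"] == "subregion") & (ai["region"] == "bankssts")]["ai"]
        assert np.corrcoef(lobe.to_numpy(), sub.to_numpy())[0, 1] > 0.9

    def test_whole_brain_moment_calibration(self):
        cfg = c.GeneratorConfig.whole_brain_moments("student", n=1000)
        _, morph = c.generate_cohort(cfg, seed=4)
        wb = c.compute_ai_table(morph).query("level == 'whole_brain'")["ai"]
        assert wb.mean() == pytest.approx(3.82e-3, abs=4 * 4.02e-3 / np.sqrt(1000))
        assert wb.std() == pytest.approx(4.02e-3, rel=0.15)


class TestCoefficientRecoveryBias:
    @pytest.mark.parametrize(
        "region, level, truth",
        [
            ("temporal", "lobe", TEMPORAL_AI_MODEL),
            ("parahippocampal", "subregion", PARAHIPPOCAMPAL_AI_MODEL),
        ],
    )
    def test_mean_estimate_over_seeds_is_unbiased(self, region, level, truth):
        """Average refitted coefficients over 50 seeds sit on the injected
        values (within 10% or the Monte-Carlo noise floor, whichever is
        larger)."""
        cfg = c.GeneratorConfig.recovery(region, truth, n_per_group=500)
        cfg = dataclasses.replace(cfg, rois=c.default_lobe_map().rois_of("temporal"))
        estimates = {name: [] for name in
                     ("intercept", "age", "pedagogy", "sex", "ses", "age_x_pedagogy")}
        for seed in range(50):
            demo, morph = c.generate_cohort(cfg, 40_000 + seed)
            ai = c.compute_ai_table(morph)
            m = fit_ai_mlr(
                ai[(ai["level"] == level) & (ai["region"] == region)], demo
            )
            for name in estimates:
                estimates[name].append(m.term(name).beta)
        truths = {
            "intercept": truth.intercept,
            "age": truth.beta_age,
            "pedagogy": truth.beta_pedagogy,
            "sex": truth.beta_sex,
            "ses": truth.beta_ses,
            "age_x_pedagogy": truth.beta_age_pedagogy,
        }
        for name, values in estimates.items():
            arr = np.asarray(values)
            sem = arr.std(ddof=1) / np.sqrt(len(arr))
            tol = max(0.1 * abs(truths[name]), 3 * sem)
            assert abs(arr.mean() - truths[name]) < tol, name
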