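"""Life-table engine: closed forms, schedule contracts, decomposition,
standardization, scenarios."""

import math

import numpy as np
import pandas as pd
import pytest

import lymphrisk as lr
from lymphrisk.risk_engine import (
    HazardSchedule,
    age_sex_stratum,
    build_hazard_schedule,
    cumulative_incidence,
    cumulative_mortality,
    standardize,
)


def _schedule(h_cause, h_other, horizon=30):
    return HazardSchedule(
        endpoints=("c",),
        hazards=np.full((horizon, 1), h_cause),
        other=np.full(horizon, h_other),
    )


class TestCumulativeMortality:
    def test_constant_competing_hazards_closed_form(self):
        # h_c/(h_c+h_o) * (1 - exp(-H*(h_c+h_o)))
        amr = cumulative_mortality(_schedule(0.01, 0.01), "c")
        assert amr == pytest.approx(0.5 * (1 - math.exp(-0.6)), rel=1e-12)

    def test_single_cause_exponential_survival(self):
        amr = cumulative_mortality(_schedule(0.02, 0.0), "c")
        assert amr == pytest.approx(1 - math.exp(-0.6), rel=1e-12)

    def test_large_competing_hazard_suppresses_cause(self):
        amr = cumulative_mortality(_schedule(0.01, 1e6), "c")
        assert amr < 1e-6

    def test_zero_total_hazard_year_contributes_zero(self):
        hz = np.zeros((30, 1))
        hz[10:, 0] = 0.01
        sched = HazardSchedule(endpoints=("c",), hazards=hz, other=np.zeros(30))
        amr = cumulative_mortality(sched, "c")
        assert amr == pytest.approx(1 - math.exp(-0.2), rel=1e-12)

    def test_negative_hazard_rejected(self):
        with pytest.raises(lr.DataValidationError, match="negative"):
            _schedule(-0.01, 0.0)

    def test_competing_hazard_monotonicity(self):
        amrs = [cumulative_mortality(_schedule(0.01, h), "c") for h in (0.0, 0.05, 0.2)]
        assert amrs[0] > amrs[1] > amrs[2]

    def test_conservation_sums_to_total_mortality(self):
        rng = np.random.default_rng(7)
        hz = rng.uniform(0, 0.1, size=(30, 4))
        other = rng.uniform(0, 0.1, size=30)
        sched = HazardSchedule(endpoints=tuple("abcd"), hazards=hz, other=other)
        amr, amr_other = cumulative_incidence(sched)
        total = 1 - math.exp(-(hz.sum() + other.sum()))
        assert sum(amr.values()) + amr_other == pytest.approx(total, abs=1e-12)


class TestHazardScheduleLayers:
    def test_background_layer_independent_of_exposures(self, cohort, us_rates, cfg):
        p = cohort[0]
        from dataclasses import replace

        stripped = replace(p, anthracycline_dose=0.0,
                           doses=dict(p.doses))
        a = build_hazard_schedule(p, None, us_rates, cfg, "background")
        b = build_hazard_schedule(stripped, None, us_rates, cfg, "background")
        assert np.array_equal(a.hazards, b.hazards)

    def test_chemo_layer_touches_cvd_only(self, cohort, us_rates, cfg):
        p = next(c for c in cohort if c.anthracycline_dose > 0)
        bg = build_hazard_schedule(p, None, us_rates, cfg, "background")
        ch = build_hazard_schedule(p, None, us_rates, cfg, "chemo")
        idx = {e: i for i, e in enumerate(bg.endpoints)}
        for cancer in ("lung_cancer", "breast_cancer", "esophageal_cancer"):
            assert np.array_equal(bg.hazards[:, idx[cancer]], ch.hazards[:, idx[cancer]])
        assert np.all(ch.hazards[:, idx["heart_failure"]]
                      > bg.hazards[:, idx["heart_failure"]])

    def test_null_exposure_full_layer_collapses_to_background(self, us_rates, cfg):
        doses = {m: lr.DoseSummary(
            modality=m, whole_heart=0, left_ventricle=0, aortic_valve=0,
            mitral_valve=0, tricuspid_valve=0, carotid_arteries=0, lungs=0,
            breast=0, esophagus=0, normal_tissue=0) for m in ("photon", "proton")}
        p = lr.PatientRecord(id="z", sex="female", age_at_treatment=30, smoking="never",
                             anthracycline_dose=0.0, doses=doses)
        bg = build_hazard_schedule(p, None, us_rates, cfg, "background")
        full = build_hazard_schedule(p, "photon", us_rates, cfg, "full")
        assert np.array_equal(bg.hazards, full.hazards)
        assert np.array_equal(bg.other, full.other)

    def test_smoking_scales_all_layers(self, us_rates, cfg):
        doses = {m: lr.DoseSummary(
            modality=m, whole_heart=10, left_ventricle=5, aortic_valve=10,
            mitral_valve=10, tricuspid_valve=10, carotid_arteries=20, lungs=8,
            breast=2, esophagus=15, normal_tissue=4) for m in ("photon", "proton")}

        def make(smoking):
            return lr.PatientRecord(id="s", sex="male", age_at_treatment=30,
                                    smoking=smoking, anthracycline_dose=300, doses=doses)

        idx = dict((e, i) for i, e in enumerate(lr.ENDPOINTS))
        for layer in ("background", "full"):
            never = build_hazard_schedule(make("never"), "photon", us_rates, cfg, layer)
            smoker = build_hazard_schedule(make("current"), "photon", us_rates, cfg, layer)
            ratio = smoker.hazards[:, idx["lung_cancer"]] / never.hazards[:, idx["lung_cancer"]]
            assert np.allclose(ratio, 14.0)

    def test_attained_age_window_is_start_of_year(self, cfg):
        """An age-30 patient projected 30 years consults ages 30..59 only."""
        rows = []
        for sex in ("male", "female"):
            for cause in lr.ENDPOINTS + (lr.ALL_OTHER,):
                rows.append((sex, cause, 0.0, 30.0, np.nan))  # poisoned below 30
                rows.append((sex, cause, 30.0, 60.0, 100.0))
                rows.append((sex, cause, 60.0, np.inf, np.nan))  # poisoned from 60
        table = lr.RateTable("window", pd.DataFrame(
            rows, columns=["sex", "cause", "age_lo", "age_hi", "rate_per_100k"]))
        doses = {m: lr.DoseSummary(modality=m, whole_heart=0, left_ventricle=0,
                                   aortic_valve=0, mitral_valve=0, tricuspid_valve=0,
                                   carotid_arteries=0, lungs=0, breast=0, esophagus=0,
                                   normal_tissue=0) for m in ("photon", "proton")}
        p = lr.PatientRecord(id="w", sex="female", age_at_treatment=30, smoking="never",
                             anthracycline_dose=0, doses=doses)
        sched = build_hazard_schedule(p, None, table, cfg, "background")
        assert np.all(np.isfinite(sched.hazards)) and np.all(np.isfinite(sched.other))


class TestDecomposePatient:
    def test_equal_modality_doses_give_equal_excess(self, us_rates, cfg):
        d = dict(whole_heart=9, left_ventricle=5, aortic_valve=14, mitral_valve=14,
                 tricuspid_valve=14, carotid_arteries=25, lungs=8, breast=2,
                 esophagus=16, normal_tissue=4)
        doses = {m: lr.DoseSummary(modality=m, **d) for m in ("photon", "proton")}
        p = lr.PatientRecord(id="e", sex="female", age_at_treatment=35, smoking="never",
                             anthracycline_dose=300, doses=doses)
        decomp = lr.decompose_patient(p, us_rates, cfg)
        for risk in decomp.risks.values():
            assert risk.excess_rt("photon") == risk.excess_rt("proton")

    def test_null_exposure_all_excess_zero(self, us_rates, cfg):
        doses = {m: lr.DoseSummary(modality=m, whole_heart=0, left_ventricle=0,
                                   aortic_valve=0, mitral_valve=0, tricuspid_valve=0,
                                   carotid_arteries=0, lungs=0, breast=0, esophagus=0,
                                   normal_tissue=0) for m in ("photon", "proton")}
        p = lr.PatientRecord(id="n", sex="male", age_at_treatment=40, smoking="never",
                             anthracycline_dose=0, doses=doses)
        decomp = lr.decompose_patient(p, us_rates, cfg)
        for risk in decomp.risks.values():
            assert risk.excess_chemo == 0.0
            assert risk.excess_rt("photon") == 0.0
            assert risk.excess_rt("proton") == 0.0

    def test_cvd_total_is_sum_of_member_causes(self, cohort, us_rates, cfg):
        decomp = lr.decompose_patient(cohort[0], us_rates, cfg)
        for attr in ("background", "chemo"):
            assert getattr(decomp.risks["cvd"], attr) == pytest.approx(
                sum(getattr(decomp.risks[c], attr) for c in lr.CVD_ENDPOINTS), abs=1e-15)

    def test_missing_modality_rejected(self, us_rates, cfg, cohort):
        from dataclasses import replace

        p = replace(cohort[0], doses={"photon": cohort[0].doses["photon"]})
        with pytest.raises(lr.DataValidationError, match="proton"):
            lr.decompose_patient(p, us_rates, cfg)

    def test_unknown_smoking_flagged(self, us_rates, cfg, cohort):
        from dataclasses import replace

        p = replace(cohort[0], smoking="unknown")
        decomp = lr.decompose_patient(p, us_rates, cfg)
        assert "smoking_unknown_treated_as_never" in decomp.flags


class TestStandardize:
    def test_two_strata_hand_computed(self):
        values = pd.Series([0.02, 0.06], index=["a", "b"])
        strata = pd.Series(["s1", "s2"], index=["a", "b"])
        standard = pd.Series({"s1": 0.5, "s2": 0.5})
        assert standardize(values, strata, standard).value == pytest.approx(0.04, abs=1e-15)

    def test_matching_composition_equals_crude_mean(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.uniform(0, 0.2, 40))
        strata = pd.Series(rng.choice(["x", "y", "z"], 40))
        result = standardize(values, strata)  # standard = own distribution
        assert result.value == pytest.approx(values.mean(), abs=1e-12)
        assert not result.flagged

    def test_all_weight_on_one_stratum(self):
        values = pd.Series([1.0, 2.0, 10.0])
        strata = pd.Series(["a", "a", "b"])
        standard = pd.Series({"a": 1.0, "b": 0.0})
        assert standardize(values, strata, standard).value == pytest.approx(1.5)

    def test_empty_stratum_with_weight_flags_not_renormalizes(self):
        values = pd.Series([1.0, 2.0])
        strata = pd.Series(["a", "a"])
        standard = pd.Series({"a": 0.5, "b": 0.5})
        result = standardize(values, strata, standard)
        assert result.flagged and result.missing_strata == ("b",)
        renorm = standardize(values, strata, standard, renormalize=True)
        assert not renorm.flagged
        assert renorm.value == pytest.approx(1.5)

    def test_age_sex_stratum_banding(self):
        p = lr.PatientRecord(id="x", sex="female", age_at_treatment=35,
                             smoking="never", anthracycline_dose=0)
        assert age_sex_stratum(p) == ("[35,45)", "female")


class TestScenario:
    def test_smoker_risk_exceeds_never_smoker(self, us_rates, cfg):
        doses = lr.DoseSummary(modality="photon", whole_heart=16.5, left_ventricle=11.2,
                               aortic_valve=21, mitral_valve=21, tricuspid_valve=21,
                               carotid_arteries=25, lungs=9.5, breast=3.7,
                               esophagus=16.4, normal_tissue=4.7)
        never = lr.scenario_risk(30, "male", "never", doses, 340, us_rates, cfg)
        smoker = lr.scenario_risk(30, "male", "current", doses, 340, us_rates, cfg)
        for g in ("cvd", "lung_cancer"):
            for m in ("photon", "proton"):
                assert smoker.risks[g].full[m] > never.risks[g].full[m]

    def test_high_overlap_doses_widen_modality_gap(self, us_rates, cfg):
        def gap(photon_d, proton_d):
            doses = {
                "photon": lr.DoseSummary(modality="photon", **photon_d),
                "proton": lr.DoseSummary(modality="proton", **proton_d),
            }
            s = lr.scenario_risk(30, "female", "never", doses, 340, us_rates, cfg)
            return s.risks["cvd"].full["photon"] - s.risks["cvd"].full["proton"]

        common = dict(carotid_arteries=25, lungs=8, breast=2, esophagus=16,
                      normal_tissue=4)
        ge40_gap = gap(dict(whole_heart=16.5, left_ventricle=11.2, aortic_valve=21,
                            mitral_valve=21, tricuspid_valve=21, **common),
                       dict(whole_heart=13.3, left_ventricle=5.7, aortic_valve=15.9,
                            mitral_valve=15.9, tricuspid_valve=15.9, **common))
        lt40_gap = gap(dict(whole_heart=6.7, left_ventricle=3.0, aortic_valve=11.2,
                            mitral_valve=11.2, tricuspid_valve=11.2, **common),
                       dict(whole_heart=7.1, left_ventricle=2.1, aortic_valve=9.5,
                            mitral_valve=9.5, tricuspid_valve=9.5, **common))
        assert ge40_gap > lt40_gap > 0


def test_excess_risk_regression_recovers_err_sign_and_ordering(us_rates, cfg):
    """On a synthetic cohort, regressing radiation excess against driving
    dose recovers the generating ERR's sign, and halving the ERR halves
    the recovered slope (ordering preserved)."""
    from scipy import stats

    cohort, _ = lr.simulate_cohort(lr.CohortSimSpec(seed=77, n_patients=150))
    half = cfg.model_copy(deep=True)
    half.endpoints["lung_cancer"].err_per_gy = cfg.endpoints["lung_cancer"].err_per_gy / 2

    def slope(config):
        doses, excess = [], []
        for p in cohort:
            d = lr.decompose_patient(p, us_rates, config)
            doses.append(p.doses["photon"].get("lungs"))
            # relative excess ~ ERR * D, free of age/sex/smoking confounding
            r = d.risks["lung_cancer"]
            excess.append(r.full["photon"] / r.chemo - 1.0)
        return stats.linregress(doses, excess)

    full_fit = slope(cfg)
    assert full_fit.slope > 0 and full_fit.pvalue < 1e-6
    half_fit = slope(half)
    assert 0 < half_fit.slope < full_fit.slope


def test_predict_cohort_report_shape_and_determinism(cohort, regions, cfg):
    r1 = lr.predict_cohort(cohort, regions, cfg)
    r2 = lr.predict_cohort(cohort, regions, cfg)
    assert r1.report.equals(r2.report)
    assert set(r1.report["disease"]) == {"cvd", "lung_cancer", "breast_cancer",
                                         "esophageal_cancer"}
    assert set(r1.report["region"]) == set(regions)
    assert set(r1.report["modality"]) == {"photon", "proton"}
    assert ((r1.report["amr30_pct"] >= 0) & (r1.report["amr30_pct"] <= 100)).all()
    all_rows = r1.report[(r1.report["patient_group"] == "all")
                         & (r1.report["disease"] == "cvd")]
    assert len(all_rows) == len(regions) * 2
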