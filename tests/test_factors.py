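"""Threshold derivation: printed cuts, inequality directions, unknowns."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from prestart import ThresholdConfig, TriState, derive_profile
from prestart.errors import ConfigurationError, ValidationError
from prestart.factors import (
    derive_family_history,
    derive_high_bp,
    derive_high_glucose,
    derive_high_sugar,
    derive_high_waist,
    derive_low_fruit_veg,
    derive_low_physical_activity,
    derive_metabolic_syndrome,
    derive_overweight_obese,
    derive_parental_obesity,
    derive_rapid_weight_gain,
    derive_screen_time,
)
from .test_cohort import make_record

P, A, U = TriState.PRESENT, TriState.ABSENT, TriState.UNKNOWN
CFG = ThresholdConfig()


class TestBoundaries:
    """Each printed cut classifies its boundary value on the printed side:
    'high' factors are inclusive (>=), 'low' factors strict (<)."""

    @pytest.mark.parametrize("z, expected", [
        (1.04, P), (1.05, P), (1.03, A), (0.0, A), (None, U),
    ])
    def test_overweight_obese_at_85th_percentile(self, z, expected):
        assert derive_overweight_obese(z, CFG) is expected

    @pytest.mark.parametrize("waist, age, sex, expected", [
        (84.5, 12, "male", P), (84.4, 12, "male", A),
        (81.2, 12, "female", P), (81.1, 12, "female", A),
        (87.9, 13, "male", P), (87.8, 13, "male", A),
        (84.1, 13, "female", P), (84.0, 13, "female", A),
        (91.3, 14, "male", P), (91.2, 14, "male", A),
        (86.9, 14, "female", P), (86.8, 14, "female", A),
        (None, 14, "male", U),
    ])
    def test_waist_age_sex_cut_points(self, waist, age, sex, expected):
        assert derive_high_waist(waist, age, sex, CFG) is expected

    def test_waist_unconfigured_age_errors(self):
        with pytest.raises(ConfigurationError):
            derive_high_waist(80.0, 11, "male", CFG)

    @pytest.mark.parametrize("hours, expected", [
        (2.0, P), (1.99, A), (0.0, A), (None, U),
    ])
    def test_screen_time_two_hours_inclusive(self, hours, expected):
        assert derive_screen_time(hours, CFG) is expected

    @pytest.mark.parametrize("minutes, expected", [
        (60.0, A), (59.9, P), (0.0, P), (None, U),
    ])
    def test_low_activity_strict_below_sixty(self, minutes, expected):
        assert derive_low_physical_activity(minutes, CFG) is expected

    @pytest.mark.parametrize("portions, expected", [
        (5.0, A), (4.9, P), (None, U),
    ])
    def test_low_fruit_veg_strict_below_five(self, portions, expected):
        assert derive_low_fruit_veg(portions, CFG) is expected

    @pytest.mark.parametrize("ml, expected", [
        (532.0, P), (531.9, A), (None, U),
    ])
    def test_sugar_one_and_a_half_cans(self, ml, expected):
        assert derive_high_sugar(ml, CFG) is expected

    @pytest.mark.parametrize("rate, expected", [
        (908.0, P), (907.9, A), (500.0, A), (None, U),
    ])
    def test_rapid_weight_gain_two_pounds(self, rate, expected):
        assert derive_rapid_weight_gain(rate, CFG) is expected

    def test_negative_exposures_rejected(self):
        for fn in (derive_screen_time, derive_low_physical_activity,
                   derive_high_sugar, derive_rapid_weight_gain):
            with pytest.raises(ValidationError):
                fn(-1.0, CFG)


class TestParentalObesity:
    def test_white_european_cut_thirty(self):
        assert derive_parental_obesity(30.0, P, None, U, CFG) is P
        assert derive_parental_obesity(29.9, P, 24.0, P, CFG) is A

    def test_other_ethnicity_cut_twenty_seven(self):
        assert derive_parental_obesity(27.5, A, 24.0, P, CFG) is P

    def test_both_known_below_is_absent(self):
        assert derive_parental_obesity(24.0, P, 24.0, P, CFG) is A

    def test_unknown_ethnicity_between_cuts_is_unknown(self):
        # 28 is obese if non-White-European, not if White European
        assert derive_parental_obesity(28.0, U, 20.0, P, CFG) is U
        # above the stricter cut the answer is ethnicity-free
        assert derive_parental_obesity(31.0, U, None, U, CFG) is P
        assert derive_parental_obesity(26.0, U, 25.0, U, CFG) is A

    def test_all_unknown_propagates(self):
        assert derive_parental_obesity(None, U, None, U, CFG) is U


class TestFamilyHistory:
    @pytest.mark.parametrize("first, second, include, expected", [
        (A, P, True, P),
        (A, P, False, A),
        (U, A, True, U),
        (P, U, True, P),
        (A, A, True, A),
    ])
    def test_second_degree_extension(self, first, second, include, expected):
        assert derive_family_history(first, second, include) is expected


class TestBloodPressure:
    def test_average_of_last_two_readings(self):
        # (122+124)/2 = 123 >= 120 and (81+83)/2 = 82 >= 80
        assert derive_high_bp(
            [(118, 78), (122, 81), (124, 83)], CFG) is P

    def test_conjunction_systolic_alone_insufficient(self):
        assert derive_high_bp(
            [(130, 70), (135, 72), (133, 74)], CFG) is A

    def test_single_reading_used_directly(self):
        assert derive_high_bp([(125, 85)], CFG) is P
        assert derive_high_bp([(125, 75)], CFG) is A

    def test_no_readings_unknown(self):
        assert derive_high_bp([], CFG) is U

    def test_first_reading_discarded(self):
        # first reading alone would be high; the last two are not
        assert derive_high_bp([(150, 95), (110, 70), (112, 72)], CFG) is A


class TestGlucose:
    @pytest.mark.parametrize("glucose, fasting, expected", [
        (7.0, P, P), (6.9, P, A),
        (11.1, A, P), (7.5, A, A),
        (11.1, U, P), (7.5, U, A),  # unknown status -> non-fasting cut
        (None, P, U),
    ])
    def test_fasting_dependent_cuts(self, glucose, fasting, expected):
        assert derive_high_glucose(glucose, fasting, CFG) is expected


class TestMetabolicSyndrome:
    def _record(self, **overrides):
        # baseline: all four components known absent
        base = dict(
            bp_readings=[(100.0, 60.0), (100.0, 60.0), (100.0, 60.0)],
            total_chol_mmol_l=4.0, ldl_mmol_l=2.0,
            triglycerides_mmol_l=1.0, glucose_mmol_l=4.5,
            fasting=P,
        )
        base.update(overrides)
        return make_record(**base)

    def test_three_of_four_present(self):
        rec = self._record(
            bp_readings=[(125.0, 85.0)] * 3,
            triglycerides_mmol_l=2.0,
            glucose_mmol_l=6.0,
        )
        assert derive_metabolic_syndrome(rec, CFG) is P

    def test_two_present_two_absent(self):
        rec = self._record(
            bp_readings=[(125.0, 85.0)] * 3, triglycerides_mmol_l=2.0)
        assert derive_metabolic_syndrome(rec, CFG) is A

    def test_two_present_two_unknown_could_reach_three(self):
        rec = self._record(
            bp_readings=[(125.0, 85.0)] * 3, triglycerides_mmol_l=2.0,
            glucose_mmol_l=None, total_chol_mmol_l=None, ldl_mmol_l=None)
        assert derive_metabolic_syndrome(rec, CFG) is U

    def test_diabetes_range_glucose_not_a_component(self):
        # "high glucose but not in the diabetes range"
        rec = self._record(glucose_mmol_l=8.0)
        assert derive_metabolic_syndrome(rec, CFG) is A

    def test_cholesterol_via_ldl(self):
        rec = self._record(total_chol_mmol_l=4.0, ldl_mmol_l=3.0,
                           bp_readings=[(125.0, 85.0)] * 3,
                           triglycerides_mmol_l=1.8)
        assert derive_metabolic_syndrome(rec, CFG) is P


class TestProfile:
    def test_healthy_record_all_absent(self):
        rec = make_record(
            bmi_z=0.0, waist_cm=60.0, screen_hours_per_day=1.0,
            physical_activity_min_per_day=90.0,
            fruit_veg_portions_per_day=6.0, sugary_drink_ml_per_day=100.0,
            infant_weight_gain_g_per_month=500.0,
            parent1_bmi=24.0, parent2_bmi=23.0,
            parent1_white_european=P, parent2_white_european=P,
            breast_fed=P, first_degree_fh_diabetes=A,
            second_degree_fh_diabetes=A, ethnicity_caucasian=P,
            acanthosis_nigricans=A, fatty_liver=A, pcos=A,
            prediabetes_flag=A, sga_flag=A,
            glucose_mmol_l=4.5, hba1c_pct=5.0, total_chol_mmol_l=4.0,
            ldl_mmol_l=2.0, triglycerides_mmol_l=1.0, fasting=P,
        )
        profile = derive_profile(rec)
        assert all(v is A for v in profile.values.values())

    def test_breast_fed_inverts_to_not_breast_fed(self):
        rec = make_record(breast_fed=A)
        assert derive_profile(rec)["BF"] is P

    def test_unknown_ethnicity_propagates(self):
        rec = make_record(ethnicity_caucasian=U)
        assert derive_profile(rec)["ETH"] is U

    def test_fully_unknown_record_derives_no_known_factor(self):
        """No factor may be present or absent when every contributing
        raw field is unknown."""
        rec = make_record(
            bmi=None, bmi_z=None, waist_cm=None, screen_hours_per_day=None,
            physical_activity_min_per_day=None,
            fruit_veg_portions_per_day=None, sugary_drink_ml_per_day=None,
            bp_readings=[], breast_fed=U, first_degree_fh_diabetes=U,
        )
        profile = derive_profile(rec)
        assert all(v is U for v in profile.values.values())


class TestMonotonicity:
    """Raising an exposure never flips its 'high' factor present->absent;
    raising a protective quantity never flips its 'low' factor
    absent->present."""

    @given(st.floats(40, 150), st.floats(0, 30))
    def test_waist_monotone(self, waist, bump):
        lo = derive_high_waist(waist, 13, "male", CFG)
        hi = derive_high_waist(waist + bump, 13, "male", CFG)
        assert not (lo is P and hi is A)

    @given(st.floats(0, 12), st.floats(0, 6))
    def test_screen_monotone(self, hours, bump):
        lo = derive_screen_time(hours, CFG)
        hi = derive_screen_time(hours + bump, CFG)
        assert not (lo is P and hi is A)

    @given(st.floats(0, 300), st.floats(0, 120))
    def test_activity_protective(self, minutes, bump):
        lo = derive_low_physical_activity(minutes, CFG)
        hi = derive_low_physical_activity(minutes + bump, CFG)
        assert not (lo is A and hi is P)

    @given(st.floats(15, 45), st.floats(0, 10))
    def test_parent_bmi_monotone(self, bmi, bump):
        lo = derive_parental_obesity(bmi, P, None, U, CFG)
        hi = derive_parental_obesity(bmi + bump, P, None, U, CFG)
        assert not (lo is P and hi in (A, U))
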