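"""Risk-factor derivation: raw measurements -> tri-state factor profile.

Each factor follows the screening tool's printed threshold, with the
printed inequality direction: "high" factors are inclusive (>=), "low"
factors strict (<).  Unknown raw values propagate to unknown factors;
they never default to absent at this layer (the rule engine decides how
to treat unknowns).

Factor abbreviations used throughout the package:

==== ==========================================================
OO   overweight/obese (BMI z-score >= 1.04, the 85th percentile)
WC   high waist circumference (age/sex cut points)
ST   high screen time (>= 2 h/day)
LPA  low physical activity (< 60 min/day)
LFV  low fruit & vegetable intake (< 5 portions/day)
SI   high sugar intake (>= 532 ml sugary drinks/day)
FH   first-degree family history of diabetes
FH2  first- or second-degree family history of diabetes
OP   parental obesity (BMI >= 30 White European, >= 27 otherwise)
BF   never breast fed
AN   acanthosis nigricans
FLD  fatty liver disease
PCOS polycystic ovary syndrome
PDM  pre-diabetes
MS   metabolic syndrome (>= 3 of 4 components)
ETH  non-Caucasian ethnicity
WG04 rapid infant weight gain (>= 908 g/month)
SGA  small for gestational age
==== ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .cohort import ParticipantRecord
from .errors import ConfigurationError, ValidationError
from .tristate import TriState, tri_any

#: canonical factor names (short code -> long name)
FACTOR_NAMES: Dict[str, str] = {
    "OO": "overweight_obese",
    "WC": "high_waist",
    "ST": "screen_time",
    "LPA": "low_physical_activity",
    "LFV": "low_fruit_veg",
    "SI": "high_sugar",
    "FH": "family_history",
    "FH2": "family_history_ext",
    "OP": "parental_obesity",
    "BF": "not_breast_fed",
    "AN": "acanthosis_nigricans",
    "FLD": "fatty_liver",
    "PCOS": "pcos",
    "PDM": "prediabetes",
    "MS": "metabolic_syndrome",
    "ETH": "non_caucasian",
    "WG04": "rapid_weight_gain",
    "SGA": "small_for_gestational_age",
}

ALL_FACTORS: Tuple[str, ...] = tuple(FACTOR_NAMES)


@dataclass
class ThresholdConfig:
    """All tunable cut points, with the tool's published defaults.

    The metabolic-syndrome component cuts (total cholesterol, LDL,
    triglycerides, non-diabetic glucose band) are documented assumptions:
    the tool's definition lists the four components but not their cuts,
    so standard clinical values are used and every one is overridable.
    """

    waist_cutpoints: Dict[Tuple[int, str], float] = field(
        default_factory=lambda: {
            (12, "male"): 84.5,
            (12, "female"): 81.2,
            (13, "male"): 87.9,
            (13, "female"): 84.1,
            (14, "male"): 91.3,
            (14, "female"): 86.9,
        }
    )
    bmi_z_cut: float = 1.04          # 85th percentile
    screen_hours_cut: float = 2.0
    pa_min_cut: float = 60.0
    fv_portions_cut: float = 5.0
    sugar_ml_cut: float = 532.0      # 1.5 cans
    parent_bmi_cut_we: float = 30.0
    parent_bmi_cut_other: float = 27.0
    weight_gain_cut_g_per_month: float = 908.0   # 2 lb / month
    bp_sys_cut: float = 120.0
    bp_dia_cut: float = 80.0
    glucose_fasting_cut: float = 7.0
    glucose_nonfasting_cut: float = 11.1
    ms_min_components: int = 3
    ms_chol_total_cut: float = 6.0
    ms_ldl_cut: float = 3.0
    ms_tg_cut: float = 1.7
    # "high glucose but not in the diabetes range": impaired fasting band
    ms_glucose_band: Tuple[float, float] = (5.6, 7.0)
    prediabetes_hba1c_band: Tuple[float, float] = (6.0, 6.5)

    def __post_init__(self) -> None:
        for name in (
            "bmi_z_cut", "screen_hours_cut", "pa_min_cut", "fv_portions_cut",
            "sugar_ml_cut", "parent_bmi_cut_we", "parent_bmi_cut_other",
            "weight_gain_cut_g_per_month", "bp_sys_cut", "bp_dia_cut",
            "glucose_fasting_cut", "glucose_nonfasting_cut",
            "ms_chol_total_cut", "ms_ldl_cut", "ms_tg_cut",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for cut in self.waist_cutpoints.values():
            if not cut > 0:
                raise ConfigurationError("waist cut points must be positive")
        if not 1 <= self.ms_min_components <= 4:
            raise ConfigurationError("ms_min_components must be in [1, 4]")

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        """Load overrides from a YAML file; unlisted cuts keep defaults."""
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        if "waist_cutpoints" in raw:
            kwargs["waist_cutpoints"] = {
                (int(entry["age"]), str(entry["sex"])): float(entry["cm"])
                for entry in raw.pop("waist_cutpoints")
            }
        for key, value in raw.items():
            if key in ("ms_glucose_band", "prediabetes_hba1c_band"):
                kwargs[key] = tuple(float(v) for v in value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["waist_cutpoints"] = [
            {"age": age, "sex": sex, "cm": cm}
            for (age, sex), cm in self.waist_cutpoints.items()
        ]
        data["ms_glucose_band"] = list(self.ms_glucose_band)
        data["prediabetes_hba1c_band"] = list(self.prediabetes_hba1c_band)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


#: module-level defaults, shared by callers that pass no config
DEFAULT_CONFIG = ThresholdConfig()


@dataclass
class RiskFactorProfile:
    """Tri-state value for every named risk factor."""

    values: Dict[str, TriState]

    def __post_init__(self) -> None:
        missing = set(ALL_FACTORS) - set(self.values)
        extra = set(self.values) - set(ALL_FACTORS)
        if missing or extra:
            raise ValidationError(
                f"profile must cover exactly the canonical factors; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, factor: str) -> TriState:
        return self.values[factor]


def _cut_ge(value: Optional[float], cut: float) -> TriState:
    """present iff value >= cut; unknown propagates."""
    if value is None:
        return TriState.UNKNOWN
    return TriState.from_bool(value >= cut)


def _cut_lt(value: Optional[float], cut: float) -> TriState:
    """present iff value < cut (a 'low' factor); unknown propagates."""
    if value is None:
        return TriState.UNKNOWN
    return TriState.from_bool(value < cut)


def _check_nonnegative(value: Optional[float], what: str) -> None:
    if value is not None and value < 0:
        raise ValidationError(f"{what} must be non-negative, got {value}")


def derive_overweight_obese(
    bmi_z: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """Overweight/obese: BMI z-score >= 1.04 (the 85th percentile), inclusive."""
    return _cut_ge(bmi_z, cfg.bmi_z_cut)


def derive_high_waist(
    waist_cm: Optional[float],
    age_years: int,
    sex: str,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> TriState:
    """High waist circumference against the age/sex cut point."""
    key = (age_years, sex)
    if key not in cfg.waist_cutpoints:
        raise ConfigurationError(
            f"no waist cut point configured for age={age_years}, sex={sex}"
        )
    return _cut_ge(waist_cm, cfg.waist_cutpoints[key])


def derive_screen_time(
    hours: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """High screen time: >= 2 h of TV/computer viewing per day."""
    _check_nonnegative(hours, "screen hours")
    return _cut_ge(hours, cfg.screen_hours_cut)


def derive_low_physical_activity(
    minutes: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """Low physical activity: strictly less than 60 min per day."""
    _check_nonnegative(minutes, "physical activity minutes")
    return _cut_lt(minutes, cfg.pa_min_cut)


def derive_low_fruit_veg(
    portions: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """Low fruit & vegetable intake: strictly less than 5 portions per day."""
    _check_nonnegative(portions, "fruit/veg portions")
    return _cut_lt(portions, cfg.fv_portions_cut)


def derive_high_sugar(
    ml: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """High sugar intake: >= 1.5 cans (532 ml) of sugary drinks per day."""
    _check_nonnegative(ml, "sugary drink ml")
    return _cut_ge(ml, cfg.sugar_ml_cut)


def _parent_obese(
    bmi: Optional[float], white_european: TriState, cfg: ThresholdConfig
) -> TriState:
    if bmi is None:
        return TriState.UNKNOWN
    if white_european is TriState.PRESENT:
        return TriState.from_bool(bmi >= cfg.parent_bmi_cut_we)
    if white_european is TriState.ABSENT:
        return TriState.from_bool(bmi >= cfg.parent_bmi_cut_other)
    # unknown ethnicity: above the stricter cut is obese under either
    # ethnicity; between the cuts the answer depends on ethnicity
    if bmi >= cfg.parent_bmi_cut_we:
        return TriState.PRESENT
    if bmi < cfg.parent_bmi_cut_other:
        return TriState.ABSENT
    return TriState.UNKNOWN


def derive_parental_obesity(
    parent1_bmi: Optional[float],
    parent1_we: TriState,
    parent2_bmi: Optional[float],
    parent2_we: TriState,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> TriState:
    """Parental obesity: either parent's BMI >= 30 (White European) or
    >= 27 (other ethnicities)."""
    return tri_any([
        _parent_obese(parent1_bmi, parent1_we, cfg),
        _parent_obese(parent2_bmi, parent2_we, cfg),
    ])


def derive_family_history(
    first_degree: TriState,
    second_degree: TriState,
    include_second: bool = False,
) -> TriState:
    """Family history of diabetes, optionally extended to 2nd degree."""
    if not include_second:
        return first_degree
    return tri_any([first_degree, second_degree])


def derive_high_bp(
    bp_readings: Sequence[Tuple[float, float]],
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> TriState:
    """High blood pressure from up to three readings.

    With two or more readings the average of the last two is used (the
    first reading is discarded as an acclimatisation measurement); with
    one reading that reading is used; with none the result is unknown.
    High iff mean systolic >= 120 AND mean diastolic >= 80.
    """
    if not bp_readings:
        return TriState.UNKNOWN
    if len(bp_readings) >= 2:
        used = bp_readings[-2:]
    else:
        used = bp_readings
    mean_sys = sum(r[0] for r in used) / len(used)
    mean_dia = sum(r[1] for r in used) / len(used)
    return TriState.from_bool(
        mean_sys >= cfg.bp_sys_cut and mean_dia >= cfg.bp_dia_cut
    )


def derive_high_glucose(
    glucose_mmol_l: Optional[float],
    fasting: TriState,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> TriState:
    """Diabetes-range glucose: >= 7.0 mmol/L fasting, >= 11.1 non-fasting.

    When fasting status is unknown the non-fasting cut applies
    (participants were not required to fast, so unknown status is treated
    as non-fasting — the conservative choice).
    """
    if glucose_mmol_l is None:
        return TriState.UNKNOWN
    if fasting is TriState.PRESENT:
        cut = cfg.glucose_fasting_cut
    else:
        cut = cfg.glucose_nonfasting_cut
    return TriState.from_bool(glucose_mmol_l >= cut)


def _ms_glucose_component(
    glucose_mmol_l: Optional[float], fasting: TriState, cfg: ThresholdConfig
) -> TriState:
    """High glucose but not in the diabetes range (impaired fasting band).

    The band is defined on fasting samples.  For non-fasting or
    unknown-status samples, a glucose below the band's lower bound is
    known absent and a diabetes-range glucose is known absent (excluded
    by definition); in between, the fasting value is unknowable, so the
    component is unknown.
    """
    if glucose_mmol_l is None:
        return TriState.UNKNOWN
    low, high = cfg.ms_glucose_band
    if fasting is TriState.PRESENT:
        return TriState.from_bool(low <= glucose_mmol_l < high)
    if glucose_mmol_l < low:
        return TriState.ABSENT
    if glucose_mmol_l >= cfg.glucose_nonfasting_cut:
        return TriState.ABSENT
    return TriState.UNKNOWN


def derive_metabolic_syndrome(
    record: ParticipantRecord, cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """Metabolic syndrome: >= 3 of {high BP, high cholesterol, high
    triglycerides, high non-diabetic glucose}.

    Three-valued counting: present when enough components are known
    present; absent when the present + unknown components cannot reach
    the minimum; unknown otherwise.
    """
    chol = tri_any([
        _cut_ge(record.total_chol_mmol_l, cfg.ms_chol_total_cut),
        _cut_ge(record.ldl_mmol_l, cfg.ms_ldl_cut),
    ])
    components = [
        derive_high_bp(record.bp_readings, cfg),
        chol,
        _cut_ge(record.triglycerides_mmol_l, cfg.ms_tg_cut),
        _ms_glucose_component(record.glucose_mmol_l, record.fasting, cfg),
    ]
    n_present = sum(c is TriState.PRESENT for c in components)
    n_unknown = sum(c is TriState.UNKNOWN for c in components)
    if n_present >= cfg.ms_min_components:
        return TriState.PRESENT
    if n_present + n_unknown < cfg.ms_min_components:
        return TriState.ABSENT
    return TriState.UNKNOWN


def derive_rapid_weight_gain(
    rate_g_per_month: Optional[float], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> TriState:
    """Rapid infant weight gain: >= 908 g (2 lb) per month."""
    _check_nonnegative(rate_g_per_month, "infant weight gain rate")
    return _cut_ge(rate_g_per_month, cfg.weight_gain_cut_g_per_month)


def derive_prediabetes(
    hba1c_pct: Optional[float],
    prediabetes_flag: TriState,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> TriState:
    """Pre-diabetes: HbA1c in the [6.0%, 6.5%) band, or an explicit
    clinician flag."""
    if prediabetes_flag is TriState.PRESENT:
        return TriState.PRESENT
    if hba1c_pct is None:
        return prediabetes_flag
    low, high = cfg.prediabetes_hba1c_band
    return TriState.from_bool(low <= hba1c_pct < high)


def derive_profile(
    record: ParticipantRecord, cfg: ThresholdConfig = DEFAULT_CONFIG
) -> RiskFactorProfile:
    """Derive the full tri-state risk-factor profile for one record."""
    values: Dict[str, TriState] = {
        "OO": derive_overweight_obese(record.bmi_z, cfg),
        "WC": derive_high_waist(record.waist_cm, record.age_years, record.sex, cfg),
        "ST": derive_screen_time(record.screen_hours_per_day, cfg),
        "LPA": derive_low_physical_activity(record.physical_activity_min_per_day, cfg),
        "LFV": derive_low_fruit_veg(record.fruit_veg_portions_per_day, cfg),
        "SI": derive_high_sugar(record.sugary_drink_ml_per_day, cfg),
        "FH": derive_family_history(
            record.first_degree_fh_diabetes,
            record.second_degree_fh_diabetes,
            include_second=False,
        ),
        "FH2": derive_family_history(
            record.first_degree_fh_diabetes,
            record.second_degree_fh_diabetes,
            include_second=True,
        ),
        "OP": derive_parental_obesity(
            record.parent1_bmi, record.parent1_white_european,
            record.parent2_bmi, record.parent2_white_european, cfg,
        ),
        "BF": record.breast_fed.negate(),        # never breast fed
        "AN": record.acanthosis_nigricans,
        "FLD": record.fatty_liver,
        "PCOS": record.pcos,
        "PDM": derive_prediabetes(record.hba1c_pct, record.prediabetes_flag, cfg),
        "MS": derive_metabolic_syndrome(record, cfg),
        "ETH": record.ethnicity_caucasian.negate(),  # non-Caucasian
        "WG04": derive_rapid_weight_gain(record.infant_weight_gain_g_per_month, cfg),
        "SGA": record.sga_flag,
    }
    return RiskFactorProfile(values)


def derive_profiles(
    records: Sequence[ParticipantRecord], cfg: ThresholdConfig = DEFAULT_CONFIG
) -> List[RiskFactorProfile]:
    return [derive_profile(r, cfg) for r in records]
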