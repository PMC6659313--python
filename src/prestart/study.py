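"""Published summary numbers from the five-country evaluation study.

The individual-level data are request-only, but the publication prints
the marginal counts and rounded metrics.  These constants are inputs to
the reconstruction and cross-check routines — every derived quantity in
this package is recomputed from them at run time, not copied.
"""

from typing import Dict

#: participants recruited per country
COUNTRY_N: Dict[str, int] = {
    "UK": 81, "Germany": 100, "Portugal": 226, "Spain": 129, "Greece": 100,
}

TOTAL_N: int = sum(COUNTRY_N.values())  # 636

#: clinician-consensus high-risk counts per country
CLINICIAN_HIGH_BY_COUNTRY: Dict[str, int] = {
    "UK": 27, "Germany": 53, "Portugal": 43, "Spain": 67, "Greece": 51,
}

#: original (initial) tool high-risk counts per country
INITIAL_TOOL_HIGH_BY_COUNTRY: Dict[str, int] = {
    "UK": 18, "Germany": 51, "Portugal": 30, "Spain": 51, "Greece": 64,
}

#: refined (final) tool high-risk counts per country
REFINED_TOOL_HIGH_BY_COUNTRY: Dict[str, int] = {
    "UK": 26, "Germany": 63, "Portugal": 69, "Spain": 116, "Greece": 69,
}

#: overall marginals
CLINICIAN_HIGH: int = 241
INITIAL_TOOL_HIGH: int = 214
REFINED_TOOL_HIGH: int = 343

#: published accuracy metrics (percent, 1 dp) for the initial tool
INITIAL_METRICS_PCT: Dict[str, float] = {
    "sensitivity": 63.9, "specificity": 84.8, "ppv": 72.0, "npv": 79.4,
}

#: published accuracy metrics (percent, 1 dp) for the refined tool
REFINED_METRICS_PCT: Dict[str, float] = {
    "sensitivity": 92.5, "specificity": 66.8, "ppv": 63.0, "npv": 93.6,
}

#: proportion of cases where the two primary clinician raters agreed
RATER_AGREEMENT: float = 0.76

#: refined-tool risk-factor prevalences (proportion of n=636)
FACTOR_PREVALENCE: Dict[str, float] = {
    "OO": 0.558,   # BMI above the 85th percentile
    "WC": 0.315,   # high waist circumference
    "ST": 0.552,   # > 2 h screen time per day
    "LPA": 0.068,  # < 60 min physical activity per day
    "LFV": 0.552,  # < 5 portions fruit/veg per day
    "FH": 0.115,   # family history of diabetes (1st or 2nd degree)
    "SI": 0.140,   # high sugar intake
    "BF": 0.176,   # never breast fed
    "OP": 0.344,   # either parent obese
}
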