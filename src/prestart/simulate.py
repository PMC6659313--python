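"""Seeded synthetic cohort generator and noisy-clinician rater simulator.

The evaluation study's individual-level data are available only on
request, so this module generates cohorts with the same statistical
skeleton: the five country strata at their recruited sizes, risk-factor
prevalences matching the published refined-tool prevalence table, country
-level anthropometric and biochemical moments, the over-sampled BMI
distribution, structurally missing ethnicity in Greece and Portugal, and
a two-plus-tiebreak clinician rating process calibrated to the published
76% pairwise agreement.

Threshold-defined factors are generated indicator-first: a Gaussian
copula draws each factor's indicator at its target prevalence (with
positive dependence between adiposity-linked indicators), then the
underlying measurement is drawn from a truncated normal on the matching
side of the cut.  This guarantees the factor prevalences in expectation;
the numeric marginals are realistic but only approximately match the
country moment targets (see the methods note for what this does and does
not emulate).

The clinician model is an explicit assumption — the study recorded no
data on how clinicians judged — with weight (overweight/obese status) as
the dominant coefficient, reflecting the investigators' own reading of
their raters' behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .cohort import ParticipantRecord
from .errors import CalibrationError, ConfigurationError
from .factors import DEFAULT_CONFIG, ThresholdConfig, derive_profile
from .rules import RiskClassification, RuleSet, classify
from .tristate import TriState
from . import study


# --------------------------------------------------------------------------
# spec types

@dataclass
class CountryStratum:
    """Per-country sample size, demographics and measurement moments."""

    n: int
    pct_male: float
    age_mean: float                      # completed years, in [12, 14]
    p_overweight_obese: float            # P(BMI z >= 1.04)
    p_caucasian: Optional[float]         # None -> ethnicity not collected
    bmi: Tuple[float, float]             # mean, SD (kg/m^2)
    waist: Tuple[float, float]           # mean, SD (cm)
    systolic: Tuple[float, float]        # mean, SD (mmHg)
    diastolic: Tuple[float, float]
    hba1c: Tuple[float, float]           # mean, SD (%)
    glucose: Tuple[float, float]         # mean, SD (mmol/L)
    triglycerides: Tuple[float, float]
    total_chol: Tuple[float, float]
    ldl: Tuple[float, float]

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError("stratum n must be non-negative")
        if not 0 <= self.pct_male <= 1:
            raise ConfigurationError("pct_male must be in [0, 1]")
        if not 12 <= self.age_mean <= 14:
            raise ConfigurationError("age_mean must lie in [12, 14]")
        if not 0 <= self.p_overweight_obese <= 1:
            raise ConfigurationError("p_overweight_obese must be in [0, 1]")
        for name in ("bmi", "waist", "systolic", "diastolic", "hba1c",
                     "glucose", "triglycerides", "total_chol", "ldl"):
            mean, sd = getattr(self, name)
            if sd <= 0:
                raise ConfigurationError(f"{name} SD must be positive")


def _default_strata() -> Dict[str, CountryStratum]:
    """The five published strata at their recruited sizes and moments."""
    return {
        "UK": CountryStratum(
            n=81, pct_male=0.741, age_mean=13.5, p_overweight_obese=0.346,
            p_caucasian=0.457, bmi=(20.5, 4.4), waist=(74.9, 12.1),
            systolic=(110.4, 10.5), diastolic=(65.3, 8.6), hba1c=(5.5, 0.7),
            glucose=(4.9, 0.8), triglycerides=(1.2, 1.4),
            total_chol=(3.4, 1.2), ldl=(1.6, 0.5)),
        "Germany": CountryStratum(
            n=100, pct_male=0.50, age_mean=13.3, p_overweight_obese=0.65,
            p_caucasian=0.92, bmi=(24.9, 6.4), waist=(80.9, 15.9),
            systolic=(115.6, 10.2), diastolic=(70.8, 8.1), hba1c=(5.2, 0.3),
            glucose=(4.8, 0.5), triglycerides=(1.1, 0.7),
            total_chol=(3.5, 0.8), ldl=(2.2, 0.7)),
        "Portugal": CountryStratum(
            n=226, pct_male=0.469, age_mean=13.5, p_overweight_obese=0.323,
            p_caucasian=None, bmi=(20.9, 3.8), waist=(75.0, 10.1),
            systolic=(103.7, 12.5), diastolic=(66.4, 8.5), hba1c=(5.3, 0.4),
            glucose=(5.1, 0.7), triglycerides=(1.1, 0.8),
            total_chol=(3.4, 0.6), ldl=(1.7, 0.4)),
        "Spain": CountryStratum(
            n=129, pct_male=0.465, age_mean=12.9, p_overweight_obese=0.907,
            p_caucasian=0.861, bmi=(25.6, 4.0), waist=(84.6, 11.3),
            systolic=(113.9, 12.2), diastolic=(66.6, 8.6), hba1c=(5.4, 0.3),
            glucose=(4.6, 0.7), triglycerides=(0.9, 0.4),
            total_chol=(3.5, 0.7), ldl=(1.9, 0.1)),
        "Greece": CountryStratum(
            n=100, pct_male=0.56, age_mean=12.9, p_overweight_obese=0.71,
            p_caucasian=None, bmi=(25.3, 5.6), waist=(84.8, 14.3),
            systolic=(113.2, 10.8), diastolic=(67.0, 8.4), hba1c=(5.2, 0.4),
            glucose=(4.4, 0.7), triglycerides=(1.0, 0.6),
            total_chol=(3.5, 1.0), ldl=(1.9, 0.6)),
    }


def _default_prevalences() -> Dict[str, float]:
    """Overall factor prevalence targets.

    The refined tool's published prevalences where available; the
    remaining factors (not in the refined tool, hence not published) use
    plausible paediatric values, documented in the methods note.
    """
    out = dict(study.FACTOR_PREVALENCE)   # OO, WC, ST, LPA, LFV, FH, SI, BF, OP
    out.update({
        "AN": 0.03, "FLD": 0.015, "PCOS": 0.02, "SGA": 0.05, "WG04": 0.10,
    })
    return out


def _default_missingness() -> Dict[str, float]:
    """Per-field completely-at-random missingness, at the published
    missing-value counts (out of 636) for fields that report one."""
    n = float(study.TOTAL_N)
    return {
        "waist_cm": 1 / n,
        "bp_readings": 9 / n,
        "hba1c_pct": 34 / n,
        "glucose_mmol_l": 9 / n,
        "total_chol_mmol_l": 43 / n,
        "triglycerides_mmol_l": 50 / n,
        "ldl_mmol_l": 285 / n,
        "infant_weight_gain_g_per_month": 0.05,
    }


@dataclass
class CohortSpec:
    """Everything the generator needs; defaults are the study conditions."""

    strata: Dict[str, CountryStratum] = field(default_factory=_default_strata)
    prevalences: Dict[str, float] = field(default_factory=_default_prevalences)
    #: sampling-frame BMI quota bands (normal / overweight / obese); the
    #: overweight:obese ratio splits the overweight-obese group between
    #: the z in [1.04, 2) and z >= 2 bands
    quota_normal: float = 0.175
    quota_overweight: float = 0.375
    quota_obese: float = 0.40
    missingness: Dict[str, float] = field(default_factory=_default_missingness)
    #: Gaussian-copula correlation between the adiposity latent and the
    #: waist / parental-obesity indicators
    rho_waist: float = 0.7
    rho_parent: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name, stratum in self.strata.items():
            stratum.validate()
        for factor, p in self.prevalences.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(
                    f"prevalence for {factor!r} must be in [0, 1], got {p}"
                )
        quota_sum = self.quota_normal + self.quota_overweight + self.quota_obese
        if quota_sum > 1 + 1e-9:
            raise ConfigurationError(
                f"BMI quota bands must sum to at most 1, got {quota_sum}"
            )
        for rate in self.missingness.values():
            if not 0 <= rate <= 1:
                raise ConfigurationError("missingness rates must be in [0, 1]")
        for rho in (self.rho_waist, self.rho_parent):
            if not -1 < rho < 1:
                raise ConfigurationError("correlations must lie in (-1, 1)")

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.strata.values())


# --------------------------------------------------------------------------
# sampling helpers

def _tnorm(rng: np.random.Generator, mean: float, sd: float,
           low: float, high: float, size: int) -> np.ndarray:
    """Truncated normal via inverse-CDF (vectorised, reproducible)."""
    a = norm.cdf((low - mean) / sd)
    b = norm.cdf((high - mean) / sd)
    if b - a < 1e-12:
        # degenerate band: fall back to the nearer bound
        return np.full(size, low if a > 0.5 else high)
    u = rng.uniform(a, b, size)
    return mean + sd * norm.ppf(u)


def _age_probs(age_mean: float) -> np.ndarray:
    """Categorical distribution over {12, 13, 14} with the given mean."""
    p13 = 0.4
    p12 = (1 - p13 - (age_mean - 13.0)) / 2.0
    p14 = 1 - p13 - p12
    p = np.clip(np.array([p12, p13, p14]), 0.0, 1.0)
    return p / p.sum()


def _correlated_indicator(rng: np.random.Generator, latent: np.ndarray,
                          rho: float, p: float) -> np.ndarray:
    """Bernoulli(p) indicator with Gaussian-copula correlation to latent."""
    n = latent.shape[0]
    b = rho * latent + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    return b > norm.ppf(1 - p)


# --------------------------------------------------------------------------
# cohort generation

def generate_cohort(
    spec: Optional[CohortSpec] = None,
    seed: Optional[int] = None,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> List[ParticipantRecord]:
    """Generate a synthetic cohort; deterministic under a fixed seed.

    ``seed`` overrides ``spec.seed`` when given.  Thresholds in ``cfg``
    are used to place measurements on the intended side of each cut.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    prev = spec.prevalences
    quota_oo = spec.quota_overweight + spec.quota_obese
    p_obese_given_oo = (spec.quota_obese / quota_oo) if quota_oo > 0 else 0.5

    records: List[ParticipantRecord] = []
    counter = 0
    for country, st in spec.strata.items():
        n = st.n
        if n == 0:
            continue
        male = rng.uniform(size=n) < st.pct_male
        sex = np.where(male, "male", "female")
        age = rng.choice([12, 13, 14], size=n, p=_age_probs(st.age_mean))

        # adiposity latent drives the overweight/obese indicator at the
        # country-specific prevalence, and (through the copula) waist and
        # parental obesity at their overall target prevalences
        latent = rng.standard_normal(n)
        oo = latent > norm.ppf(1 - st.p_overweight_obese)
        wc = _correlated_indicator(rng, latent, spec.rho_waist, prev["WC"])
        op = _correlated_indicator(rng, latent, spec.rho_parent, prev["OP"])

        # BMI z-score: overweight band [1.04, 2), obese band [2, 4.5)
        obese = oo & (rng.uniform(size=n) < p_obese_given_oo)
        bmi_z = _tnorm(rng, 0.2, 0.8, -3.5, cfg.bmi_z_cut - 1e-6, n)
        bmi_z[oo] = _tnorm(rng, 1.5, 0.5, cfg.bmi_z_cut, 2.0 - 1e-6,
                           int(oo.sum()))
        bmi_z[obese] = _tnorm(rng, 2.6, 0.7, 2.0, 4.5, int(obese.sum()))
        bmi = np.maximum(13.0, st.bmi[0] + (st.bmi[1] / 1.2) * (bmi_z - 0.9)
                         + rng.normal(0, 0.8, n))

        # waist relative to each participant's age/sex cut point
        cuts = np.array([
            cfg.waist_cutpoints[(int(a), s)] for a, s in zip(age, sex)
        ])
        above = _tnorm(rng, 5.0, 6.0, 0.0, 40.0, n)
        below = _tnorm(rng, 8.0, 5.0, 0.1, 35.0, n)
        waist = np.where(wc, cuts + above, np.maximum(45.0, cuts - below))

        # lifestyle summaries, indicator-first
        st_ind = rng.uniform(size=n) < prev["ST"]
        screen = np.where(
            st_ind,
            _tnorm(rng, 3.2, 1.2, cfg.screen_hours_cut, 12.0, n),
            _tnorm(rng, 1.2, 0.7, 0.05, cfg.screen_hours_cut - 1e-6, n))
        lpa = rng.uniform(size=n) < prev["LPA"]
        pa = np.where(lpa,
                      _tnorm(rng, 40.0, 15.0, 5.0, cfg.pa_min_cut - 1e-6, n),
                      _tnorm(rng, 95.0, 30.0, cfg.pa_min_cut, 300.0, n))
        lfv = rng.uniform(size=n) < prev["LFV"]
        portions = np.where(
            lfv, _tnorm(rng, 3.0, 1.3, 0.5, cfg.fv_portions_cut - 1e-6, n),
            _tnorm(rng, 6.5, 1.5, cfg.fv_portions_cut, 15.0, n))
        si = rng.uniform(size=n) < prev["SI"]
        sugar = np.where(si, _tnorm(rng, 750.0, 250.0, cfg.sugar_ml_cut, 2500.0, n),
                         _tnorm(rng, 200.0, 150.0, 1.0, cfg.sugar_ml_cut - 1e-6, n))

        # perinatal history
        wg = rng.uniform(size=n) < prev["WG04"]
        gain = np.where(
            wg, _tnorm(rng, 1100.0, 250.0, cfg.weight_gain_cut_g_per_month, 2200.0, n),
            _tnorm(rng, 550.0, 200.0, 50.0, cfg.weight_gain_cut_g_per_month - 1e-6, n))
        not_bf = rng.uniform(size=n) < prev["BF"]
        sga = rng.uniform(size=n) < prev["SGA"]

        # parents: when the parental-obesity indicator is set, parent 1 is
        # obese under their ethnicity-specific cut (parent 2 too, ~35%)
        p1_we = rng.uniform(size=n) < 0.85
        p2_we = rng.uniform(size=n) < 0.85
        p2_also = op & (rng.uniform(size=n) < 0.35)
        cut1 = np.where(p1_we, cfg.parent_bmi_cut_we, cfg.parent_bmi_cut_other)
        cut2 = np.where(p2_we, cfg.parent_bmi_cut_we, cfg.parent_bmi_cut_other)
        p1_bmi = np.where(op, cut1 + _tnorm(rng, 3.0, 2.5, 0.0, 20.0, n),
                          cut1 - _tnorm(rng, 4.0, 2.5, 0.05, 10.0, n))
        p2_bmi = np.where(p2_also, cut2 + _tnorm(rng, 3.0, 2.5, 0.0, 20.0, n),
                          cut2 - _tnorm(rng, 4.0, 2.5, 0.05, 10.0, n))

        # family history: the 1st-or-2nd-degree union hits the target
        fh_union = rng.uniform(size=n) < prev["FH"]
        fh_first = fh_union & (rng.uniform(size=n) < 0.6)
        fh_second = fh_union & (~fh_first | (rng.uniform(size=n) < 0.3))

        # clinical signs
        an = rng.uniform(size=n) < prev["AN"]
        fld = rng.uniform(size=n) < prev["FLD"]
        pcos = (~male) & (rng.uniform(size=n) < prev["PCOS"])

        # blood pressure triplet: mild first-reading elevation, systolic
        # always above diastolic
        sys_r = np.stack([
            _tnorm(rng, st.systolic[0] + (3.0 if i == 0 else 0.0),
                   st.systolic[1], 70.0, 190.0, n)
            for i in range(3)
        ])
        dia_r = np.stack([
            _tnorm(rng, st.diastolic[0], st.diastolic[1], 40.0, 120.0, n)
            for i in range(3)
        ])
        dia_r = np.minimum(dia_r, sys_r - 5.0)

        # biochemistry
        hba1c = _tnorm(rng, st.hba1c[0], st.hba1c[1], 3.5, 12.0, n)
        glucose = _tnorm(rng, st.glucose[0], st.glucose[1], 2.5, 20.0, n)
        tg = _tnorm(rng, st.triglycerides[0], st.triglycerides[1], 0.2, 8.0, n)
        chol = _tnorm(rng, st.total_chol[0], st.total_chol[1], 1.5, 12.0, n)
        ldl = _tnorm(rng, st.ldl[0], st.ldl[1], 0.3, 8.0, n)
        fasting_u = rng.uniform(size=n)

        # completely-at-random missingness masks
        miss = {
            fld_name: rng.uniform(size=n) < rate
            for fld_name, rate in spec.missingness.items()
        }

        def _num(arr, i, fld_name):
            if fld_name in miss and miss[fld_name][i]:
                return None
            return float(arr[i])

        caucasian_known = (None if st.p_caucasian is None
                           else rng.uniform(size=n) < st.p_caucasian)

        for i in range(n):
            counter += 1
            if caucasian_known is None:
                eth = TriState.UNKNOWN
            else:
                eth = TriState.from_bool(bool(caucasian_known[i]))
            if "bp_readings" in miss and miss["bp_readings"][i]:
                readings: List[Tuple[float, float]] = []
            else:
                readings = [(float(sys_r[j, i]), float(dia_r[j, i]))
                            for j in range(3)]
            if fasting_u[i] < 0.3:
                fasting = TriState.PRESENT
            elif fasting_u[i] < 0.9:
                fasting = TriState.ABSENT
            else:
                fasting = TriState.UNKNOWN
            records.append(ParticipantRecord(
                id=f"SYN-{counter:05d}",
                country=country,
                sex=str(sex[i]),
                age_years=int(age[i]),
                bmi=float(bmi[i]),
                bmi_z=float(bmi_z[i]),
                waist_cm=_num(waist, i, "waist_cm"),
                screen_hours_per_day=float(screen[i]),
                physical_activity_min_per_day=float(pa[i]),
                fruit_veg_portions_per_day=float(portions[i]),
                sugary_drink_ml_per_day=float(sugar[i]),
                infant_weight_gain_g_per_month=_num(
                    gain, i, "infant_weight_gain_g_per_month"),
                parent1_bmi=float(p1_bmi[i]),
                parent2_bmi=float(p2_bmi[i]),
                glucose_mmol_l=_num(glucose, i, "glucose_mmol_l"),
                hba1c_pct=_num(hba1c, i, "hba1c_pct"),
                total_chol_mmol_l=_num(chol, i, "total_chol_mmol_l"),
                ldl_mmol_l=_num(ldl, i, "ldl_mmol_l"),
                triglycerides_mmol_l=_num(tg, i, "triglycerides_mmol_l"),
                bp_readings=readings,
                breast_fed=TriState.from_bool(not bool(not_bf[i])),
                first_degree_fh_diabetes=TriState.from_bool(bool(fh_first[i])),
                second_degree_fh_diabetes=TriState.from_bool(bool(fh_second[i])),
                ethnicity_caucasian=eth,
                acanthosis_nigricans=TriState.from_bool(bool(an[i])),
                fatty_liver=TriState.from_bool(bool(fld[i])),
                pcos=TriState.from_bool(bool(pcos[i])),
                prediabetes_flag=TriState.UNKNOWN,
                sga_flag=TriState.from_bool(bool(sga[i])),
                parent1_white_european=TriState.from_bool(bool(p1_we[i])),
                parent2_white_european=TriState.from_bool(bool(p2_we[i])),
                fasting=fasting,
            ))
    return records


# --------------------------------------------------------------------------
# clinician rater simulator

def _default_coefficients() -> Dict[str, float]:
    """Weight-dominant latent score: overweight/obese plus two or more
    secondary factors pushes the log-odds above zero."""
    coefs = {"OO": 1.5}
    for factor in ("WC", "FH2", "OP", "BF", "SI", "ST", "LPA", "LFV"):
        coefs[factor] = 0.3
    return coefs


@dataclass
class RaterModel:
    """Latent-score clinician model with independent per-rater noise.

    Each participant's latent log-odds of "judged high risk" is
    ``intercept + sum(coefficients[f] for f present)``; the shared base
    judgement is latent > 0, and each of the three raters independently
    flips it with probability ``noise``.  ``ruleset``, when set, replaces
    the linear score with the rule itself (latent +1 for high, -1 for
    low) — the exact-thresholding limit used in identity tests.
    """

    coefficients: Dict[str, float] = field(default_factory=_default_coefficients)
    intercept: float = -2.0
    noise: float = 0.14
    ruleset: Optional[RuleSet] = None
    n_raters: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 0.5:
            raise ConfigurationError("rater noise must lie in [0, 0.5)")
        for factor, coef in self.coefficients.items():
            if not math.isfinite(coef):
                raise ConfigurationError(f"coefficient for {factor!r} not finite")
        if not math.isfinite(self.intercept):
            raise ConfigurationError("intercept must be finite")

    @classmethod
    def from_ruleset(cls, ruleset: RuleSet, noise: float = 0.0) -> "RaterModel":
        """A clinician that thresholds exactly on a tool rule."""
        return cls(coefficients={}, intercept=0.0, noise=noise, ruleset=ruleset)

    def latent_scores(
        self,
        records: Sequence[ParticipantRecord],
        cfg: ThresholdConfig = DEFAULT_CONFIG,
    ) -> np.ndarray:
        scores = np.empty(len(records))
        for i, record in enumerate(records):
            profile = derive_profile(record, cfg)
            if self.ruleset is not None:
                high = classify(profile, self.ruleset) is RiskClassification.HIGH
                scores[i] = 1.0 if high else -1.0
            else:
                scores[i] = self.intercept + sum(
                    coef for factor, coef in self.coefficients.items()
                    if profile[factor] is TriState.PRESENT
                )
        return scores


def simulate_raters(
    records: Sequence[ParticipantRecord],
    model: RaterModel,
    seed: int = 0,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    annotate: bool = True,
) -> np.ndarray:
    """Simulate three conditionally-independent raters per record.

    Returns a boolean array of shape (n_records, 3) — True = judged
    high.  With ``annotate`` (default) the records' rater columns are
    filled in so the cohort can be adjudicated directly.
    """
    rng = np.random.default_rng(seed)
    base = model.latent_scores(records, cfg) > 0
    flips = rng.uniform(size=(len(records), model.n_raters)) < model.noise
    labels = base[:, None] ^ flips
    if annotate:
        for record, row in zip(records, labels):
            record.rater1_high = TriState.from_bool(bool(row[0]))
            record.rater2_high = TriState.from_bool(bool(row[1]))
            record.rater3_high = TriState.from_bool(bool(row[2]))
    return labels


def pairwise_agreement(labels: np.ndarray) -> float:
    """Proportion of records where the two primary raters agree."""
    return float(np.mean(labels[:, 0] == labels[:, 1]))


def calibrate_agreement(
    model: RaterModel,
    records: Sequence[ParticipantRecord],
    target_agreement: float,
    seed: int = 0,
    tolerance: float = 0.005,
    replicates: int = 40,
    max_iter: int = 40,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> RaterModel:
    """Tune the rater noise so simulated primary-rater agreement matches
    the target (monotone bisection on the flip probability).

    Expected agreement is 1 - 2*noise*(1 - noise), strictly decreasing
    in noise on [0, 0.5), so bisection converges; the returned model is
    checked by Monte-Carlo simulation.  Targets at or below 0.5 (the
    coin-flip floor) are unattainable.
    """
    if not 0.5 < target_agreement <= 1.0:
        raise CalibrationError(
            f"target agreement must lie in (0.5, 1], got {target_agreement} "
            f"(0.5 is the independent-noise floor)"
        )
    if target_agreement == 1.0:
        return replace(model, noise=0.0)

    rng = np.random.default_rng(seed)
    # the base judgement is fixed by the records; only the flips vary
    base = model.latent_scores(records, cfg) > 0

    def simulated(noise: float) -> float:
        values = np.empty(replicates)
        for r in range(replicates):
            flips = rng.uniform(size=(len(records), 2)) < noise
            labels = base[:, None] ^ flips
            values[r] = np.mean(labels[:, 0] == labels[:, 1])
        return float(np.mean(values))

    lo, hi = 0.0, 0.5 - 1e-9   # agreement(lo)=1 >= target > agreement(hi)
    noise = 0.25
    for _ in range(max_iter):
        noise = 0.5 * (lo + hi)
        value = simulated(noise)
        if abs(value - target_agreement) <= tolerance:
            break
        if value > target_agreement:
            lo = noise
        else:
            hi = noise
    return replace(model, noise=noise)
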