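"""Synthetic claims and cohort generator with known ground truth.

Emulates the structure of a Medicare-like inpatient claims extract for an
emergent-surgery comparison: a beneficiary presents with a ruptured abdominal
aortic aneurysm, receives one of two repair procedures (endovascular, coded
``PROC_EVAR``, treated arm Z=1; open, coded ``PROC_OAR``, Z=0), and is followed
to death, disenrollment, or an administrative study end.

What is emulated and how:

* baseline covariates (age, sex, race, repair year, 20 binary comorbid
  conditions) drawn from configurable marginals whose defaults match the
  pooled descriptive statistics of the reference cohort;
* confounded treatment assignment through an explicit logistic propensity
  model with configurable coefficients on the encoded covariate scale;
* event times from per-arm Weibull hazards with log-linear covariate effects
  (identical arm baselines give proportional hazards; differing arm shapes
  give a non-proportional regime);
* long-term censoring from an exponential loss-to-follow-up hazard plus
  administrative censoring at the study end; the short-term outcome is an
  independent time heavily administratively censored at a configurable
  horizon (30 days after a typical discharge);
* claim-shaped records with admission/discharge/treatment dates, stand-in
  diagnosis/procedure code strings, planted ineligible records covering every
  exclusion criterion, and configurable missingness.

Stand-in code strings (``PROC_EVAR``, ``DX_RAAA``, ...) are used because real
ICD-9-CM lists are configuration-supplied; they are drop-in replaceable.
Dates are ISO-8601 calendar dates; the time unit is days throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITION_COLUMNS

__all__ = ["SimConfig", "GroundTruth", "OutcomeSpec", "simulate_cohort",
           "simulate_claims", "default_code_lists"]

STUDY_ENROLL_START = "2011-01-01"
STUDY_ENROLL_END = "2015-09-30"
STUDY_END = "2019-06-30"

#: condition prevalences pooled over both arms of the reference cohort
DEFAULT_PREVALENCE = {
    "chf": 0.0975, "arrhythmia": 0.1321, "valvular": 0.0474,
    "coronary": 0.1739, "diabetes": 0.0748, "hypertension": 0.2975,
    "copd": 0.1650, "lower_extremity_vascular": 0.0068,
    "renal_atherosclerosis": 0.0060, "vascular_intestine": 0.0011,
    "renal_failure": 0.1087, "other_renal": 0.0005,
    "kidney_transplant": 0.0009, "liver": 0.0081,
    "cerebrovascular": 0.0204, "other_neuro": 0.0341,
    "hyperlipidemia": 0.1922, "cancer": 0.0280, "rheumatoid": 0.0147,
    "prior_aaa": 0.1215,
}

#: true propensity-model coefficients on the encoded covariate scale.
#: Signs follow the imbalance pattern of the reference cohort: the treated
#: (endovascular) arm is older, sicker, and more frequent in later years.
DEFAULT_PS_COEFFICIENTS = {
    "intercept": -0.75, "age": 0.20, "male": 0.22,
    "race=black": 0.32, "race=other": -0.12,
    "year=2012": 0.12, "year=2013": 0.25, "year=2014": 0.40, "year=2015": 0.52,
    "chf": 0.45, "arrhythmia": 0.32, "valvular": 0.12, "coronary": 0.25,
    "diabetes": 0.25, "hypertension": 0.17, "copd": 0.20,
    "lower_extremity_vascular": -0.05, "renal_atherosclerosis": -0.30,
    "vascular_intestine": 0.80, "renal_failure": 0.32, "other_renal": 1.00,
    "kidney_transplant": 0.20, "liver": 0.06, "cerebrovascular": 0.31,
    "other_neuro": 0.27, "hyperlipidemia": 0.18, "cancer": 0.40,
    "rheumatoid": 0.65, "prior_aaa": 0.13,
}

DEFAULT_LONG_BETAS = {
    "age": 0.35, "male": 0.08, "race=black": -0.15, "race=other": 0.05,
    "chf": 0.30, "arrhythmia": -0.12, "coronary": 0.15, "diabetes": 0.10,
    "hypertension": -0.05, "copd": 0.20, "renal_failure": 0.35,
    "cancer": 0.50, "prior_aaa": -0.15,
}

DEFAULT_SHORT_BETAS = {
    "age": 0.30, "race=black": -0.10, "chf": 0.25, "renal_failure": 0.30,
    "prior_aaa": -0.25,
}


@dataclass
class OutcomeSpec:
    """Per-arm Weibull event-time model for one outcome.

    The hazard for a subject in arm z is the arm's Weibull baseline times
    exp(beta'x + effect*z); identical arm baselines give proportional hazards,
    differing shapes a non-proportional regime.
    """

    arm0_shape: float
    arm0_scale: float
    arm1_shape: float
    arm1_scale: float
    treatment_log_hr: float
    covariate_log_hr: dict = field(default_factory=dict)

    def validate(self):
        for v in (self.arm0_shape, self.arm0_scale, self.arm1_shape,
                  self.arm1_scale):
            if not v > 0:
                raise ValueError("Weibull shape/scale must be strictly positive")


@dataclass
class SimConfig:
    """Full specification of one synthetic study; the seed determines output."""

    n_beneficiaries: int = 2000
    seed: int = 0
    # covariate marginals
    age_mean: float = 77.3
    age_sd: float = 7.2
    p_male: float = 0.742
    race_probs: dict = field(default_factory=lambda: {
        "white": 0.9122, "black": 0.0546, "other": 0.0332})
    year_probs: dict = field(default_factory=lambda: {
        2011: 0.2327, 2012: 0.2277, 2013: 0.2050, 2014: 0.1965, 2015: 0.1381})
    condition_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    # treatment assignment
    ps_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_PS_COEFFICIENTS))
    # outcomes
    # low Weibull shape = heavy early hazard: a large share of deaths fall in
    # the perioperative window, as in real emergency aneurysm repair, so the
    # single claims-level death process yields realistic incidences for BOTH
    # derived outcomes (~36% perioperative, ~64% all-cause)
    long_term: OutcomeSpec = field(default_factory=lambda: OutcomeSpec(
        0.22, 2800.0, 0.22, 2800.0, float(np.log(0.85)),
        dict(DEFAULT_LONG_BETAS)))
    short_term: OutcomeSpec = field(default_factory=lambda: OutcomeSpec(
        0.55, 115.0, 0.55, 115.0, float(np.log(0.70)),
        dict(DEFAULT_SHORT_BETAS)))
    # censoring
    ltfu_hazard: float = 4e-5          # per day; ~1.5%/year disenrollment
    study_end: str | None = STUDY_END  # None disables administrative censoring
    short_horizon: float | None = 35.0  # days; None disables
    enroll_start: str = STUDY_ENROLL_START
    enroll_end: str = STUDY_ENROLL_END
    # missingness (claims level)
    missing_treatment_date_frac: float = 0.0535
    missing_covariate_frac: float = 0.002
    # planted ineligible records (claims level), fraction of n each
    ineligible: dict = field(default_factory=lambda: {
        "no_rupture_code": 0.01, "under_65": 0.01, "conversion": 0.01,
        "excluded_dx": 0.01, "excluded_proc": 0.01,
        "short_enrollment": 0.01, "duplicate": 0.02,
    })

    def validate(self):
        if self.n_beneficiaries <= 0:
            raise ValueError("n_beneficiaries must be positive")
        probs = ([self.p_male, self.missing_treatment_date_frac,
                  self.missing_covariate_frac]
                 + list(self.race_probs.values())
                 + list(self.year_probs.values())
                 + list(self.condition_prevalence.values())
                 + list(self.ineligible.values()))
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all prevalences/probabilities must lie in [0,1]")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-6:
            raise ValueError("race probabilities must sum to 1")
        if abs(sum(self.year_probs.values()) - 1.0) > 1e-6:
            raise ValueError("year probabilities must sum to 1")
        if self.ltfu_hazard < 0:
            raise ValueError("loss-to-follow-up hazard must be >= 0")
        if set(self.condition_prevalence) != set(CONDITION_COLUMNS):
            raise ValueError("condition_prevalence keys must match the 20 "
                             "condition columns")
        self.long_term.validate()
        self.short_term.validate()

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def nonproportional(self) -> "SimConfig":
        """Variant with crossing arm-specific hazards for the long outcome."""
        npspec = dataclasses.replace(self.long_term, arm0_shape=1.4,
                                     arm1_shape=0.7, treatment_log_hr=0.0)
        return self.replace(long_term=npspec)


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated cohort (for recovery testing)."""

    propensity: np.ndarray
    treatment_log_hr_long: float
    treatment_log_hr_short: float
    event_time_long: np.ndarray
    censor_time_long: np.ndarray
    event_time_short: np.ndarray
    censor_time_short: np.ndarray


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _encoded_features(cohort: pd.DataFrame, cfg: SimConfig) -> dict:
    """True-model encoding: standardized age, dummies against reference levels."""
    feats = {"intercept": np.ones(len(cohort)),
             "age": (cohort["age"].to_numpy() - cfg.age_mean) / cfg.age_sd,
             "male": (cohort["sex"] == "male").to_numpy(float)}
    for lv in ("black", "other"):
        feats[f"race={lv}"] = (cohort["race"] == lv).to_numpy(float)
    for yr in (2012, 2013, 2014, 2015):
        feats[f"year={yr}"] = (cohort["repair_year"] == yr).to_numpy(float)
    for c in CONDITION_COLUMNS:
        feats[c] = cohort[c].to_numpy(float)
    return feats


def _linear_predictor(feats: dict, coefs: dict) -> np.ndarray:
    lp = np.zeros(len(feats["intercept"]))
    for k, v in coefs.items():
        if k not in feats:
            raise ValueError(f"unknown coefficient key {k!r}")
        lp += v * feats[k]
    return lp


def _draw_weibull(rng, shape, scale, lp):
    """Weibull-PH event time: S(t|x) = exp(-(t/scale)^shape * exp(lp))."""
    u = rng.uniform(size=len(lp))
    return scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)


def _draw_outcome(rng, cohort, feats, spec: OutcomeSpec):
    Z = cohort["treatment"].to_numpy()
    lp = _linear_predictor(feats, spec.covariate_log_hr) \
        + spec.treatment_log_hr * Z
    T = np.where(
        Z == 1,
        _draw_weibull(rng, spec.arm1_shape, spec.arm1_scale, lp),
        _draw_weibull(rng, spec.arm0_shape, spec.arm0_scale, lp))
    return T


def _treatment_dates(rng, cohort, cfg: SimConfig) -> pd.Series:
    """Treatment date uniform within the subject's repair year, inside the
    enrollment window, so the calendar year agrees with the year covariate."""
    start = pd.Timestamp(cfg.enroll_start)
    end = pd.Timestamp(cfg.enroll_end)
    dates = np.empty(len(cohort), dtype="datetime64[D]")
    years = cohort["repair_year"].to_numpy()
    for yr in np.unique(years):
        lo = max(pd.Timestamp(int(yr), 1, 1), start)
        hi = min(pd.Timestamp(int(yr), 12, 31), end)
        span = (hi - lo).days + 1
        mask = years == yr
        offs = rng.integers(0, span, size=int(mask.sum()))
        dates[mask] = (lo.to_numpy().astype("datetime64[D]")
                       + offs.astype("timedelta64[D]"))
    return pd.Series(dates, index=cohort.index, name="treatment_date")


def simulate_cohort(config: SimConfig):
    """Draw an analysis-ready cohort table plus its ground truth.

    Returns ``(cohort, GroundTruth)``.  Cohort columns: subject_id, treatment
    (1 = endovascular), age, sex, race, repair_year, the 20 condition
    indicators, and (y_short, d_short, y_long, d_long) with times in days.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_beneficiaries

    cohort = pd.DataFrame({"subject_id": [f"B{i:07d}" for i in range(n)]})
    cohort["age"] = np.clip(rng.normal(config.age_mean, config.age_sd, n),
                            65.0, 105.0)
    cohort["sex"] = np.where(rng.uniform(size=n) < config.p_male,
                             "male", "female")
    races = list(config.race_probs)
    cohort["race"] = rng.choice(races, size=n,
                                p=[config.race_probs[r] for r in races])
    years = list(config.year_probs)
    cohort["repair_year"] = rng.choice(years, size=n,
                                       p=[config.year_probs[y] for y in years])
    for c in CONDITION_COLUMNS:
        cohort[c] = (rng.uniform(size=n)
                     < config.condition_prevalence[c]).astype(int)

    feats = _encoded_features(cohort, config)
    ps = _expit(_linear_predictor(feats, config.ps_coefficients))
    cohort["treatment"] = (rng.uniform(size=n) < ps).astype(int)
    feats = _encoded_features(cohort, config)  # refresh (treatment not used)

    treat_date = _treatment_dates(rng, cohort, config)

    # long-term outcome: death vs loss to follow-up vs administrative end
    T_long = _draw_outcome(rng, cohort, feats, config.long_term)
    if config.ltfu_hazard > 0:
        ltfu = rng.exponential(1.0 / config.ltfu_hazard, size=n)
    else:
        ltfu = np.full(n, np.inf)
    if config.study_end is not None:
        admin = (pd.Timestamp(config.study_end)
                 - treat_date).dt.days.to_numpy(dtype=float)
    else:
        admin = np.full(n, np.inf)
    C_long = np.minimum(ltfu, admin)
    cohort["y_long"] = np.minimum(T_long, C_long)
    cohort["d_long"] = (T_long <= C_long).astype(int)
    # censored by disenrollment rather than by the administrative end
    cohort["_lost"] = (cohort["d_long"] == 0) & (ltfu < admin)

    # short-term outcome: independent time, heavy administrative censoring
    T_short = _draw_outcome(rng, cohort, feats, config.short_term)
    C_short = np.full(n, np.inf) if config.short_horizon is None \
        else np.full(n, float(config.short_horizon))
    cohort["y_short"] = np.minimum(T_short, C_short)
    cohort["d_short"] = (T_short <= C_short).astype(int)

    cohort["_treatment_date"] = treat_date
    truth = GroundTruth(
        propensity=ps,
        treatment_log_hr_long=config.long_term.treatment_log_hr,
        treatment_log_hr_short=config.short_term.treatment_log_hr,
        event_time_long=T_long, censor_time_long=C_long,
        event_time_short=T_short, censor_time_short=C_short,
    )
    return cohort, truth


# ------------------------------------------------------------------ claims

def default_code_lists() -> dict:
    """Stand-in code lists; real ICD-9-CM lists are drop-in replacements."""
    return {
        "rupture_dx": ["DX_RAAA"],
        "evar_proc": ["PROC_EVAR"],
        "oar_proc": ["PROC_OAR"],
        "excluded_dx": ["DX_THORACIC_ANEURYSM", "DX_THORACOABD_ANEURYSM",
                        "DX_AORTIC_DISSECTION"],
        "excluded_proc": ["PROC_THORACIC_REPAIR", "PROC_VISCERAL_BYPASS",
                          "PROC_RENAL_BYPASS"],
        "conditions": {c: [f"DX_{c.upper()}"] for c in CONDITION_COLUMNS},
    }


def _claim_row(beneficiary_id, admission, discharge, treatment_date, dx, proc,
               age, sex, race, enroll_start, enroll_end, death):
    def _d(x):
        return "" if x is None else str(pd.Timestamp(x).date())
    return {
        "beneficiary_id": beneficiary_id,
        "admission_date": _d(admission),
        "discharge_date": _d(discharge),
        "treatment_date": _d(treatment_date),
        "diagnosis_codes": ";".join(dx),
        "procedure_codes": ";".join(proc),
        "age_at_admission": age,
        "sex": sex,
        "race": race,
        "enrollment_start": _d(enroll_start),
        "enrollment_end": _d(enroll_end),
        "death_date": _d(death),
    }


def simulate_claims(config: SimConfig) -> pd.DataFrame:
    """Emit a claims-level table: eligible records plus planted ineligibles.

    One claim per eligible beneficiary (drawn via :func:`simulate_cohort`,
    with the long-term event time acting as the death time so both derived
    outcomes are internally consistent), plus planted records violating each
    exclusion criterion, plus exact-count treatment-date and covariate
    missingness.  Code columns hold semicolon-joined stand-in code strings.
    """
    cohort, truth = simulate_cohort(config)
    codes = default_code_lists()
    rng = np.random.default_rng(config.seed + 1)
    n = len(cohort)

    treat_date = cohort["_treatment_date"]
    lag = rng.binomial(1, 0.53, size=n)          # admission-to-treatment lag
    admission = treat_date - pd.to_timedelta(lag, unit="D")
    los = 1 + rng.poisson(6.0, size=n)
    discharge = admission + pd.to_timedelta(np.maximum(los, lag), unit="D")
    enroll_back = rng.integers(380, 3000, size=n)
    enroll_start = admission - pd.to_timedelta(enroll_back, unit="D")

    death_day = np.where(cohort["d_long"] == 1, cohort["y_long"], np.nan)
    lost = cohort["_lost"].to_numpy()

    rows = []
    for i in range(n):
        dx = list(codes["rupture_dx"])
        for c in CONDITION_COLUMNS:
            if cohort.at[i, c]:
                dx += codes["conditions"][c]
        proc = list(codes["evar_proc"] if cohort.at[i, "treatment"] == 1
                    else codes["oar_proc"])
        death = (treat_date[i] + pd.Timedelta(days=round(death_day[i]))
                 if np.isfinite(death_day[i]) else None)
        eend = (treat_date[i] + pd.Timedelta(days=round(cohort.at[i, "y_long"]))
                if lost[i] else None)
        rows.append(_claim_row(
            cohort.at[i, "subject_id"], admission[i], discharge[i],
            treat_date[i], dx, proc, round(float(cohort.at[i, "age"]), 1),
            cohort.at[i, "sex"], cohort.at[i, "race"], enroll_start[i], eend,
            death))

    # exact-count missingness on the eligible records
    k_missing = int(np.floor(config.missing_treatment_date_frac * n))
    for i in rng.choice(n, size=k_missing, replace=False):
        rows[i]["treatment_date"] = ""
    k_cov = int(np.floor(config.missing_covariate_frac * n))
    for i in rng.choice(n, size=k_cov, replace=False):
        rows[i]["race"] = ""

    # planted ineligible records, one criterion each
    def _base_plant(j, tag):
        adm = pd.Timestamp(config.enroll_start) + pd.Timedelta(
            days=int(rng.integers(0, 1200)))
        return dict(
            beneficiary_id=f"P{tag}{j:05d}", admission=adm,
            discharge=adm + pd.Timedelta(days=int(rng.integers(2, 12))),
            treatment_date=adm, dx=list(codes["rupture_dx"]),
            proc=list(codes["evar_proc"] if rng.uniform() < 0.5
                      else codes["oar_proc"]),
            age=round(float(rng.uniform(66, 90)), 1),
            sex="male" if rng.uniform() < 0.7 else "female",
            race="white", enroll_start=adm - pd.Timedelta(days=900),
            enroll_end=None, death=None)

    plant_counts = {k: int(np.floor(v * n))
                    for k, v in config.ineligible.items()}
    for j in range(plant_counts.get("no_rupture_code", 0)):
        r = _base_plant(j, "N")
        r["dx"] = ["DX_OTHER"]
        rows.append(_claim_row(**{k: r[k] for k in r}))
    for j in range(plant_counts.get("under_65", 0)):
        r = _base_plant(j, "U")
        r["age"] = round(float(rng.uniform(40, 64)), 1)
        rows.append(_claim_row(**r))
    for j in range(plant_counts.get("conversion", 0)):
        r = _base_plant(j, "C")
        r["proc"] = list(codes["evar_proc"]) + list(codes["oar_proc"])
        rows.append(_claim_row(**r))
    for j in range(plant_counts.get("excluded_dx", 0)):
        r = _base_plant(j, "D")
        r["dx"] = r["dx"] + [codes["excluded_dx"][0]]
        rows.append(_claim_row(**r))
    for j in range(plant_counts.get("excluded_proc", 0)):
        r = _base_plant(j, "X")
        r["proc"] = r["proc"] + [codes["excluded_proc"][0]]
        rows.append(_claim_row(**r))
    for j in range(plant_counts.get("short_enrollment", 0)):
        r = _base_plant(j, "S")
        r["enroll_start"] = r["admission"] - pd.Timedelta(days=180)
        rows.append(_claim_row(**r))
    # duplicates: a later second claim for an existing eligible beneficiary
    dup_n = plant_counts.get("duplicate", 0)
    if dup_n > 0:
        targets = rng.choice(n, size=min(dup_n, n), replace=False)
        for j, t in enumerate(targets):
            base = rows[t]
            adm = pd.Timestamp(base["admission_date"] or
                               base["treatment_date"]) + pd.Timedelta(
                days=int(rng.integers(60, 400)))
            rows.append(_claim_row(
                base["beneficiary_id"], adm,
                adm + pd.Timedelta(days=int(rng.integers(2, 12))), adm,
                base["diagnosis_codes"].split(";"),
                base["procedure_codes"].split(";"),
                base["age_at_admission"], base["sex"], base["race"],
                base["enrollment_start"], None, base["death_date"] or None))

    return pd.DataFrame(rows)
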