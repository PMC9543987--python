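"""Synthetic ELSA-like cohort generator.

Emulates a baseline cohort of Brazilian adults (35-74 years) with 31
predictors — sociodemographic, lifestyle/dietary, anthropometric and
family-history variables — and 10 chronic-condition labels.  Each
condition is drawn from a logistic model

    y_il ~ Bernoulli( sigmoid( a_l + b_l . x_i
                               + lam_cardio,l f_cardio,i
                               + lam_mental,l f_mental,i ) )

with two shared standard-normal latent factors per participant: a
*cardio-metabolic* factor loading on the dyslipidemia / diabetes / heart
disease / kidney analogs and a *musculoskeletal-mental* factor loading on
the common-mental-disorder / migraine / joint analogs.  The factors induce
label co-occurrence beyond what the observed predictors explain, which is
what dependence-aware classifiers (CC, DBR, the multivariate forest) can
exploit.

Per-label intercepts are calibrated by root finding so the simulated
marginal prevalences hit the configured targets; the default targets place
the most prevalent condition (dyslipidemia analog) at 44.2%, give a label
cardinality of 1.86 and a MeanIR of ~3.8.

Feature values are masked missing completely at random at a small
configurable rate (labels are never masked).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import ConfigError, MultiLabelDataset

__all__ = [
    "LabelSpec",
    "SyntheticConfig",
    "default_config",
    "generate_cohort",
    "calibrate_intercepts",
    "calibrated_default_config",
]


@dataclass
class LabelSpec:
    """One condition: target prevalence, covariate effects, factor loadings.

    ``effects`` maps named standardized covariates (see module source for
    the inventory) to log-odds coefficients.  ``intercept`` is filled by
    calibration.
    """

    name: str
    target_prevalence: float
    effects: dict = field(default_factory=dict)
    loading_cardio: float = 0.0
    loading_mental: float = 0.0
    intercept: float | None = None

    def __post_init__(self):
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError(f"target prevalence for {self.name!r} must be in (0, 1)")
        for k, v in self.effects.items():
            if not np.isfinite(v):
                raise ConfigError(f"non-finite effect {k!r} for label {self.name!r}")


@dataclass
class SyntheticConfig:
    n: int = 14836
    labels: list = field(default_factory=lambda: _default_labels())
    missing_rate: float = 0.02
    seed: int | None = None
    #: internal sample size and seed used for intercept calibration
    calibration_n: int = 40000
    calibration_seed: int = 977101

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("cohort size must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        names = [ls.name for ls in self.labels]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate label names")


def _default_labels() -> list[LabelSpec]:
    """Default 10-condition specification.

    The three largest prevalence targets are the cohort's printed values
    (dyslipidemia 44.2%, migraine 29.5%, common mental disorder 26.7%);
    the remaining seven are plausible values chosen so the target
    cardinality is 1.86 and the MeanIR ~3.8.  Effect sizes make the BMI
    analog the strongest aggregate predictor, followed by blood pressure,
    age and sex.
    """
    return [
        LabelSpec("dyslipidemia", 0.442,
                  {"bmi_z": 0.80, "age_z": 0.35, "whr_z": 0.30, "sbp_z": 0.20},
                  loading_cardio=0.7),
        LabelSpec("migraine", 0.295,
                  {"female": 0.70, "age_z": -0.35, "bmi_z": 0.15},
                  loading_mental=0.9),
        LabelSpec("common_mental_disorder", 0.267,
                  {"female": 0.50, "sleeping_problem": 0.45, "sleep_symptom": 0.40,
                   "bmi_z": 0.20},
                  loading_mental=1.0),
        LabelSpec("diabetes", 0.216,
                  {"bmi_z": 0.85, "age_z": 0.45, "whr_z": 0.35, "fh_diabetes": 0.50},
                  loading_cardio=0.9),
        LabelSpec("joint_problems", 0.198,
                  {"age_z": 0.45, "bmi_z": 0.55, "female": 0.35},
                  loading_mental=0.5),
        LabelSpec("asthma", 0.143,
                  {"fh_asthma": 0.55, "bmi_z": 0.20, "smoking_current": 0.15},
                  loading_mental=0.5),
        LabelSpec("heart_disease", 0.112,
                  {"age_z": 0.45, "sbp_z": 0.35, "bmi_z": 0.40, "female": -0.30,
                   "fh_heart_disease": 0.40},
                  loading_cardio=0.9),
        LabelSpec("cancer", 0.085,
                  {"age_z": 0.45, "fh_cancer": 0.40, "smoking_current": 0.30}),
        LabelSpec("kidney_disease", 0.058,
                  {"age_z": 0.30, "sbp_z": 0.30, "bmi_z": 0.35},
                  loading_cardio=0.5),
        LabelSpec("cirrhosis", 0.044,
                  {"alcohol_excessive": 0.60, "age_z": 0.25, "bmi_z": 0.20},
                  loading_cardio=0.3),
    ]


def default_config(n: int = 14836, seed: int | None = None, **kwargs) -> SyntheticConfig:
    return SyntheticConfig(n=n, seed=seed, **kwargs)


# ----------------------------------------------------------------------
# Feature generation

_EDU = ["elementary_or_less", "secondary", "university"]
_RACE = ["white", "pardo", "black", "indigenous", "asian"]
_MATERNAL_EDU = ["never_attended", "incomplete_elementary", "elementary",
                 "secondary", "undergraduate"]
_SMOKING = ["never", "past", "current"]
_ALCOHOL = ["none", "moderate", "excessive"]
_ACTIVITY = ["weak", "moderate", "strong"]
_FREQ4 = ["high", "daily", "weekly", "rarely"]
_COFFEE = ["no", "caffeinated", "decaffeinated"]
_FH = ["fh_hypertension", "fh_diabetes", "fh_heart_disease", "fh_stroke",
       "fh_cerebrovascular_accident", "fh_angioplasty", "fh_sudden_death",
       "fh_asthma", "fh_cancer"]
_FH_RATES = [0.45, 0.30, 0.28, 0.15, 0.10, 0.08, 0.07, 0.15, 0.25]


def _draw_features(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(52.1, 9.1, n), 35, 74)
    sex = np.where(rng.random(n) < 0.544, "female", "male")
    female = (sex == "female").astype(float)
    bmi = np.clip(rng.normal(26.9 + 0.05 * (age - 52), 4.6, n), 16, 55)
    sbp = rng.normal(119 + 0.50 * (age - 52) + 0.80 * (bmi - 27), 13, n)
    dbp = rng.normal(76 + 0.15 * (age - 52) + 0.60 * (bmi - 27), 9, n)
    heart_rate = rng.normal(72, 9, n)
    whr = rng.normal(np.where(female == 1, 0.85, 0.93) + 0.005 * (bmi - 27), 0.055, n)
    income = np.exp(rng.normal(np.log(650.0), 0.75, n))
    frame = pd.DataFrame({
        "age": np.round(age, 1),
        "sex": sex,
        "education": rng.choice(_EDU, n, p=[0.127, 0.348, 0.525]),
        "race": rng.choice(_RACE, n, p=[0.527, 0.285, 0.163, 0.010, 0.015]),
        "marital_status": rng.choice(["single", "not_single"], n, p=[0.339, 0.661]),
        "income": np.round(income, 2),
        "children": rng.choice(["yes", "no"], n, p=[0.72, 0.28]),
        "maternal_education": rng.choice(_MATERNAL_EDU, n,
                                         p=[0.18, 0.27, 0.22, 0.20, 0.13]),
        "smoking": rng.choice(_SMOKING, n, p=[0.57, 0.30, 0.13]),
        "alcohol": rng.choice(_ALCOHOL, n, p=[0.32, 0.58, 0.10]),
        "physical_activity": rng.choice(_ACTIVITY, n, p=[0.65, 0.20, 0.15]),
        "activity_days": rng.integers(0, 8, n).astype(float),
        "sleep_symptom": rng.choice(["yes", "no"], n, p=[0.35, 0.65]),
        "sleeping_problem": rng.choice(["yes", "no"], n, p=[0.30, 0.70]),
        "fruit_consumption": rng.choice(_FREQ4, n, p=[0.20, 0.45, 0.25, 0.10]),
        "vegetable_consumption": rng.choice(_FREQ4, n, p=[0.22, 0.48, 0.22, 0.08]),
        "coffee": rng.choice(_COFFEE, n, p=[0.12, 0.82, 0.06]),
        "bmi": np.round(bmi, 1),
        "systolic_bp": np.round(sbp, 0),
        "diastolic_bp": np.round(dbp, 0),
        "heart_rate": np.round(heart_rate, 0),
        "waist_hip_ratio": np.round(whr, 3),
    })
    for name, rate in zip(_FH, _FH_RATES):
        frame[name] = rng.choice(["yes", "no"], n, p=[rate, 1 - rate])
    return frame


def _covariates(X: pd.DataFrame) -> dict[str, np.ndarray]:
    """Named standardized covariates available to label effects."""
    cov = {
        "age_z": (X["age"].to_numpy() - 52.1) / 9.1,
        "bmi_z": (X["bmi"].to_numpy() - 27.0) / 4.7,
        "sbp_z": (X["systolic_bp"].to_numpy() - 120.0) / 15.5,
        "dbp_z": (X["diastolic_bp"].to_numpy() - 76.0) / 9.8,
        "hr_z": (X["heart_rate"].to_numpy() - 72.0) / 9.0,
        "whr_z": (X["waist_hip_ratio"].to_numpy() - 0.886) / 0.07,
        "income_z": (np.log(X["income"].to_numpy()) - np.log(650.0)) / 0.75,
        "female": (X["sex"] == "female").to_numpy(float),
        "smoking_current": (X["smoking"] == "current").to_numpy(float),
        "alcohol_excessive": (X["alcohol"] == "excessive").to_numpy(float),
        "activity_weak": (X["physical_activity"] == "weak").to_numpy(float),
        "sleep_symptom": (X["sleep_symptom"] == "yes").to_numpy(float),
        "sleeping_problem": (X["sleeping_problem"] == "yes").to_numpy(float),
        "edu_low": (X["education"] == "elementary_or_less").to_numpy(float),
    }
    for name in _FH:
        cov[name] = (X[name] == "yes").to_numpy(float)
    return cov


def _linear_predictors(config: SyntheticConfig, X: pd.DataFrame,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-label linear predictors *excluding* the intercept."""
    cov = _covariates(X)
    n = len(X)
    f_cardio = rng.standard_normal(n)
    f_mental = rng.standard_normal(n)
    eta = np.zeros((n, len(config.labels)))
    for j, ls in enumerate(config.labels):
        for key, beta in ls.effects.items():
            if key not in cov:
                raise ConfigError(f"unknown effect covariate {key!r} in label {ls.name!r}")
            eta[:, j] += beta * cov[key]
        eta[:, j] += ls.loading_cardio * f_cardio + ls.loading_mental * f_mental
    return eta


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SyntheticConfig | None = None,
                    seed: int | None = None) -> MultiLabelDataset:
    """Draw one cohort from a (calibrated) configuration.

    Uncalibrated label intercepts are resolved on the fly via
    :func:`calibrate_intercepts`.  ``seed`` overrides ``config.seed``.
    """
    if config is None:
        config = calibrated_default_config()
    if any(ls.intercept is None for ls in config.labels):
        config = calibrate_intercepts(config)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    X = _draw_features(config.n, rng)
    eta = _linear_predictors(config, X, rng)
    Y = {}
    for j, ls in enumerate(config.labels):
        prob = _sigmoid(ls.intercept + eta[:, j])
        y = (rng.random(config.n) < prob).astype(np.int8)
        if config.n >= 200 and (y.mean() < 0.005 or y.mean() > 0.995):
            warnings.warn(f"label {ls.name!r} is nearly degenerate "
                          f"(prevalence {y.mean():.4f})")
        Y[ls.name] = y
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = X.mask(pd.DataFrame(mask, index=X.index, columns=X.columns))
    return MultiLabelDataset(X, pd.DataFrame(Y))


# ----------------------------------------------------------------------
# Calibration


def calibrate_intercepts(config: SyntheticConfig,
                         targets: dict[str, float] | None = None,
                         tolerance: float = 1e-4) -> SyntheticConfig:
    """Solve each label's intercept so its expected prevalence hits target.

    A large reference sample of linear predictors (size
    ``config.calibration_n``, drawn with the fixed calibration seed) is
    held fixed while the intercept of each label is found by monotone
    root finding on the expected prevalence
    ``mean_i sigmoid(alpha + eta_i)``.  Returns a new config with
    intercepts set; raises if any root search fails to bracket.
    """
    config = copy.deepcopy(config)
    if targets:
        by_name = {ls.name: ls for ls in config.labels}
        for name, t in targets.items():
            if name not in by_name:
                raise ConfigError(f"unknown label {name!r} in calibration targets")
            if not 0.0 < t < 1.0:
                raise ConfigError(f"calibration target for {name!r} must be in (0, 1)")
            by_name[name].target_prevalence = t
    rng = np.random.default_rng(config.calibration_seed)
    X = _draw_features(config.calibration_n, rng)
    eta = _linear_predictors(config, X, rng)
    for j, ls in enumerate(config.labels):
        target = ls.target_prevalence

        def gap(alpha, col=eta[:, j], t=target):
            return float(_sigmoid(alpha + col).mean() - t)

        lo, hi = -30.0, 30.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise ConfigError(f"cannot bracket intercept for label {ls.name!r}")
        ls.intercept = float(brentq(gap, lo, hi, xtol=tolerance / 10))
        if abs(gap(ls.intercept)) > tolerance:
            raise ConfigError(f"calibration failed for label {ls.name!r}")
    return config


_CALIBRATED_DEFAULT: SyntheticConfig | None = None


def calibrated_default_config() -> SyntheticConfig:
    """Default configuration with intercepts calibrated (cached per process)."""
    global _CALIBRATED_DEFAULT
    if _CALIBRATED_DEFAULT is None:
        _CALIBRATED_DEFAULT = calibrate_intercepts(default_config())
    return copy.deepcopy(_CALIBRATED_DEFAULT)
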