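"""Closed-form hemoglobin- and blood-loss estimators.

The central quantity is the hemoglobin mass (g) lost during a procedure,
inferred from the *dilution* of circulating hemoglobin: after a bleed the
plasma volume re-equilibrates, so the Hb concentration measured ~24 h later
falls roughly in proportion to the loss.  The sex-specific formulas

    HB_female = 42.212 + (0.160*h^3 + 0.015*w + 0.083) * (HB_pre - HB_post)
    HB_male   = 61.767 + (0.165*h^3 + 0.015*w + 0.272) * (HB_pre - HB_post)

(h body height in m, w body weight in kg, Hb concentrations in g/L, result
in g Hb) were derived by regressing directly measured controlled-bleed
losses on the dilution signal.  Their slope is, to within a few percent,
0.45 times the Nadler blood volume — i.e. the formula is the classical
"blood volume times concentration drop" estimate with an empirically fitted
proportionality and a sex-specific offset.

This module also carries the Nadler blood-volume equation and the legacy
blood/red-cell-loss calculators (Meunier, Gross, Ward, Bourke, Mercuriali,
Lisander) that the formula is benchmarked against, each returning its
native quantity (whole-blood mL, RBC mL, or g Hb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats

from .units import convert_hb  # noqa: F401  (re-exported convenience)


class Sex(str, Enum):
    female = "female"
    male = "male"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in {"f", "female", "w"}:
            return cls.female
        if v in {"m", "male"}:
            return cls.male
        raise ValueError(f"unrecognised sex {value!r}; expected one of f/m/female/male")


#: Published formula coefficients: intercept (g) and the slope pieces
#: multiplying h^3 (m^3), weight (kg) and 1, all times (HB_pre - HB_post).
FORMULA_COEF = {
    Sex.female: {"intercept": 42.212, "h3": 0.160, "weight": 0.015, "const": 0.083},
    Sex.male: {"intercept": 61.767, "h3": 0.165, "weight": 0.015, "const": 0.272},
}

#: Nadler total-blood-volume constants (litres): BV = a*h^3 + b*w + c.
#: Transcribed from the classical surgery literature; guarded by the
#: formula-slope/Nadler near-identity test (ratio ~0.45 for every term).
NADLER_COEF = {
    Sex.male: {"h3": 0.3669, "weight": 0.03219, "const": 0.6041},
    Sex.female: {"h3": 0.3561, "weight": 0.03308, "const": 0.1833},
}

LEGACY_FORMULA_IDS = ("meunier", "gross", "ward", "bourke", "mercuriali", "lisander", "new")


class UnitError(ValueError):
    """A value was plausibly supplied in the wrong unit (e.g. height in cm)."""


@dataclass(frozen=True)
class DonorProfile:
    """Anthropometrics driving blood-volume estimates and formula selection.

    height is in metres, weight in kilograms.  ``age`` and ``bmi`` are
    optional; the final prediction formula uses neither.
    """

    sex: Sex
    height: float
    weight: float
    age: Optional[float] = None
    bmi: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if self.height is None:
            raise ValueError("missing field: height")
        if self.weight is None:
            raise ValueError("missing field: weight")
        if self.height > 3:
            raise UnitError(
                f"height {self.height} looks like centimetres; the API takes metres "
                "(divide by 100, or use the CLI's --height-cm flag)"
            )
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height {self.height} m outside plausible range (0.5, 2.5)")
        if not 20 < self.weight < 300:
            raise ValueError(f"weight {self.weight} kg outside plausible range (20, 300)")
        if self.bmi is not None:
            derived = self.weight / self.height**2
            if abs(self.bmi - derived) > 0.01 * derived:
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with weight/height^2 = {derived:.2f}"
                )

    @property
    def bmi_derived(self) -> float:
        return self.weight / self.height**2


def _check_hct(name: str, value: float) -> float:
    """Hematocrit is a volume fraction; percent inputs are auto-scaled with a warning."""
    if value > 1:
        warnings.warn(
            f"{name}={value} > 1 interpreted as percent and divided by 100",
            UserWarning,
            stacklevel=3,
        )
        value = value / 100.0
    if not 0.10 < value < 0.65:
        raise ValueError(f"{name}={value} outside plausible hematocrit range (0.10, 0.65)")
    return value


@dataclass(frozen=True)
class PeriProcedureLabs:
    """Pre/post-procedure complete-blood-count values.

    Hb concentrations are in g/L (measured before and 24-28 h after the
    procedure), hematocrits are fractions in [0, 1], platelet and leukocyte
    counts are per microlitre.  The dilution signal hb_diff = hb_pre -
    hb_post is always derived, never stored.
    """

    hb_pre: float
    hb_post: Optional[float] = None
    hct_pre: Optional[float] = None
    hct_post: Optional[float] = None
    plt_pre: Optional[float] = None
    leuco_pre: Optional[float] = None

    def __post_init__(self):
        for name in ("hb_pre", "hb_post"):
            v = getattr(self, name)
            if v is not None and not 30 < v < 250:
                raise ValueError(f"{name}={v} g/L outside plausible range (30, 250)")
        for name in ("hct_pre", "hct_post"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _check_hct(name, v))

    @property
    def hb_diff(self) -> float:
        if self.hb_post is None:
            raise ValueError("missing field: hb_post (needed for the dilution signal)")
        return self.hb_pre - self.hb_post

    @property
    def hct_diff(self) -> float:
        if self.hct_pre is None or self.hct_post is None:
            raise ValueError("missing field: hct_pre/hct_post")
        return self.hct_pre - self.hct_post


@dataclass(frozen=True)
class HbLossEstimate:
    """Point estimate of Hb loss (g), optionally with a prediction interval."""

    point: float
    pi_low: Optional[float] = None
    pi_high: Optional[float] = None
    level: Optional[float] = None
    formula_id: str = "new"

    def __post_init__(self):
        if self.pi_low is not None and self.pi_high is not None:
            if not self.pi_low <= self.point <= self.pi_high:
                raise ValueError("prediction interval must bracket the point estimate")

    def convert(self, target: str) -> float:
        return convert_hb(max(self.point, 0.0), target) if self.point >= 0 else -convert_hb(-self.point, target)


@dataclass(frozen=True)
class LegacyEstimate:
    """Estimate from one of the registered loss calculators, in its native quantity."""

    value: float
    quantity: str  # blood_mL | rbc_mL | hb_g
    formula_id: str
    negative: bool = False  # machine-readable flag: estimate below zero, left unclamped


def formula_slope(sex: Sex, height_m: float, weight_kg: float) -> float:
    """The published slope multiplying (HB_pre - HB_post), in g per (g/L)."""
    c = FORMULA_COEF[Sex.parse(sex)]
    return c["h3"] * height_m**3 + c["weight"] * weight_kg + c["const"]


def estimate_hb_loss(profile: DonorProfile, labs: PeriProcedureLabs) -> HbLossEstimate:
    """Hemoglobin loss (g) from the published sex-specific dilution formula.

    Negative estimates (hb_post > hb_pre) are returned unclamped — the
    dilution signal is noisy and an honest interval may include zero.
    """
    c = FORMULA_COEF[profile.sex]
    point = c["intercept"] + formula_slope(profile.sex, profile.height, profile.weight) * labs.hb_diff
    return HbLossEstimate(point=point, formula_id="new")


def nadler_blood_volume(profile: DonorProfile) -> float:
    """Total blood volume (litres) from Nadler's sex-specific equation."""
    c = NADLER_COEF[profile.sex]
    return c["h3"] * profile.height**3 + c["weight"] * profile.weight + c["const"]


def meunier_blood_loss(profile: DonorProfile, labs: PeriProcedureLabs) -> LegacyEstimate:
    """Whole-blood loss (mL): Nadler blood volume times the relative Hb drop.

    BV_mL * (hb_pre - hb_post) / hb_pre — the classical single-compartment
    dilution estimate used as the medical reference model.
    """
    if labs.hb_pre <= 0:
        raise ValueError("hb_pre must be positive")
    bv_ml = nadler_blood_volume(profile) * 1000.0
    value = bv_ml * labs.hb_diff / labs.hb_pre
    neg = value < 0
    if neg:
        warnings.warn("hb_post exceeds hb_pre; negative loss returned unclamped", UserWarning)
    return LegacyEstimate(value=value, quantity="blood_mL", formula_id="meunier", negative=neg)


def legacy_blood_loss(
    formula_id: str,
    profile: DonorProfile,
    labs: PeriProcedureLabs,
    transfused_rbc_mL: float = 0.0,
) -> LegacyEstimate:
    """Evaluate one of the registered legacy loss calculators.

    All Hct-based forms use the estimated blood volume EBV from Nadler (mL)
    and hematocrit fractions:

    * ``gross``      — EBV * (hct_pre - hct_post) / hct_mean, whole-blood mL
      (linear dilution around the mean hematocrit).
    * ``ward``       — EBV * ln(hct_pre / hct_post), whole-blood mL
      (exponential-dilution/compartment model).
    * ``bourke``     — EBV * (hct_pre - hct_post) * (3 - hct_mean), blood mL
      (polynomial approximation to the logarithmic model).
    * ``mercuriali`` / ``lisander`` — EBV * (hct_pre - hct_post)
      + transfused RBC mL, packed-red-cell mL; identical whenever no blood
      was transfused.
    * ``meunier``    — delegated to :func:`meunier_blood_loss` (Hb-based).
    * ``new``        — the published formula, g Hb.
    """
    fid = formula_id.lower()
    if fid == "meunier":
        return meunier_blood_loss(profile, labs)
    if fid == "new":
        est = estimate_hb_loss(profile, labs)
        return LegacyEstimate(est.point, "hb_g", "new", negative=est.point < 0)
    if fid not in {"gross", "ward", "bourke", "mercuriali", "lisander"}:
        raise ValueError(f"unknown formula_id {formula_id!r}; registry: {LEGACY_FORMULA_IDS}")
    if labs.hct_pre is None or labs.hct_post is None:
        raise ValueError(f"formula {fid!r} needs hct_pre and hct_post")
    ebv = nadler_blood_volume(profile) * 1000.0
    d = labs.hct_diff
    mean_hct = (labs.hct_pre + labs.hct_post) / 2.0
    if fid == "gross":
        value, qty = ebv * d / mean_hct, "blood_mL"
    elif fid == "ward":
        value, qty = ebv * np.log(labs.hct_pre / labs.hct_post), "blood_mL"
    elif fid == "bourke":
        value, qty = ebv * d * (3.0 - mean_hct), "blood_mL"
    else:  # mercuriali / lisander
        value, qty = ebv * d + transfused_rbc_mL, "rbc_mL"
    neg = value < 0
    if neg:
        warnings.warn("post-procedure hematocrit exceeds pre; negative loss returned unclamped", UserWarning)
    return LegacyEstimate(value=value, quantity=qty, formula_id=fid, negative=neg)


def prediction_interval(
    profile: DonorProfile,
    labs: PeriProcedureLabs,
    fit: "FittedFormula",
    level: float = 0.90,
) -> HbLossEstimate:
    """Point estimate with a prediction interval for a new donor.

    The half-width combines the residual scatter of the fitted model with
    the (heteroscedasticity-robust) uncertainty of its coefficients:

        point +/- t_{(1+level)/2, df} * sqrt(s^2 + x' V x)

    where s^2 is the residual variance, V the coefficient covariance and x
    the donor's design row.  Bounds may include zero or negative values.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if fit.cov_params is None or fit.resid_var is None:
        raise ValueError("fitted model lacks a coefficient covariance / residual scale")
    x = fit.design_row(profile, labs)
    point = float(x @ fit.params)
    var = fit.resid_var + float(x @ fit.cov_params @ x)
    half = stats.t.ppf(0.5 + level / 2.0, fit.df_resid) * np.sqrt(var)
    return HbLossEstimate(
        point=point, pi_low=point - half, pi_high=point + half, level=level, formula_id="new"
    )


@dataclass(frozen=True)
class FittedFormula:
    """Minimal fitted-model payload needed for prediction intervals.

    ``params`` are the coefficients of the published covariate structure
    [1, h^3 * dHb, w * dHb, dHb]; ``cov_params`` their covariance (use an
    HC-robust estimate when residuals are heteroscedastic); ``resid_var``
    and ``df_resid`` the residual variance and degrees of freedom of the
    training fit.  See :func:`hbloss.model.default_fitted_formula` for the
    synthetic-calibrated default shipped with the package.
    """

    sex: Sex
    params: np.ndarray
    cov_params: np.ndarray
    resid_var: float
    df_resid: int
    training: str = ""

    @staticmethod
    def design_row(profile: DonorProfile, labs: PeriProcedureLabs) -> np.ndarray:
        d = labs.hb_diff
        return np.array([1.0, profile.height**3 * d, profile.weight * d, d])
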