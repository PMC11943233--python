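"""Patient covariates and the covariate -> parameter scaling model.

The study protocol doses rocuronium on ideal body weight (Devine
convention) and characterizes renal function with the Cockcroft-Gault
estimated creatinine clearance, so both helpers live here alongside the
multiplicative covariate model that turns the reference parameter set
into an individual one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .params import PKPDParameters, REFERENCE_HEIGHT_CM

MALE = "male"
FEMALE = "female"

_CM_PER_INCH = 2.54
_DEVINE_BASE_HEIGHT_CM = 152.4  # 5 ft


@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and physiologic inputs to the covariate model."""

    sex: str
    age_y: float
    height_cm: float
    weight_kg: float
    serum_creatinine_mg_dl: float
    asian: bool = True
    sevoflurane: bool = False  # always False in a TIVA protocol

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise InputError(f"sex must be {MALE!r} or {FEMALE!r}, got {self.sex!r}")
        if self.age_y < 20.0:
            raise InputError(f"age must be >= 20 y (adult inclusion criterion), got {self.age_y}")
        for name in ("height_cm", "weight_kg", "serum_creatinine_mg_dl"):
            if getattr(self, name) <= 0.0:
                raise InputError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def ibw_kg(self) -> float:
        return ideal_body_weight(self.height_cm, self.sex)

    @property
    def eccr_ml_min(self) -> float:
        return cockcroft_gault(
            self.age_y, self.weight_kg, self.serum_creatinine_mg_dl, self.sex
        )


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight in kg.

    50 kg (male) or 45.5 kg (female) at 5 ft, plus 2.3 kg per inch of
    height above that.  Below 5 ft the height term is floored at zero.
    """
    if height_cm <= 0.0:
        raise InputError(f"height must be positive, got {height_cm}")
    if sex == MALE:
        base = 50.0
    elif sex == FEMALE:
        base = 45.5
    else:
        raise InputError(f"sex must be {MALE!r} or {FEMALE!r}, got {sex!r}")
    inches_over = max(0.0, (height_cm - _DEVINE_BASE_HEIGHT_CM) / _CM_PER_INCH)
    return base + 2.3 * inches_over


def cockcroft_gault(age_y: float, weight_kg: float, scr_mg_dl: float, sex: str) -> float:
    """Cockcroft-Gault estimated creatinine clearance, mL/min.

    (140 - age) * weight / (72 * Scr), multiplied by 0.85 for females;
    clamped at zero for ages at or beyond 140 y.
    """
    if scr_mg_dl <= 0.0:
        raise InputError(f"serum creatinine must be positive, got {scr_mg_dl}")
    if weight_kg <= 0.0:
        raise InputError(f"weight must be positive, got {weight_kg}")
    if sex not in (MALE, FEMALE):
        raise InputError(f"sex must be {MALE!r} or {FEMALE!r}, got {sex!r}")
    eccr = (140.0 - age_y) * weight_kg / (72.0 * scr_mg_dl)
    if sex == FEMALE:
        eccr *= 0.85
    return max(0.0, eccr)


def creatinine_for_eccr(eccr_ml_min: float, age_y: float, weight_kg: float, sex: str) -> float:
    """Serum creatinine (mg/dL) that yields the requested Cockcroft-Gault
    clearance -- the analytic inverse used by the cohort generator."""
    if eccr_ml_min <= 0.0:
        raise InputError(f"target eCCr must be positive, got {eccr_ml_min}")
    if age_y >= 140.0:
        raise InputError("Cockcroft-Gault is not invertible at age >= 140 y")
    scr = (140.0 - age_y) * weight_kg / (72.0 * eccr_ml_min)
    if sex == FEMALE:
        scr *= 0.85
    return scr


def reference_patient() -> PatientCovariates:
    """The covariate vector at which ``apply_covariates`` is the identity."""
    return PatientCovariates(
        sex=MALE,
        age_y=40.0,
        height_cm=REFERENCE_HEIGHT_CM,
        weight_kg=60.0,
        # Scr chosen so that Cockcroft-Gault returns exactly 100 mL/min.
        serum_creatinine_mg_dl=(140.0 - 40.0) * 60.0 / (72.0 * 100.0),
        asian=True,
        sevoflurane=False,
    )


def apply_covariates(base: PKPDParameters, cov: PatientCovariates) -> PKPDParameters:
    """Scale the reference parameter set to one individual.

    The model is multiplicative and continuous in every covariate:

    * size: rocuronium disposition scales with ideal body weight,
      sugammadex and complex disposition with actual body weight
      (volumes with exponent ``size_exp_v``, clearances ``size_exp_cl``);
    * renal function: sugammadex and complex clearances scale linearly
      with eCCr; rocuronium clearance only through its renal fraction;
    * age: small linear fractional effects on clearances and on the
      twitch EC50 (older subjects are more sensitive);
    * population: non-Asian subjects get the configured clearance and
      EC50 factors (the defaults describe the Asian population, the
      study's reference);
    * sevoflurane: EC50 potentiation factor, unity under TIVA.
    """
    base.validate()
    ibw = cov.ibw_kg
    eccr = cov.eccr_ml_min

    size_v_rb = (ibw / base.ref_weight_kg) ** base.size_exp_v
    size_cl_rb = (ibw / base.ref_weight_kg) ** base.size_exp_cl
    size_v_sgx = (cov.weight_kg / base.ref_weight_kg) ** base.size_exp_v
    size_cl_sgx = (cov.weight_kg / base.ref_weight_kg) ** base.size_exp_cl

    renal = eccr / base.ref_eccr_ml_min
    age_cl = max(0.1, 1.0 + base.age_coef_cl * (cov.age_y - base.ref_age_y))
    age_ec50 = max(0.1, 1.0 + base.age_coef_ec50 * (cov.age_y - base.ref_age_y))
    pop_cl = 1.0 if cov.asian else base.non_asian_cl_factor
    pop_ec50 = 1.0 if cov.asian else base.non_asian_ec50_factor
    sevo = base.sevo_ec50_factor if cov.sevoflurane else 1.0

    rb_renal_scale = 1.0 - base.renal_frac_rb + base.renal_frac_rb * renal

    return base.replace(
        v1_rb=base.v1_rb * size_v_rb,
        v2_rb=base.v2_rb * size_v_rb,
        cl_rb=base.cl_rb * size_cl_rb * rb_renal_scale * age_cl * pop_cl,
        q_rb=base.q_rb * size_cl_rb,
        v1_sgx=base.v1_sgx * size_v_sgx,
        v2_sgx=base.v2_sgx * size_v_sgx,
        cl_sgx=base.cl_sgx * size_cl_sgx * renal * age_cl * pop_cl,
        q_sgx=base.q_sgx * size_cl_sgx,
        v1_cpx=base.v1_cpx * size_v_sgx,
        v2_cpx=base.v2_cpx * size_v_sgx,
        cl_cpx=base.cl_cpx * size_cl_sgx * renal * age_cl * pop_cl,
        q_cpx=base.q_cpx * size_cl_sgx,
        ec50_t1=base.ec50_t1 * age_ec50 * pop_ec50 * sevo,
    )
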