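"""Virtual-patient cohort generator.

Emulates the demographic and physiologic structure of the modelled
clinical population: predominantly female, around 62 y, 159 cm, BMI restricted
to 18-26 kg/m^2, estimated creatinine clearance around 76 mL/min, and
operations of about 2.5 h.  Weight is derived from the sampled BMI and
height; serum creatinine is back-solved from the sampled eCCr target
through the Cockcroft-Gault inverse, so the printed eCCr distribution
is reproduced exactly rather than emerging from an assumed creatinine
distribution.  Between-subject variability enters as mean-one
log-normal multipliers on clearance, central volume and twitch EC50.

Truncated normals are drawn by rejection, so the hard bounds (the BMI
window, the adult-age inclusion) hold for every sample, always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import (
    FEMALE,
    MALE,
    PatientCovariates,
    apply_covariates,
    creatinine_for_eccr,
)
from .errors import ConfigError
from .params import PKPDParameters, default_params


@dataclass(frozen=True)
class TruncatedNormal:
    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self, name: str) -> None:
        if self.sd <= 0.0:
            raise ConfigError(f"{name}: SD must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ConfigError(f"{name}: bounds must be ordered, got {self.lower}..{self.upper}")
        # a mean many SDs outside the window makes rejection hopeless
        if (self.lower - self.mean) / self.sd > 6 or (self.mean - self.upper) / self.sd > 6:
            raise ConfigError(f"{name}: truncation bounds unsatisfiable for this mean/SD")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(10000):
            x = rng.normal(self.mean, self.sd)
            if self.lower <= x <= self.upper:
                return float(x)
        raise ConfigError("rejection sampling failed; bounds too tight")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level sampling distributions (study defaults)."""

    age_y: TruncatedNormal = TruncatedNormal(62.2, 14.0, 20.0, 95.0)
    height_cm: TruncatedNormal = TruncatedNormal(159.0, 7.8, 135.0, 190.0)
    bmi: TruncatedNormal = TruncatedNormal(22.3, 2.2, 18.0, 26.0)
    eccr_ml_min: TruncatedNormal = TruncatedNormal(75.9, 20.6, 25.0, 140.0)
    operation_time_h: TruncatedNormal = TruncatedNormal(2.5, 1.0, 0.5, 6.0)
    female_fraction: float = 49.0 / 74.0
    cv_cl: float = 0.30
    cv_v1: float = 0.30
    cv_ec50: float = 0.40
    cv_ke0: float = 0.25

    def validate(self) -> None:
        for name in ("age_y", "height_cm", "bmi", "eccr_ml_min", "operation_time_h"):
            getattr(self, name).validate(name)
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        for name in ("cv_cl", "cv_v1", "cv_ec50", "cv_ke0"):
            if getattr(self, name) < 0.0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortMember:
    patient_id: int
    covariates: PatientCovariates
    params: PKPDParameters
    operation_time_h: float
    mult_cl: float
    mult_v1: float
    mult_ec50: float
    mult_ke0: float


def _lognormal_mult(rng: np.random.Generator, cv: float) -> float:
    """Mean-one log-normal multiplier with coefficient of variation ``cv``."""
    if cv == 0.0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def sample_patient(
    rng: np.random.Generator,
    config: CohortConfig | None = None,
    base_params: PKPDParameters | None = None,
) -> tuple[PatientCovariates, PKPDParameters, dict[str, float]]:
    """Draw one virtual patient and their individual parameter set.

    Returns the covariates, the scaled + randomized parameters, and the
    individual multipliers (for export / reproducibility).
    """
    config = config or CohortConfig()
    config.validate()
    base = base_params or default_params()

    sex = FEMALE if rng.random() < config.female_fraction else MALE
    age = config.age_y.sample(rng)
    height = config.height_cm.sample(rng)
    bmi = config.bmi.sample(rng)
    weight = bmi * (height / 100.0) ** 2
    eccr = config.eccr_ml_min.sample(rng)
    scr = creatinine_for_eccr(eccr, age, weight, sex)
    cov = PatientCovariates(
        sex=sex,
        age_y=age,
        height_cm=height,
        weight_kg=weight,
        serum_creatinine_mg_dl=scr,
        asian=True,
        sevoflurane=False,
    )

    mults = {
        "cl": _lognormal_mult(rng, config.cv_cl),
        "v1": _lognormal_mult(rng, config.cv_v1),
        "ec50": _lognormal_mult(rng, config.cv_ec50),
        "ke0": _lognormal_mult(rng, config.cv_ke0),
    }
    params = apply_covariates(base, cov)
    params = params.replace(
        cl_rb=params.cl_rb * mults["cl"],
        cl_sgx=params.cl_sgx * mults["cl"],
        cl_cpx=params.cl_cpx * mults["cl"],
        v1_rb=params.v1_rb * mults["v1"],
        v1_sgx=params.v1_sgx * mults["v1"],
        v1_cpx=params.v1_cpx * mults["v1"],
        ec50_t1=params.ec50_t1 * mults["ec50"],
        ke0=params.ke0 * mults["ke0"],
    )
    return cov, params, mults


def generate_cohort(
    n: int,
    seed: int,
    config: CohortConfig | None = None,
    base_params: PKPDParameters | None = None,
) -> list[CohortMember]:
    """Generate ``n`` virtual patients with per-patient operation times.

    Patients are drawn from per-patient child streams of the seed, so a
    cohort is reproducible and individual patients are independent.
    """
    if n < 1:
        raise ConfigError(f"cohort size must be >= 1, got {n}")
    config = config or CohortConfig()
    config.validate()
    base = base_params or default_params()
    seeds = np.random.SeedSequence(seed).spawn(n)
    members = []
    for i, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        cov, params, mults = sample_patient(rng, config, base)
        op_time = config.operation_time_h.sample(rng)
        members.append(
            CohortMember(
                patient_id=i,
                covariates=cov,
                params=params,
                operation_time_h=op_time,
                mult_cl=mults["cl"],
                mult_v1=mults["v1"],
                mult_ec50=mults["ec50"],
                mult_ke0=mults["ke0"],
            )
        )
    return members


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    rows = []
    for m in members:
        c = m.covariates
        rows.append(
            {
                "id": m.patient_id,
                "sex": c.sex,
                "age_y": c.age_y,
                "height_cm": c.height_cm,
                "weight_kg": c.weight_kg,
                "bmi": c.bmi,
                "scr_mg_dl": c.serum_creatinine_mg_dl,
                "eccr_ml_min": c.eccr_ml_min,
                "op_time_h": m.operation_time_h,
                "mult_cl": m.mult_cl,
                "mult_v1": m.mult_v1,
                "mult_ec50": m.mult_ec50,
                "mult_ke0": m.mult_ke0,
            }
        )
    return pd.DataFrame.from_records(rows)


def cohort_from_frame(
    frame: pd.DataFrame, base_params: PKPDParameters | None = None
) -> list[CohortMember]:
    """Rebuild cohort members (covariates + individual parameters) from
    an exported cohort table."""
    base = base_params or default_params()
    members = []
    for row in frame.itertuples(index=False):
        cov = PatientCovariates(
            sex=row.sex,
            age_y=row.age_y,
            height_cm=row.height_cm,
            weight_kg=row.weight_kg,
            serum_creatinine_mg_dl=row.scr_mg_dl,
        )
        params = apply_covariates(base, cov)
        params = params.replace(
            cl_rb=params.cl_rb * row.mult_cl,
            cl_sgx=params.cl_sgx * row.mult_cl,
            cl_cpx=params.cl_cpx * row.mult_cl,
            v1_rb=params.v1_rb * row.mult_v1,
            v1_sgx=params.v1_sgx * row.mult_v1,
            v1_cpx=params.v1_cpx * row.mult_v1,
            ec50_t1=params.ec50_t1 * row.mult_ec50,
            ke0=params.ke0 * getattr(row, "mult_ke0", 1.0),
        )
        members.append(
            CohortMember(
                patient_id=int(row.id),
                covariates=cov,
                params=params,
                operation_time_h=float(row.op_time_h),
                mult_cl=float(row.mult_cl),
                mult_v1=float(row.mult_v1),
                mult_ec50=float(row.mult_ec50),
                mult_ke0=float(getattr(row, "mult_ke0", 1.0)),
            )
        )
    return members
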