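"""Model parameters for the rocuronium / sugammadex PK-PD system.

A single :class:`PKPDParameters` instance carries everything the engine
needs for one subject: two-compartment disposition terms for free
rocuronium, free sugammadex and the 1:1 complex, the molar binding rate
constants, the plasma -> effect-site link constant ``ke0``, the
four-twitch train-of-four (TOF) pharmacodynamic constants, and the
covariate coefficients used by :func:`nmbsim.covariates.apply_covariates`.

Default values describe an Asian reference adult (male, 40 y, 60 kg,
creatinine clearance 100 mL/min).  Disposition magnitudes are in the
range reported for the two drugs in adults; the pharmacodynamic constants
(EC50, Hill slope, fade ratios) and the binding/link constants were
calibrated so that the simulated observables sit on the clinical anchors
the model is meant to reproduce: an intraoperative TOF-count-1 plateau
concentration near 1.2 ug/mL, recovery (TOFR >= 0.9) concentrations near
0.3 ug/mL, reversal of shallow block by sugammadex 2 mg/kg in under two
minutes, a post-reversal nadir of the free effect-site concentration a
few minutes after recovery, and a small rebound peaking roughly half an
hour later.  Every value can be overridden via keyword, dict, or a flat
YAML/JSON parameter file (see :func:`load_params` / :func:`save_params`).

Units convention: volumes L, clearances L/min, first-order rate
constants 1/min, ``kon`` 1/(uM*min), concentrations ug/mL, molecular
weights g/mol.  Simulation time is handled in seconds by the engine;
the conversion happens there, not here.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import yaml

from .errors import ConfigError, ParseError

SCHEMA_VERSION = 1

#: molecular weight of rocuronium bromide cation basis, g/mol
MW_ROCURONIUM = 609.7
#: molecular weight of sugammadex sodium, g/mol
MW_SUGAMMADEX = 2178.0

#: reference body weight (kg) at which the default disposition terms hold
REFERENCE_WEIGHT_KG = 60.0
#: reference age (years) of the covariate model
REFERENCE_AGE_Y = 40.0
#: reference creatinine clearance (mL/min)
REFERENCE_ECCR_ML_MIN = 100.0
#: height (cm) whose Devine ideal body weight is exactly 60 kg (male)
REFERENCE_HEIGHT_CM = 152.4 + 2.54 * 10.0 / 2.3


@dataclass(frozen=True)
class PKPDParameters:
    """Complete per-subject parameter set (after covariate scaling)."""

    # --- free rocuronium, two-compartment ---
    v1_rb: float = 3.0        # central volume, L
    v2_rb: float = 9.0        # peripheral volume, L
    cl_rb: float = 0.24       # elimination clearance, L/min
    q_rb: float = 0.70        # inter-compartmental clearance, L/min

    # --- free sugammadex, two-compartment ---
    v1_sgx: float = 3.6
    v2_sgx: float = 6.0
    cl_sgx: float = 0.09      # renal; scaled by eCCr in the covariate model
    q_sgx: float = 0.15

    # --- rocuronium-sugammadex complex (sugammadex-like disposition) ---
    v1_cpx: float = 3.6
    v2_cpx: float = 6.0
    cl_cpx: float = 0.09      # renal; scaled by eCCr
    q_cpx: float = 0.15

    # --- 1:1 binding ---
    kon: float = 100.0        # 1/(uM*min)
    koff: float = 10.0        # 1/min  (Kd = koff/kon = 0.1 uM)

    # --- effect-site link ---
    ke0: float = 0.72         # 1/min

    # --- pharmacodynamics (four-twitch TOF construction) ---
    ec50_t1: float = 0.55     # effect-site EC50 of the first twitch, ug/mL
    hill_gamma: float = 3.5   # Hill slope, shared by the four twitches
    fade2: float = 0.87       # EC50 ratio twitch 2 / twitch 1
    fade3: float = 0.855      # EC50 ratio twitch 3 / twitch 1
    fade4: float = 0.84       # EC50 ratio twitch 4 / twitch 1
    twitch_threshold_pct: float = 5.0  # detection threshold, % of control

    # --- molecular weights ---
    mw_rb: float = MW_ROCURONIUM
    mw_sgx: float = MW_SUGAMMADEX

    # --- covariate model coefficients (see covariates.apply_covariates) ---
    ref_weight_kg: float = REFERENCE_WEIGHT_KG
    ref_age_y: float = REFERENCE_AGE_Y
    ref_eccr_ml_min: float = REFERENCE_ECCR_ML_MIN
    size_exp_v: float = 1.0     # allometric exponent for volumes
    size_exp_cl: float = 0.75   # allometric exponent for clearances
    renal_frac_rb: float = 0.3  # renally-cleared fraction of rocuronium CL
    age_coef_cl: float = -0.003   # fractional CL change per year above ref
    age_coef_ec50: float = -0.004  # fractional EC50 change per year
    non_asian_cl_factor: float = 1.05   # applied when asian is False
    non_asian_ec50_factor: float = 1.10
    sevo_ec50_factor: float = 1.0  # volatile potentiation; null under TIVA

    def validate(self) -> None:
        """Raise :class:`ConfigError` on a physically meaningless value."""
        positive = (
            "v1_rb v2_rb cl_rb q_rb v1_sgx v2_sgx cl_sgx q_sgx "
            "v1_cpx v2_cpx cl_cpx q_cpx koff ke0 ec50_t1 mw_rb mw_sgx "
            "ref_weight_kg ref_eccr_ml_min"
        ).split()
        for name in positive:
            value = getattr(self, name)
            if not (value > 0.0 and value < float("inf")):
                raise ConfigError(f"parameter {name!r} must be positive and finite, got {value!r}")
        # kon = 0 is the explicit "binding disabled" switch
        if not (self.kon >= 0.0 and self.kon < float("inf")):
            raise ConfigError(f"kon must be non-negative and finite, got {self.kon!r}")
        if self.hill_gamma < 1.0:
            raise ConfigError(f"hill_gamma must be >= 1, got {self.hill_gamma}")
        fades = (self.fade2, self.fade3, self.fade4)
        if not all(0.0 < f <= 1.0 for f in fades):
            raise ConfigError(f"fade ratios must be in (0, 1], got {fades}")
        if not (1.0 >= self.fade2 >= self.fade3 >= self.fade4):
            raise ConfigError("fade ratios must be non-increasing from twitch 2 to 4")
        if not 0.0 < self.twitch_threshold_pct < 100.0:
            raise ConfigError("twitch_threshold_pct must be in (0, 100)")

    @property
    def kd_um(self) -> float:
        """Equilibrium dissociation constant of the complex, uM."""
        return self.koff / self.kon if self.kon > 0.0 else float("inf")

    def replace(self, **changes: float) -> "PKPDParameters":
        out = dataclasses.replace(self, **changes)
        out.validate()
        return out

    def to_dict(self) -> dict:
        d = {"schema_version": SCHEMA_VERSION}
        d.update(dataclasses.asdict(self))
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PKPDParameters":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ParseError(f"unsupported parameter schema version {version!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown parameter keys: {sorted(unknown)}")
        out = cls(**data)
        out.validate()
        return out


def default_params() -> PKPDParameters:
    """The calibrated Asian reference-adult parameter set."""
    p = PKPDParameters()
    p.validate()
    return p


def load_params(path: str | pathlib.Path) -> PKPDParameters:
    """Load a flat YAML or JSON parameter file."""
    path = pathlib.Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"parameter file {path} must hold a flat mapping")
    return PKPDParameters.from_dict(data)


def save_params(params: PKPDParameters, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
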