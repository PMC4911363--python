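"""Model parameter containers.

Parameters are grouped by sub-model (leaf hydraulics, leaf--air aerodynamics
and energy balance, stomatal kinetics, FvCB biochemistry).  Defaults are the
cucumber-leaf calibration the simulator was built around; every value can be
overridden from a flat TOML/YAML config file whose keys match the dataclass
field names.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError

__all__ = [
    "HydraulicParams",
    "AeroParams",
    "StomatalParams",
    "FvCBParams",
    "ModelParams",
    "load_params",
]


@dataclass
class HydraulicParams:
    """Leaf water relations: xylem-to-mesophyll conductance and potentials.

    Units: conductance constants ``a``/``b`` in g H2O m-2 s-1 MPa-1,
    ``tau_c`` in g H2O m-2 s-1 MPa-2, potentials in MPa, water contents in
    mol H2O m-2.
    """

    a: float = 0.0259            # light-independent hydraulic conductance
    b: float = 0.2268            # light-dependent hydraulic conductance gain
    ppfd_lim: float = 1000.0     # PPFD at which the light response saturates
    tau_c: float = 0.324 / 15.0  # amplitude of the endogenous oscillation
    psi_x: float = -0.08         # xylem water potential, held constant
    psi_m_r: float = -0.9        # reference mesophyll water potential
    cv_f1: float = 0.05556       # g H2O -> mol H2O conversion
    cv_f2: float = 55.56         # L H2O -> mol H2O conversion
    gas_constant: float = 8.3145e-3  # L MPa mol-1 K-1
    n_xy: float = 0.0003         # xylem sap solute concentration, mol mol-1
    c_i: float = 2.0             # ion exchange factor (solute loading)
    c_e: float = 0.2             # Na+ exclusion coefficient; parsed, unused
    alpha: float = 2.4           # full turgor pressure, MPa
    beta: float = 10.6           # mesophyll elasticity
    wm_max: float = 16.0         # mesophyll water content at full hydration
    osc_time_unit: str = "minutes"  # time unit fed to the oscillation phase

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.tau_c < 0:
            raise ParameterError("hydraulic conductance constants must be >= 0")
        if self.wm_max <= 0:
            raise ParameterError("wm_max must be positive")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        if self.osc_time_unit not in ("minutes", "hours"):
            raise ParameterError(
                f"osc_time_unit must be 'minutes' or 'hours', got {self.osc_time_unit!r}"
            )


@dataclass
class AeroParams:
    """Boundary layer, psychrometrics, and radiation conversion.

    The molar unit system is used throughout: ``rho_a`` is the molar mass of
    air (g mol-1) and ``rho_a * c_p`` the molar heat capacity (~29.3
    J mol-1 K-1), consistent with molar conductances in the transpiration and
    leaf-temperature equations.
    """

    g_bw: float = 2.7        # boundary-layer conductance to water vapour, mol m-2 s-1
    rho_a: float = 28.9645   # molar mass of air, g mol-1
    c_p: float = 1.012       # specific heat of air, J g-1 K-1
    gamma: float = 0.0665    # psychrometric constant, kPa K-1
    lam: float = 44172.0     # latent heat of vaporisation, J mol-1 H2O
    a1: float = 0.61375      # saturation vapour pressure scale, kPa
    a2: float = 17.502       # Magnus coefficient, dimensionless
    a3: float = 240.97       # Magnus coefficient, K offset
    g_i: float = 0.0         # ground/soil heat flux, J m-2 s-1 (0 for a leaf)
    k_rad: float = 0.4376    # PPFD -> net radiation conversion, J umol-1
    slope_mode: str = "literal"  # saturation-slope formula: literal | saturation

    def __post_init__(self) -> None:
        if self.g_bw <= 0:
            raise ParameterError("g_bw must be positive")
        if self.gamma <= 0 or self.lam <= 0:
            raise ParameterError("gamma and lam must be positive")
        if self.slope_mode not in ("literal", "saturation"):
            raise ParameterError(
                f"slope_mode must be 'literal' or 'saturation', got {self.slope_mode!r}"
            )

    @property
    def g_ah(self) -> float:
        """Conductance to diffusive heat transfer (heat/water diffusivity ratio 1.15)."""
        return self.g_bw / 1.15


@dataclass
class StomatalParams:
    """Dynamic stomatal conductance model: steady-state target and kinetics."""

    g0: float = 0.009          # residual (dark) conductance to CO2, mol m-2 s-1
    g1: float = 3.51           # slope parameter of the steady-state target
    alpha_g: float = 4.0516e-3  # kinetic time constant, s-1
    r0: float = 2.674e-3       # initial-lag conductance offset, mol H2O m-2 s-1
    s_f: float = 4.9           # sensitivity to water potential, MPa-1
    psi_r: float = -0.9        # reference water potential of the gating curve, MPa
    de_min: float = 0.01       # floor on vapour pressure deficit in the target, kPa

    def __post_init__(self) -> None:
        if self.alpha_g <= 0:
            raise ParameterError("alpha_g must be positive")
        if self.r0 < 0:
            raise ParameterError("r0 must be >= 0")
        if self.de_min <= 0:
            raise ParameterError("de_min must be positive")


@dataclass
class FvCBParams:
    """FvCB photosynthesis with mesophyll conductance (no temperature response)."""

    vcmax: float = 102.0       # max carboxylation rate, umol CO2 m-2 s-1
    jmax: float = 140.0        # max electron transport rate, umol e- m-2 s-1
    theta: float = 0.75        # convexity of the light response
    kappa2_ll: float = 0.425   # quantum yield of electron transport at low light
    gamma_star: float = 43.02  # CO2 compensation point sans day respiration, umol mol-1
    km: float = 711.0          # effective Michaelis constant for CO2, umol mol-1
    rd: float = 1.08           # day respiration, umol CO2 m-2 s-1
    gm: float = 0.3            # mesophyll conductance to CO2, mol m-2 s-1
    ca: float = 380.0          # ambient CO2 mole fraction, umol mol-1
    subtract_rd: bool = False  # subtract Rd from the reported assimilation

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ParameterError("theta must lie in (0, 1)")
        for name in ("vcmax", "jmax", "kappa2_ll", "gamma_star", "km", "gm", "ca"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass
class ModelParams:
    """The full parameter set, grouped by sub-model."""

    hydraulics: HydraulicParams = field(default_factory=HydraulicParams)
    aero: AeroParams = field(default_factory=AeroParams)
    stomata: StomatalParams = field(default_factory=StomatalParams)
    fvcb: FvCBParams = field(default_factory=FvCBParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_hash(self) -> str:
        """Stable short hash of the resolved parameter set, for run metadata."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **flat: float) -> "ModelParams":
        """Return a copy with flat field overrides routed to their group."""
        groups = {
            "hydraulics": dict(dataclasses.asdict(self.hydraulics)),
            "aero": dict(dataclasses.asdict(self.aero)),
            "stomata": dict(dataclasses.asdict(self.stomata)),
            "fvcb": dict(dataclasses.asdict(self.fvcb)),
        }
        for key, value in flat.items():
            placed = False
            for gname, gdict in groups.items():
                if key in gdict:
                    gdict[key] = value
                    placed = True
            if not placed:
                raise ParameterError(f"unknown parameter {key!r}")
        return ModelParams(
            hydraulics=HydraulicParams(**groups["hydraulics"]),
            aero=AeroParams(**groups["aero"]),
            stomata=StomatalParams(**groups["stomata"]),
            fvcb=FvCBParams(**groups["fvcb"]),
        )

    @classmethod
    def from_dict(cls, flat: dict) -> "ModelParams":
        return cls().replace(**flat)


def load_params(path: str | Path) -> ModelParams:
    """Load a flat TOML or YAML parameter file.

    Keys are the dataclass field names (``vcmax``, ``g1``, ``alpha_g``, ...);
    a key shared by several groups (none by default) overrides all of them.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        flat = tomllib.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        import yaml

        flat = yaml.safe_load(text) or {}
    elif path.suffix == ".json":
        flat = json.loads(text)
    else:
        raise ParameterError(f"unsupported parameter file type: {path.suffix!r}")
    if not isinstance(flat, dict):
        raise ParameterError("parameter file must contain a flat table of key = value")
    # allow nested group tables as well as flat keys
    merged: dict = {}
    for key, value in flat.items():
        if isinstance(value, dict):
            merged.update(value)
        else:
            merged[key] = value
    for key, value in merged.items():
        if isinstance(value, bool):
            continue
        if isinstance(value, (int, float)) and not math.isfinite(value):
            raise ParameterError(f"parameter {key!r} is not finite")
    return ModelParams.from_dict(merged)
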