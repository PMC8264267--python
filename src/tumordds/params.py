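"""Physical parameter registry and unit conversion.

All tissue, drug, nanoparticle, vessel and growth-law constants used by the
simulator live here, in one coherent internal unit system (SI: Pa, m, s,
mol/m³; Gompertz rates in month⁻¹ because treatment schedules are specified
in months).  Literature values are tabulated in their native units (mmHg,
cm, minutes, molar) and converted exactly once at load time.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Any

#: Pa per mmHg.
MMHG_PA = 133.322
#: mol/m³ per mol/L (molar).
MOLAR_TO_SI = 1000.0
#: Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23

NORMAL = "normal"
TUMOR = "tumor"
FREE_DRUG = "free_drug"
NP_PRIMARY = "np_primary"
NP_SECONDARY = "np_secondary"


def convert_pressure(value_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    if not math.isfinite(value_mmhg):
        raise ValueError(f"pressure must be finite, got {value_mmhg!r}")
    return value_mmhg * MMHG_PA


def pressure_to_mmhg(value_pa: float) -> float:
    """Inverse of :func:`convert_pressure`."""
    if not math.isfinite(value_pa):
        raise ValueError(f"pressure must be finite, got {value_pa!r}")
    return value_pa / MMHG_PA


# --------------------------------------------------------------------------
# Native-unit literature defaults.
#
# Tissue transport constants (per tissue type):
#   pi_B, pi_i [mmHg]; sigma_s [-]; L_p [cm/(mmHg s)];
#   lymph_filtration = L_pL (S/V)_L [1/(mmHg s)]; kappa [cm²/(mmHg s)];
#   P_L [Pa].
# Agent constants: D [m²/s] per tissue; P [m/s] per tissue; k_d in minutes;
#   C_rec in molar; everything else already SI.
# --------------------------------------------------------------------------

_NATIVE_DEFAULTS: dict[str, Any] = {
    "tissue": {
        NORMAL: {
            "pi_B": 20.0,
            "pi_i": 10.0,
            "sigma_s": 0.91,
            "L_p": 0.36e-7,
            "lymph_filtration": 1.33e-5,
            "kappa": 8.53e-9,
            "P_L": 0.0,
        },
        TUMOR: {
            "pi_B": 20.0,
            "pi_i": 15.0,
            "sigma_s": 0.82,
            "L_p": 2.8e-7,
            "lymph_filtration": 0.0,
            "kappa": 4.13e-8,
            "P_L": 0.0,
        },
    },
    "agent": {
        FREE_DRUG: {
            "D": {NORMAL: 1.58e-10, TUMOR: 3.40e-10},
            "P": {NORMAL: 3.75e-7, TUMOR: 3.00e-6},
            "sigma_f": 0.35,
            "K_ON": 15.0,
            "K_OFF": 8e-3,
            "K_INT": 5e-5,
            "phi": 0.4,
            "C_rec": 1e-5,      # molar
            "k_d": 6.0,         # minutes
            "K_rel": 0.0,
            "alpha": 1.0,
            "beta": 1.0,
            "omega": 0.6603,    # m³/mol
            "diameter": 0.0,
        },
        # Baseline nanocarrier: 20 nm particle, 200 nm vessel-wall pore.
        NP_PRIMARY: {
            "D": {NORMAL: 7e-12, TUMOR: 7e-12},
            "P": {NORMAL: None, TUMOR: None},   # from pore theory at load
            "sigma_f": None,                     # from pore theory at load
            "K_ON": 15.0,
            "K_OFF": 8e-3,
            "K_INT": 5e-5,
            "phi": 0.05,
            "C_rec": 1e-5,
            "k_d": 1320.0,      # minutes
            "K_rel": 2.1e-6,
            "alpha": 20.0,
            "beta": 1.0,
            "omega": 0.6603,
            "diameter": 20e-9,
        },
        # Secondary particle of a three-stage system (born in tissue).
        NP_SECONDARY: {
            "D": {NORMAL: 2.8e-11, TUMOR: 2.8e-11},
            "P": {NORMAL: None, TUMOR: None},
            "sigma_f": None,
            "K_ON": 15.0,
            "K_OFF": 8e-3,
            "K_INT": 5e-5,
            "phi": 0.05,
            "C_rec": 1e-5,
            "k_d": 1320.0,
            "K_rel": 2.1e-6,
            "alpha": 20.0,
            "beta": 20.0,
            "omega": 0.6603,
            "diameter": 5e-9,
        },
    },
    "vessel": {
        "P_inlet1": 25.0,   # mmHg
        "P_inlet2": 25.0,   # mmHg
        "P_outlet": 10.0,   # mmHg
        "mu_blood": 3e-3,   # Pa s
        "r_vessel": 5e-6,   # m
    },
    "gompertz": {
        "N0": 5e9,
        "N_inf": 3.1e12,
        "b": 0.0283,         # month⁻¹
        "N_healthy": 4.64e12,
        "density_ratio": 0.2,
    },
    "pore": {
        "gamma": 1e-4,
        "L": 5e-6,          # m
        "eta": 7e-4,        # Pa s
        "T": 310.0,         # K
        "r_o": 1e-7,        # m (200 nm pore diameter)
    },
}

#: Fields converted mmHg→Pa at load.
_TISSUE_PRESSURE_FIELDS = ("pi_B", "pi_i")
#: cm-based conductivities: cm/(mmHg s) → m/(Pa s), cm²/(mmHg s) → m²/(Pa s).
_LP_FACTOR = 1e-2 / MMHG_PA
_KAPPA_FACTOR = 1e-4 / MMHG_PA
_LYMPH_FACTOR = 1.0 / MMHG_PA


@dataclass
class TissueParams:
    """Interstitial transport constants of one tissue type, SI units."""

    pi_B: float          # Pa
    pi_i: float          # Pa
    sigma_s: float       # -
    L_p: float           # m/(Pa s)
    lymph_filtration: float  # 1/(Pa s)
    kappa: float         # m²/(Pa s)
    P_L: float           # Pa

    def validate(self) -> None:
        if not 0.0 <= self.sigma_s <= 1.0:
            raise ValueError(f"sigma_s must be in [0,1], got {self.sigma_s}")
        for name in ("L_p", "lymph_filtration", "kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AgentParams:
    """Transport and kinetic constants for one agent species, SI units."""

    D: dict[str, float]            # m²/s per tissue
    P: dict[str, float | None]     # m/s per tissue (None: from pore theory)
    sigma_f: float | None
    K_ON: float                    # m³/(mol s)
    K_OFF: float                   # 1/s
    K_INT: float                   # 1/s
    phi: float                     # -
    C_rec: float                   # mol/m³
    k_d: float                     # s (plasma e-folding time)
    K_rel: float                   # 1/s
    alpha: float                   # payload count of primary carrier
    beta: float                    # payload count of secondary carrier
    omega: float                   # m³/mol
    diameter: float                # m (0 for a free molecule)

    def validate(self) -> None:
        if self.sigma_f is not None and not 0.0 <= self.sigma_f <= 1.0:
            raise ValueError(f"sigma_f must be in [0,1], got {self.sigma_f}")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError(f"phi must be in (0,1], got {self.phi}")
        for name in ("K_ON", "K_OFF", "K_INT", "K_rel", "C_rec", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_d <= 0:
            raise ValueError("k_d must be > 0")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def binding_rate(self) -> float:
        """Effective first-order binding rate (1/φ)·K_ON·C_rec, in s⁻¹."""
        return self.K_ON * self.C_rec / self.phi


@dataclass
class VesselParams:
    P_inlet1: float   # Pa
    P_inlet2: float   # Pa
    P_outlet: float   # Pa
    mu_blood: float   # Pa s
    r_vessel: float   # m

    def validate(self) -> None:
        if self.mu_blood <= 0 or self.r_vessel <= 0:
            raise ValueError("mu_blood and r_vessel must be > 0")


@dataclass
class GompertzParams:
    N0: float
    N_inf: float
    b: float            # month⁻¹
    N_healthy: float
    density_ratio: float

    def validate(self) -> None:
        if not 0 < self.N0 <= self.N_inf:
            raise ValueError("need 0 < N0 <= N_inf")
        if self.b < 0:
            raise ValueError("b must be >= 0")


@dataclass
class PoreParams:
    gamma: float   # -
    L: float       # m
    eta: float     # Pa s
    T: float       # K
    r_o: float     # m

    def validate(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0,1]")
        if min(self.L, self.eta, self.T, self.r_o) <= 0:
            raise ValueError("L, eta, T, r_o must be > 0")


@dataclass
class ParameterSet:
    """Full simulator parameter set in SI units."""

    tissue: dict[str, TissueParams]
    agent: dict[str, AgentParams]
    vessel: VesselParams
    gompertz: GompertzParams
    pore: PoreParams

    def validate(self) -> None:
        for t in self.tissue.values():
            t.validate()
        for a in self.agent.values():
            a.validate()
        self.vessel.validate()
        self.gompertz.validate()
        self.pore.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            tissue={k: TissueParams(**v) for k, v in d["tissue"].items()},
            agent={k: AgentParams(**v) for k, v in d["agent"].items()},
            vessel=VesselParams(**d["vessel"]),
            gompertz=GompertzParams(**d["gompertz"]),
            pore=PoreParams(**d["pore"]),
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(copy.deepcopy(self.to_dict()))


def _native_to_si(native: dict) -> dict:
    si = copy.deepcopy(native)
    for tis in si["tissue"].values():
        for f in _TISSUE_PRESSURE_FIELDS:
            tis[f] = convert_pressure(tis[f])
        tis["L_p"] *= _LP_FACTOR
        tis["kappa"] *= _KAPPA_FACTOR
        tis["lymph_filtration"] *= _LYMPH_FACTOR
    for ag in si["agent"].values():
        ag["C_rec"] *= MOLAR_TO_SI
        ag["k_d"] *= 60.0
    for f in ("P_inlet1", "P_inlet2", "P_outlet"):
        si["vessel"][f] = convert_pressure(si["vessel"][f])
    return si


def _si_to_native(si: dict) -> dict:
    native = copy.deepcopy(si)
    for tis in native["tissue"].values():
        for f in _TISSUE_PRESSURE_FIELDS:
            tis[f] = pressure_to_mmhg(tis[f])
        tis["L_p"] /= _LP_FACTOR
        tis["kappa"] /= _KAPPA_FACTOR
        tis["lymph_filtration"] /= _LYMPH_FACTOR
    for ag in native["agent"].values():
        ag["C_rec"] /= MOLAR_TO_SI
        ag["k_d"] /= 60.0
    for f in ("P_inlet1", "P_inlet2", "P_outlet"):
        native["vessel"][f] = pressure_to_mmhg(native["vessel"][f])
    return native


def native_defaults() -> dict:
    """Literature defaults in their native (published) units."""
    return copy.deepcopy(_NATIVE_DEFAULTS)


def _apply_override(tree: dict, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    node = tree
    for p in parts[:-1]:
        if not isinstance(node, dict) or p not in node:
            raise KeyError(f"unknown parameter key {dotted!r}")
        node = node[p]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(f"unknown parameter key {dotted!r}")
    node[leaf] = value


def load_parameter_set(overrides: dict[str, Any] | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from literature defaults.

    Parameters
    ----------
    overrides
        Mapping of dotted SI-unit parameter paths to replacement values, e.g.
        ``{"tissue.tumor.sigma_s": 0.8, "agent.np_primary.K_rel": 1e-4}``.
        Keys must reference existing fields; invariant violations raise.
    """
    si = _native_to_si(_NATIVE_DEFAULTS)
    if overrides:
        for key, value in overrides.items():
            _apply_override(si, key, value)
    ps = ParameterSet.from_dict(si)
    ps.validate()
    return ps
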