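"""Size-dependent vessel-wall transport of particles in cylindrical pores.

Hindered-transport theory for a rigid sphere of radius ``r_s`` crossing a
vessel wall pierced by cylindrical pores of radius ``r_o``.  With the size
ratio λ = r_s/r_o the steric partition coefficient is F = (1−λ)², and the
diffusive/convective hindrance factors follow the Bungay–Brenner composite
expansion

    K = (9/4)π²√2 (1−λ)^(−5/2) [1 + Σ_{n=1,2} c_n (1−λ)^n]
        + Σ_{n=0..4} c_{n+3} λ^n

with one coefficient set for the resistance to translation (K_t) and one
for shear (K_s).  The wall coefficients then are

    L_p = γ r_o² / (8 η L),   P = γ H D_o / L,   σ_f = 1 − W,

where D_o is the free-solution Stokes–Einstein diffusivity and γ, L the
pore area fraction and wall thickness.  Electrostatic particle–pore
interactions are neglected throughout (E = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import K_BOLTZMANN, PoreParams

#: Bungay–Brenner coefficients for K_t (translation).
A_COEFFS = (-73.0 / 60.0, 77.293 / 50.400, -22.5083, -5.617, -0.3363, -1.216, 1.647)
#: Bungay–Brenner coefficients for K_s (shear).
B_COEFFS = (7.0 / 60.0, -2.227 / 50.400, 4.0180, -3.9788, -1.9215, 4.392, 5.006)


@dataclass
class PoreGeometry:
    """Particle/pore pairing for one agent crossing the vessel wall."""

    r_s: float            # particle radius, m
    r_o: float            # pore radius, m
    gamma: float          # pore area fraction of the wall, -
    L: float              # wall thickness, m
    eta: float            # solvent viscosity at T, Pa s
    T: float = 310.0      # K

    def __post_init__(self) -> None:
        if self.r_s <= 0 or self.r_o <= 0:
            raise ValueError("particle and pore radii must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0,1]")
        if self.L <= 0 or self.eta <= 0 or self.T <= 0:
            raise ValueError("L, eta, T must be > 0")

    @property
    def lam(self) -> float:
        return self.r_s / self.r_o

    @classmethod
    def for_particle(cls, r_s: float, pore: PoreParams) -> "PoreGeometry":
        return cls(r_s=r_s, r_o=pore.r_o, gamma=pore.gamma, L=pore.L,
                   eta=pore.eta, T=pore.T)


@dataclass
class HindranceResult:
    """All intermediate and final wall-transport coefficients."""

    lam: float
    F: float
    K_t: float
    K_s: float
    H: float
    W: float
    D_o: float      # m²/s
    L_p: float      # m/(Pa s)
    P: float        # m/s
    sigma_f: float


def stokes_einstein_diffusivity(r_s: float, T: float, eta: float) -> float:
    """Free-solution diffusivity k_B·T/(6π·η·r_s) of a sphere, m²/s."""
    if r_s <= 0 or T <= 0 or eta <= 0:
        raise ValueError("r_s, T, eta must all be > 0")
    return K_BOLTZMANN * T / (6.0 * np.pi * eta * r_s)


def partition_coefficient(lam: float) -> float:
    """Steric partition coefficient F = (1−λ)²."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0,1], got {lam}")
    return (1.0 - lam) ** 2


def kt_ks(lam: float) -> tuple[float, float]:
    """Hydrodynamic resistance functions (K_t, K_s) of the centred sphere.

    Diverges as (1−λ)^(−5/2) for λ→1; λ ≥ 1 is rejected.
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lam must be in [0,1), got {lam}")

    def _series(c: tuple[float, ...]) -> float:
        pref = 2.25 * np.pi**2 * np.sqrt(2.0) * (1.0 - lam) ** -2.5
        bracket = 1.0 + c[0] * (1.0 - lam) + c[1] * (1.0 - lam) ** 2
        tail = sum(c[2 + n] * lam**n for n in range(5))
        return pref * bracket + tail

    return _series(A_COEFFS), _series(B_COEFFS)


def hindrance_factors(lam: float) -> tuple[float, float]:
    """Diffusive and convective hindrance (H, W) at size ratio λ.

    H = 6πF/K_t and W = F(2−F)·K_s/(2K_t); both equal 1 at λ = 0 and fall
    monotonically toward 0 as the particle approaches the pore size.
    """
    K_t, K_s = kt_ks(lam)
    F = partition_coefficient(lam)
    H = 6.0 * np.pi * F / K_t
    W = F * (2.0 - F) * K_s / (2.0 * K_t)
    return H, W


def vessel_wall_coefficients(geom: PoreGeometry,
                             oversize: str = "error") -> HindranceResult:
    """Compute all vessel-wall transport coefficients for one particle.

    Parameters
    ----------
    geom
        Particle/pore pairing.
    oversize
        Behaviour for λ ≥ 1: ``"error"`` raises (direct API use);
        ``"exclude"`` returns the excluded-particle limit σ_f = 1, P = 0
        with L_p unchanged, letting size sweeps cross the pore size.
    """
    if oversize not in ("error", "exclude"):
        raise ValueError("oversize must be 'error' or 'exclude'")
    lam = geom.lam
    D_o = stokes_einstein_diffusivity(geom.r_s, geom.T, geom.eta)
    L_p = geom.gamma * geom.r_o**2 / (8.0 * geom.eta * geom.L)
    if lam >= 1.0:
        if oversize == "error":
            raise ValueError(f"particle does not fit pore (lambda={lam:.3g})")
        return HindranceResult(lam=lam, F=0.0, K_t=np.inf, K_s=np.inf,
                               H=0.0, W=0.0, D_o=D_o, L_p=L_p, P=0.0,
                               sigma_f=1.0)
    K_t, K_s = kt_ks(lam)
    H, W = hindrance_factors(lam)
    return HindranceResult(
        lam=lam,
        F=partition_coefficient(lam),
        K_t=K_t,
        K_s=K_s,
        H=H,
        W=W,
        D_o=D_o,
        L_p=L_p,
        P=geom.gamma * H * D_o / geom.L,
        sigma_f=1.0 - W,
    )


def size_sweep(diameters_m, pore: PoreParams):
    """Wall coefficients over a particle-diameter sweep (CLI `nanoprops`).

    Returns a list of (diameter, HindranceResult); oversized particles get
    the excluded limit rather than an error.
    """
    out = []
    for d in np.atleast_1d(diameters_m):
        geom = PoreGeometry.for_particle(0.5 * float(d), pore)
        out.append((float(d), vessel_wall_coefficients(geom, oversize="exclude")))
    return out
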