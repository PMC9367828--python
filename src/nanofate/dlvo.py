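"""Sphere-sphere DLVO interaction-energy profiles for nanoparticle suspensions.

Total interaction energy V_total(D) = V_vdw(D) + V_edl(D) between two
spheres at surface separation D: a retarded van der Waals attraction
(Gregory's form, with characteristic wavelength lambda) plus the
constant-potential electrical double-layer repulsion with the measured
zeta-potential standing in for the surface potential. A positive maximum of
V_total is the energy barrier opposing aggregation; its disappearance with
rising ionic strength marks the transition from reaction-limited to
diffusion-limited aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "HamakerSpec",
    "ElectrostaticMedium",
    "ParticlePair",
    "InteractionProfile",
    "debye_kappa",
    "v_vdw",
    "v_edl",
    "v_total_profile",
    "energy_barrier",
    "barrier_vs_ionic_strength",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants as used in the double-layer screening expression."""

    k_B: float = 1.38e-23  # J/K
    N_A: float = 6.02e23  # 1/mol
    e: float = 1.602e-19  # C
    epsilon_0: float = 8.85e-12  # C^2 N^-1 m^-2


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class HamakerSpec:
    """Hamaker constant for particle-medium-particle and the retardation wavelength."""

    A_131: float = 3.7e-20  # J, citrate-coated AgNPs across water
    lambda_c: float = 1.0e-7  # m, characteristic wavelength of interaction

    def __post_init__(self) -> None:
        if self.A_131 < 0:
            raise ValueError("A_131 must be >= 0")
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be > 0")


def debye_kappa(
    ionic_strength: float,
    temperature: float = 298.15,
    epsilon_r: float = 78.5,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float]:
    """Debye screening parameter kappa (1/m) and the Debye length kappa^-1 (m).

    kappa = sqrt(2 N_A I e^2 / (eps_r eps_0 k_B T)) with I in mol/L
    converted to mol/m^3; kappa^-1(0.1 M, 298 K) ~ 0.96 nm.
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be > 0 (infinite screening length)")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    i_m3 = ionic_strength * 1000.0
    kappa = math.sqrt(
        2.0 * constants.N_A * i_m3 * constants.e**2
        / (epsilon_r * constants.epsilon_0 * constants.k_B * temperature)
    )
    return kappa, 1.0 / kappa


@dataclass(frozen=True)
class ElectrostaticMedium:
    """Dielectric continuum with ionic screening."""

    ionic_strength: float  # mol/L
    temperature: float = 298.15  # K
    epsilon_r: float = 78.5

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.temperature, self.epsilon_r)[0]

    @property
    def debye_length(self) -> float:
        return 1.0 / self.kappa


@dataclass(frozen=True)
class ParticlePair:
    """Two interacting spheres; for a monodisperse suspension a1 = a2, z1 = z2."""

    a_p1: float  # m
    a_p2: float  # m
    zeta_p1: float  # V, signed
    zeta_p2: float  # V, signed

    def __post_init__(self) -> None:
        if self.a_p1 <= 0 or self.a_p2 <= 0:
            raise ValueError("particle radii must be > 0")

    @classmethod
    def monodisperse(cls, radius: float, zeta: float) -> "ParticlePair":
        return cls(radius, radius, zeta, zeta)


def v_vdw(D, pair: ParticlePair, hamaker: HamakerSpec = HamakerSpec()):
    """Retarded sphere-sphere van der Waals attraction (J).

    -A131 a1 a2 / (6 D (a1+a2)) * [1 - (5.32 D/lam) ln(1 + lam/(5.32 D))].
    Strictly <= 0; recovers the unretarded Hamaker form as D/lam -> 0.
    Accepts scalar or array D (m).
    """
    d = np.asarray(D, dtype=float)
    if np.any(d <= 0):
        raise ValueError("separation D must be > 0")
    lam = hamaker.lambda_c
    geo = pair.a_p1 * pair.a_p2 / (pair.a_p1 + pair.a_p2)
    retard = 1.0 - (5.32 * d / lam) * np.log1p(lam / (5.32 * d))
    out = -hamaker.A_131 * geo / (6.0 * d) * retard
    return out if out.ndim else float(out)


def v_edl(
    D,
    pair: ParticlePair,
    medium: ElectrostaticMedium,
    constants: PhysicalConstants = CONSTANTS,
    method: str = "literal",
):
    """Constant-potential electrical double-layer interaction (J).

    ``method='literal'`` evaluates the general two-sphere expression
        pi eps_r eps_0 a1 a2/(a1+a2) * [ 2 z1 z2 ln((1+e^-kD)/(1-e^-kD))
                                         + (z1^2+z2^2) ln(1-e^-2kD) ];
    ``method='equal'`` uses the algebraically equivalent closed form for
    identical spheres, pi eps_r eps_0 (a/2) z^2 * 4 ln(1+e^-kD), kept as an
    independent cross-check of the literal path.
    """
    d = np.asarray(D, dtype=float)
    if np.any(d <= 0):
        raise ValueError("separation D must be > 0")
    kappa = medium.kappa
    pref = (
        math.pi
        * medium.epsilon_r
        * constants.epsilon_0
        * pair.a_p1
        * pair.a_p2
        / (pair.a_p1 + pair.a_p2)
    )
    ekd = np.exp(-kappa * d)
    if method == "literal":
        z1, z2 = pair.zeta_p1, pair.zeta_p2
        # log1p keeps the bracket accurate deep in the screened tail,
        # where exp(-kappa D) is far below machine epsilon of 1
        bracket = 2.0 * z1 * z2 * (np.log1p(ekd) - np.log1p(-ekd)) + (
            z1 * z1 + z2 * z2
        ) * np.log1p(-(ekd * ekd))
        out = pref * bracket
    elif method == "equal":
        if pair.a_p1 != pair.a_p2 or pair.zeta_p1 != pair.zeta_p2:
            raise ValueError("closed form requires identical particles")
        out = pref * pair.zeta_p1**2 * 4.0 * np.log1p(ekd)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out if np.ndim(out) else float(out)


@dataclass
class InteractionProfile:
    """Energy terms on a separation grid; v_total = v_vdw + v_edl pointwise."""

    separations: np.ndarray  # m
    v_vdw: np.ndarray  # J
    v_edl: np.ndarray  # J
    v_total: np.ndarray  # J
    v_total_kbt: np.ndarray  # dimensionless, at the medium temperature
    temperature: float


def v_total_profile(
    pair: ParticlePair,
    medium: ElectrostaticMedium,
    hamaker: HamakerSpec = HamakerSpec(),
    d_min: float = 1.0e-10,
    d_max: float = 1.0e-7,
    n_points: int = 2000,
    constants: PhysicalConstants = CONSTANTS,
) -> InteractionProfile:
    """Pointwise DLVO profile on a log-spaced separation grid."""
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    d = np.logspace(math.log10(d_min), math.log10(d_max), n_points)
    vdw = v_vdw(d, pair, hamaker)
    edl = v_edl(d, pair, medium, constants)
    total = vdw + edl
    kbt = constants.k_B * medium.temperature
    return InteractionProfile(d, vdw, edl, total, total / kbt, medium.temperature)


def energy_barrier(profile: InteractionProfile) -> tuple[float, float] | None:
    """Barrier height (k_B T) and position (m), or None if no positive maximum.

    The grid maximum is refined by a local quadratic fit through the three
    points around it.
    """
    v = profile.v_total_kbt
    if v.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(v))
    if v[i] <= 0:
        return None
    if 0 < i < v.size - 1:
        # quadratic through the three points around the grid maximum, in
        # log-D to respect the log spacing of the grid
        x = np.log(profile.separations[i - 1 : i + 2])
        a, b, c = np.polyfit(x - x[1], v[i - 1 : i + 2], 2)
        if a < 0:
            xv = -b / (2.0 * a)
            if abs(xv) <= x[2] - x[1]:
                height = a * xv * xv + b * xv + c
                return float(max(height, v[i])), float(math.exp(x[1] + xv))
    return float(v[i]), float(profile.separations[i])


def barrier_vs_ionic_strength(
    pair: ParticlePair,
    hamaker: HamakerSpec,
    temperature: float,
    is_grid,
    epsilon_r: float = 78.5,
    **profile_kwargs,
) -> tuple[list[tuple[float, float | None]], float | None]:
    """Barrier height across an ionic-strength grid (fixed zeta).

    Returns the (I, barrier-height-or-None) list and the first grid I at
    which the barrier has vanished — a fixed-potential proxy for the
    critical coagulation concentration.
    """
    rows: list[tuple[float, float | None]] = []
    ccc_proxy: float | None = None
    for i_s in sorted(is_grid):
        medium = ElectrostaticMedium(i_s, temperature, epsilon_r)
        prof = v_total_profile(pair, medium, hamaker, **profile_kwargs)
        b = energy_barrier(prof)
        height = None if b is None else b[0]
        rows.append((float(i_s), height))
        if height is None and ccc_proxy is None:
            ccc_proxy = float(i_s)
    return rows, ccc_proxy
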