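"""Instrument-like synthetic datasets for the four exposure conditions.

Generates NTA size series (logistic growth to a plateau), DLS
zeta-potential series (fast step completed within ~5 min), AAS dissolved-Ag
series (time-stable level) and NTA dilution series with a detection floor.
The scenario defaults are the measured summary values for citrate-coated
AgNPs diluted in DI water or synthetic high-ammonia wastewater (SW), with
or without anammox sludge; logistic rate constants are set so that the
maximum slope r*K/4 matches the measured maximum aggregation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import SizeTimeSeries

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario",
    "gen_size_series",
    "gen_zeta_series",
    "gen_dissolution_series",
    "gen_dilution_series",
    "logistic_size",
    "DEFAULT_TOTAL_AG_MG_L",
    "STOCK_NUMBER_CONC",
    "NTA_DETECTION_FLOOR",
]

DEFAULT_TOTAL_AG_MG_L = 1.68  # mg/L at the 50x working dilution
STOCK_NUMBER_CONC = 8.50e11  # particles/mL of the synthesized stock
NTA_DETECTION_FLOOR = 1.0e8  # particles/mL, ~10 particles on screen


@dataclass(frozen=True)
class ScenarioSpec:
    """Generator parameters for one exposure condition."""

    label: str
    d0: float = 21.5  # nm, initial hydrodynamic diameter
    d_plateau: float = 21.5  # nm, plateau diameter
    rate_const: float = 0.0  # 1/min, logistic rate
    zeta_initial: float = -37.4  # mV
    zeta_final: float = -37.4  # mV
    zeta_step_time: float = 5.0  # min
    dissolved_level: float = 4.3  # ug/L
    suspended_percent: float = 90.0  # % of particles still suspended at end
    noise_sd_size: float = 5.0  # nm
    noise_sd_zeta: float = 1.0  # mV
    noise_sd_dissolved: float = 5.0  # ug/L
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_plateau >= self.d0 > 0:
            raise ValueError("require d_plateau >= d0 > 0")
        if self.zeta_step_time < 0:
            raise ValueError("zeta_step_time must be >= 0")


#: Measured endpoints per condition: plateau size, max rate (via r = 4k/K),
#: zeta step, stable dissolved level, and final suspended share.
SCENARIOS: dict[str, ScenarioSpec] = {
    "DI": ScenarioSpec(
        label="DI",
        dissolved_level=4.3,
        suspended_percent=90.0,
    ),
    "SW": ScenarioSpec(
        label="SW",
        d_plateau=388.8,
        rate_const=4.0 * 15.43 / 388.8,
        zeta_final=-18.4,
        dissolved_level=156.7,
        suspended_percent=10.7,
    ),
    "DI+sludge": ScenarioSpec(
        label="DI+sludge",
        d_plateau=220.1,
        rate_const=4.0 * 5.0 / 220.1,
        zeta_final=-42.0,
        dissolved_level=30.0,
        suspended_percent=60.0,
    ),
    "SW+sludge": ScenarioSpec(
        label="SW+sludge",
        d_plateau=313.4,
        rate_const=4.0 * 12.8 / 313.4,
        zeta_final=-22.2,
        dissolved_level=577.5,
        suspended_percent=20.0,
    ),
}


def scenario(label: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """A preset scenario with a chosen seed and optional field overrides."""
    try:
        spec = SCENARIOS[label]
    except KeyError:
        raise ValueError(
            f"unknown scenario {label!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return replace(spec, seed=seed, **overrides)


def logistic_size(spec: ScenarioSpec, times: np.ndarray) -> np.ndarray:
    """Noise-free logistic growth D(t) = K / (1 + ((K-d0)/d0) e^(-r t))."""
    t = np.asarray(times, dtype=float)
    if spec.d_plateau == spec.d0 or spec.rate_const == 0.0:
        return np.full_like(t, spec.d0)
    ratio = (spec.d_plateau - spec.d0) / spec.d0
    return spec.d_plateau / (1.0 + ratio * np.exp(-spec.rate_const * t))


def gen_size_series(spec: ScenarioSpec, times) -> SizeTimeSeries:
    """NTA mean-size time series: logistic growth plus iid Gaussian noise."""
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(spec.seed)
    sizes = logistic_size(spec, t) + rng.normal(0.0, 1.0, t.size) * spec.noise_sd_size
    # sizes are physical diameters; the noise floor keeps them positive
    return SizeTimeSeries(t, np.maximum(sizes, 1e-3))


def gen_zeta_series(spec: ScenarioSpec, times) -> np.ndarray:
    """DLS zeta series (mV): linear ramp completed by zeta_step_time, then flat."""
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(spec.seed + 1)
    if spec.zeta_step_time == 0:
        clean = np.full_like(t, spec.zeta_final)
    else:
        frac = np.clip(t / spec.zeta_step_time, 0.0, 1.0)
        clean = spec.zeta_initial + (spec.zeta_final - spec.zeta_initial) * frac
    return clean + rng.normal(0.0, 1.0, t.size) * spec.noise_sd_zeta


def gen_dissolution_series(spec: ScenarioSpec, times) -> np.ndarray:
    """AAS dissolved-Ag series (ug/L): stable level plus noise, floored at 0."""
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(spec.seed + 2)
    out = spec.dissolved_level + rng.normal(0.0, 1.0, t.size) * spec.noise_sd_dissolved
    return np.maximum(out, 0.0)


def gen_dilution_series(
    mode: str,
    start_conc: float = STOCK_NUMBER_CONC,
    factors=(1, 10, 20, 50, 100, 500),
    detection_floor: float = NTA_DETECTION_FLOOR,
    beta: float = 1.5,
) -> list[tuple[float, float, bool]]:
    """(factor, measured concentration, censored) for an NTA dilution series.

    ``linear`` mode divides the stock by the dilution factor (conservative
    dilution); ``exponential`` mode decays as factor^-beta with beta > 1
    (dilution compounded by aggregation/settling losses). Readings below
    the detection floor are clamped to it and flagged censored.
    """
    if mode not in ("linear", "exponential"):
        raise ValueError(f"unknown dilution mode {mode!r}")
    if beta <= 1:
        raise ValueError("exponential mode requires beta > 1")
    rows = []
    for f in factors:
        if f < 1:
            raise ValueError("dilution factors must be >= 1")
        conc = start_conc / f if mode == "linear" else start_conc * f ** (-beta)
        censored = conc < detection_floor
        rows.append((float(f), float(max(conc, detection_floor)), censored))
    return rows
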