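"""Suspended / dissolved / settled partition of total silver.

Dissolved Ag comes from AAS on the supernatant after an isolation spin;
the suspended fraction from the NTA number concentration relative to a
control; settlement (sedimentation plus container adsorption, not
distinguished) closes the balance to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MassBalanceRecord",
    "dissolution_percent",
    "suspended_fraction",
    "close_balance",
    "ug_per_l_to_mg_per_l",
    "mg_per_l_to_ug_per_l",
]

CLOSURE_TOL = 0.5  # percentage points


def ug_per_l_to_mg_per_l(x: float) -> float:
    return x / 1000.0


def mg_per_l_to_ug_per_l(x: float) -> float:
    return x * 1000.0


@dataclass(frozen=True)
class MassBalanceRecord:
    """One condition's partition; fractions are percent of total Ag."""

    total_ag: float  # mg/L
    dissolved_ag: float  # ug/L
    suspended_fraction: float  # %
    dissolved_fraction: float  # %
    settled_fraction: float  # %

    def __post_init__(self) -> None:
        for name in ("suspended_fraction", "dissolved_fraction", "settled_fraction"):
            v = getattr(self, name)
            if not -CLOSURE_TOL <= v <= 100.0 + CLOSURE_TOL:
                raise ValueError(f"{name} = {v} outside [0, 100]")
        s = self.suspended_fraction + self.dissolved_fraction + self.settled_fraction
        if abs(s - 100.0) > CLOSURE_TOL:
            raise ValueError(f"fractions sum to {s}, not 100 +/- {CLOSURE_TOL}")


def dissolution_percent(dissolved_ag: float, total_ag: float) -> float:
    """Dissolved share of the nanoparticle dose: 100 * (ug/L) / (1000 * mg/L).

    Returned unrounded; display formatting rounds to 1 decimal.
    """
    if total_ag <= 0:
        raise ValueError("total Ag must be > 0")
    if dissolved_ag < 0:
        raise ValueError("dissolved Ag must be >= 0")
    if dissolved_ag > mg_per_l_to_ug_per_l(total_ag):
        raise ValueError("dissolved Ag exceeds the total Ag dose")
    return 100.0 * dissolved_ag / mg_per_l_to_ug_per_l(total_ag)


def suspended_fraction(sample_number_conc: float, control_number_conc: float) -> float:
    """Percent of particles still NTA-measurable relative to the control, capped at 100."""
    if control_number_conc <= 0:
        raise ValueError("control number concentration must be > 0")
    if sample_number_conc < 0:
        raise ValueError("sample number concentration must be >= 0")
    return min(100.0, 100.0 * sample_number_conc / control_number_conc)


def close_balance(
    total_ag: float, dissolved_ag: float, suspended_fraction: float
) -> MassBalanceRecord:
    """Close the partition: settled = 100 - suspended - dissolved%.

    Raises if the implied settled fraction is negative beyond the closure
    tolerance (physically impossible inputs).
    """
    diss = dissolution_percent(dissolved_ag, total_ag)
    settled = 100.0 - suspended_fraction - diss
    if settled < -CLOSURE_TOL:
        raise ValueError(
            f"suspended ({suspended_fraction}%) + dissolved ({diss:.2f}%) exceed 100%"
        )
    return MassBalanceRecord(
        total_ag=total_ag,
        dissolved_ag=dissolved_ag,
        suspended_fraction=suspended_fraction,
        dissolved_fraction=diss,
        settled_fraction=max(settled, 0.0) if settled > -CLOSURE_TOL else settled,
    )
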