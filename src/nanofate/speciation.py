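"""Aqueous chemical-equilibrium speciation by the tableau method.

An equilibrium problem is posed as a set of *components* (conserved totals:
Na+, Cl-, NH4+, CO3^2-, ...) and *species* formed from them by mass-action
laws with base-10 formation constants referenced to zero ionic strength.
The proton is a component with fixed activity (pH is measured, not
predicted), so no proton balance is solved. Free-ion activity coefficients
come from the Davies equation; the ionic strength may be solved
self-consistently or fixed to a measured value.

The solver is a damped Newton iteration on the log10 free concentrations of
the non-fixed components, wrapped in an outer fixed-point loop over the
activity coefficients. Mineral precipitation is not modelled: measured
dissolved totals are speciated as-is.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Component",
    "SpeciesDef",
    "SpeciationProblem",
    "SpeciationResult",
    "SpeciationError",
    "ConvergenceError",
    "HumicSiteModel",
    "ionic_strength",
    "davies_log_gamma",
    "solve_equilibrium",
    "percent_distribution",
    "speciate_dissolved_silver",
    "bind_humic",
    "load_thermo_db",
    "default_thermo_db",
    "thermo_db_checksum",
    "load_recipe",
    "sw_problem",
    "AG_MOLAR_MASS",
]

AG_MOLAR_MASS = 107.8682  # g/mol

#: Convergence settings for the Newton solve (relative mass-balance residual)
#: and the outer activity-coefficient fixed point.
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 200
NEWTON_MAX_STEP = 1.0  # log10 units per update
ACTIVITY_LOOP_MAX = 50
ACTIVITY_LOOP_TOL = 1e-10
CONC_FLOOR = 1e-20  # mol/L floor for initial guesses


class SpeciationError(ValueError):
    """Raised for ill-posed speciation inputs."""


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails; carries the last residuals."""

    def __init__(self, message: str, residuals: Mapping[str, float] | None = None):
        super().__init__(message)
        self.residuals = dict(residuals or {})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """A conserved chemical building block with a total concentration.

    ``fixed_log_activity`` marks a component whose free activity is imposed
    rather than solved (the proton at fixed pH); its mass balance is then
    not enforced.
    """

    name: str
    charge: int
    total_conc: float = 0.0  # mol/L
    fixed_log_activity: float | None = None

    def __post_init__(self) -> None:
        if self.fixed_log_activity is None and self.total_conc < 0:
            raise SpeciationError(
                f"component {self.name!r}: total_conc must be >= 0, got {self.total_conc}"
            )


@dataclass(frozen=True)
class SpeciesDef:
    """A dissolved species defined by component stoichiometry.

    ``log_k`` is the base-10 formation constant at 25 degC and zero ionic
    strength for: species = sum(stoich[c] * component c), written in
    activities. ``kind`` distinguishes free ions, ordinary complexes and
    humic-bound species (the last are excluded from some reports).
    """

    name: str
    stoichiometry: Mapping[str, int]
    log_k: float
    charge: int
    kind: str = "complex"  # free | complex | ha_bound

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_k):
            raise SpeciationError(f"species {self.name!r}: log_k must be finite")

    def check_charge(self, components: Mapping[str, Component]) -> bool:
        """True iff charge equals the stoichiometry-weighted component charges."""
        s = sum(
            coeff * components[comp].charge
            for comp, coeff in self.stoichiometry.items()
        )
        return s == self.charge


@dataclass(frozen=True)
class SpeciationProblem:
    """A complete equilibrium problem: components, species, pH, T, activity model."""

    components: tuple[Component, ...]
    species: tuple[SpeciesDef, ...]
    pH: float
    temperature: float = 298.15  # K
    activity_model: str = "davies"  # davies | none
    ionic_strength: float | None = None  # mol/L; None = self-consistent

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise SpeciationError("component names must be unique")
        if not 0.0 <= self.pH <= 14.0:
            raise SpeciationError(f"pH must lie in [0, 14], got {self.pH}")
        if self.activity_model not in ("davies", "none"):
            raise SpeciationError(f"unknown activity model {self.activity_model!r}")
        declared = set(names) | {"H"}
        for sp in self.species:
            missing = set(sp.stoichiometry) - declared
            if missing:
                raise SpeciationError(
                    f"species {sp.name!r} references undeclared components {sorted(missing)}"
                )

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise SpeciationError(f"unknown component {name!r}")

    def with_component(
        self, comp: Component, extra_species: Iterable[SpeciesDef] = ()
    ) -> "SpeciationProblem":
        """A new problem with one more component (replacing any same-named one)."""
        comps = tuple(c for c in self.components if c.name != comp.name) + (comp,)
        existing = {s.name for s in self.species}
        species = self.species + tuple(
            s for s in extra_species if s.name not in existing
        )
        return replace(self, components=comps, species=species)


@dataclass
class SpeciationResult:
    """Solved equilibrium state.

    ``residuals`` are relative mass-balance errors per non-fixed component;
    ``gamma`` maps |charge| -> activity coefficient at the solved (or
    imposed) ionic strength.
    """

    problem: SpeciationProblem
    free_conc: dict[str, float]  # component -> mol/L (free form)
    species_conc: dict[str, float]  # species -> mol/L
    gamma: dict[int, float]
    ionic_strength: float
    residuals: dict[str, float]
    converged: bool
    iterations: int = 0

    def total_recovered(self, component: str) -> float:
        """Component total recomputed from the solved species."""
        t = self.free_conc.get(component, 0.0)
        for sp in self.problem.species:
            coeff = sp.stoichiometry.get(component, 0)
            if coeff:
                t += coeff * self.species_conc[sp.name]
        return t


# ---------------------------------------------------------------------------
# Activity model
# ---------------------------------------------------------------------------


def ionic_strength(
    concentrations: Mapping[str, float], charges: Mapping[str, int]
) -> float:
    """I = 1/2 * sum(c_i * z_i^2) in mol/L.

    Raises on negative concentrations; species absent from ``charges`` are an
    error only if they carry concentration.
    """
    total = 0.0
    for name, conc in concentrations.items():
        if conc < 0:
            raise SpeciationError(f"negative concentration for {name!r}: {conc}")
        z = charges.get(name)
        if z is None:
            raise SpeciationError(f"no charge given for species {name!r}")
        total += conc * z * z
    return 0.5 * total


def _debye_huckel_A(temperature: float) -> float:
    # A = 1.8248e6 / (eps_r * T)^1.5 with the Malmberg-Maryott dielectric fit
    # (unit water density); gives 0.511 at 25 degC.
    t_c = temperature - 273.15
    eps = 87.740 - 0.40008 * t_c + 9.398e-4 * t_c**2 - 1.410e-6 * t_c**3
    return 1.824829238e6 / (eps * temperature) ** 1.5


def davies_log_gamma(
    charge: int, ionic_strength: float, temperature: float = 298.15
) -> float:
    """Davies equation: log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)."""
    if ionic_strength < 0:
        raise SpeciationError(f"ionic strength must be >= 0, got {ionic_strength}")
    if charge == 0 or ionic_strength == 0:
        return 0.0
    a = _debye_huckel_A(temperature)
    sqrt_i = math.sqrt(ionic_strength)
    return -a * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------


def _gamma_table(
    charges: Iterable[int], i_s: float, temperature: float, model: str
) -> dict[int, float]:
    zs = {abs(z) for z in charges}
    if model == "none" or i_s == 0.0:
        return {z: 1.0 for z in zs}
    return {z: 10.0 ** davies_log_gamma(z, i_s, temperature) for z in zs}


def _solve_at_gamma(
    problem: SpeciationProblem,
    gamma: dict[int, float],
    x0: np.ndarray | None = None,
):
    """Inner Newton solve at fixed activity coefficients.

    Unknowns are log10 free concentrations of the non-fixed components.
    Returns (x, species_conc_array, residual_map, n_iter, converged).
    """
    comps = problem.components
    free_idx = [i for i, c in enumerate(comps) if c.fixed_log_activity is None]
    fixed_log_act = {"H": -problem.pH}
    for c in comps:
        if c.fixed_log_activity is not None:
            fixed_log_act[c.name] = c.fixed_log_activity

    species = problem.species
    n_sp = len(species)
    n_x = len(free_idx)
    names = [comps[i].name for i in free_idx]
    totals = np.array([comps[i].total_conc for i in free_idx])

    # Structural check: a positive total needs at least one species or its
    # own free form to carry it (the free form always exists, so only a
    # fully-fixed system can be structurally impossible here).
    if n_x == 0:
        conc = np.empty(n_sp)
        for s_i, sp in enumerate(species):
            log_c = sp.log_k - math.log10(gamma[abs(sp.charge)])
            for comp, coeff in sp.stoichiometry.items():
                log_c += coeff * fixed_log_act[comp]
            conc[s_i] = 10.0**log_c
        return np.empty(0), conc, {}, 0, True

    # stoichiometry matrices: nu[s, j] over unknowns; fixed contribution per species
    nu = np.zeros((n_sp, n_x))
    log_k_eff = np.empty(n_sp)
    for s_i, sp in enumerate(species):
        lk = sp.log_k - math.log10(gamma[abs(sp.charge)])
        for comp, coeff in sp.stoichiometry.items():
            if comp in fixed_log_act:
                lk += coeff * fixed_log_act[comp]
            else:
                j = names.index(comp)
                nu[s_i, j] = coeff
                # activity of free component = gamma * conc
                lk += coeff * math.log10(gamma[abs(comps[free_idx[j]].charge)])
        log_k_eff[s_i] = lk

    if x0 is None:
        x = np.log10(np.maximum(totals, CONC_FLOOR))
    else:
        x = x0.copy()

    scale = np.maximum(totals, CONC_FLOOR)
    ln10 = math.log(10.0)
    converged = False
    n_iter = 0
    for n_iter in range(1, NEWTON_MAX_ITER + 1):
        log_c_sp = log_k_eff + nu @ x
        np.clip(log_c_sp, -300, 300, out=log_c_sp)
        c_sp = 10.0**log_c_sp
        c_free = 10.0**x
        recovered = c_free + nu.T @ c_sp
        resid = (recovered - totals) / scale
        if np.max(np.abs(resid)) < NEWTON_TOL:
            converged = True
            break
        # J[j,k] = d recovered_j / d x_k = ln10 * (delta_jk c_j + sum_s nu_sj nu_sk c_s)
        jac = ln10 * (np.diag(c_free) + nu.T @ (c_sp[:, None] * nu))
        try:
            step = np.linalg.solve(jac, -(recovered - totals))
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(jac, -(recovered - totals), rcond=None)[0]
        np.clip(step, -NEWTON_MAX_STEP, NEWTON_MAX_STEP, out=step)
        x = x + step

    log_c_sp = log_k_eff + nu @ x
    np.clip(log_c_sp, -300, 300, out=log_c_sp)
    c_sp = 10.0**log_c_sp
    c_free = 10.0**x
    recovered = c_free + nu.T @ c_sp
    resid_map = {
        name: float(abs(r) ) for name, r in zip(names, (recovered - totals) / scale)
    }
    return x, c_sp, resid_map, n_iter, converged


def solve_equilibrium(problem: SpeciationProblem) -> SpeciationResult:
    """Solve the equilibrium problem.

    Mass-action laws hold in activities for every species; mass balance is
    enforced to a relative tolerance of ``NEWTON_TOL`` for every non-fixed
    component. With ``activity_model='davies'`` and no imposed ionic
    strength, the activity coefficients are iterated to consistency with
    the solved ionic strength.
    """
    if not problem.components:
        raise SpeciationError("problem must declare at least one component")
    comps = {c.name: c for c in problem.components}
    for c in problem.components:
        if c.fixed_log_activity is not None or c.total_conc == 0:
            continue
        # structurally fine: the free form always carries mass

    charges = [c.charge for c in problem.components] + [
        s.charge for s in problem.species
    ]
    i_s = problem.ionic_strength if problem.ionic_strength is not None else 0.0
    self_consistent = (
        problem.ionic_strength is None and problem.activity_model == "davies"
    )

    x = None
    gamma = _gamma_table(charges, i_s, problem.temperature, problem.activity_model)
    result = None
    for outer in range(ACTIVITY_LOOP_MAX):
        x, c_sp, resid_map, n_iter, converged = _solve_at_gamma(problem, gamma, x)
        if not converged:
            raise ConvergenceError(
                f"Newton iteration did not converge within {NEWTON_MAX_ITER} steps",
                resid_map,
            )
        free_names = [
            c.name for c in problem.components if c.fixed_log_activity is None
        ]
        free_conc = {n: float(10.0**v) for n, v in zip(free_names, x)}
        for c in problem.components:
            if c.fixed_log_activity is not None:
                z = abs(c.charge)
                free_conc[c.name] = float(
                    10.0**c.fixed_log_activity / gamma.get(z, 1.0)
                )
        all_conc = dict(free_conc)
        all_charges = {c.name: c.charge for c in problem.components}
        for sp, cv in zip(problem.species, c_sp):
            all_conc[sp.name] = float(cv)
            all_charges[sp.name] = sp.charge
        # proton/hydroxide contribute negligibly at circumneutral pH but are included
        i_new = ionic_strength(all_conc, all_charges)
        result = SpeciationResult(
            problem=problem,
            free_conc=free_conc,
            species_conc={sp.name: float(cv) for sp, cv in zip(problem.species, c_sp)},
            gamma=dict(gamma),
            ionic_strength=float(i_new if self_consistent else i_s),
            residuals=resid_map,
            converged=True,
            iterations=n_iter,
        )
        if not self_consistent:
            return result
        if abs(i_new - i_s) <= ACTIVITY_LOOP_TOL * max(i_new, 1e-30):
            return result
        i_s = i_new
        gamma = _gamma_table(
            charges, i_s, problem.temperature, problem.activity_model
        )
    raise ConvergenceError(
        f"activity-coefficient loop did not converge within {ACTIVITY_LOOP_MAX} rounds",
        result.residuals if result else None,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def percent_distribution(
    result: SpeciationResult, component: str
) -> list[tuple[str, float]]:
    """Ranked (species, % of component total) including the free form.

    Percentages are mole-fraction based: 100 * stoich * species_conc / total.
    """
    if not result.converged:
        raise SpeciationError("result did not converge; no distribution available")
    comp = result.problem.component(component)
    total = comp.total_conc
    if comp.fixed_log_activity is not None or total <= 0:
        raise SpeciationError(
            f"component {component!r} has no positive solved total to distribute"
        )
    entries = [(component, 100.0 * result.free_conc[component] / total)]
    for sp in result.problem.species:
        coeff = sp.stoichiometry.get(component, 0)
        if coeff:
            entries.append(
                (sp.name, 100.0 * coeff * result.species_conc[sp.name] / total)
            )
    entries.sort(key=lambda kv: kv[1], reverse=True)
    return entries


def speciate_dissolved_silver(
    medium: SpeciationProblem,
    total_dissolved_ag: float,
    db: Sequence[SpeciesDef] | None = None,
) -> list[tuple[str, float]]:
    """Speciate a measured dissolved-Ag total within a medium.

    ``total_dissolved_ag`` is in mol/L. Adds Ag+ as a component, enables the
    Ag species from the database that the medium's components support
    (chloro, ammine, hydroxo, nitrito, sulfato ladders), re-solves and
    returns the ranked percent distribution of silver.
    """
    if total_dissolved_ag <= 0:
        raise SpeciationError("total dissolved Ag must be > 0")
    if db is None:
        db = default_thermo_db()
    declared = {c.name for c in medium.components} | {"H", "Ag"}
    ag_species = [
        sp
        for sp in db
        if sp.stoichiometry.get("Ag", 0) and set(sp.stoichiometry) <= declared
    ]
    prob = medium.with_component(
        Component("Ag", charge=1, total_conc=total_dissolved_ag), ag_species
    )
    res = solve_equilibrium(prob)
    return percent_distribution(res, "Ag")


@dataclass(frozen=True)
class HumicSiteModel:
    """Discrete two-site humic-acid ligand model.

    Site densities are mol of sites per gram of HA; ``log_k_h`` are proton
    association constants (pKa) and ``log_k_ag`` the Ag+ association
    constants for the deprotonated sites. Defaults describe a generic
    carboxylic/phenolic pair and are assumptions, not fitted values.
    """

    site_density_1: float = 4.0e-3  # carboxylic-type, mol/g
    site_density_2: float = 2.0e-3  # phenolic-type, mol/g
    log_k_h_1: float = 4.0
    log_k_h_2: float = 9.5
    log_k_ag_1: float = 5.0
    log_k_ag_2: float = 7.5

    def __post_init__(self) -> None:
        if self.site_density_1 < 0 or self.site_density_2 < 0:
            raise SpeciationError("humic site densities must be >= 0")


def bind_humic(
    medium: SpeciationProblem,
    ha_conc: float,
    site_model: HumicSiteModel | None = None,
) -> SpeciationProblem:
    """Augment a problem with discrete humic-acid binding sites.

    ``ha_conc`` is in mg/L. With ``ha_conc == 0`` the problem is returned
    unchanged. Sites are monoprotic ligands; Ag-site species are tagged
    ``ha_bound``.
    """
    if ha_conc < 0:
        raise SpeciationError("HA concentration must be >= 0")
    if ha_conc == 0:
        return medium
    sm = site_model or HumicSiteModel()
    prob = medium
    if all(c.name != "Ag" for c in prob.components):
        # placeholder silver total so the Ag-site species are well-defined;
        # a later with_component("Ag", ...) supplies the measured total
        prob = prob.with_component(Component("Ag", charge=1, total_conc=0.0))
    for idx, (dens, lk_h, lk_ag) in enumerate(
        [
            (sm.site_density_1, sm.log_k_h_1, sm.log_k_ag_1),
            (sm.site_density_2, sm.log_k_h_2, sm.log_k_ag_2),
        ],
        start=1,
    ):
        name = f"HA{idx}"
        total = dens * ha_conc * 1e-3  # mg/L * mol/g * g/mg
        species = [
            SpeciesDef(f"H-{name}", {name: 1, "H": 1}, lk_h, 0, kind="ha_bound"),
            SpeciesDef(f"Ag-{name}", {name: 1, "Ag": 1}, lk_ag, 0, kind="ha_bound"),
        ]
        prob = prob.with_component(Component(name, charge=-1, total_conc=total), species)
    return prob


# ---------------------------------------------------------------------------
# Database and recipes
# ---------------------------------------------------------------------------

_DATA = importlib.resources.files("nanofate") / "data"


def _parse_stoich(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for pair in text.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        comp, coeff = pair.split(":")
        out[comp.strip()] = int(coeff)
    return out


def load_thermo_db(path: str | Path | None = None) -> list[SpeciesDef]:
    """Load a TSV thermodynamic database.

    Columns: species, charge, log_k, ref_temp_C, stoichiometry (semicolon-
    separated ``component:coeff`` pairs). ``#`` starts a comment.
    """
    if path is None:
        text = (_DATA / "thermo_db.tsv").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    species = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or line.lower().startswith("species\t"):
            continue
        fields = [f.strip() for f in line.split("\t") if f.strip() != ""]
        if len(fields) != 5:
            raise SpeciationError(f"malformed database line: {line!r}")
        name, charge, log_k, _ref_t, stoich = fields
        species.append(
            SpeciesDef(name, _parse_stoich(stoich), float(log_k), int(charge))
        )
    return species


def default_thermo_db() -> list[SpeciesDef]:
    """The shipped MINTEQ-family constant set (25 degC, I = 0)."""
    return load_thermo_db(None)


def thermo_db_checksum(path: str | Path | None = None) -> str:
    """SHA-256 of the database file, recorded in run manifests."""
    if path is None:
        data = (_DATA / "thermo_db.tsv").read_bytes()
    else:
        data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()


def load_recipe(
    path: str | Path | None = None,
    db: Sequence[SpeciesDef] | None = None,
) -> SpeciationProblem:
    """Build a SpeciationProblem from a YAML medium recipe.

    Schema: ``components: {name: {total_mM, charge}}``, ``pH``,
    ``temperature_C``, ``activity_model`` and optional
    ``ionic_strength_mM`` (fixed override). Species are drawn from the
    database, keeping those whose components are all declared.
    """
    if path is None:
        text = (_DATA / "sw_recipe.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    if db is None:
        db = default_thermo_db()
    comps = tuple(
        Component(name, charge=int(spec["charge"]), total_conc=float(spec["total_mM"]) * 1e-3)
        for name, spec in cfg["components"].items()
    )
    declared = {c.name for c in comps} | {"H"}
    species = tuple(sp for sp in db if set(sp.stoichiometry) <= declared)
    i_s = cfg.get("ionic_strength_mM")
    return SpeciationProblem(
        components=comps,
        species=species,
        pH=float(cfg["pH"]),
        temperature=float(cfg.get("temperature_C", 25.0)) + 273.15,
        activity_model=cfg.get("activity_model", "davies"),
        ionic_strength=None if i_s is None else float(i_s) * 1e-3,
    )


def sw_problem(pH: float = 7.7) -> SpeciationProblem:
    """The synthetic high-ammonia wastewater recipe at a chosen fixed pH.

    The shipped recipe carries the measured component totals, Davies
    activities and the measured ionic strength (100 mM) as a fixed
    override; pH 7.7 is the medium without sludge, 8.7 with sludge.
    """
    prob = load_recipe(None)
    return replace(prob, pH=pH)


def micrograms_ag_per_l_to_molar(ug_per_l: float) -> float:
    """µg/L of silver -> mol/L."""
    return ug_per_l * 1e-6 / AG_MOLAR_MASS
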