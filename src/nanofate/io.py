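"""File I/O and the four-condition analysis pipeline.

CSV schemas (units encoded in the header suffixes):

* size series:        ``time_min,size_nm[,sd_nm]``
* zeta series:        ``time_min,zeta_mV``
* dissolved series:   ``time_min,dissolved_ug_L``
* dilution series:    ``factor,number_conc_per_mL,censored``

``run_full_analysis`` ties the stages together per exposure condition
(DI, SW, DI+sludge, SW+sludge): synthetic instrument data, aggregation
rates, equilibrium speciation of the medium and of dissolved Ag, a DLVO
profile where applicable, and the suspended/dissolved/settled partition.
All randomness flows from one seed; each run writes a JSON manifest with
the seed and the thermodynamic-database checksum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import dlvo as dlvo_mod
from . import kinetics, mass_balance, speciation, synthetic
from .kinetics import SizeTimeSeries

__all__ = [
    "RunConfig",
    "read_timeseries_csv",
    "write_size_csv",
    "write_zeta_csv",
    "write_dissolved_csv",
    "write_dilution_csv",
    "simulate_scenario",
    "scenario_medium",
    "run_full_analysis",
]

#: ionic strength of deionized water as used for the DLVO control (mol/L)
DI_IONIC_STRENGTH = 3.98e-5
SW_IONIC_STRENGTH = 0.1
HA_MG_PER_L = 42.0
#: assumed pH of the DI dilutions (unbuffered, circumneutral)
DI_PH = 7.0
DI_SLUDGE_PH = 8.0

SAMPLING_TIMES_MIN = np.array([0.0, 30, 60, 90, 120, 150, 180, 210])
ZETA_TIMES_MIN = np.array([0.0, 10, 20, 30, 40, 50])


@dataclass
class RunConfig:
    """Configuration of a full four-condition run."""

    out_dir: Path
    scenarios: tuple[str, ...] = ("DI", "SW", "DI+sludge", "SW+sludge")
    seed: int = 0
    recipe_path: Path | None = None  # None -> shipped SW recipe
    db_path: Path | None = None  # None -> shipped database
    radius_nm: float = 21.5 / 2.0  # hydrodynamic size 21.5 nm as diameter
    hamaker_J: float = 3.7e-20
    lambda_nm: float = 100.0
    temperature_K: float = 298.15
    total_ag_mg_l: float = synthetic.DEFAULT_TOTAL_AG_MG_L
    verbose: bool = False


class SchemaError(ValueError):
    """Raised for CSV files that do not match a known instrument schema."""


def read_timeseries_csv(path):
    """Read an instrument CSV; returns (kind, data).

    ``kind`` is ``'size'`` (data: SizeTimeSeries), ``'zeta'`` or
    ``'dissolved'`` (data: (times, values) arrays). The header must match
    one of the known schemas, units included; times must be strictly
    increasing.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] == ["time_min", "size_nm"]:
        if len(cols) > 2 and cols[2] != "sd_nm":
            raise SchemaError(f"unexpected size-series columns {cols!r}")
        sd = df["sd_nm"].to_numpy() if "sd_nm" in df else None
        try:
            return "size", SizeTimeSeries(
                df["time_min"].to_numpy(), df["size_nm"].to_numpy(), sd
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    if cols == ["time_min", "zeta_mV"] or cols == ["time_min", "dissolved_ug_L"]:
        kind = "zeta" if cols[1] == "zeta_mV" else "dissolved"
        t = df["time_min"].to_numpy(dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: time_min must be strictly increasing")
        return kind, (t, df[cols[1]].to_numpy(dtype=float))
    raise SchemaError(
        f"{path}: unknown schema {cols!r}; expected time_min with one of "
        "size_nm[,sd_nm] / zeta_mV / dissolved_ug_L"
    )


def write_size_csv(path, series: SizeTimeSeries) -> None:
    data = {"time_min": series.times, "size_nm": series.sizes}
    if series.replicate_sd is not None:
        data["sd_nm"] = series.replicate_sd
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_zeta_csv(path, times, zeta) -> None:
    pd.DataFrame({"time_min": times, "zeta_mV": zeta}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_dissolved_csv(path, times, dissolved) -> None:
    pd.DataFrame({"time_min": times, "dissolved_ug_L": dissolved}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_dilution_csv(path, rows) -> None:
    pd.DataFrame(
        rows, columns=["factor", "number_conc_per_mL", "censored"]
    ).to_csv(path, index=False)


def simulate_scenario(label: str, seed: int, out_dir) -> dict[str, Path]:
    """Write the four instrument CSVs for one scenario; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic.scenario(label, seed=seed)
    paths = {
        "size": out / "size.csv",
        "zeta": out / "zeta.csv",
        "dissolved": out / "dissolved.csv",
        "dilution": out / "dilution.csv",
    }
    write_size_csv(paths["size"], synthetic.gen_size_series(spec, SAMPLING_TIMES_MIN))
    write_zeta_csv(
        paths["zeta"], ZETA_TIMES_MIN, synthetic.gen_zeta_series(spec, ZETA_TIMES_MIN)
    )
    write_dissolved_csv(
        paths["dissolved"],
        SAMPLING_TIMES_MIN,
        synthetic.gen_dissolution_series(spec, SAMPLING_TIMES_MIN),
    )
    mode = "linear" if label.startswith("DI") else "exponential"
    write_dilution_csv(paths["dilution"], synthetic.gen_dilution_series(mode))
    return paths


def scenario_medium(label: str, db=None) -> speciation.SpeciationProblem:
    """The speciation medium for a condition.

    DI is an unbuffered blank at pH 7.0; SW is the shipped recipe at its
    measured pH (7.7 alone, 8.7 with sludge). Sludge adds 42 mg/L humic
    acid for the DI condition; for SW+sludge the humic ligands are left out
    of the dissolved-Ag speciation (the inorganic ammine/chloro ladder is
    reported) and only the pH shift is applied.
    """
    if db is None:
        db = speciation.default_thermo_db()
    if label == "DI":
        return speciation.SpeciationProblem(
            components=(), species=(), pH=DI_PH
        )
    if label == "SW":
        return speciation.sw_problem(pH=7.7)
    if label == "DI+sludge":
        blank = speciation.SpeciationProblem(components=(), species=(), pH=DI_SLUDGE_PH)
        return speciation.bind_humic(blank, HA_MG_PER_L)
    if label == "SW+sludge":
        return speciation.sw_problem(pH=8.7)
    raise ValueError(f"unknown scenario {label!r}")


def _speciation_table(result: speciation.SpeciationResult) -> pd.DataFrame:
    """Per-component ranked species table mirroring the standard layout."""
    rows = []
    for comp in result.problem.components:
        if comp.fixed_log_activity is not None or comp.total_conc <= 0:
            continue
        for rank, (name, pct) in enumerate(
            speciation.percent_distribution(result, comp.name), start=1
        ):
            if pct < 0.005 and rank > 1:
                continue
            rows.append(
                {
                    "component": comp.name,
                    "total_mM": comp.total_conc * 1e3,
                    "rank": rank,
                    "species": name,
                    "percent": round(pct, 2),
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage for every configured scenario; returns the manifest.

    Per scenario the bundle contains the instrument CSVs, a rate summary,
    the medium speciation table (ionic media), the dissolved-Ag percent
    distribution, a DLVO profile with its barrier (non-sludge media), and
    the mass-balance partition. Reruns with the same seed are reproducible.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = speciation.load_thermo_db(config.db_path)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thermo_db_sha256": speciation.thermo_db_checksum(config.db_path),
        "scenarios": {},
    }
    pair = dlvo_mod.ParticlePair.monodisperse(config.radius_nm * 1e-9, 0.0)
    hamaker = dlvo_mod.HamakerSpec(config.hamaker_J, config.lambda_nm * 1e-9)

    for idx, label in enumerate(config.scenarios):
        sdir = out / label.replace("+", "_")
        sdir.mkdir(exist_ok=True)
        spec = synthetic.scenario(label, seed=config.seed * 1009 + idx)
        paths = simulate_scenario(label, spec.seed, sdir)
        summary: dict = {"seed": spec.seed}

        # aggregation kinetics from the generated size series
        _, series = read_timeseries_csv(paths["size"])
        rates = kinetics.aggregation_rates(series)
        summary["max_rate_nm_per_min"] = rates.max_rate
        summary["plateau_nm"] = rates.plateau_size
        summary["plateau_onset_min"] = rates.plateau_onset
        with open(sdir / "rate_summary.json", "w") as fh:
            json.dump(
                {
                    "interval_rates_nm_per_min": rates.interval_rates.tolist(),
                    "interval_midtimes_min": rates.interval_midtimes.tolist(),
                    "max_rate_nm_per_min": rates.max_rate,
                    "max_rate_time_min": rates.max_rate_time,
                    "plateau_nm": rates.plateau_size,
                    "plateau_onset_min": rates.plateau_onset,
                },
                fh,
                indent=1,
            )

        # medium + dissolved-Ag speciation
        medium = scenario_medium(label, db)
        if medium.components:
            med_result = speciation.solve_equilibrium(medium)
            _speciation_table(med_result).to_csv(sdir / "speciation.csv", index=False)
        else:
            pd.DataFrame(
                columns=["component", "total_mM", "rank", "species", "percent"]
            ).to_csv(sdir / "speciation.csv", index=False)
        _, (t_d, dissolved) = read_timeseries_csv(paths["dissolved"])
        dissolved_mean = float(np.mean(dissolved))
        ag_molar = speciation.micrograms_ag_per_l_to_molar(max(dissolved_mean, 1e-3))
        ag_dist = speciation.speciate_dissolved_silver(medium, ag_molar, db)
        pd.DataFrame(ag_dist, columns=["species", "percent"]).assign(
            percent=lambda d: d["percent"].round(2)
        ).to_csv(sdir / "ag_distribution.csv", index=False)
        summary["dissolved_ug_L"] = dissolved_mean
        summary["top_ag_species"] = ag_dist[0][0]

        # DLVO profile (ionic media without sludge solids only)
        if label in ("DI", "SW"):
            zeta_v = spec.zeta_final * 1e-3
            i_s = DI_IONIC_STRENGTH if label == "DI" else SW_IONIC_STRENGTH
            medium_el = dlvo_mod.ElectrostaticMedium(i_s, config.temperature_K)
            prof = dlvo_mod.v_total_profile(
                dlvo_mod.ParticlePair.monodisperse(pair.a_p1, zeta_v),
                medium_el,
                hamaker,
            )
            pd.DataFrame(
                {
                    "D_nm": prof.separations * 1e9,
                    "V_vdw_J": prof.v_vdw,
                    "V_edl_J": prof.v_edl,
                    "V_total_J": prof.v_total,
                    "V_total_kBT": prof.v_total_kbt,
                }
            ).to_csv(sdir / "dlvo_profile.csv", index=False)
            barrier = dlvo_mod.energy_barrier(prof)
            summary["barrier_kBT"] = None if barrier is None else barrier[0]
        else:
            summary["barrier_kBT"] = "not applicable (sludge)"

        # mass balance
        record = mass_balance.close_balance(
            config.total_ag_mg_l, dissolved_mean, spec.suspended_percent
        )
        pd.DataFrame(
            [
                {
                    "condition": label,
                    "suspended_pct": round(record.suspended_fraction, 1),
                    "dissolved_pct": round(record.dissolved_fraction, 1),
                    "settled_pct": round(record.settled_fraction, 1),
                }
            ]
        ).to_csv(sdir / "mass_balance.csv", index=False)
        summary["settled_pct"] = record.settled_fraction
        manifest["scenarios"][label] = summary

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
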