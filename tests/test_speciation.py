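"""Equilibrium speciation: activity model, Newton solver, distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanofate as nf
from nanofate.speciation import (
    Component,
    SpeciationError,
    SpeciesDef,
    SpeciationProblem,
    micrograms_ag_per_l_to_molar,
)

# charges of the components the shipped database is written over
COMPONENT_CHARGES = {
    "H": 1, "NH4": 1, "Na": 1, "K": 1, "Ca": 2, "Mg": 2,
    "Cl": -1, "NO2": -1, "SO4": -2, "CO3": -2, "Ag": 1,
}


def simple_problem(components, species, pH=7.0, **kw):
    return SpeciationProblem(
        components=tuple(components), species=tuple(species), pH=pH, **kw
    )


class TestIonicStrength:
    @pytest.mark.parametrize(
        "conc, charges, expected",
        [
            ({"Na": 0.1, "Cl": 0.1}, {"Na": 1, "Cl": -1}, 0.1),
            ({"Mg": 0.01, "SO4": 0.01}, {"Mg": 2, "SO4": -2}, 0.04),
            ({"X": 0.0, "Y": 0.3}, {"X": 3, "Y": 0}, 0.0),
        ],
    )
    def test_known_values(self, conc, charges, expected):
        assert nf.ionic_strength(conc, charges) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(SpeciationError):
            nf.ionic_strength({"Na": -0.1}, {"Na": 1})

    def test_sw_species_sum_matches_bruteforce(self, sw_result):
        conc = dict(sw_result.free_conc)
        charges = {c.name: c.charge for c in sw_result.problem.components}
        for sp in sw_result.problem.species:
            conc[sp.name] = sw_result.species_conc[sp.name]
            charges[sp.name] = sp.charge
        brute = 0.5 * sum(conc[k] * charges[k] ** 2 for k in conc)
        assert nf.ionic_strength(conc, charges) == pytest.approx(brute, rel=1e-12)


class TestDavies:
    def test_neutral_species_unaffected(self):
        assert nf.davies_log_gamma(0, 0.5) == 0.0

    def test_charge_sign_symmetry(self):
        assert nf.davies_log_gamma(1, 0.1) == nf.davies_log_gamma(-1, 0.1)
        assert nf.davies_log_gamma(2, 0.03) == nf.davies_log_gamma(-2, 0.03)

    def test_hand_evaluation_at_tenth_molar(self):
        # -A (sqrt(.1)/(1+sqrt(.1)) - 0.03) with A ~ 0.51 at 25 degC
        assert nf.davies_log_gamma(1, 0.1, 298.15) == pytest.approx(-0.107, abs=2e-3)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(SpeciationError):
            nf.davies_log_gamma(1, -0.1)


class TestDatabase:
    def test_every_entry_charge_consistent(self, thermo_db):
        comps = {
            name: Component(name, charge=z) for name, z in COMPONENT_CHARGES.items()
        }
        for sp in thermo_db:
            assert sp.check_charge(comps), f"{sp.name} fails the charge balance"

    def test_checksum_is_stable_hex(self):
        c1 = nf.thermo_db_checksum()
        assert c1 == nf.thermo_db_checksum() and len(c1) == 64


class TestSolver:
    def test_identity_system_free_equals_total(self):
        prob = simple_problem([Component("Na", 1, 0.01)], [], activity_model="none")
        res = nf.solve_equilibrium(prob)
        assert res.free_conc["Na"] == pytest.approx(0.01, rel=1e-10)
        assert res.converged

    def test_monoprotic_acid_half_equivalence(self):
        # HA formation constant equal to 10^pH puts the acid at its pKa:
        # exact 50/50 split of a 1 mM total
        acid = SpeciesDef("HA", {"A": 1, "H": 1}, log_k=7.0, charge=0)
        prob = simple_problem(
            [Component("A", -1, 1e-3)], [acid], pH=7.0, activity_model="none"
        )
        res = nf.solve_equilibrium(prob)
        assert res.free_conc["A"] == pytest.approx(5e-4, rel=1e-8)
        assert res.species_conc["HA"] == pytest.approx(5e-4, rel=1e-8)

    def test_mass_balance_closes_on_sw(self, sw_result):
        for comp in sw_result.problem.components:
            if comp.fixed_log_activity is not None or comp.total_conc == 0:
                continue
            recovered = sw_result.total_recovered(comp.name)
            assert recovered == pytest.approx(comp.total_conc, rel=1e-6)
        assert max(sw_result.residuals.values()) < 1e-6

    def test_empty_problem_rejected(self):
        with pytest.raises(SpeciationError):
            nf.solve_equilibrium(
                SpeciationProblem(components=(), species=(), pH=7.0)
            )

    def test_undeclared_component_in_species_rejected(self):
        with pytest.raises(SpeciationError):
            simple_problem(
                [Component("Na", 1, 0.01)],
                [SpeciesDef("NaX", {"Na": 1, "X": 1}, 1.0, 0)],
            )

    def test_activity_model_vanishes_at_infinite_dilution(self):
        # Davies and ideal solutions must coincide as I -> 0
        comps = [Component("M", 2, 1e-9), Component("L", -1, 2e-9)]
        species = [
            SpeciesDef("ML", {"M": 1, "L": 1}, 3.0, 1),
            SpeciesDef("ML2", {"M": 1, "L": 2}, 5.0, 0),
        ]
        ideal = nf.solve_equilibrium(
            simple_problem(comps, species, activity_model="none")
        )
        davies = nf.solve_equilibrium(
            simple_problem(comps, species, activity_model="davies")
        )
        for key in ("M", "L"):
            assert davies.free_conc[key] == pytest.approx(
                ideal.free_conc[key], rel=1e-4
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        log_k1=st.floats(-2, 6),
        log_k2=st.floats(-2, 6),
        t_m=st.floats(1e-6, 0.3),
        t_l=st.floats(1e-6, 0.3),
    )
    def test_newton_matches_bisection_oracle(self, log_k1, log_k2, t_m, t_l):
        """Two components, ML and ML2: Newton vs brute-force 1-D bisection."""
        k1, k2 = 10.0**log_k1, 10.0**log_k2
        species = [
            SpeciesDef("ML", {"M": 1, "L": 1}, log_k1, 1),
            SpeciesDef("ML2", {"M": 1, "L": 2}, log_k1 + log_k2, 0),
        ]
        prob = simple_problem(
            [Component("M", 2, t_m), Component("L", -1, t_l)],
            species,
            activity_model="none",
        )
        res = nf.solve_equilibrium(prob)

        def l_residual(l_free):
            m_free = t_m / (1.0 + k1 * l_free + k1 * k2 * l_free**2)
            ml = k1 * m_free * l_free
            return l_free + ml + 2.0 * k1 * k2 * m_free * l_free**2 - t_l

        lo, hi = 0.0, t_l
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if l_residual(mid) > 0:
                hi = mid
            else:
                lo = mid
        l_free = 0.5 * (lo + hi)
        m_free = t_m / (1.0 + k1 * l_free + k1 * k2 * l_free**2)
        assert res.free_conc["L"] == pytest.approx(l_free, rel=1e-8)
        assert res.free_conc["M"] == pytest.approx(m_free, rel=1e-8)


class TestDistributions:
    def test_identity_distribution_is_single_100(self):
        prob = simple_problem([Component("Na", 1, 0.01)], [], activity_model="none")
        res = nf.solve_equilibrium(prob)
        assert nf.percent_distribution(res, "Na") == [("Na", pytest.approx(100.0))]

    def test_distribution_sums_to_100(self, sw_result):
        for comp in ("NH4", "Cl", "SO4", "CO3", "Mg", "Na", "K"):
            total = sum(p for _, p in nf.percent_distribution(sw_result, comp))
            assert total == pytest.approx(100.0, abs=0.1)

    def test_unknown_component_rejected(self, sw_result):
        with pytest.raises(SpeciationError):
            nf.percent_distribution(sw_result, "Xe")

    def test_symmetric_ladder_splits_evenly(self):
        # AH and AH2 with log K2 = log K1 + pH are forced equal; a large K1
        # leaves the free form negligible, so each carries ~50%
        species = [
            SpeciesDef("AH", {"A": 1, "H": 1}, 10.0, 0),
            SpeciesDef("AH2", {"A": 1, "H": 2}, 17.0, 1),
        ]
        prob = simple_problem(
            [Component("A", -1, 1e-3)], species, pH=7.0, activity_model="none"
        )
        dist = dict(nf.percent_distribution(nf.solve_equilibrium(prob), "A"))
        assert dist["AH"] == pytest.approx(dist["AH2"], rel=1e-10)
        assert dist["AH"] == pytest.approx(50.0, abs=0.1)

    def test_ph_77_not_87_reproduces_ammonium_split(self, sw_result):
        """The printed NH4+/NH3 split needs pH 7.7; at 8.7 free NH4+ falls below 90%."""
        nh4_77 = dict(nf.percent_distribution(sw_result, "NH4"))["NH4"]
        assert nh4_77 == pytest.approx(96.85, abs=3.0)
        res_87 = nf.solve_equilibrium(nf.sw_problem(pH=8.7))
        nh4_87 = dict(nf.percent_distribution(res_87, "NH4"))["NH4"]
        assert nh4_87 < 90.0


class TestDissolvedSilver:
    def test_unit_conversion(self):
        assert micrograms_ag_per_l_to_molar(107.8682) == pytest.approx(1e-6)

    def test_no_ligands_all_free(self):
        medium = simple_problem([Component("Na", 1, 1e-3)], [], pH=7.0)
        dist = nf.speciate_dissolved_silver(medium, 1e-6)
        assert dist[0][0] == "Ag"
        assert dist[0][1] == pytest.approx(100.0, abs=0.01)

    def test_chloride_ladder_ratio_independent_of_total(self):
        """AgCl2-:AgCl(aq) is set by the chloride activity alone in the
        dilute regime; three decades of total Ag must not move it."""
        medium = nf.sw_problem(pH=7.7)
        ratios = []
        for ug_l in (0.1567, 1.567, 15.67, 156.7):
            dist = dict(
                nf.speciate_dissolved_silver(
                    medium, micrograms_ag_per_l_to_molar(ug_l)
                )
            )
            ratios.append(dist["AgCl2-"] / dist["AgCl(aq)"])
        # dilute regime: silver consumes a negligible share of the chloride,
        # so the ladder ratio is pinned by the chloride activity alone
        assert np.ptp(ratios) / ratios[0] < 1e-3

    def test_nonpositive_total_rejected(self):
        with pytest.raises(SpeciationError):
            nf.speciate_dissolved_silver(nf.sw_problem(), 0.0)


class TestHumicBinding:
    def test_zero_ha_is_identity(self):
        prob = nf.sw_problem()
        assert nf.bind_humic(prob, 0.0) is prob

    def test_negative_site_density_rejected(self):
        with pytest.raises(SpeciationError):
            nf.HumicSiteModel(site_density_1=-1e-3)

    def test_di_water_with_ha_binds_most_silver(self):
        blank = SpeciationProblem(components=(), species=(), pH=8.0)
        medium = nf.bind_humic(blank, 42.0)
        dist = dict(
            nf.speciate_dissolved_silver(medium, micrograms_ag_per_l_to_molar(30.0))
        )
        bound = dist.get("Ag-HA1", 0.0) + dist.get("Ag-HA2", 0.0)
        assert bound > 90.0

    def test_ligand_excess_limit_binds_everything(self):
        blank = SpeciationProblem(components=(), species=(), pH=7.0)
        model = nf.HumicSiteModel(
            site_density_1=1e-2, site_density_2=0.0, log_k_h_1=2.0, log_k_ag_1=12.0
        )
        medium = nf.bind_humic(blank, 100.0, model)
        dist = dict(nf.speciate_dissolved_silver(medium, 1e-8))
        assert dist["Ag-HA1"] == pytest.approx(100.0, abs=1e-3)


class TestRecipeIO:
    def test_shipped_recipe_matches_measured_totals(self):
        prob = nf.load_recipe()
        totals = {c.name: c.total_conc for c in prob.components}
        assert totals["NH4"] == pytest.approx(18.10e-3)
        assert totals["Cl"] == pytest.approx(18.50e-3)
        assert prob.pH == 7.7
        assert prob.ionic_strength == pytest.approx(0.1)

    def test_custom_recipe_roundtrip(self, tmp_path):
        path = tmp_path / "medium.yaml"
        path.write_text(
            "components:\n  Na: {total_mM: 10.0, charge: 1}\n"
            "  Cl: {total_mM: 10.0, charge: -1}\npH: 6.5\ntemperature_C: 25\n"
        )
        prob = nf.load_recipe(path)
        assert prob.pH == 6.5 and prob.ionic_strength is None
        res = nf.solve_equilibrium(prob)
        assert res.free_conc["Na"] == pytest.approx(
            0.01 - res.species_conc["NaCl(aq)"], rel=1e-9
        )

    def test_malformed_db_line_rejected(self, tmp_path):
        bad = tmp_path / "db.tsv"
        bad.write_text("species\tcharge\tlog_k\nOH-\t-1\t-14\n")
        with pytest.raises(SpeciationError):
            nf.load_thermo_db(bad)
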