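# Methods

## Chemical-equilibrium speciation

### Model

A medium is posed in tableau form: components `c` with conserved analytical
totals `T_c`, and species `s` defined by integer stoichiometries `ν_sc` and
base-10 formation constants `log K_s` (25 °C, zero ionic strength), so that
in activities

log a_s = log K_s + Σ_c ν_sc · log a_c.

The proton is a fixed-activity component: pH is a measured input, its
activity is pinned at 10^−pH and no proton balance is solved. Water has
unit activity and is left implicit; hydroxide and hydrolysis species are
written with negative proton coefficients (e.g. NH₃ = NH₄⁺ − H⁺). This is
the appropriate formulation for reproducing speciation at a measured pH;
the package does not predict pH (nor redox, nor mineral precipitation —
dissolved totals are speciated exactly as measured, so a supersaturated
AgCl(s) would simply appear as a large chloro-complex load, never as a
removed solid).

Free-ion activity coefficients follow the Davies equation,
log₁₀ γ = −A z² (√I/(1+√I) − 0.3·I), with the Debye–Hückel slope
A = 1.8248×10⁶/(ε_r T)^1.5 evaluated with the Malmberg–Maryott dielectric
fit at unit water density (A ≈ 0.511 at 25 °C). Neutral species have γ = 1.
The Davies form is adequate to I ≈ 0.5 M, comfortably covering the 100 mM
wastewater.

### Solver

Unknowns are log₁₀ free concentrations of the non-fixed components. The
residual is the relative mass-balance error per component; the Jacobian
ln10·(diag(c_free) + νᵀ diag(c_s) ν) is symmetric positive definite for
tableau systems, and the Newton step is damped to at most 1 log unit per
component per iteration. Convergence requires a maximum relative residual
below 1e−8 (cap 200 iterations; failure raises an error carrying the last
residuals). When the ionic strength is not imposed, an outer fixed-point
loop recomputes I = ½Σc_iz_i² from the solved species and refreshes γ until
I is stable to 1e−10 relative (cap 50 rounds). Initial guesses are the
component totals floored at 1e−20 M. Species log concentrations are clipped
to ±300 to avoid overflow during early iterations.

Degenerate inputs: a component with zero total converges to a vanishing
free concentration (used for the placeholder silver component that
humic-ligand augmentation introduces); duplicate component names, species
referencing undeclared components, pH outside [0, 14] and negative totals
are rejected up front.

### Thermodynamic constants

The shipped TSV database (`nanofate/data/thermo_db.tsv`, SHA-256 recorded
in every run manifest) carries MINTEQ-family/NIST critically-selected
constants for: water/hydroxide, the ammonium/ammonia and carbonate systems,
the Na/K/Mg/Ca ion pairs with chloride, sulfate and carbonate, and the
silver ladders — AgClₓ (x = 1..3; log K₁ 3.31, log β₂ 5.25, log β₃ 5.20),
Ag(NH₃)ₓ⁺ (log K₁ 3.31, log β₂ 7.22), AgOH/Ag(OH)₂⁻, AgNO₂(aq) (log K 1.6)
and AgSO₄⁻ (log K 1.29). Constants were taken from the compilations once;
no value was adjusted to improve agreement with any reference output.
Compilation-to-compilation drift of ±0.1–0.2 log units moves the reported
percentages by a few points at most, which is why comparisons elsewhere
use percentage-point tolerances. No temperature correction of log K is
applied (reference 25 °C; enthalpies are not part of the database schema).
Trace metals and EDTA are omitted from the default database: at their
sub-micromolar totals they cannot move the major-ion or silver
distributions.

### Wastewater recipe and the two pH values

The SW recipe ships with the measured component totals (NH₄⁺ 18.10, Na⁺
22.84, K⁺ 12.42, Mg²⁺ 2.10, Cl⁻ 18.50, NO₂⁻ 23.19, SO₄²⁻ 2.03, CO₃²⁻
0.05 mM), the measured ionic strength (100 mM) imposed as a fixed
override, and pH 7.7. The medium's pH is 7.7 without sludge and 8.7 with
sludge, and both are plain inputs (`sw_problem(pH=...)`). The choice of
7.7 for the sludge-free matrix is forced by internal consistency of the
reference speciation itself: an NH₄⁺/NH₃ split of 96.85/2.26 back-solves
(pK_a 9.244, Davies γ at I = 0.1 M) to pH ≈ 7.72, and the HCO₃⁻/H₂CO₃*
split of 94.48/3.30 to the same value; at pH 8.7 free NH₄⁺ would fall
below 90%. The test suite asserts both facts.

A caveat the package documents rather than hides: the reference value for
free Mg²⁺ (84.11%) is not reproducible from the same inputs with any
standard constant set. The sulfate side of the same reference table closes
to ~100% and thereby pins MgSO₄(aq) at ~5.6% of Mg; with MgCl⁺ ~3% and all
other magnesium ligands negligible at these totals (total carbonate is
only 0.05 mM), free Mg²⁺ cannot be far from ~93%, which is what this
package computes. The corresponding check is intentionally left failing
rather than absorbed by a widened tolerance or a tuned MgSO₄ constant.

### Humic-acid binding

Sludge-derived humic acid is modelled as a discrete two-site monoprotic
ligand: a carboxylic-type site (4.0 mmol/g, pK_a 4.0, log K_Ag 5.0) and a
phenolic-type site (2.0 mmol/g, pK_a 9.5, log K_Ag 7.5). These defaults
are stated assumptions in the range reported for humic substances, not
fitted values, and the humic model is excluded from quantitative
comparisons — it exists to reproduce the qualitative result that 42 mg/L
HA binds >90% of 30 µg/L dissolved silver in DI water. A full
NICA-Donnan or Stockholm-humic treatment is out of scope.

## DLVO interaction energies

Equal spheres with the measured hydrodynamic radius and ζ-potential as
surface potential (constant-potential assumption). Terms:

* van der Waals: Gregory's retarded sphere–sphere form with
  A₁₃₁ = 3.7×10⁻²⁰ J and λ = 100 nm; strictly attractive, recovers
  −A·a/(12D) for equal spheres as D/λ → 0.
* double layer: the general two-sphere constant-potential expression; for
  identical particles it collapses algebraically to
  πε_rε₀(a/2)ζ²·4ln(1+e^(−κD)), and both code paths are kept and
  cross-checked to 1e−12 relative (the literal path uses log1p to stay
  accurate deep in the screened tail).
* screening: κ = √(2N_A I e²/(ε_rε₀k_BT)) with the constants as commonly
  printed for this expression (k_B 1.38×10⁻²³ J/K, N_A 6.02×10²³ /mol,
  e 1.602×10⁻¹⁹ C, ε₀ 8.85×10⁻¹² C²N⁻¹m⁻², ε_r 78.5), giving
  κ⁻¹ ≈ 0.96 nm at 0.1 M and 25 °C.

Profiles are evaluated on a log-spaced grid from 0.1 nm to 100 nm (2000
points by default); the lower bound avoids the contact divergence of the
van der Waals term. The barrier is the positive maximum of V/k_BT, refined
by a quadratic fit through the three grid points around the maximum (in
log D); an everywhere-non-positive profile reports "no barrier". A
fixed-potential scan of barrier height versus ionic strength reports the
first I at which the barrier vanishes — a proxy for the critical
coagulation concentration that ignores charge regulation, so it should be
read as an ordering tool, not a predicted CCC.

Radius convention: the hydrodynamic size (21.5 nm) is taken as a diameter
by default (a = 10.75 nm); `--radius-convention size` switches to
size-as-radius. The reported barrier heights for the DI and SW conditions
cannot both be matched exactly under any single convention and
temperature, so the package treats the DI ≫ SW barrier ordering (≥5×) as
the reproducible claim; with the default convention the SW condition has
no barrier at all, consistent with its observed diffusion-limited
aggregation. DLVO is not applied to sludge-containing conditions (solid
particles and polymer bridging violate its assumptions); the pipeline
marks those as not applicable.

Temperature enters κ and the k_BT scale explicitly (defaults 298.15 K,
configurable; the reactor ran at 35 °C, which changes the barrier heights
by only a few percent).

## Aggregation kinetics

Rates are plain consecutive-interval slopes ΔD/Δt; an optional centered
moving average (truncated at the ends) stands in for replicate averaging.
No parametric model is fitted. A plateau is declared at the first two
consecutive intervals with |slope| below 1 nm/min — chosen because the
slowest slope still described as stabilization in practice is ~0.44
nm/min — and the plateau size is the mean size from that window onward.
With coarse 30-min sampling the maximum interval slope underestimates the
instantaneous maximum of a fast sigmoid; the round-trip tests therefore
use dense sampling when checking the analytic logistic maximum r·K/4.

## Mass balance

dissolved% = 100·(dissolved µg/L)/(1000·dose mg/L); suspended% =
100·(NTA number concentration)/(control), capped at 100; settled% closes
the sum to 100 (±0.5 closure tolerance; physically impossible inputs are
rejected). Two documented simplifications, inherited from the measurement
design: "settled" conflates sedimentation with container adsorption, and
the number-to-mass mapping of the control is applied to aggregated
samples, which biases the suspended mass low once aggregates form.

## Synthetic data generator

The generator emulates the *statistical structure* of the instrument
record, not its physics: logistic size growth D(t) = K/(1+((K−d₀)/d₀)e^(−rt))
(the observed rise is sigmoidal; no mechanistic model was fitted), a
linear ζ ramp completed by 5 min, a constant dissolved-Ag level, and
dilution series that decay as 1/factor (conservative) or factor^−β, β>1
(losses), clamped at the NTA floor of 1e8 particles/mL. Scenario defaults
are the measured condition summaries — d₀ 21.5 nm; plateaus 21.5 / 388.8 /
220.1 / 313.4 nm; ζ −37.4 → {−37.4, −18.4, −42.0, −22.2} mV; dissolved
4.3 / 156.7 / 30.0 / 577.5 µg/L; suspended 90 / 10.7 / 60 / 20% — and the
logistic rate constants come from the measured maximum rates through the
max-slope identity r = 4·k_max/K (SW: 0.159/min, DI+sludge: 0.091/min,
SW+sludge: 0.163/min), which puts the SW plateau inside ~100 min as
observed. Measurement noise is i.i.d. Gaussian (sd 5 nm size, 1 mV ζ,
5 µg/L dissolved; replicate scatter was not reported, these are plausible
instrument figures). All generators are seeded and bit-reproducible.

Because the generator is i.i.d.-Gaussian around an idealized curve,
passing round-trip tests demonstrates that the analysis stages recover
known parameters under realistic noise levels — not that real NTA records
(autocorrelated drift, multimodal aggregate distributions, occasional
dropouts) would be analyzed equally well.

## Problem sizes and orchestration

The default SW solve has 9 components and 24 unknown quantities in total
and converges in ~11 Newton iterations; the silver-bearing solves add the
Ag component and 11 species. The recovery study uses 50 seeds on 22-point
series. The four-condition pipeline (`run_full_analysis`) derives one
sub-seed per scenario from the single run seed, reads its own generated
CSVs back through the validating readers, and stamps every manifest with
the package version, seed, and database checksum.
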