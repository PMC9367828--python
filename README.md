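# nanofate

Colloidal and chemical fate of citrate-coated silver nanoparticles
(cit-AgNPs) in synthetic high-ammonia-nitrogen wastewater (SW) and anammox
sludge. The package is aimed at environmental chemists and wastewater
engineers who want to reproduce — or re-run with their own numbers — the
computational half of a nanoparticle-fate study: which dissolved silver
species form, whether an electrostatic energy barrier still protects the
particles from aggregating, how fast they aggregate, and where the silver
mass ends up (suspended, dissolved, or settled).

## What it computes

**Equilibrium speciation** (`nanofate.speciation`). A tableau-method
solver: each medium is a set of *components* with conserved totals
(NH₄⁺, Na⁺, K⁺, Mg²⁺, Cl⁻, NO₂⁻, SO₄²⁻, CO₃²⁻, Ag⁺, …) and *species*
formed by mass-action laws, log K referenced to 25 °C and zero ionic
strength (a shipped TSV database drawn from MINTEQ-family compilations).
The proton is a fixed-activity component (pH is an input), single-ion
activity coefficients follow the Davies equation

log₁₀ γ = −A z² ( √I/(1+√I) − 0.3 I ),

and the solver is a damped Newton iteration on the log free
concentrations with an outer fixed-point loop over γ. Dissolved silver
measured by AAS is speciated in the medium via the chloro (AgCl(aq),
AgCl₂⁻, AgCl₃²⁻), ammine (AgNH₃⁺, Ag(NH₃)₂⁺), hydroxo, nitrito and
sulfato ladders, plus an optional discrete two-site humic-acid ligand.

**DLVO stability** (`nanofate.dlvo`). Sphere–sphere total interaction
energy V(D) = V_vdw + V_edl: retarded van der Waals attraction (Gregory)

V_vdw = −A₁₃₁ a₁a₂ / (6D(a₁+a₂)) · [1 − (5.32D/λ) ln(1 + λ/(5.32D))]

and constant-potential double-layer repulsion with the measured
ζ-potential standing in for the surface potential, screened by
κ = √(2 N_A I e²/(ε_r ε₀ k_B T)). The energy barrier (positive maximum of
V, in k_BT) separates reaction-limited from diffusion-limited aggregation.

**Aggregation kinetics** (`nanofate.kinetics`). Rates k = ΔD/Δt over
consecutive NTA size measurements, the maximum rate, and plateau
detection.

**Mass balance** (`nanofate.mass_balance`). Suspended (NTA number
concentration vs control), dissolved (AAS / dose) and settled (closure
to 100%) fractions of the silver dose.

**Synthetic data** (`nanofate.synthetic`). Seeded generators that emulate
the study's measurement structure for the four conditions (DI, SW,
DI+sludge, SW+sludge): logistic size growth 21.5 → 388.8 nm, ζ step
−37.4 → −18.4 mV completed within 5 min, time-stable dissolved silver,
and dilution series with the NTA detection floor.

## Worked example

Speciate the SW matrix (totals in the shipped recipe, pH 7.7, Davies,
I = 100 mM) together with the measured 156.7 µg/L dissolved silver:

```sh
$ nanofate speciate --ag-ug-l 156.7
component,total_mM,rank,species,percent
NH4,18.1,1,NH4,97.18
NH4,18.1,2,NH3,2.17
...
Cl,18.5,1,Cl,98.8
Cl,18.5,2,NaCl(aq),0.68
...
CO3,0.05,1,HCO3-,94.5
CO3,0.05,2,H2CO3*,3.31
...
Ag,0.001453,1,AgCl2-,55.83
Ag,0.001453,2,AgCl(aq),35.08
Ag,0.001453,3,Ag(NH3)2+,3.92
```

Free NH₄⁺ carries ~97% of the ammonium and free Cl⁻ ~99% of the chloride
— the SW is dominated by its free major ions — while the dissolved silver
is almost entirely chloro-complexed (AgCl₂⁻ + AgCl(aq) ≈ 91%), with
essentially no diammine silver at pH 7.7. Re-running the silver solve at
the sludge-amended pH 8.7 with 577.5 µg/L flips the distribution to
Ag(NH₃)₂⁺ ≈ 72%.

DLVO profiles for the DI control versus SW:

```sh
$ nanofate dlvo --zeta-mv -37.4 --is-mm 0.0398 --temp-c 25 --out di.csv
barrier: 9.36 kBT at D = 6.25 nm
$ nanofate dlvo --zeta-mv -18.4 --is-mm 100 --temp-c 25 --out sw.csv
barrier: none (attractive at all separations)
```

In DI water a ~9 k_BT barrier keeps the particles dispersed; at the SW
ionic strength and its weakened ζ-potential the barrier is gone and
aggregation is diffusion-limited — matching the observed growth from
21.5 nm to ~389 nm.

The full four-condition pipeline (synthetic instrument data → kinetics →
speciation → DLVO → mass balance, with a manifest recording the seed and
database checksum):

```sh
nanofate run --out results/full --seed 7
```

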