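# Synthetic high-ammonia-nitrogen wastewater (SW): measured component totals,
# measured pH without sludge (7.7; 8.7 with sludge) and the measured initial
# ionic strength (100 mM) imposed as a fixed override. Trace metals and EDTA
# are omitted (sub-micromolar; they do not move the major-ion speciation).
components:
  NH4: {total_mM: 18.10, charge: 1}
  Na: {total_mM: 22.84, charge: 1}
  K: {total_mM: 12.42, charge: 1}
  Mg: {total_mM: 2.10, charge: 2}
  Cl: {total_mM: 18.50, charge: -1}
  NO2: {total_mM: 23.19, charge: -1}
  SO4: {total_mM: 2.03, charge: -2}
  CO3: {total_mM: 0.05, charge: -2}
pH: 7.7
temperature_C: 25.0
activity_model: davies
ionic_strength_mM: 100.0
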