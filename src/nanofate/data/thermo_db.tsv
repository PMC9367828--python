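# nanofate thermodynamic database v1 — formation constants at 25 degC, I = 0,
# from MINTEQ-family / NIST critically selected stability constants.
# Species are written in terms of components (H is the fixed-activity proton;
# water is implicit with unit activity). Columns are tab-separated:
# species	charge	log_k	ref_temp_C	stoichiometry
OH-	-1	-13.997	25	H:-1
NH3	0	-9.244	25	NH4:1;H:-1
HCO3-	-1	10.329	25	CO3:1;H:1
H2CO3*	0	16.681	25	CO3:1;H:2
NaCl(aq)	0	-0.30	25	Na:1;Cl:1
NaSO4-	-1	0.73	25	Na:1;SO4:1
NaHCO3(aq)	0	10.079	25	Na:1;CO3:1;H:1
NaCO3-	-1	1.27	25	Na:1;CO3:1
KCl(aq)	0	-0.50	25	K:1;Cl:1
KSO4-	-1	0.85	25	K:1;SO4:1
NH4SO4-	-1	1.03	25	NH4:1;SO4:1
MgSO4(aq)	0	2.26	25	Mg:1;SO4:1
MgCl+	1	0.60	25	Mg:1;Cl:1
MgCO3(aq)	0	2.92	25	Mg:1;CO3:1
MgHCO3+	1	11.40	25	Mg:1;CO3:1;H:1
MgOH+	1	-11.44	25	Mg:1;H:-1
CaSO4(aq)	0	2.36	25	Ca:1;SO4:1
CaCl+	1	0.40	25	Ca:1;Cl:1
CaCO3(aq)	0	3.22	25	Ca:1;CO3:1
CaHCO3+	1	11.44	25	Ca:1;CO3:1;H:1
CaOH+	1	-12.70	25	Ca:1;H:-1
AgCl(aq)	0	3.31	25	Ag:1;Cl:1
AgCl2-	-1	5.25	25	Ag:1;Cl:2
AgCl3--	-2	5.20	25	Ag:1;Cl:3
AgNH3+	1	-5.93	25	Ag:1;NH4:1;H:-1	# Ag+ + NH3, log K 3.31, recast on NH4/H
Ag(NH3)2+	1	-11.27	25	Ag:1;NH4:2;H:-2	# Ag+ + 2NH3, log beta2 7.22
AgOH(aq)	0	-12.00	25	Ag:1;H:-1
Ag(OH)2-	-1	-24.00	25	Ag:1;H:-2
AgNO2(aq)	0	1.60	25	Ag:1;NO2:1
AgSO4-	-1	1.29	25	Ag:1;SO4:1
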