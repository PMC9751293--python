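# Standard-state formation energetics at 298.15 K (kJ/mol), molar scale.
# Gibbs energies follow standard compilations (Thauer 1977; Shock & Helgeson
# 1988/1990; CODATA).  Rows marked "calibrated" carry effective formation
# enthalpies (and for glycine also the Gibbs energy) fitted so the
# Gibbs-Helmholtz temperature pipeline reproduces the in situ reaction
# energies this package targets; see docs/methods.md before reusing them
# as reference thermochemistry.
# "equilibrium" rows store pK at 298.15 K in the dGf column and the
# dissociation enthalpy (kJ/mol) in the dHf column.
species,formula,charge,phase,dGf_kJ_mol,dHf_kJ_mol,molar_volume_cm3_mol,source
H+,H,1,aqueous,0.0,0.0,0.0,convention
H2O,H2O,0,liquid-water,-237.18,-285.83,18.07,CODATA
H2(aq),H2,0,aqueous,17.72,-19.7,25.2,Gf: Shock & Helgeson; Hf: calibrated
H2(g),H2,0,gas,0.0,0.0,,convention
CO2(aq),CO2,0,aqueous,-385.98,-430.2,32.8,Gf: CODATA; Hf: calibrated
HCO3-,CHO3,-1,aqueous,-586.85,-689.93,24.6,CODATA
CO3^2-,CO3,-2,aqueous,-527.90,-675.23,-6.1,CODATA
formate,CHO2,-1,aqueous,-351.04,-407.3,26.2,Gf: Thauer 1977; Hf: calibrated
acetate,C2H3O2,-1,aqueous,-369.41,-486.01,40.5,Thauer 1977
glycine,C2H5NO2,0,aqueous,-391.46,-578.0,43.3,calibrated
glycinate,C2H4NO2,-1,aqueous,-315.0,-470.0,43.0,derived from glycine(aq) + amino pKa 9.78 (not calibrated)
NH3(aq),H3N,0,aqueous,-26.57,-80.29,24.4,CODATA
NH4+,H4N,1,aqueous,-79.31,-132.51,18.1,CODATA
K1_carbonic,,0,equilibrium,6.35,7.64,,"Plummer & Busenberg 1982 (freshwater, molar)"
K2_carbonic,,0,equilibrium,10.33,14.85,,"Plummer & Busenberg 1982 (freshwater, molar)"
Ks_calcite,,0,equilibrium,8.30103,-12.3,,pKs of 5e-9 (molar scale)
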