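# H2/CO2 acetogenesis forced through Calvin-Benson-Bassham CO2 fixation:
# same net reaction, minus 6 ATP of investment.  The per-ATP hydrolysis
# energy is a per-variant parameter back-solved from the study's printed
# pair of values (see docs/methods.md).
name: cbb_h2_co2
base: h2_co2_acetogenesis
atp_investment:
  n_atp: 6
  atp_hydrolysis_kj: -59.66
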