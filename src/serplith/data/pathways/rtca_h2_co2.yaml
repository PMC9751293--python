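# H2/CO2 acetogenesis via the reductive tricarboxylic acid cycle:
# same net reaction, minus 1 ATP of investment.
name: rtca_h2_co2
base: h2_co2_acetogenesis
atp_investment:
  n_atp: 1
  atp_hydrolysis_kj: -57.97
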