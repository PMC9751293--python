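# Conventional H2/CO2 homoacetogenesis (Wood-Ljungdahl pathway), ATP
# ledger per the Acetobacterium woodii scheme: acetate kinase (+1),
# formyl-THF synthetase (-1), and a net chemiosmotic gain of +0.3 ATP
# per acetate from the Rnf / ATP-synthase loop.
name: h2_co2_acetogenesis
description: 4 H2 + 2 CO2 -> acetate- + H+ + 2 H2O (Wood-Ljungdahl)
reaction:
  H2(aq): -4
  CO2(aq): -2
  acetate: 1
  H+: 1
  H2O: 2
basis: acetate
atp_ledger:
  - step: acetate kinase
    atp: 1.0
  - step: formyl-THF synthetase
    atp: -1.0
  - step: chemiosmotic (Rnf / ATP synthase)
    atp: 0.3
h2_per_basis: 4
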