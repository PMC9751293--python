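# Formate-disproportionating acetogenesis: formate is both electron
# donor (oxidized to CO2) and carbon source.  No H2 is consumed, so no
# ATP-per-H2 figure is defined for this pathway.
name: formate_disproportionation
description: 4 formate- + 3 H+ -> acetate- + 2 CO2 + 2 H2O
reaction:
  formate: -4
  H+: -3
  acetate: 1
  CO2(aq): 2
  H2O: 2
basis: acetate
atp_ledger:
  - step: acetate kinase
    atp: 1.0
  - step: formyl-THF synthetase
    atp: -1.0
  - step: chemiosmotic (Rnf / ATP synthase)
    atp: 0.3
h2_per_basis: 0
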