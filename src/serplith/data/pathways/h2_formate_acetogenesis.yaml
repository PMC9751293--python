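# H2-oxidizing, formate-reducing acetogenesis: formate replaces CO2 at
# the head of the methyl branch, halving CO2 usage and skipping the
# formate dehydrogenase (no energy recovery at that step).  The
# chemiosmotic entry is 3/4 of the H2/CO2 value, proportional to the H2
# oxidized, so the pathway nets 0.225 ATP per acetate = 0.075 per H2.
# The site override encodes that the printed Cedars energy for this
# pathway assumes 201 uM H2 (the concentration measured at Hakuba).
name: h2_formate_acetogenesis
description: 3 H2 + formate- + CO2 -> acetate- + 2 H2O
reaction:
  H2(aq): -3
  formate: -1
  CO2(aq): -1
  acetate: 1
  H2O: 2
basis: acetate
atp_ledger:
  - step: acetate kinase
    atp: 1.0
  - step: formyl-THF synthetase
    atp: -1.0
  - step: chemiosmotic (Rnf / ATP synthase)
    atp: 0.225
h2_per_basis: 3
condition_overrides:
  cedars:
    H2(aq): 201.0e-6
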