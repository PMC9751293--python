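# H2-oxidizing glycine reduction via the selenoprotein glycine reductase
# (Grd).  Electrons flow H2 -> NADPH -> thioredoxin -> Grd; the acetyl
# phosphate released by Grd yields one substrate-level ATP via acetate
# kinase, so the pathway recovers 1 ATP per H2.  Glycine is written as
# the neutral zwitterion and the net reaction releases one proton (the
# protonation convention that reproduces the study's energies; see
# docs/methods.md).  The internal steps use abstract carrier species and
# telescope exactly to the net reaction plus the ADP -> ATP event.
# The Cedars evaluation of this pathway assumes 201 uM H2.
name: glycine_reduction
description: H2 + glycine -> acetate- + NH3 + H+ (glycine reductase)
reaction:
  H2(aq): -1
  glycine: -1
  acetate: 1
  NH3(aq): 1
  H+: 1
basis: glycine
atp_ledger:
  - step: acetate kinase
    atp: 1.0
h2_per_basis: 1
condition_overrides:
  cedars:
    H2(aq): 201.0e-6
internal_steps:
  - name: hydrogenase (Hox)
    stoichiometry: {H2(aq): -1, NADP_ox: -1, NADP_red: 1, H+: 1}
  - name: NADP-linked thioredoxin reductase
    stoichiometry: {NADP_red: -1, H+: -1, Trx_ox: -1, NADP_ox: 1, Trx_red: 1}
  - name: glycine reductase (Grd)
    stoichiometry: {glycine: -1, Trx_red: -1, acetyl_phosphate: 1, NH3(aq): 1, Trx_ox: 1}
  - name: acetate kinase
    stoichiometry: {acetyl_phosphate: -1, ADP: -1, acetate: 1, H+: 1, ATP: 1}
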