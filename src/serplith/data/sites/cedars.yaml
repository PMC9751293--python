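# The Cedars GPS1 spring (hyperalkaline serpentinite springs, California).
# H2 was not measured at The Cedars; the highest Hakuba value is used as
# the site default.  Ionic strength is an implementation default.
site: cedars
temperature_C: 17.0
pH: 11.9
pressure_bar: 1.0
ionic_strength_M: 0.005
concentrations:
  H2(aq): 664.0e-6
  formate: 6.9e-6
  acetate: 69.3e-6
  glycine: 5.4e-9
  NH3(aq): 1.0e-6
  TIC: 35.0e-6
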