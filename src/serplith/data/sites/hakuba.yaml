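# Hakuba Happo hot spring, drilling well #3 (hyperalkaline serpentinite
# spring, Japan).  Concentrations in mol/L; TIC = total inorganic carbon.
# Ionic strength is an implementation default (not a field measurement).
site: hakuba
temperature_C: 48.0
pH: 10.7
pressure_bar: 1.0
ionic_strength_M: 0.01
concentrations:
  H2(aq): 201.0e-6
  formate: 8.0e-6
  acetate: 4.0e-6
  glycine: 5.4e-9
  NH3(aq): 2.9e-6
  TIC: 1.0e-7
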