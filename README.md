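# serplith

Bioenergetics of H₂-driven lithotrophy in hyperalkaline serpentinite
springs, plus conserved-motif screening of glycine reductase proteins.

## The problem

Serpentinization produces hyperalkaline (pH 10.7–11.9), H₂-rich spring
waters that are almost devoid of CO₂: at pH ≫ pK₂ nearly all dissolved
inorganic carbon sits as CO₃²⁻, so the equilibrium CO₂(aq) available to
a CO₂-reducing acetogen collapses to sub-nanomolar levels.  Whether a
candidate catabolism can actually support life there is a quantitative
question: the in situ Gibbs free energy

ΔG = ΔG°(T) + RT·ln Q,  ΔG°(T) = ΔG°₂₉₈·(T/T₀) + ΔH°₂₉₈·(1 − T/T₀)

must reach the catabolic energy quantum, ΔG ≤ −20 kJ per mol reaction.
`serplith` evaluates this pipeline for the candidate metabolisms of two
well-characterized springs — Hakuba Happo (48 °C, pH 10.7) and The
Cedars (17 °C, pH 11.9) — including H₂/CO₂ and H₂/formate
acetogenesis, formate disproportionation, ATP-invested CO₂ fixation
variants (CBB, rTCA), and H₂-oxidizing glycine reduction via the
selenoprotein glycine reductase (Grd), with per-pathway ATP ledgers
(substrate-level and chemiosmotic) and ATP-per-H₂ efficiency.

A second component screens protein sequences for the conserved-residue
signatures that distinguish glycine reductase substrate subunits
(GrdB) from their sarcosine-reductase paralogs (GrdF), using a
PROSITE-style grammar (literals, `x(n,m)` bounded gaps, `[...]`
alternative sets, selenocysteine-aware matching) and greedy
longest-first clustering at 75% global-alignment identity.

It is a library first (`import serplith`), with narrative scripts under
`examples/` and a thin `serplith` CLI (`speciate`, `energetics`,
`sensitivity`, `grdscan`, `simulate`, `report`).

## Worked example

```python
>>> import serplith as sp
>>> constants = sp.load_constants()
>>> registry = sp.load_pathways(constants)
>>> hakuba = sp.load_site("hakuba")
>>> rep = sp.evaluate_pathway(registry["h2_co2_acetogenesis"], hakuba, constants)
>>> round(rep.dG_insitu, 2), rep.viable
(-3.73, False)
>>> rep = sp.evaluate_pathway(registry["glycine_reduction"], hakuba, constants)
>>> round(rep.dG_insitu, 2), rep.viable, rep.atp_per_h2
(-85.84, True, 1.0)
>>> st = sp.speciate(10.7, 1e-7, 321.15, 0.01, "davies", constants)
>>> round(st.co2_aq * 1e9, 4)   # CO2(aq) in nM at Hakuba
0.0005
```

Reading: under Hakuba conditions conventional H₂/CO₂ acetogenesis
releases only ~3.7 kJ per mol acetate — exergonic, but far above the
−20 kJ/mol quantum, so it cannot fuel ATP synthesis; the culprit is the
~0.0005 nM equilibrium CO₂.  H₂-oxidizing glycine reduction releases
~86 kJ per mol glycine and recovers a full 1 ATP per mol H₂ (versus
0.075 for the Wood–Ljungdahl routes), which is why an organism
specializing in it fits these springs.  `python examples/energetics_survey.py`
prints the full pathway × site table.

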