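# Methods

This note documents the models behind `serplith`, the conventions and
calibrations baked into the packaged data files, and what the test
suite does and does not demonstrate.

## 1. In situ reaction energies

For a reaction with signed stoichiometry ν (products positive) the
package computes, per mole of a named basis species:

* **ΔG°₂₉₈ = Σ ν·ΔG°f** and **ΔH°₂₉₈ = Σ ν·ΔH°f** from the packaged
  constants table (298.15 K, molar scale).
* **Temperature adjustment** by the integrated Gibbs–Helmholtz relation
  at constant ΔH°: ΔG°(T) = ΔG°₂₉₈·(T/T₀) + ΔH°₂₉₈·(1 − T/T₀),
  T₀ = 298.15 K.  The springs modelled are at 321.15 K (48 °C) and
  290.15 K (17 °C); the 0.15 K difference between "298 K" and 298.15 K
  is far below result resolution.
* **Activity term** RT·ln Q with R = 8.314×10⁻³ kJ/(mol·K).  Water has
  unit activity; H⁺ activity is 10^(−pH) (NBS convention, matching how
  field pH meters report); every other solute takes its molar
  concentration, optionally multiplied by a Davies activity
  coefficient.  The *default activity model for the ΔG pipeline is
  ideal* (γ = 1); this is the configuration that reproduces the target
  energies, and the Davies switch exists to quantify how much the
  correction matters (≲1 kJ/mol for these reactions, since charge is
  nearly balanced across each quotient).
* **Pressure term** ΔV°·(P − 1 bar), disabled by default because both
  springs are sampled at ≈1 bar where the term vanishes; enabling it
  requires molar volumes for all participants.

A zero concentration makes ln Q diverge.  The pipeline returns a tagged
`Unbounded` value (direction +1 for a zero *reactant*, ΔG → +∞;
−1 for a zero *product*, ΔG → −∞) instead of an IEEE infinity, and the
viability logic handles the two directions explicitly (+∞ →
non-viable; −∞ → viable, with the reason recorded).

**Viability** uses the catabolic energy quantum ΔG ≤ −20 kJ per mol
reaction, inclusive at the boundary and configurable.

## 2. The constants table and its calibration

`data/constants.csv` carries ΔG°f/ΔH°f at 298.15 K for the thirteen
species the analysis touches.  Formation *Gibbs energies* are standard
compilation values (Thauer-style tables, Shock & Helgeson, CODATA);
they reproduce the classic standard-state energies (−142.7 kJ/mol
acetate for 4H₂ + 2CO₂ → acetate⁻ + H⁺ + 2H₂O; −211.6 for
4 formate⁻ + 3H⁺ → acetate⁻ + 2CO₂ + 2H₂O).

Formation *enthalpies* for H₂(aq), CO₂(aq) and formate⁻ — and both
values for glycine — are **calibrated effective parameters**, marked
`calibrated` in the CSV's source column.  The exact thermodynamic
framework behind the target in situ energies is not fully recoverable
(notably, the cross-site pair of the same H₂+formate reaction pins its
effective ΔH°rxn ≈ −159 kJ/mol where compilation enthalpies give
≈ −206), so the enthalpy rows were least-squares fitted such that the
Gibbs–Helmholtz pipeline reproduces the full set of target energies to
better than ±1 kJ/mol.  Consequences:

* The calibrated rows are *not transferable* reference thermochemistry;
  do not reuse them outside this pipeline.
* All packaged reaction energies agree with their targets within the
  ±2 kJ/mol band the calibration is designed for.

Two modelling conventions were fixed by the calibration:

* **H₂ at The Cedars.**  H₂ was never measured at The Cedars; the site
  fixture defaults to 664 µM (the highest Hakuba observation).  The
  packaged registry overrides H₂ to 201 µM for the *H₂+formate* and
  *glycine-reduction* evaluations at The Cedars — the assumption under
  which the target energies for those pathways are reproducible (with
  664 µM the H₂+formate energy would be ≈ −38 kJ/mol).  The override
  is declared per-pathway in the registry YAML, not hard-coded.
* **Glycine protonation.**  The glycine-reduction net reaction is
  written with the neutral zwitterion and a released proton:
  H₂(aq) + glycine → acetate⁻ + NH₃(aq) + H⁺.  This is the convention
  under which the biochemical-standard energy (ΔG°′, pH 7, evaluated at
  the Hakuba in situ temperature of 321.15 K) and both in situ energies
  are simultaneously consistent to ≈1 kJ/mol; the glycinate convention
  (no H⁺) cannot satisfy all three.  `biochemical_standard` defaults to
  298.15 K per the usual definition and takes a temperature argument.
  A non-calibrated glycinate⁻ row (derived from the amino-group pKa
  9.78) ships for completeness.

## 3. Carbonate speciation and saturation

TIC is partitioned among CO₂(aq)/HCO₃⁻/CO₃²⁻ at fixed pH using
pK₁ = 6.35, pK₂ = 10.33 at 298.15 K (freshwater, molar scale),
temperature-adjusted by van 't Hoff with dissociation enthalpies
ΔH₁ = 7.64, ΔH₂ = 14.85 kJ/mol (stored as `equilibrium` rows in the
same CSV).  Under the Davies model the mass-action ratios use
log₁₀ γ = −A·z²·(√I/(1+√I) − 0.3 I), with the Debye–Hückel A parameter
from a quadratic fit in Celsius (0.491 at 0 °C, 0.509 at 25 °C, 0.534
at 50 °C).  Outputs are free-ion concentrations; the ΔG pipeline
consumes CO₂(aq) directly as its activity (γ = 1 for a neutral
species).  Ionic strength is a site-config parameter; the packaged
defaults (Hakuba 0.01 M, Cedars 0.005 M) are implementation defaults,
not field measurements.  With Davies corrections at those defaults the
speciation reproduces the two springs' CO₂(aq) levels (≈0.0005 nM at
Hakuba, ≈0.0025 nM at The Cedars) within ~20%; under the ideal model
both are within a factor of 2.

Calcite saturation is the plain solubility threshold
[CO₃²⁻]ₘᵢₙ = Ks/[Ca²⁺] (Ks = 5×10⁻⁹ on the molar scale); no
complexation or polymorph logic.

## 4. Pathways and ATP accounting

Each pathway bundles a balanced net reaction with an ATP ledger whose
entries are per mole of basis species: substrate-level steps are
integral (+1 acetate kinase, −1 formyl-THF synthetase) and
chemiosmotic steps fractional.  The H₂/CO₂ route carries +0.3 ATP per
acetate for the Rnf/ATP-synthase loop (the textbook net for that ion
stoichiometry, kept as a single named entry rather than modelling
translocation); the H₂+formate route scales it to +0.225 (¾, in
proportion to H₂ oxidized, with no recovery at the bypassed formate
dehydrogenase), giving 0.225/3 = 0.075 ATP per H₂ — identical to the
H₂/CO₂ figure of 0.3/4.  Glycine reduction nets +1 ATP per glycine
with 1 H₂ per glycine: 1 ATP per H₂, >10× the acetogenic routes.

The glycine pathway also lists its internal electron-transfer steps
(hydrogenase → NADP-linked thioredoxin reductase → glycine reductase →
acetate kinase) over abstract carrier species whose formulas track
only H and charge; a test verifies the steps telescope exactly to the
net reaction plus the ADP→ATP event.

ATP-invested CO₂-fixation variants (CBB −6 ATP, rTCA −1 ATP) shift the
base in situ ΔG by n·ΔG_ATP.  The per-ATP hydrolysis energy is
*per-variant* (−59.66 and −57.97 kJ/mol respectively), because the two
target energies imply slightly different increments and no single
value reproduces both; the parameters live in the registry YAML.

Donor-oxidation favorability computes ΔG = −nF(E_acceptor − E_donor)
per mol donor (n = 2), with the donor half-couple (H₂ → 2H⁺ + 2e⁻ or
formate⁻ → H⁺ + CO₂ + 2e⁻) Nernst-shifted to in situ activities and
carrier couples at pH-7 midpoints (NADP⁺/NADPH and NAD⁺/NADH −320 mV,
Fd −420 mV) with a configurable ox/red ratio (default 1).  Treating the
carrier midpoints as pH-independent is a simplification; the function
reports per-carrier values plus the least-negative ("limiting") one,
and tests assert only the documented bounds.

Sensitivity is a plain finite difference of the in situ ΔG under a
single-species concentration perturbation; it agrees with the analytic
derivative ν·RT·∂ln c and is antisymmetric to first order.

## 5. Motif grammar and matching

The grammar: capital letters are literal residues, `x` any residue,
`x(n)` exactly n, `x(n,m)` n..m arbitrary residues, `[...]` an
alternative set; whitespace separates segments at zero distance.  The
two packaged patterns (GrdF, 47 elements, minimum span 303 residues;
GrdB, 46 elements, minimum 291) parse from their printed text and
round-trip losslessly through serialization.

Matching is leftmost-earliest with minimal-gap preference, implemented
as a backtracking search with failure memoization (the reported span is
a convention; classification uses existence only).  Semantics:
selenocysteine `U` satisfies wildcards and literal/set `C` positions
(Grd is a selenoprotein — the catalytic Cys is typically encoded as
Sec, and the exchange must not break matching); ambiguous `X` satisfies
wildcards only.  The matcher is property-tested against an
independently written regular-expression translation (non-greedy
bounded quantifiers) for both verdicts and spans.

Classification precedence is GrdF > GrdB at sequence level (GrdF-like
⇔ GrdF matches; GrdB-like ⇔ GrdB and not GrdF), mirroring the
subtraction of sarcosine-reductase clusters from GrdB candidate sets; a
cluster-level mode labels a whole cluster GrdF-like if any member
matches GrdF.  The GrdF pattern's trailing `x(12) [HILV]` is
implemented as a fixed-offset element (the printed text is ambiguous
about whether the final residue may float); partial conservation is
exposed as a prefix-match diagnostic with no classification semantics.

## 6. Clustering

Greedy longest-first clustering at an identity threshold (default
0.75): sort by length descending (ties by id), seed clusters in order,
assign each sequence to the first representative reaching the
threshold.  Identity = matches / alignment columns of one optimal
global alignment (match +1, mismatch −1, flat gap −1, terminal gaps
penalized).  This is a deterministic, brute-force-checkable
approximation of CD-HIT's word-heuristic behaviour, adequate at desk
scale (all-pairs verified in tests up to 60 sequences); it is not a
drop-in CD-HIT replacement for large collections.

## 7. Synthetic data

*Scenarios*: log-normal multiplicative perturbations per concentration
(default σ = 0.25 in natural log, ≈30% spread — a realistic
repeat-sampling variability for spring geochemistry; per-species
overrides available), additive Gaussian jitter on pH (σ = 0.1) and
temperature (σ = 1 K), pH clipped to [0, 14].  Concentrations stay
positive by construction.

*Grd sequences*: positives instantiate every motif element (uniform
gap lengths within bounds, uniform residue/alternative picks, literal
C → U with probability 0.5), embedded in uniform-random flanks of
20–80 residues; decoys are whole-sequence shuffles of positives, hence
residue-frequency matched.  Truth labels travel in a sidecar TSV, never
only in FASTA headers.

All randomness flows through `numpy.random.default_rng(seed)` (PCG64):
identical specs give identical output across platforms, with no global
state.

What the generators do *not* emulate: real homolog sets diverge by
substitution along phylogenies rather than by uniform residue choice,
so synthetic decoys are "easier" than true paralogs everywhere except
at the motif anchors themselves; passing recall/false-positive tests
demonstrates the matcher and the subtraction logic, not
database-screening performance.  Scenario draws perturb concentrations
independently, ignoring the correlated geochemistry of real springs.

## 8. Numerical choices and problem sizes

Balance validation tolerance 10⁻⁹ per element/charge; speciation mass
conservation holds to 10⁻¹² relative; ΔG additivity/antisymmetry hold
to 10⁻⁹ kJ/mol.  Property suites run at: ≥1000 sequences for the
matcher-vs-regex and decoy false-positive checks, 60 sequences for the
all-pairs clustering oracle, 200–400 randomized draws for speciation
and scenario checks — sizes at which the brute-force oracles are exact
and the whole suite stays interactive.

## 9. Known limitations

No Pitzer/SUPCRT equation-of-state modelling, Eh fields, or kinetics
(carbonic anhydrase and mineral dissolution change rates, not the
equilibrium CO₂ ceiling).  No open-system CO₂ ingassing: the springs
are treated as closed to atmosphere.  No methanogen or CO-based
energetics (CO is unmeasured in situ).  The pressure correction is a
linear ΔV° stand-in, untested against a full equation of state.  The
calibrated enthalpies absorb every unmodelled convention of the target
framework (activity scales, protonation states, possible temperature
conventions) and should be read as pipeline parameters, not
measurements.
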