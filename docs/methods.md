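# Methods

## Scope and model structure

The package implements a constraint-based modeling workflow for
*Ralstonia eutropha* H16: model construction with pH-resolved charge
balancing, biomass/energetics assembly, FBA/FVA/MOMA analyses, maintenance
calibration, and four in-silico studies. Because the organism's published
genome-scale reconstruction is distributed only as supplementary documents
without a machine-readable accession, the workflow is exercised on a
hand-curated **core network** (`cbmflux.synthetic`) built to reproduce the
qualitative physiology those studies probe. All claims verified by the test
suite are claims about this core model; where the full reconstruction would
be required (absolute growth rates, the exact optimal C/N ratio of 1.26, the
53 % mutant growth figure), the suite asserts the corresponding *property*
(a positive deterministic optimum, an interior C/N optimum, mutant growth
strictly below wild type) rather than the full-model number.

### The core network

Two compartments (cytosol/external), ~87 metabolites, ~100 reactions, all
with real elemental formulas and pKa-derived charges. Content: fructose
uptake and Entner–Doudoroff catabolism (no phosphofructokinase; a `pfk`
insertion template exists), lower glycolysis, full TCA cycle, PEP
carboxylase anaplerosis, serine/glycine/tetrahydrofolate one-carbon
metabolism, PHB synthesis (phaA/phaB/phaC) with an export sink, the
2-methylcitrate cycle (prpC/prpD/acnM/prpB) with a 2-MCA exchange and a
propionate-activation + methylmalonyl-CoA propionyl-CoA supply, a lumped
Calvin (CBB) reaction, soluble NAD- and NADP-reducing hydrogenases, NAD- and
NADP-linked formate dehydrogenases, lumped respiration, two denitrification
steps, ammonium assimilation, lumped fatty-acid synthesis for seven acyl
chains (odd chains primed with propionyl-CoA), glycogen synthesis, and a
composition-derived biomass reaction plus a fixed maintenance reaction.

Deliberate design devices, chosen once when the network was designed:

* **Growth-coupled NADPH.** NADP-linked enzymes are confined to the
  one-carbon/formate couple and the hydrogenase; isocitrate and glutamate
  dehydrogenases are NAD(H)-linked, as is the lumped fatty-acid synthase.
  On fructose, NADPH supply is therefore proportional to biosynthetic flux
  (glycine/serine demand), and the PHB reductase (NADPH-dependent) cannot
  run at zero growth. This yields the observed *interior* optimum of PHB
  production along the nitrogen axis: rising with N while NADPH supply
  limits, falling with N once leftover carbon limits.
* **Exact glycolytic ATP ratio.** Transport and phosphorylation
  stoichiometries are set so fermentative (substrate-level) catabolism
  yields exactly 1 ATP per fructose via the ED route and 2 via the EMP
  route; the pfk study's ATP comparison is evaluated in that fermentative
  setting (O₂ and alternative acceptors closed, lactate valve open,
  maintenance freed), making the factor of two an exact model property.
* **Propionate co-feed for the 2-MCA screen.** The knockout screen fixes a
  small propionate co-uptake (1 mmol·gDCW⁻¹·h⁻¹ by default), emulating the
  experimental co-feeding strategy for methylcitrate production. The forced
  propionyl-CoA influx makes knockouts of the cycle's consumption steps
  (*prpB*, *prpD*, *acnM*) redirect carbon into obligatory 2-MCA secretion,
  while the wild-type optimum recycles it completely (zero secretion at
  maximal growth). The dehydratase steps are reversible, so all three
  knockouts are exactly equivalent — one top priority class.
* **Redundancy of central enzymes.** Lumped multi-step reactions
  (respiratory chain, succinate dehydrogenase complex) carry no single-ORF
  association, and genuinely duplicated enzymes (fumarase, malate
  dehydrogenase/Mqo, the succinyl-CoA synthetase operon, nitrate reductase)
  carry isozyme OR-rules — reflecting the organism's bipartite genome with
  its duplicated central metabolism. Without this, the single-gene screen
  would rank central-metabolism lesions (which also dead-end carbon into
  2-MCA) above the methylcitrate-cycle targets.

What the fixture does *not* emulate: genome-scale redundancy (93 subsystems,
1391 reactions), RNA/DNA/cofactor biosynthesis (those biomass fractions are
zero; protein, carbohydrate and lipid carry the composition), the 131-carbon-
source utilization table (three representative substrates — fructose,
H₂+CO₂, formate — are supported), and periplasmic chemiosmosis (oxidative
phosphorylation is lumped with fixed P/O = 2 for NADH, 1 for nitrate/nitrite
respiration). Passing tests therefore demonstrate the correctness of the
workflow and the qualitative physiology, not genome-scale predictions.

### Anaerobic behavior

With organic-acid secretion closed (the default constraint set: acetate,
lactate, pyruvate, ethanol exchanges at zero, reflecting the organism's
non-fermentative batch physiology), the model cannot grow without an
electron acceptor; even with the valves open, fermentative ATP capacity
(1 ATP/fructose × 2.6) cannot cover the fixed maintenance of 3, so the
strictly respiratory phenotype is robust. Denitrification (NO₃⁻ or NO₂⁻
opened) restores growth; that check opens the acetate valve because the
lumped succinate dehydrogenase is O₂-coupled, leaving acetyl-CoA overflow
as the anaerobic carbon outlet.

## Charges and pH variants

Average charge follows Henderson–Hasselbalch,
z(pH) = z₀ − Σₖ 1/(1+10^(pKaₖ−pH)), continuous and non-increasing in pH.
For model building the average is rounded to the nearest integer (H⁺
stoichiometry must close exactly); half-integer ties round toward the pH-7
charge. The real-valued average remains available for audits. A pH-variant
model is produced by re-deriving each metabolite's charge at the target pH,
shifting its hydrogen count with the charge (one H per unit), and
readjusting every reaction's proton coefficient to zero net charge — after
which element balance closes automatically. In the bundled network only
orthophosphate (pKa₂ = 6.8) changes protonation state across pH 6→8; most
synthetic pKa profiles are placed outside the 6–8 window so that the three
variants stay flux-equivalent controls, with real pKas used where they are
well known (acetate 4.76, amino-acid side groups, phosphate).

## Biomass and energetics

Monomer drains are fraction × 1000 / MW mmol·gDCW⁻¹. The default weight
basis is the free monomer molecular weight; a residue basis (water
subtracted per condensation, with the water released explicitly) is
available via `weight_basis="residue"`. The GAME ATP coefficient is
game × 1000 / MW(ATP) with the molecular weight taken from the model's own
ATP formula (503.15 g·mol⁻¹ for the −4 species), and a raw-mmol mode
(`game_units="mmol"`) bypasses the conversion — both conventions circulate
in the literature, and the calibration is consistent under either. Protons
are added to close the biomass reaction's charge and the biomass
pseudo-metabolite's formula is defined as the exact net elemental content,
so the reaction is balanced by construction. Macromolecule fractions
(protein 0.68 / carbohydrate 0.17 / lipid 0.15 g·gDCW⁻¹) and the protein
monomer split are literature-typical values fixed at design time; the two
growth conditions differ only in the fatty-acid profile (palmitoleate down,
heptadecanoate 0.6 % → 11.2 %, plus C14:1/C19:0 appearing under nitrogen
limitation).

## Calibration

Model-predicted uptake at dilution rate D is the FBA *minimum* substrate
uptake at growth fixed to D — the dual reading of growth maximization at
fixed uptake, which makes the D → q_s map single-valued and monotone in both
maintenance parameters. Stage 1 bisects GAME until the predicted slope over
the observed D range matches the fitted OLS slope; stage 2 bisects NGAME on
the intercept (extrapolated to D → 0 from two evaluations at and below the
smallest observed rate, avoiding the degenerate D = 0 solve). Bisection
tolerance 1e-6 on the matched quantity; default brackets GAME ∈ [0, 100]
g·gDCW⁻¹, NGAME ∈ [0, 20] mmol·gDCW⁻¹·h⁻¹. Below ≈1 g·gDCW⁻¹ GAME the
response is flat (surplus catabolic NADH covers the ATP term), so noisy
data can place the fitted slope below the achievable floor;
`on_boundary="clamp"` then returns the bracket endpoint as the constrained
estimate — the convention used in the noisy-recovery benchmark, where the
*median* over seeds is the estimator. The "direct" mode inverts the
piecewise-linear uptake response through one secant anchored at GAME 10/20
and NGAME 1/5 (inside the physiologically typical, strictly sensitive
range) instead of iterating.

## Flux analyses

LPs are solved with scipy's HiGHS backend at feasibility/optimality
tolerances of 1e-9; every run is deterministic, and each optimal solution
can be audited against |S·v| ≤ 1e-6 and its bounds. The objective value is
the contract; flux vectors at degenerate optima are alternate solutions,
which FVA quantifies (default objective fraction 1.0). The MOMA reference
flux is the parsimonious wild-type solution (FBA followed by total-|v|
minimization), seed-free and deterministic. The MOMA QP itself is the
Euclidean projection of the reference onto the mutant polytope, computed by
ADMM over the null-space of S and the bound box (ρ = 2, tolerance 1e-10,
unique limit by strict convexity), cross-checked against closed-form
projections. Knockout rankings group production rates equal within 1e-6
into one priority class. Production envelopes fix growth at k/(n−1) of the
model's own optimum; points infeasible at low growth (the fixed maintenance
flux cannot be paid at zero catabolism) are reported as NaN rather than
silently dropped.

## Gas-sweep sensitivity statistic

On the default symmetric grid (H₂ and CO₂ from 0 to 20 in 21 steps,
O₂ = 10), whichever gas is stoichiometrically cheaper per unit growth binds
over more grid area; since fixing one CO₂ requires ≥ 2 H₂ of reducing power
(≈3.5 with ATP costs), an area-weighted mean derivative is dominated by H₂
for any feasible Calvin-cycle stoichiometry — a property of the grid
geometry, not of the gases' marginal value. `gas_sensitivities` therefore
reports both statistics: the unconditional grid mean and the mean response
*where the gas is limiting* (nonzero finite difference). The latter is the
marginal value of one mmol of gas where it is scarce and is the quantity
behind the observation that lithoautotrophic growth responds more strongly
to the CO₂/O₂ ratio than to the H₂/O₂ ratio; on the core model it favors
CO₂ by ≈3–5×.

## Numerical conventions

Default bounds ±1000 (reversible) or [0, 1000] mmol·gDCW⁻¹·h⁻¹; exchange
convention: negative lower bound = uptake allowed, uptake rates reported as
positive magnitudes. Numbers are serialized with 12 significant digits.
GPR rules use uppercase AND/OR with parentheses and case-insensitive gene
tokens. Unique-reaction counts deduplicate identical stoichiometries after
sorting metabolite ids and normalizing direction. Problem sizes used by the
benchmark runs — 20 random ≤8-reaction models for the LP oracle, 40–100
seeds for noisy calibration, 21-point sweep grids, 11-point envelopes —
were chosen as the package's own defaults and match the study design where
one is stated (dilution rates 0.05/0.07/0.10 h⁻¹, fructose cap 2.6,
nitrogen 0–3, O₂ = 10).

## Known limitations

* The core model's absolute rates (growth 0.32 h⁻¹ at fructose 2.6, mutant
  growth 66 % of wild type, C/N optimum ≈1.9) are fixture properties, not
  genome-scale predictions.
* pH variants are deliberately near-equivalent in flux space; pH-dependent
  *yield* differences require the full reconstruction's proton
  stoichiometry.
* MOMA's ADMM solver is exact only in the limit; tolerances are set so the
  residual error is ≤1e-6 on problems of this size, and the toy-model
  cross-checks pin it down.
* The SBML export drops the fractional-composition biomass formula (FBC
  requires integer formulas); stoichiometry, bounds, GPRs and the objective
  round-trip exactly.
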