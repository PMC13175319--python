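# Methods

## Constraint-based model and FBA

A model is a stoichiometric matrix **S** (metabolites × reactions), flux
bounds l ≤ v ≤ u (mmol·gDW⁻¹·h⁻¹) and a linear objective c·v. FBA solves
max c·v s.t. **S**·v = 0, l ≤ v ≤ u as an LP (scipy's HiGHS interface, primal
feasibility tolerance 1e-9; campaign tables are written to 6 decimals).
Exchange reactions are written `met_e →`, so negative flux is uptake; default
bounds are (0, 1000) for irreversible and (−1000, 1000) for reversible
reactions; compartments are limited to cytosol (`_c`) and extracellular
(`_e`). Gene deletions act through boolean GPR rules (AND binds tighter than
OR); a reaction whose rule evaluates false gets both bounds set to zero.
Deleting a gene the model does not contain is a warned no-op.

FBA optima are generically degenerate, so no biological claim in this package
rests on the particular vertex a solve returns: claims about individual fluxes
go through flux variability analysis (FVA), the per-reaction min/max flux with
the objective held at a fraction of its optimum. The optimum is held with a
relative slack of 1e-6, so an "exactly zero" FVA range is zero up to that
slack (tests use 1e-4 as the numerical meaning of "pinned to zero").

For networks of at most 12 reactions with finite bounds,
`enumerate_vertices_oracle` computes the optimum independently of any LP
solver by enumerating basic solutions: with r = rank(S), every choice of
n − r coordinates fixed at a bound and each feasible solution of the remaining
square system is visited. Finite bounds make the polytope bounded, so a
nonempty feasible set has a vertex and the optimum is attained at one. The
test suite requires solver/oracle agreement to 1e-6 on 100 seeded toy chains
and on reduced campaign scenarios; cobrapy (with its own solver stack) serves
as a second, independent cross-check on the full mini-core.

## The mini-core host

The bundled host emulates the functional blocks of the *E. coli* core model
that the fuculose question exercises, with lumped stoichiometry:

| reaction | stoichiometry | note |
|---|---|---|
| GLYC_UP | glc + 2 atp → dhap + g3p + 2 adp | upper glycolysis, DHAP/G3P split |
| TPI | dhap ⇌ g3p (gene *tpiA*) | the DHAP drain the Fuc 2 design removes |
| GLYC_LO | g3p + 2 adp + nad → pyr + 2 atp + nadh | |
| RESP | nadh + ½ o2 + 2 adp → nad + 2 atp | P/O ratio 2, configurable |
| LDH / ACK | pyr + nadh → lac + nad; pyr + adp → ac + atp | fermentative overflow |
| BIOMASS | pyr + 10 atp → 10 adp + biomass | growth objective |
| ATPM | atp → adp, lower bound 1 | maintenance demand |

plus transport/exchange for glucose (uptake bound −10), oxygen (−20), acetate,
lactate and biomass. Water and inorganic phosphate are also present as freely
exchanged species: the lumped core reactions do not need them, but the
phosphatase step of the added pathway does, and including them lets every
added reaction be elementally balanced. They couple to nothing else, so no
flux result depends on them. Defaults (glc 10 : LAD 5 : O₂ 20, maintenance 1)
are the study conditions used by every campaign and test; all are overridable
through `MiniCoreSpec`.

The lumped host reactions elide CO₂/water and deliberately carry no elemental
formulas, so the mass-balance checker skips them; the checker fully verifies
the fucose pathway, whose species all carry formulas (LAD C3H6O2, DHAP
C3H7O6P, fuculose-1-phosphate C6H13O8P, L-fuculose/L-fucose C6H12O5, 1,2-PDO
C3H8O2, lactate C3H6O3). Cofactor pairs are balanced by their net difference
(NADH−NAD = H2, ATP−ADP = HPO3) so carriers without full structures can still
be checked.

A deliberate feature of the lumped scheme: the bare host cannot grow
anaerobically (LDH, its only anaerobic NADH sink, consumes one pyruvate per
NADH), while the extended model can, because FucO's LAD → 1,2-PDO reduction
supplies the missing electron sink. This is what makes the anaerobic routing
result sharp: at the anaerobic growth optimum (24/11 flux units from
11·μ = 2·glc + lad − maintenance), LAD uptake is forced to its bound with all
of it reduced to 1,2-PDO, and the fuculose exchange range is (0, 0).

## Pathway extension

`extend_with_fuculose_pathway` adds, with all toggles on, 14 reactions: LAD
uptake (LADt, EX_lad, default bound −5), the reversible FucA aldolase FCPA
(dhap + lad ⇌ fc1p; reversible because slow dephosphorylation can push the
condensation backwards), the innate phosphatase FCP (fc1p + h2o → fcl + pi;
water/phosphate omitted if the host lacks them), the FucK kinase FCLK, the
FucI isomerase FUCI with fucose transport/exchange (an isomerase with no
product exit could never carry steady-state flux, so the exporter comes with
it), the reversible FucO oxidoreductase, the AldA dehydrogenase, and
secretion-only transport/exchange for L-fuculose and 1,2-PDO. Each of the five
pathway genes maps to exactly one reaction. FucA overexpression is represented
only by FCPA being present at default capacity — FBA has no notion of
expression level, so "overexpression" cannot scale a flux bound in any
principled way. The extension is non-destructive and id-collision-checked;
"L-fuculose production" is realized as the exchange EX_fcl, the boundary
reaction that lets FBA carry net product flux.

## Campaign protocols

Production is always strictly growth-suboptimal in these models (every mole of
DHAP routed to fuculose forgoes ATP), so a plain max-growth FBA shows zero
product everywhere. The envelopes are therefore computed in two steps:
maximize growth, then maximize product secretion subject to a growth floor.

The floor is **fixed across a grid** at `biomass_fraction` (default 0.5) × the
maximum growth under the model's as-configured reference condition (aerobic,
glucose-replete by default). A per-grid-point floor was considered and
rejected: because an ATP- and redox-neutral fuculose route exists anaerobically
(glc → DHAP + G3P; G3P → pyr + NADH; NADH sunk by LDH; DHAP + LAD → fuculose),
a floor that shrinks with the per-point optimum would report positive
anaerobic production at any fraction < 1, and at fraction = 1 the aerobic
envelope collapses to zero as well. The fixed floor reads as the intended
trade-off: "how much product can the strain make while still achieving half of
its normal growth?" — unreachable without oxygen (reported as 0 with status
`growth_infeasible`), and it makes monotonicity rigorous, since relaxing an
uptake bound only enlarges a feasible set measured against a constant floor.
Under it, the substrate scan turns production on exactly when glucose uptake
reaches the LAD supply (−5 of −5), i.e. glucose must at least match
lactaldehyde.

Grids: O₂ 0 to −20 in steps of −2; glucose {0, −1, −2.5, −5, −10} at LAD −5.
Within the redox-scenario tables, FVA is run at 100 % of the growth optimum;
the per-scenario product maximum uses that scenario's own half-max growth
(reported for context, not for cross-scenario comparison). The strain series
uses each strain's own half-max growth, since the comparison there is between
genotypes, not conditions. Campaigns are pure functions of (model, config,
grid); CSVs are written with fixed formatting and are byte-identical across
reruns.

## Fermentation metrics and the synthetic generator

Titer is the maximum observed product concentration (an endpoint mode exists;
max is robust to late-phase degradation). Substrate consumption is first
present LAD − minimum present LAD. Molar yield is
100 × (titer / 164.16 g·mol⁻¹) / consumed LAD (mM); the consumed-LAD molar
basis is this package's explicit definition — published percentage yields
computed with unstated denominators are not reproduced or asserted. Missing
values ("ND", blanks) are excluded, never imputed. Fold improvement is a plain
titer ratio reported to 3 significant figures.

The generator emulates the observed course structure: logistic OD600 reaching
stationary phase by ~24 h (K = 5, r = 0.25 h⁻¹), glucose draw-down coupled to
growth, LAD declining linearly to zero at 84 h (complete consumption after
72 h, inside a 96 h run sampled at 0/12/24/36/48/72/96 h), 1,2-PDO at 0.8 mol
per mol LAD consumed, and product = yield × consumed LAD × 164.16 mg/L.
Measurement noise is Gaussian: σ (mg/L) on the product and σ/164.16 (mM) on
LAD, negative values clipped at zero. Noise-free output inverts exactly
through `summarize_fermentation` (the parameter-recovery oracle); with σ = 2
mg/L the titer-max statistic carries a small positive selection bias
(second-highest noise-free point sits ~4σ below the maximum), so the mean
recovered yield stays well within 5 % of truth. What these curves do not
emulate: growth–production coupling, DHAP toxicity (the observed Fuc 2
defect), pH/aeration effects, or replicate-level variance structure — passing
recovery tests validate the metric arithmetic, not fermentation biology.

## Numerical choices and degenerate inputs

LP status maps: infeasible and unbounded are reported as such, never raised,
except where an operation needs a base optimum (FVA propagates infeasibility
as an error). FVA min/max pairs are averaged if solver jitter inverts them
(only possible on a fixed flux). The oracle refuses networks over 12 reactions
or with infinite bounds. Zero consumed substrate yields 0 % for a zero titer
and NaN otherwise. Grid values must be non-positive (they are uptake lower
bounds); empty grids are rejected.

## Known limitations

* The mini-core is a functional emulation, not the published core model; flux
  values are in arbitrary "flux units" and match no laboratory rates. Loading
  a real BiGG-dialect core model is supported but not bundled.
* FBA predicts flux capabilities, not batch titers: the published strain
  titers (38.92 / 32.15 / 45.30 / 50.25 mg/L) enter only as inputs to the
  fold-improvement arithmetic. In particular, the experimental strain ranking
  (Fuc 4 > Fuc 3 > Fuc 1 > Fuc 2) is not predicted — Fuc 2's defect is
  attributed to DHAP toxicity, which a stoichiometric model cannot represent.
* Kinetics, expression levels, and the fucose/fuculose isomerase equilibrium
  are out of scope; FucI/FucK/AldA presence is toggleable because different
  reconstructions disagree on which of them to include.
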