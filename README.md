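# fucsim — in-silico strain design for L-fuculose production in *E. coli*

L-Fuculose is a rare deoxyketohexose of interest to the cosmetic and
functional-food industries, present only in traces in nature. A practical
route to it is a microbial cell factory: *E. coli* overexpressing the
fuculose-1-phosphate aldolase FucA condenses lactaldehyde (LAD) with
dihydroxyacetone phosphate (DHAP) into L-fuculose-1-phosphate, which innate
sugar phosphatases dephosphorylate to L-fuculose. The design question is where
the carbon actually goes: FucO drains LAD to 1,2-propanediol, AldA to lactate,
TpiA pulls DHAP into glycolysis, and FucI/FucK drain the product itself.

`fucsim` is an analysis package that answers that question with constraint-
based modeling. It implements flux balance analysis (FBA) — maximize c·v
subject to steady-state mass balance **S**·v = 0 and bounds l ≤ v ≤ u, fluxes
in mmol·gDW⁻¹·h⁻¹ — plus flux variability analysis (FVA) to make claims that
are robust to degenerate optima, gene-deletion simulation through boolean
gene–protein–reaction (GPR) rules, and a set of simulation campaigns:

* **redox scenarios** — aerobic vs anaerobic flux tables;
* **oxygen sweep** — growth and L-fuculose envelopes across O₂-uptake bounds;
* **substrate scan** — the glucose:LAD ratio needed to sustain production;
* **strain series** — the Fuc 1–4 knockout genotypes
  (ΔfucI ΔfucK → +ΔtpiA → +ΔfucO → +ΔaldA);
* **fermentation metrics** — titer, substrate consumption, molar yield and
  fold improvement from time-course tables.

It is aimed at metabolic engineers who want the strain-design reasoning to be
reproducible and testable: every input is generated in-code (a bundled
"mini-core" network emulating the *E. coli* core model's functional blocks,
seeded toy LPs with enumerable optima, synthetic fermentation curves), and any
real BiGG-dialect JSON core model loads through the same reader.

## Worked example

```python
from fucsim import (build_extended_mini_core, run_redox_scenarios,
                    oxygen_sweep, fold_improvement)

model = build_extended_mini_core()          # mini-core + fuculose pathway
scenarios = run_redox_scenarios(model)
print(scenarios["anaerobic"].table.set_index("reaction").round(4))
```

```
          flux  fva_min  fva_max
reaction
EX_fcl    -0.0     -0.0      0.0
EX_lad    -5.0     -5.0     -5.0
EX_pdo     5.0      5.0      5.0
FUCO       5.0      5.0      5.0
FCPA      -0.0     -0.0      0.0
ALDA       0.0      0.0      0.0
```

Anaerobically, the full 5 mmol·gDW⁻¹·h⁻¹ of lactaldehyde uptake (EX_lad = −5)
is matched by 1,2-PDO secretion (EX_pdo = 5) through FucO — the cell's only
anaerobic electron sink — and the L-fuculose exchange range collapses to
(0, 0): no production without oxygen. The oxygen sweep shows the flip side:

```python
print(oxygen_sweep(model)[["o2_lower_bound", "max_growth", "max_fuculose"]])
```

growth rises from 2.18 (anaerobic) to 8.09 (fully aerobic) and the fuculose
envelope from 0 to its LAD-limited plateau of 5. The fermentation arithmetic
uses published titers as plain inputs:

```python
fold_improvement(50.25, 1.55)   # -> 32.4  (final strain vs prior platform)
```

The numbered scripts under `analysis/` run each campaign end to end and write
their tables to `results/` (`python analysis/02_redox_scenarios.py`, …). The
`fucsim` command line exposes the same steps
(`fucsim build-model`, `sweep-o2`, `scan-substrate`, `strains`, `metrics`,
`synth`); see `fucsim --help`.

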