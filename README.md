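# paretoflux

Multi-objective flux analysis for constraint-based metabolic models:
mapping the n-dimensional Pareto front of competing cellular objectives
with the Normalized Normal Constraint (NNC) method on top of a flux
balance analysis (FBA) engine.

The package is aimed at systems biologists studying metabolic trade-offs —
for example, how a photoheterotrophic purple non-sulfur bacterium balances
growth, carbon efficiency, ATP production and hydrogen evolution when light,
not carbon, limits its metabolism, and what H₂ production costs the cell.
It provides:

- **FBA core** — steady-state linear programs `max c·v` s.t. `S·v = 0`,
  `α ≤ v ≤ β`, with parsimonious (min Σ|v|) refinement of alternate optima,
  flux variability analysis (FVA), absolute-value transport minimization,
  single-gene knockout scans over boolean GPR rules, and bisection fitting
  of an uptake bound to a measured growth rate.
- **MOFA/NNC** — n-objective Pareto fronts: per-objective anchor points
  ("archetypes"), scale-free normalization of objective space, an even
  simplex lattice on the utopia hyperplane (spacing 1/m, `C(m+n−1, n−1)`
  points), one constrained LP per lattice point, and dominance filtering.
- **GX-FBA** — transcriptome-constrained flux prediction across an
  environmental transition, maximizing
  `Z = Σ_{i∈T} log₂(C_i) · v_i / v̄_i` over expression-mapped reactions.
- **Redox accounting** — Roels degree-of-reduction κ (electron equivalents
  per C-mole; CO₂ = 0, acetate = 4, biomass ≈ 4.2), element/charge balance
  checks for model reactions and lumped overall conversion equations, and
  boundary electron-balance audits of flux solutions.
- **Model I/O** — SBML Level 2/3 with the `fbc` package (via python-libsbml),
  a plain-TSV model dialect, YAML medium/objective configs.
- **A synthetic toy phototroph** — a 14-reaction, hand-checkable network
  with light-driven ATP supply, two CO₂-fixation routes of different ATP
  cost, a nitrogenase-like H₂ valve and a reduced-byproduct export, used
  throughout the test suite.

## Worked example

```python
import paretoflux as pf

toy = pf.make_toy(P=50, A=10)          # photon cap 50, acetate cap 10 mmol/gDW/h
growth = pf.FluxObjective.for_reaction("EX_biomass", label="growth")
h2 = pf.FluxObjective.for_reaction("EX_h2", label="h2")

sol = pf.fba(toy, growth)
print(sol.objective_value, sol["EX_h2"])        # 1.0 9.0
print(pf.boundary_electron_balance(toy, sol))   # 0.0

front = pf.run_mofa(pf.MofaProblem(toy, [growth, h2], spacing=10))
for pt in front.solutions[:3]:
    print(pt.objective_values)                  # [ 0. 20.] [ 0.1 18.9] [ 0.2 17.8]
```

The carbon-limited growth optimum converts all ten acetate carbons into one
biomass unit; electron balance then forces the nine excess reducing
equivalents out through the H₂ valve (9.0), and the boundary electron audit
closes to zero. The two-objective front runs from the H₂ archetype
(growth 0, H₂ 20 — complete oxidation of the substrate, two H₂ per
acetate carbon) to the growth archetype (growth 1, H₂ 9): every unit of H₂
beyond the growth archetype's level costs growth, and maximum H₂ stops
growth entirely.

κ arithmetic:

```python
pf.degree_of_reduction(pf.parse_formula("CH1.93O0.54N0.22"))  # 4.19
pf.degree_of_reduction(pf.parse_formula("C2H4O2"))            # 4.0  (acetate)
```

## Command line

```sh
paretoflux fixtures write-toy --out toy.tsv
paretoflux fba --model toy.tsv
paretoflux mofa --model toy.tsv --objectives obj.yaml --spacing 10 --out front.tsv
paretoflux balance --equation "CH1.5O + 0.05 H+ + 0.17 NH4+ -> 0.76 CH1.93O0.54N0.22 + 0.29 H2O + 0.06 CO2 + 0.18 CHO"
paretoflux gxfba --model m.xml --medium1 a.yaml --medium2 b.yaml --expr fc.tsv
```

Every file-producing command writes a manifest JSON (inputs hashed, solver
id, tolerances) next to its output; identical manifests imply identical
outputs.

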