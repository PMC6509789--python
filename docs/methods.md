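# Methods

## Constraint-based model and FBA

A metabolic network is represented by its stoichiometric matrix `S`
(m metabolites × n reactions). Under the steady-state assumption every
internal metabolite balances, `Σ_j S_ij v_j = 0`, and each flux is bounded,
`α_i ≤ v_i ≤ β_i` (mmol·gDW⁻¹·h⁻¹; the biomass flux is the specific growth
rate μ in h⁻¹, doubling time ln 2 / μ). FBA maximizes a linear objective
over this polytope. All LPs are solved with HiGHS through scipy, behind a
single internal interface (`paretoflux.lp`); numerical conventions are a
primal feasibility tolerance of 1e-9 and a zero-flux threshold of 1e-9.

Exchange reactions are single-metabolite reactions written `met →`, so
positive flux is export and uptake is a negative flux; medium configs may
state `uptake_max: x`, which translates to a lower bound of −x. "Unlimited"
capacities are encoded as a finite big-M of 1e6 so every LP stays bounded.
Non-growth-associated maintenance ATP is modeled, when a model declares a
maintenance reaction, as a fixed lower bound (conventionally
7.6 mmol·gDW⁻¹·h⁻¹, overridable per config); varying it is absorbed by the
light-absorption flux in phototrophic models, so the bundled toy omits it.

**Alternate optima.** FBA optima are usually degenerate in individual
fluxes. Every reported flux vector is therefore refined lexicographically:
the objective is fixed at its optimum and the total absolute flux Σ|v| is
minimized (auxiliary variables s_j ≥ |v_j|; an exact LP, no integer terms).
Route-level claims (e.g. which CO₂-fixation pathway carries flux) should be
read as properties of this parsimonious representative; where a range is the
honest answer, FVA provides it. The same split-variable construction gives
the nutrient-allocation objective, minimization of Σ|v| over exchange
reactions only, optionally with fluxes pinned (e.g. growth at its optimum).

**Knockouts.** GPR rules are boolean expressions over gene ids (AND =
enzyme complex, OR = isozymes), parsed by a small recursive-descent parser.
A gene knockout disables every reaction whose rule evaluates false, the LP
is re-solved, and genes with optima below 1e-9 are flagged essential.

**Uptake fitting.** `fit_uptake_to_target` assumes the FBA optimum is
monotone non-decreasing in the dialed uptake capacity (true for any relaxed
bound by LP duality) and bisects the capacity until the optimum matches a
target, e.g. a measured growth rate expressed as ln 2 / doubling time.

## Multi-objective flux analysis (NNC)

Trade-offs among n ≥ 2 flux objectives are mapped with the Normalized
Normal Constraint method:

1. **Anchors.** Each objective is optimized alone (with parsimonious
   refinement); anchor k's full objective vector is recorded. Anchors are
   the single-task archetypes of the system.
2. **Normalization.** Objectives are converted to maximization sense
   (minimization objectives negated) and affinely mapped so the best anchor
   value (utopia component) is 1 and the worst over anchors (nadir) is 0.
   Anchor k attains 1 in its own coordinate; the front is thereby
   independent of objective scales and units. A degenerate span
   (objective constant across anchors) falls back to a unit denominator.
3. **Lattice.** Weight vectors w on the (n−1)-simplex with steps of 1/m
   (`C(m+n−1, n−1)` points, deterministic lexicographic order) place evenly
   spaced points p = Σ w_k ē_k on the utopia hyperplane spanned by the
   normalized anchors ē_k.
4. **Per-point LPs.** At each p the n−1 half-spaces
   (ē_n − ē_k)·(z̄ − p) ≤ 0 (k < n) are added in normalized objective space
   — each is a linear constraint on fluxes — and the last declared
   objective is maximized, then refined. This is the canonical Messac
   normal constraint transformed to maximization sense (z̄ = 1 − μ̄ against
   the minimization form); the inequality direction is what makes corner
   weights reproduce the anchors exactly. Infeasible lattice points are
   expected for non-convex reachable sets and are recorded, not fatal.
5. **Filtering.** Duplicates (normalized vectors equal after rounding to
   6 decimals) and dominated points (componentwise ≥ with one coordinate
   > 1e-6 better) are removed in stable order.

Unique-solution counts depend on the rounding/dominance conventions above
and on solver vertex selection; they are reported for orientation, not as
reproducible statistics. A full 8-objective, spacing-10 study is 19 448 LPs;
the `--spacing` flag scales fronts down (spacing 2–5) where a coarse map
suffices, and the test suite uses spacings 2–10 on the toy.

## GX-FBA

Flux prediction across an environment/carbon-source transition from
relative transcript changes:

1. the pre-transition condition is solved for a reference flux ν¹, using
   the parsimonious refinement as a reproducible centered representative of
   the alternate optima (a true interior-point/barrier centering would also
   do, but is solver-dependent);
2. FVA under the post-transition constraints, with the biomass floor at
   zero, yields each reaction's envelope [v_min, v_max], its mean capacity
   v̄_i = (v_min + v_max)/2, and the mean |v̄| over active reactions
   (envelope width > 1e-9), v̄^all;
3. log₂ fold changes map onto reactions through GPRs: changes below the
   threshold (default ±0.5 log₂, i.e. 50%) are ignored; among the rest the
   largest-magnitude value is used if all agree in sign, otherwise the
   reaction is excluded (set T);
4. Z = Σ_{i∈T} log₂(C_i) · v_i / v̄_i is maximized under the
   post-transition constraints. Where ν¹_i = 0 the denominator falls back
   to v̄^all; |v̄_i| is used for envelopes spanning zero, and reactions with
   |v̄_i| < 1e-9 are dropped from Z with a warning. An empty T is an error —
   there is nothing to constrain with.

## Degree of reduction and balance checks

κ (Roels) counts available electron equivalents per C-mole with valences
C = +4, H = +1, O = −2, N = −3, S = +6, P = +5, minus the net charge,
divided by the carbon count. Reference points: CO₂ = 0, acetate = 4 (on
either protonation), succinate = 3.5, α-ketoglutarate = 3.2, microbial
biomass ≈ 4.2; aromatic substrates are evaluated as neutral acids, which is
the convention under which coumarate, benzoate and 4-hydroxybenzoate
average κ = 4.17. κ is linear under carbon-weighted mixing, which the
property tests exercise.

The same numerator (without dividing by carbon) is the electron content of
any species — 2 for H₂, 0 for H₂O, NH₄⁺ and CO₂ by construction — and
summing electron content × flux over exchanges audits any steady-state
solution of an electron-balanced network: the residual must vanish.

Balance checking of lumped overall conversion equations (per-C-mole biomass
formulas such as CH₁.₉₃O₀.₅₄N₀.₂₂ are first-class: element counts are
real-valued) uses an absolute tolerance of 0.02 per element, matching
coefficients printed to two decimals; model-internal reactions use 1e-6.
`balanced` gates on element residuals only: two-decimal lumped equations
are routinely element-balanced while carrying a small net charge imbalance
(the H⁺ terms absorb hydrogen but not all charge bookkeeping), so the
charge residual is reported separately rather than failing the check. The
lumped "CHO" byproduct species is treated as an opaque {C:1, H:1, O:1}
formula for balance arithmetic only. Metabolites without formulas mark
their reactions "unchecked" (with a log note), never failed; massless
pseudo-metabolites (photons, lumped ATP-equivalent energy tokens) are
excluded from element and electron accounting by an explicit flag.

## The synthetic toy phototroph

`make_toy(P, A)` builds a 14-reaction network emulating the architecture of
anaerobic photoheterotrophic metabolism: a light-harvesting reaction
(photon → 2 ATP) decouples energy from carbon; acetate assimilation yields
cell carbon plus a reducing equivalent; two CO₂-fixation routes differ only
in ATP cost (3 vs 2, a CBB-like and a cheaper rTCA-like route); biosynthesis
consumes 10 carbon + 1 red + 15 ATP per biomass unit; an ATP-consuming
nitrogenase-like valve exports reducing equivalents as H₂; and a reduced
byproduct (κ = 4) can carry carbon plus electrons out. Defaults P = 50,
A = 10 put the model in the carbon-limited regime (growth 1.0) while
photon caps below 33 make it light-limited (growth 2P/33) — mirroring the
light-limited-then-carbon-limited behavior of phototrophic growth.

All coefficients are small integers, so every LP optimum in the test suite
has a hand-derivable closed form; every internal reaction is element- and
electron-balanced under the fixture formulas (acetate-carbon κ = 4,
cell-carbon κ = 2, byproduct κ = 4, H₂ carrier 2 e⁻).

What the toy does not emulate: realistic biomass composition, photon
physics and absorption spectra, maintenance ATP, proton/charge membrane
economy, and the combinatorial pathway redundancy of a genome-scale
network. Tests passing on the toy validate the algorithms (LP construction,
NNC geometry, electron bookkeeping, GPR semantics), not genome-scale
predictions; applying the bundled scenario ladder to a real reconstruction
requires the user to supply that model and a role/name map for its
identifiers.

One structural consequence worth noting: because the toy's only electron
sinks are biomass, byproduct and H₂, electron balance ties H₂ export to
9× growth at every maximum-growth solution — the growth archetype itself
exports H₂. The biomass-vs-H₂ Pareto front is therefore the segment from
(growth 1, H₂ 9) to (growth 0, H₂ 20): H₂ beyond the archetype's level
strictly costs growth, and maximal H₂ stops growth entirely.

## Scenario configs

`paper_scenarios()` encodes a reusable condition ladder for
photoheterotrophic acetate growth: substrate uptake fixed at
1.96 mmol·gDW⁻¹·h⁻¹; CO₂ export pinned at 0.23 mmol·gDW⁻¹·h⁻¹; the CBB
route knocked out; the fitted light-limited photon uptake of
36.6 mmol·gDW⁻¹·h⁻¹; reduced-byproduct export blocked; H₂ maximization;
and a nitrogen-starvation storage-polymer variant. Scenarios name reactions
by *role* (`acetate_exchange`, `rubisco`, …) and are resolved against a
concrete model through a name map, so the same configs drive the toy and a
genome-scale SBML reconstruction.

## Known limitations

- No thermodynamic loop-law handling: parsimonious refinement suppresses
  futile cycles in practice but does not prove their absence.
- GX-FBA implements the Z-objective formulation only; no expression-derived
  hard flux bounds.
- pKa-resolved proton speciation is out of scope; charge residuals of
  lumped equations are informational.
- SBML writing targets L3V1+fbc2; legacy L2 files are read (kinetic-law
  bounds or a sidecar YAML) but not written.
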