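# Methods

## The model

`warconj` simulates interference competition between bacterial strains in a
well-mixed batch environment when the weapon itself — a toxin/immunity
module carried on a conjugative plasmid — can move horizontally into the
strain it is meant to kill. Three populations are tracked: an attacker
`C1` carrying the plasmid, a sensitive target `C2`, and transconjugants
`C3` (former targets that received the plasmid, now immune toxin
producers and themselves donors), together with a free toxin pool `T` and
up to three nutrient pools.

The default model couples all strains through a single shared nutrient
`N1` with Monod uptake `M1 = N1/(N1 + KN1)`:

    dC1/dt = C1 rC1 M1 (1 − γ)
    dC2/dt = C2 rC2 M1 − b C2 (C1 M1 + C3 M1) − E C2 T/(T + KC2T)
    dC3/dt = C3 rC3 M1 (1 − γ) + b C2 (C1 M1 + C3 M1)
    dT/dt  = γ M1 (C1 + C3) − C2 T/(T + KC2T)
    dN1/dt = − M1 (C1 + C2 + C3)

Assumptions worth making explicit:

- **Toxin–target interaction** is a Hill function with coefficient fixed
  at 1 — functionally a second Monod term. The killing term carries the
  potency factor `E`; the toxin-absorption term in `dT/dt` does not
  (targets titrate toxin at the saturating rate itself). The Hill
  coefficient is deliberately not a parameter; generalizing it is a
  non-goal.
- **Conjugation is nutrient-gated**: transfer requires an active donor, so
  the term `b C2 (C1 + C3) M` scales with the donor's uptake factor and
  shuts off as nutrients deplete. Carrying the plasmid costs nothing;
  producing toxin costs a fraction `γ` of growth.
- **Closed batch**: nutrients only deplete, so every trajectory approaches
  a fixed point. There is no mortality other than toxin killing, no
  spatial structure, no stochasticity, no plasmid loss, no resistance
  evolution, and no helper-plasmid dynamics (the plasmid is modelled as
  self-transmissible).

The metabolic-diversity model adds private nutrients — `N2` usable only by
the attacker, `N3` only by the target lineage — by summing the accessible
Monod terms in every growth, production and conjugation factor (attacker
factor `M1 + M2`, target-lineage factor `M1 + M3`) and depleting each
private pool by its consumers only. With `N2 = N3 = 0` this reduces
*exactly* (bit-for-bit, not just approximately) to the default model,
which the test suite exploits. The `two_nutrient` variant is the same
right-hand side started from `N2 = 0, N3 = 0.25`, modelling a private pool
for the target lineage alone, sized to keep maximum realized growth rates
comparable across strains.

## Parameters

All quantities live on one dimensionless mass scale; no unit conversions
are applied anywhere.

| symbol | meaning | default |
|---|---|---|
| `rC1, rC2, rC3` | maximum intrinsic growth rates (1/time) | 1 |
| `KN1, KN2, KN3` | Monod saturation constants | 5 |
| `E` | toxin killing efficiency (potency) | 10 |
| `b` | conjugation rate | 0.25 |
| `gamma` | fractional investment in toxin production | 0.15 |
| `KC2T` | toxin–target affinity | 1.0 |
| `C1(0), C2(0), C3(0)` | initial biomasses | 0.01, 0.01, 0 |
| `N1(0)` | shared nutrient | 1.0 |
| `N2(0), N3(0)` | private nutrients (metabolic variant) | 1.0, 1.0 |
| `T(0)` | toxin | 0 |

With `KN = 5` and `N(0) = 1`, uptake starts at `M1 = 1/6` — strains grow
well below their maximal rate throughout, and roughly 50 time units
deplete the pool at default rates.

## Scenarios

Three presets mirror the experimental contrasts the model is built to
inform: `killing_only` (`b = 0`), `transfer_only` (`E = 0`), and
`killing_and_transfer` (no overrides). One genuine ambiguity: should a
transfer-only contest still *produce* the (harmless) toxin? By default the
package keeps `γ` at its configured value so that `transfer_only` changes
exactly one thing relative to the full model. The alternative convention
(`zero_gamma_in_transfer_only=True`) also sets `γ = 0`. The choice is
consequential in one place: with `γ` retained, toxin production is a pure
cost paid by attackers and transconjugants but not targets, so
transfer-only outcomes drift slightly with niche separation; with `γ = 0`
the attacker and target lineages are exactly symmetric and the
niche-separation sweep is frequency-invariant to machine precision. The
separation-invariance check therefore uses the `zero_gamma` convention;
everything else uses the default.

## Numerics

- **Integrator**: LSODA via `scipy.integrate.solve_ivp`, `rtol = 1e-8`,
  `atol = 1e-10`. The killing term makes the system moderately stiff near
  target extinction.
- **Steady state** is not defined analytically anywhere in the model, so
  the package defines it operationally: integration halts when the
  infinity-norm of the derivative vector drops below `1e-8` (a terminal
  event evaluated on the solver's natural steps), with a fallback horizon
  of `t_max = 5000` time units — two orders beyond the depletion timescale
  at default rates. Non-convergent runs are reported `converged=False`,
  never silently truncated. At the default table every scenario × variant
  combination converges between t ≈ 75 and t ≈ 150.
- **Negative overshoot**: adaptive trial steps can dip microscopically
  below zero. Inside the integrator, negative components are evaluated as
  zero; at the API boundary, values in `[−1e−9, 0)` are clamped and
  anything more negative is rejected. Stored trajectories are clamped
  non-negative.
- **Extinction** is a reporting threshold only: a strain with final
  frequency below `1e-6` is flagged extinct; the ODEs never reach exact
  zero on their own (structural zeros like `C3 ≡ 0` when `b = 0` excepted).
- **Verification oracle**: an independent classical RK4 integrator at
  fixed step (`dt = 1e-3` by default) that shares the right-hand sides but
  no stepping logic with the main path, and refuses to return unless
  halving its step moves the endpoint by less than `1e-7` relative. The
  two integrators agree at converged endpoints to better than `1e-5`
  relative on every component, where components below `1e-4` in magnitude
  (numerically extinct pools, three orders below the extinction threshold)
  are compared absolutely at `1e-9` — a strict relative comparison is
  meaningless for a pool that has decayed to `1e-9` under `atol = 1e-10`.
- **Mass ledger**: summing all derivatives collapses to
  `Σᵢ Cᵢ Gᵢ (rᵢ(1−γᵢ) + γᵢ − 1) − (E+1)·C2·T/(T+KC2T)` (with `Gᵢ` the
  strain's total uptake factor and `γᵢ = γ` for producers, 0 for targets);
  at unit growth rates only the toxin-mediated loss term survives. The
  closed form is re-derived symbolically with sympy in the test suite and
  its residual is checked to `1e-12` on random states, which catches any
  sign or factor error in a single term of the right-hand sides.

## Sweeps

Sweep grids evaluate one independent competition per cell, so results are
order-independent and reproducible cell-by-cell from the recorded
provenance (each cell stores its complete parameter table and initial
state). Published axis ranges for the heatmap figures are not fixed by the
model itself; the package defaults to `b ∈ [0, 1]` (21 linear steps) and
`E ∈ [0.1, 50]` (21 log steps), bracketing the default `(b, E) = (0.25,
10)` with structure visible on both sides, and they are fully
configurable. Frequency presets hold total inoculum at `0.02` (the default
`C1 + C2`) and are parameterized by the target's initial share `f_target`
(attacker share `1 − f_target`, no initial transconjugants); the density
axis of the density × frequency sweep overrides the total. The
niche-separation sweep holds `N1 + N2 + N3 = 3.0` with `N2 = N3` and moves
from fully shared (`N1 = 3`) to fully private (`N2 = N3 = 1.5`); its
leftmost cell reduces exactly to the default model at `N1 = 3`.

## What the defaults show

At the default table the simulations reproduce the model's qualitative
story: killing alone drives the target extinct and leaves a pure attacker
population; transfer alone preserves all three genotypes (transconjugant
frequency ≈ 0.056); combining killing with transfer still yields
transconjugants but at a markedly lower frequency (≈ 0.041), because
toxin-killed targets cannot be converted; metabolic diversity multiplies
the transconjugant endpoint about eightfold (≈ 0.339), since a private
nutrient lets converted targets grow free of attacker competition; and the
transconjugant endpoint rises monotonically with niche separation (0.096
at full overlap to 0.452 at full separation, total nutrients fixed). These
numbers are recomputed, not asserted, by the test suite and
`scripts/acceptance.py`.

## Limitations

The model is phenomenological: biomass, nutrient and toxin scales are
arbitrary, so outputs are frequencies and orderings, not CFU counts.
Batch closure means no steady nutrient supply, migration or dilution;
predictions concern single contests, not serial passage. Well-mixedness
ignores the spatial refuges that matter on surfaces. No resistance
evolution is modelled, although de novo resistance is a prominent escape
route in real competitions. The fixed-step oracle is a verification tool,
not a fast path — it is orders of magnitude slower than the adaptive
integrator by design.
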