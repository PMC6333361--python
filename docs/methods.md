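# Methods

## The mass-balance model

`trophicnet` implements the steady-state trophic mass balance used
throughout the Ecopath modelling tradition. For every living functional
group *i*:

```
B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC_ij + Y_i + NM_i + BA_i
```

Production used inside the system (left side; `EE` is the ecotrophic
efficiency) equals predation by all consumers *j*, plus fishery removals
`Y` (landings + discards), net migration `NM` (emigration −
immigration, may be negative), and biomass accumulation `BA`.
Assumptions inherited from this model family:

- the web is at steady state over the reference year; `BA` defaults to 0
  and `Z = P/B` is each group's total mortality;
- producers do not respire in the budget (their losses are unconsumed
  production) and have no `Q/B`; bacteria are ordinary consumers of
  detritus;
- a consumer's intake splits as `Q = P + R + U`, with unassimilated
  fraction `U = GS·Q` (default `GS = 0.2`) and respiration `R` defined
  as the remainder; negative `R` is flagged, not raised;
- detritus pools are non-living: they receive every group's
  unassimilated food and non-predation mortality according to a fate
  matrix, plus discards, and lose mass only to detritivory; the
  remainder is export (negative export = unsourced consumption, a
  warning).

### Solver

With exactly one unknown per living group — its `B` or its `EE` — the
master equations are linear in the unknown vector: an unknown `EE_i`
carries coefficient `B_i·PB_i`, an unknown `B_j` carries `PB_j·EE_j` on
its own production side and `−QB_j·DC_ij` inside each prey's predation
sum. The square system is solved by dense LU (`numpy.linalg.solve`); if
rank-deficient, the minimum-norm least-squares solution is reported
with a rank warning, and an inconsistent system (residual > 1e-6) is an
error naming the worst-fitting groups. Groups with both `B` and `EE`
supplied contribute no equation; their master-equation residual is
reported in the diagnostics so over-determined input can be audited.
Post-solve, every living group's residual must be below 1e-8
t·km⁻²·yr⁻¹ or it is flagged. `EE` outside [0, 1] is a diagnostic, not
an exception: balancing real models is iterative and the user needs to
see the failure pattern.

### Trophic levels and omnivory

`TL = 1` for producers and detritus; consumers solve
`TL_j = 1 + Σ_i DC'_ij·TL_i` as one linear system (verified in the
tests against fixed-point iteration). Two conventions govern the diet
fraction imported from outside the system:

- `renormalize` (default): imports are excluded and the in-system diet
  renormalized — equivalent to assigning imported food the consumer's
  mean in-system prey TL. This keeps a migratory predator that feeds
  70 % outside the area at the trophic position its local diet implies.
- `import_tl_one`: imported food counts as TL-1 material, dragging
  heavy importers toward TL 2.

A consumer with no in-system diet at all gets TL 2 by convention, with
a warning. The omnivory index is the diet-weighted variance of prey TL,
`OI_j = Σ_i DC'_ij (TL_i − (TL_j − 1))²`, under the same import
convention; the system omnivory index averages OI over consumers with
weights `ln Q_j`, guarded as `ln(1+Q_j)` when `Q_j ≤ 1` t·km⁻²·yr⁻¹ so
weights stay positive.

### System totals

Total system throughput is consumption + exports + respiration + flows
into detritus. Exports comprise landings (discards are routed to
detritus instead), net detritus export, and `NM + BA` of living groups.
`PP/R` is reported as `inf` for webs without respiring consumers.

## Mixed Trophic Impact

Components are the groups in model order followed by the fleets. The
direct net impact of *i* on *j* is `q_ij = d_ji − f_ij`:

- `d_ji` — fraction of *j*'s intake supplied by *i*: the raw diet
  fraction for consumers (imports make columns sum below 1), catch
  composition for fleets, inflow composition (including fleet discards)
  for detritus pools;
- `f_ij` — fraction of the total removal of *j* (all predation plus
  all catches; other mortality `M0` excluded) attributable to consumer
  or fleet *i*. Nothing removes a fleet, and detritivory does not harm
  detritus, so neither receives negative terms.

The diagonal of `q` is zeroed (self-impacts excluded). Total impacts
are `M = (I − q)⁻¹ − I`. The inversion is performed whenever `I − q` is
nonsingular; a spectral radius of `q` at or above 1 attaches a
non-convergence warning (the Leontief inverse exists but the pathway
series Σqⁿ does not converge) rather than raising — the 2×2
prey–predator pair, whose radius is exactly 1, is the canonical worked
example and must remain computable. The overall cumulative impact ε is
the signed row sum of `M` excluding the diagonal (the column sum gives
impact suffered); a root-sum-of-squares variant from the keystoneness
literature is available as `epsilon_definition="rss"` but the signed
sum is the default and the definition used everywhere else in the
package.

## Exploitation and benthic–pelagic coupling

`E = F/Z` with `F = ΣY/B` and `Z = P/B` (the steady-state total
mortality identity); a fleet's `CumE` sums its per-group `E`
contributions, so the additivity `Σ_fleets E_i,f = E_i` holds exactly.
Cross-domain flux sums, per group, the consumption taken from (and
supplied to) groups of the other two domains, with a configurable
exclusion list whose default removes producers, detritus, bacteria,
zooplankton, meio/suprabenthos and macrobenthos — the low-trophic-level
compartments whose enormous fluxes would otherwise mask the coupling
carried by fish, cephalopods and large decapods. The exclusion applies
to the counterpart set only; with an empty exclusion the partition
`cross-domain intake + same-domain intake + import = Q` is exact.
Cross-domain impact splits each living group's `M` entries to/from
other-domain living groups into positive and negative parts; fleets
and detritus are excluded from domain sums.

## Synthetic web generator

The generator emulates the structure of a shelf-ecosystem model:
three domains, layered trophic guilds over producers and detritus
pools, fleets with landings and discards, a biomass pyramid with the
vertex up. Construction: (1) groups are placed on layers; (2) each
consumer samples prey from strictly lower layers with the configured
connectance and Dirichlet weights (at least two prey where possible,
shares blended toward uniform); (3) `P/B` is drawn from [10, 200] yr⁻¹
for producers and from bands decreasing with layer within [0.2, 5] yr⁻¹
for consumers, with `Q/B = P/B ÷ P/Q` and `P/Q` in [0.1, 0.35]; (4)
producer biomasses seed the pyramid and each consumer's biomass is set
greedily so that no prey's implied EE can exceed the configured ceiling
(each consumer takes 15–40 % of the binding prey capacity left); a
layer whose summed biomass would exceed the layer below is shrunk;
(5) fleets catch overlapping portfolios, at most half of any group's
unconsumed production and a modest fraction (30–50 %) of its predation
pressure, with apex groups — which nothing eats — caught lightly by
every fleet so their EE is positive; (6) the model is emitted with all
EE blanked for the solver to recover.

Two numerical guarantees are engineered in:

- **Exact diet closure.** Diet shares are quantized to multiples of
  2⁻³⁰ (~1e-9, far below any ecological signal); every share and every
  partial sum is then exactly representable in float64, so diet columns
  sum to 1 exactly under any summation order.
- **Convergent impact expansion.** A food web whose consumers feed
  entirely in-system on prey removed entirely by those same consumers
  produces a direct-impact matrix with column-stochastic two-cycle
  structure — its spectral radius sits at 1 and the impact series does
  not converge. The generator therefore leans low trophic layers on
  detritus (a sink: consuming it harms nothing), lets upper layers
  scavenge a little, and spreads removal across overlapping fleets.
  The resulting radius is typically 0.85–1.05, and generation is
  retried with an incremented sub-seed (up to 60 times, still
  deterministic in the seed) until the radius is below 1.

Net migration is forced in absolute units where required (the
swordfish immigration term); since EE, TL and MTI are invariant under a
uniform rescaling of biomasses and catches, the whole web is rescaled
once so any forced inward migration stays a minor budget term.

What the generator does *not* emulate: cannibalism and within-layer
predation loops (real diet matrices have them; the solvers support
them, the generator does not produce them), seasonal or multi-stanza
structure, spatial heterogeneity, and empirically realistic bacteria
turnover rates (consumer `P/B` is capped at 5 yr⁻¹). Passing tests on
generated webs therefore demonstrate correctness of the algebra and the
analysis chain, not realism of any particular ecosystem.

## The Strait-of-Sicily-structured fixture

`data/sos_synthetic/` carries the published *structure* of the Strait
of Sicily ecosystem model — 72 groups (69 living + 3 detritus pools)
with their codes, long names, domain labels and producer/detritus
typing, 18 gear × vessel-size fleet segments with plausible target and
bycatch sets, bluefin tuna's 70 % diet import, and the small swordfish
immigration rate (0.025 t·km⁻²·yr⁻¹). Every numeric value (B, P/B,
Q/B, diets, catches) is a synthetic stand-in drawn by the generator
over that structure with a fixed seed, because the original parameter
and diet tables are not public. The fixture balances with all EE in
(0, 1) and exercises every analysis stage at full size; it does not
reproduce the published model's output values, and the one acceptance
test that documents those published values fails against it by design.

## Numerical choices

- CSV numerics are written as `repr(float)` (shortest round-trip text)
  and parsed with pandas' `float_precision="round_trip"`, making
  write → read an exact identity and pipeline reruns byte-identical.
- Missing values are empty cells, never 0: for `B`/`EE` the difference
  between "unknown" and "zero" is semantic.
- Group order is file order and is preserved in every matrix and output.
- Default detritus routing when no fate table is given: benthic and
  demersal groups to the first ordinary (non-carrion) benthic pool,
  pelagic groups to the first suspended pool; discards default to the
  carrion pool when one is identifiable (code `DC` or "carrion" in the
  name), else the benthic pool.
- Tolerances: balance residual 1e-8 (absolute, t·km⁻²·yr⁻¹); diet
  column closure 1e-6 at validation; TL/MTI oracle agreements are
  tested at 1e-10/1e-8.
- The full pipeline writes 8 core files for a fleet-less model and
  adds the 3 exploitation/BPC files only when fleets are present.
- Test and acceptance problem sizes — 30-group webs with 3 fleets, 100
  seeds for recovery, 20 for the oracle comparisons — were chosen to
  exercise every code path at sizes where independent oracles
  (enumeration, series summation, fixed-point iteration) are exact and
  fast.

## Known limitations

- No automatic rebalancing heuristics, multi-stanza biomass
  distribution, uncertainty propagation, or temporal dynamics.
- The MTI is a linearized impact propagation; with spectral radius ≥ 1
  (as happens for the shipped fixture) the Leontief inverse is still
  reported, with a warning, but it cannot be read as a convergent sum
  of pathways.
- Ecological-network indices outside the scope here (ascendency,
  capacity, Finn cycling, transfer efficiency) are not computed.
- The `E ≤ 1` exploitation bound holds only for models that actually
  balance with `EE ≤ 1`; the package reports rather than enforces it.
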