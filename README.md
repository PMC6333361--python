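# trophicnet

Mass-balance food-web modelling and trophic network analysis for marine
ecosystems, with first-class support for fishing fleets and
benthic–pelagic coupling (BPC).

Benthic, demersal and pelagic communities are usually assessed — and
fished — as if they were separate systems. They are not: predators move
between bottom and water column, discards sink, and the removal of one
fleet's target cascades through prey and competitors into another
fleet's catch. `trophicnet` quantifies these couplings on a steady-state
(Ecopath-style) mass-balance model of a food web, of the kind built for
the Strait of Sicily and many other shelf ecosystems: tens of functional
groups connected by a diet matrix, exploited by gear × vessel-size fleet
segments.

## The model

Each living group *i* (biomass `B_i`, production rate `P/B_i`,
consumption rate `Q/B_i`) must balance production against its fates:

```
B_i · (P/B)_i · EE_i = Σ_j B_j · (Q/B)_j · DC_ij + Y_i + NM_i + BA_i
```

where `DC_ij` is the fraction of prey *i* in consumer *j*'s diet, `Y_i`
the catch (landings + discards), `NM_i` net migration, `BA_i` biomass
accumulation, and `EE_i` the ecotrophic efficiency — the fraction of
production used within the system. With exactly one unknown per living
group (its `B` or its `EE`) the equations form one linear system that
the solver inverts directly; every flow, mortality term and detritus
budget follows.

On the balanced web the package computes:

- **Trophic structure** — fractional trophic levels
  (`TL_j = 1 + Σ_i DC'_ij·TL_i`), omnivory indices (diet-weighted
  variance of prey TL), the system omnivory index, and flow totals
  (production, consumption, respiration, flows to detritus, exports,
  total system throughput, PP/R, PP/B).
- **Mixed Trophic Impact (MTI)** — the direct net impact
  `q_ij = d_ji − f_ij` (diet contribution minus removal share), with
  fleets and detritus pools as network components, propagated through
  all indirect pathways by the Leontief inversion
  `M = (I − q)⁻¹ − I`; row sums give each component's overall
  cumulative impact ε on the web.
- **Exploitation** — per-group exploitation rate `E = F/Z` and each
  fleet's cumulative exploitation `CumE = Σ_i E_i`.
- **BPC decompositions** — the consumption each group exchanges with
  the two domains it does not belong to, and the positive/negative
  parts of its total impact restricted to those domains.
- **Synthetic webs** — a generator of balanced-by-construction,
  domain-labelled webs with fleets, the ground truth for every test in
  the suite.

## Worked example

```python
import pandas as pd
from trophicnet import (GroupSpec, DietMatrix, ModelDefinition, solve_balance,
                        trophic_levels, system_statistics)

groups = [
    GroupSpec("PHY", "phytoplankton", "producer", "pelagic", B=100, PB=5, GS=0),
    GroupSpec("ZOO", "zooplankton", "consumer", "pelagic", PB=1, QB=5, EE=0.5, GS=0.2),
    GroupSpec("FIS", "planktivorous fish", "consumer", "pelagic", B=0.5, PB=0.8, QB=3, EE=0, GS=0.2),
]
dc = pd.DataFrame(0.0, index=["PHY", "ZOO", "FIS"], columns=["ZOO", "FIS"])
dc.loc["PHY", "ZOO"] = 1.0   # zooplankton graze phytoplankton
dc.loc["ZOO", "FIS"] = 1.0   # fish eat zooplankton
model = ModelDefinition(groups, DietMatrix(dc, pd.Series({"ZOO": 0.0, "FIS": 0.0})))

balanced = solve_balance(model)
print(balanced.groups[["B", "PB", "QB", "EE", "P", "Q", "R"]].round(3))
```

Zooplankton biomass and phytoplankton EE are left unknown; the solver
recovers both from the balance (fish demand 0.5·3 = 1.5 t km⁻² yr⁻¹ of
zooplankton, which at EE = 0.5 requires B = 3):

```
         B   PB   QB    EE      P     Q    R
PHY  100.0  5.0  0.0  0.03  500.0   0.0  0.0
ZOO    3.0  1.0  5.0  0.50    3.0  15.0  9.0
FIS    0.5  0.8  3.0  0.00    0.4   1.5  0.8
```

`trophic_levels(balanced)` places the chain at TL 1.0 / 2.0 / 3.0, and
`system_statistics(balanced)` reports total production 503.4 and total
consumption 16.5 t km⁻² yr⁻¹ — the hand-computable sums of `B·PB` and
`B·QB`.

The same analyses run from the shell:

```
trophicnet simulate --seed 1 --out web/        # synthetic balanced web + truth
trophicnet run --model web/ --out results/     # balance → indices → MTI → BPC
```

## The Strait-of-Sicily-structured fixture

`trophicnet.strait_of_sicily` ships a 72-group, 18-fleet
parameterization with the published structure of the Strait of Sicily
ecosystem model: group codes, names, domain labels, producer/detritus
typing, the fleet segments, bluefin tuna's 70 % diet import and the
swordfish immigration term. Its numeric values (biomasses, rates, diets,
catches) are **synthetic** — generated by the package's own web
generator, because the original parameter and diet tables are not
public — so it supports structural and regression testing, not
ecological inference about the real system.

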