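"""Fractional trophic levels, omnivory and system-level flow statistics.

Trophic level is defined recursively: producers and detritus sit at
TL = 1, and a consumer sits one level above the diet-weighted mean TL
of its prey, ``TL_j = 1 + Σ_i DC'_ij · TL_i``.  The recursion is one
sparse linear system, solved directly.

Two conventions handle the diet fraction imported from outside the
system.  The default (``"renormalize"``) excludes the import and
renormalizes the in-system diet — equivalent to assigning the import
the consumer's mean in-system prey TL, so a migratory predator feeding
mostly outside keeps the trophic position its in-system diet implies.
The alternative (``"import_tl_one"``) treats imported food as TL-1
material, which drags heavy importers toward TL 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel

IMPORT_CONVENTIONS = ("renormalize", "import_tl_one")

#: consumers with annual consumption at or below this get log(1+Q) weight
#: in the SOI instead of log(Q), which would be non-positive
SOI_Q_GUARD = 1.0


def _diet_weights(balanced: BalancedModel, convention: str) -> tuple[pd.DataFrame, pd.Series]:
    """Per-consumer prey weights under the chosen import convention.

    Returns (W, import_weight): W is prey × consumer, columns summing to
    1 − import_weight; under "renormalize" import_weight is 0 and W
    columns sum to 1 (when the consumer has any in-system diet).
    """
    if convention not in IMPORT_CONVENTIONS:
        raise ValueError(f"unknown import convention {convention!r}")
    dc = balanced.definition.diet.dc
    imports = balanced.definition.diet.imports
    consumers = balanced.consumer_codes
    W = dc.reindex(columns=consumers).fillna(0.0).copy()
    if convention == "renormalize":
        sums = W.sum(axis=0)
        nonzero = sums[sums > 0].index
        W[nonzero] = W[nonzero].div(sums[nonzero], axis=1)
        imp = pd.Series(0.0, index=consumers)
    else:
        imp = imports.reindex(consumers).fillna(0.0)
    return W, imp


def trophic_levels(
    balanced: BalancedModel, *, import_convention: str = "renormalize"
) -> pd.Series:
    """Fractional trophic level of every group (model order).

    A consumer whose entire diet is imported has no in-system prey to
    average over; it is assigned TL = 2 by convention (as if its import
    were TL-1 material) and a warning is recorded on the model.
    """
    codes = balanced.codes
    n = len(codes)
    idx = {c: k for k, c in enumerate(codes)}
    W, imp = _diet_weights(balanced, import_convention)

    A = np.eye(n)
    rhs = np.ones(n)  # producers/detritus rows stay TL = 1
    raw_imports = balanced.definition.diet.imports
    for j in balanced.consumer_codes:
        col = W[j]
        if float(col.sum()) == 0.0:
            # no in-system prey: the consumer feeds entirely outside the
            # system (or has an empty diet); fix TL = 2 by convention
            rhs[idx[j]] = 2.0
            if float(raw_imports.get(j, 0.0)) > 0.0:
                balanced.warnings.append(
                    f"{j}: diet entirely imported; TL set to 2 by convention"
                )
            continue
        for prey, frac in col[col != 0.0].items():
            A[idx[j], idx[prey]] -= float(frac)
        rhs[idx[j]] = 1.0 + float(imp.get(j, 0.0))  # import counts as TL-1 prey
    return pd.Series(np.linalg.solve(A, rhs), index=codes)


def omnivory(
    balanced: BalancedModel,
    tl: pd.Series,
    *,
    import_convention: str = "renormalize",
) -> tuple[pd.Series, float]:
    """Omnivory index per consumer and the system omnivory index.

    ``OI_j = Σ_i DC'_ij · (TL_i − (TL_j − 1))²`` — the diet-weighted
    variance of prey trophic levels about their mean.  The SOI averages
    OI over consumers weighted by the logarithm of each consumer's food
    intake Q; consumers with Q ≤ 1 t·km⁻²·yr⁻¹ get weight log(1+Q) to
    keep weights positive.
    """
    W, imp = _diet_weights(balanced, import_convention)
    consumers = balanced.consumer_codes
    oi = pd.Series(0.0, index=consumers)
    for j in consumers:
        mean_prey_tl = tl[j] - 1.0
        col = W[j]
        var = float((col * (tl.reindex(col.index) - mean_prey_tl) ** 2).sum())
        if imp.get(j, 0.0) > 0:
            var += float(imp[j]) * (1.0 - mean_prey_tl) ** 2
        oi[j] = var
    q = balanced.groups.loc[consumers, "Q"].astype(float)
    weights = pd.Series(
        np.where(q > SOI_Q_GUARD, np.log(q.where(q > 0, 1.0)), np.log1p(q)),
        index=consumers,
    )
    total = float(weights.sum())
    soi = float((oi * weights).sum() / total) if total > 0 else 0.0
    return oi, soi


@dataclass
class SystemStatistics:
    """System-level flow totals, all in t·km⁻²·yr⁻¹ except the ratios."""

    total_production: float
    total_consumption: float
    total_respiration: float
    total_flow_to_detritus: float
    total_export: float
    total_system_throughput: float
    net_primary_production: float
    pp_over_r: float
    pp_over_b: float
    total_living_biomass: float
    total_catch: float

    def as_frame(self) -> pd.DataFrame:
        data = {k: [float(v)] for k, v in self.__dict__.items()}
        return pd.DataFrame(data).T.rename(columns={0: "value"})


def system_statistics(balanced: BalancedModel) -> SystemStatistics:
    """Flow totals and maturity ratios of the balanced web.

    Exports comprise landings (which leave the system), net detritus
    export, and each living group's net migration plus biomass
    accumulation.  Total system throughput is the sum of consumption,
    exports, respiration and flows into detritus.  PP/R is reported as
    ``inf`` for a web without respiring consumers.
    """
    g = balanced.groups
    living = balanced.living_codes
    total_production = float(g.loc[living, "P"].sum())
    total_consumption = float(g.loc[living, "Q"].sum())
    total_respiration = float(g.loc[living, "R"].sum())
    flow_to_detritus = float(balanced.detritus["inflow"].sum()) if len(balanced.detritus) else 0.0
    landings_total = float(balanced.landings.to_numpy().sum()) if balanced.landings.size else 0.0
    detritus_export = float(balanced.detritus["export"].sum()) if len(balanced.detritus) else 0.0
    migration = float((g.loc[living, "NM"] + g.loc[living, "BA"]).sum())
    total_export = landings_total + detritus_export + migration
    tst = total_consumption + total_export + total_respiration + flow_to_detritus
    producers = balanced.producer_codes
    pp = float(g.loc[producers, "P"].sum())
    total_b = float(g.loc[living, "B"].sum())
    total_catch = float(balanced.Y.to_numpy().sum()) if balanced.Y.size else 0.0
    pp_over_r = pp / total_respiration if total_respiration > 0 else float("inf")
    pp_over_b = pp / total_b if total_b > 0 else float("inf")
    return SystemStatistics(
        total_production=total_production,
        total_consumption=total_consumption,
        total_respiration=total_respiration,
        total_flow_to_detritus=flow_to_detritus,
        total_export=total_export,
        total_system_throughput=tst,
        net_primary_production=pp,
        pp_over_r=pp_over_r,
        pp_over_b=pp_over_b,
        total_living_biomass=total_b,
        total_catch=total_catch,
    )
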