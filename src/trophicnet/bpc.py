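"""Exploitation rates and benthic–pelagic-coupling decompositions.

Fishing pressure per group is summarised by the exploitation rate
``E = F/Z``: annual fishing mortality ``F = Y/B`` over total mortality
``Z``, which in a balanced steady-state web equals the group's P/B.  A
fleet's cumulative exploitation rate CumE sums its per-group
exploitation contributions, so fleets spreading moderate pressure over
many groups rank alongside fleets hammering one stock.

Benthic–pelagic coupling (BPC) is quantified two ways: by *flux* — the
consumption each group takes from, or supplies to, the two domains it
does not belong to — and by *impact* — the positive and negative parts
of its total mixed-trophic impact restricted to groups of the other
domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel
from .mti import ImpactMatrix


@dataclass
class ExploitationTable:
    """Per-group F/Z/E and per-fleet cumulative exploitation.

    ``per_group`` columns: ``F`` (yr⁻¹), ``Z`` (yr⁻¹), ``E``;
    ``contributions`` holds E split by fleet (group × fleet, summing to
    each group's E); ``cum_e`` is the per-fleet column sum of the
    contributions (Eq.: CumE_fleet = Σ_i E_i,fleet).
    """

    per_group: pd.DataFrame
    contributions: pd.DataFrame
    cum_e: pd.Series


def exploitation(balanced: BalancedModel) -> ExploitationTable:
    """Exploitation rates from catches (landings plus discards)."""
    living = balanced.living_codes
    g = balanced.groups.loc[living]
    F_by_fleet = balanced.F.loc[living] if balanced.F.size else pd.DataFrame(index=living)
    Z = g["PB"].astype(float)
    contributions = F_by_fleet.div(Z, axis=0) if F_by_fleet.size else F_by_fleet.copy()
    F_total = F_by_fleet.sum(axis=1) if F_by_fleet.size else pd.Series(0.0, index=living)
    E = F_total / Z
    per_group = pd.DataFrame({"F": F_total, "Z": Z, "E": E})
    cum_e = contributions.sum(axis=0) if contributions.size else pd.Series(dtype=float)
    return ExploitationTable(per_group=per_group, contributions=contributions, cum_e=cum_e)


def default_flux_exclusion(balanced: BalancedModel) -> list[str]:
    """Low-trophic-level groups excluded from the flux decomposition.

    The bulk of cross-domain consumption runs through macro-benthos,
    zooplankton, bacteria, phytoplankton and detritus; excluding them
    exposes the coupling carried by fish, cephalopods and large
    decapods.  The default excludes every group with TL-1 status
    (producers, detritus) plus consumers whose code marks them as
    bacteria, zoo-/meio-benthos or macrobenthos in the shipped
    parameterization; callers with other webs should pass their own
    exclusion list.
    """
    lower_codes = {
        "SUP", "O", "FF", "DF", "C", "PAR", "SCA", "H", "GRA", "SF", "PF",
        "BO", "EUP", "ZG", "ZL", "ZM", "ZS", "PB", "BB",
    }
    out = []
    for code, row in balanced.groups.iterrows():
        if row["type"] in ("producer", "detritus") or code in lower_codes:
            out.append(code)
    return out


def cross_domain_flux(
    balanced: BalancedModel, *, exclude: list[str] | None = None
) -> pd.DataFrame:
    """Consumption flux each group exchanges with the other two domains.

    For group *g* in domain *D*: ``consumer_flux`` sums T[prey, g] over
    prey outside *D*; ``source_flux`` sums T[g, consumer] over
    consumers outside *D*.  ``exclude`` removes groups from the
    counterpart set (both as prey and as consumers); the excluded
    groups keep their own rows.
    """
    exclude = list(exclude) if exclude is not None else []
    codes = set(balanced.codes)
    unknown = [c for c in exclude if c not in codes]
    if unknown:
        raise ValueError(f"unknown group in exclusion list: {unknown[0]!r}")
    excluded = set(exclude)
    domain = balanced.groups["domain"]
    T = balanced.T
    rows = {}
    for g in balanced.codes:
        dom = domain[g]
        consumer_flux = 0.0
        if g in T.columns:
            prey_mask = [
                p for p in T.index if domain[p] != dom and p not in excluded
            ]
            consumer_flux = float(T.loc[prey_mask, g].sum())
        cons_mask = [
            c for c in T.columns if domain[c] != dom and c not in excluded
        ]
        source_flux = float(T.loc[g, cons_mask].sum()) if g in T.index else 0.0
        rows[g] = {
            "domain": dom,
            "consumer_flux_other_domains": consumer_flux,
            "source_flux_other_domains": source_flux,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cross_domain_impact(im: ImpactMatrix, balanced: BalancedModel) -> pd.DataFrame:
    """Signed MTI sums of each living group on/from the other domains.

    ``impact_out_pos``/``impact_out_neg`` split the total impacts a
    group exerts on living groups of the other domains into their
    positive and negative parts; ``impact_in_pos``/``impact_in_neg`` do
    the same for impacts received.  Fleets and detritus pools are
    excluded from the domain sums.
    """
    living = balanced.living_codes
    M = im.M.loc[living, living]
    domain = balanced.groups["domain"]
    rows = {}
    for g in living:
        others = [h for h in living if h != g and domain[h] != domain[g]]
        out = M.loc[g, others]
        inc = M.loc[others, g]
        rows[g] = {
            "domain": domain[g],
            "impact_out_pos": float(out[out > 0].sum()),
            "impact_out_neg": float(out[out < 0].sum()),
            "impact_in_pos": float(inc[inc > 0].sum()),
            "impact_in_neg": float(inc[inc < 0].sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
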