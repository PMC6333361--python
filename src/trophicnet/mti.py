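"""Mixed Trophic Impact (MTI) analysis with fleets as network components.

The direct net impact of component *i* on component *j* is

    q[i, j] = d[j, i] − f[i, j]

where ``d[j, i]`` is the fraction of *j*'s intake supplied by *i*
(diet fraction for consumers, catch composition for fleets, inflow
composition for detritus pools) and ``f[i, j]`` the fraction of the
total removal of *j* — all predation plus all catches — attributable to
consumer or fleet *i*.  Landings leave the system, so fleets impact
detritus only positively, through the discards they route to the pools;
nothing removes a fleet or (by convention) a detritus pool, so neither
suffers a negative direct term.

Total impacts, direct plus all indirect pathways, follow from the
input–output (Leontief) inversion ``M = (I − q)⁻¹ − I``; the row sums
of M excluding the diagonal give each component's overall cumulative
impact ε on the rest of the web, the column sums the impact it suffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel

EPSILON_DEFINITIONS = ("sum", "rss")


class ImpactError(ValueError):
    """The impact propagation cannot be computed (singular I − q)."""


@dataclass
class ImpactMatrix:
    """MTI over living groups, detritus pools and fleets (in that order)."""

    components: list[str]
    group_codes: list[str]
    fleet_names: list[str]
    q: pd.DataFrame
    M: pd.DataFrame
    epsilon: pd.Series
    suffered: pd.Series
    spectral_radius: float
    epsilon_definition: str = "sum"
    warnings: list[str] = field(default_factory=list)


def net_impact_matrix(balanced: BalancedModel) -> pd.DataFrame:
    """Direct net-impact matrix q over groups then fleets.

    The diagonal is zero: self-impacts (cannibalism) are excluded from
    the direct terms.  A group nothing removes has a zero negative
    column — no component directly harms it.
    """
    codes = balanced.codes
    fleets = list(balanced.Y.columns)
    components = codes + fleets
    n = len(components)
    pos = {c: k for k, c in enumerate(components)}
    q = np.zeros((n, n))

    T = balanced.T
    Y = balanced.Y
    g = balanced.groups
    dc = balanced.definition.diet.dc

    # --- d: intake composition (entered as q[i, j] += d[j, i]) ------------
    for j in balanced.consumer_codes:
        for prey, frac in dc[j][dc[j] != 0.0].items():
            q[pos[prey], pos[j]] += float(frac)
    pools = balanced.detritus_codes
    if pools:
        fate = balanced.definition.resolved_detritus_fate()
        living = balanced.living_codes
        losses = (g.loc[living, "U"] + g.loc[living, "M0"] * g.loc[living, "B"]).astype(float)
        inflow = balanced.detritus["inflow"]
        for d in pools:
            tot = float(inflow.get(d, 0.0))
            if tot <= 0:
                continue
            contrib = fate[d].mul(losses, fill_value=0.0)
            for i, val in contrib[contrib != 0.0].items():
                q[pos[i], pos[d]] += float(val) / tot
            for f in balanced.definition.fleets:
                disc = float(f.discards.sum()) * float(f.discard_fate.get(d, 0.0))
                if disc > 0:
                    q[pos[f.name], pos[d]] += disc / tot
    for fname in fleets:
        tot = float(Y[fname].sum())
        if tot <= 0:
            continue
        for i, val in Y[fname][Y[fname] != 0.0].items():
            q[pos[i], pos[fname]] += float(val) / tot

    # --- f: removal composition (entered as q[i, j] -= f[i, j]) -----------
    predation = T.sum(axis=1)
    catches = Y.sum(axis=1) if len(fleets) else pd.Series(0.0, index=codes)
    for j in balanced.living_codes:
        removal = float(predation.get(j, 0.0)) + float(catches.get(j, 0.0))
        if removal <= 0:
            continue
        row = T.loc[j] if j in T.index else pd.Series(dtype=float)
        for c, val in row[row != 0.0].items():
            q[pos[c], pos[j]] -= float(val) / removal
        if len(fleets):
            for fname, val in Y.loc[j][Y.loc[j] != 0.0].items():
                q[pos[fname], pos[j]] -= float(val) / removal

    np.fill_diagonal(q, 0.0)
    return pd.DataFrame(q, index=components, columns=components)


def mti(q: pd.DataFrame, *, epsilon_definition: str = "sum") -> ImpactMatrix:
    """Total (direct + indirect) impact matrix ``M = (I − q)⁻¹ − I``.

    Raises :class:`ImpactError` if ``I − q`` is singular.  A spectral
    radius of q at or above 1 does not prevent the inversion, but the
    Neumann-series reading of M as summed impact pathways no longer
    converges; a warning is recorded in that case.

    ``epsilon_definition`` selects the cumulative-impact statistic:
    ``"sum"`` (default) is the signed row sum of M excluding the
    diagonal; ``"rss"`` the root-sum-of-squares variant used in the
    keystoneness literature.
    """
    if epsilon_definition not in EPSILON_DEFINITIONS:
        raise ValueError(f"unknown epsilon definition {epsilon_definition!r}")
    components = list(q.index)
    A = np.eye(len(components)) - q.to_numpy(dtype=float)
    warnings: list[str] = []
    radius = float(np.max(np.abs(np.linalg.eigvals(q.to_numpy(dtype=float))))) if len(components) else 0.0
    if radius >= 1.0:
        warnings.append(
            f"non-convergent impact propagation (spectral radius {radius:.4g} >= 1); "
            "M is the Leontief inverse but lacks a convergent pathway expansion"
        )
    try:
        Minv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ImpactError("singular impact system: I - q is not invertible") from exc
    M = Minv - np.eye(len(components))
    Mdf = pd.DataFrame(M, index=components, columns=components)
    off = M - np.diag(np.diag(M))
    if epsilon_definition == "sum":
        eps = off.sum(axis=1)
    else:
        eps = np.sqrt((off**2).sum(axis=1))
    suffered = off.sum(axis=0)
    group_codes = [c for c in components]  # refined by callers with model context
    return ImpactMatrix(
        components=components,
        group_codes=group_codes,
        fleet_names=[],
        q=q,
        M=Mdf,
        epsilon=pd.Series(eps, index=components),
        suffered=pd.Series(suffered, index=components),
        spectral_radius=radius,
        epsilon_definition=epsilon_definition,
        warnings=warnings,
    )


def impact_analysis(
    balanced: BalancedModel, *, epsilon_definition: str = "sum"
) -> ImpactMatrix:
    """Convenience chain: build q from a balanced model, then invert it."""
    q = net_impact_matrix(balanced)
    im = mti(q, epsilon_definition=epsilon_definition)
    im.group_codes = balanced.codes
    im.fleet_names = list(balanced.Y.columns)
    return im


def fleet_views(
    im: ImpactMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Fleet→group and fleet→fleet sub-matrices of M, with sign summary.

    Returns ``(fleet_on_groups, fleet_on_fleets, summary)`` where the
    summary counts conflicts (negative fleet→fleet impacts) and
    benefits (positive ones), diagonal excluded.  Empty frames for a
    model without fleets.
    """
    fleets = im.fleet_names
    groups = [c for c in im.components if c not in fleets]
    if not fleets:
        empty = pd.DataFrame(index=[], columns=groups, dtype=float)
        return empty, pd.DataFrame(dtype=float), {"conflicts": 0, "benefits": 0}
    fog = im.M.loc[fleets, groups]
    fof = im.M.loc[fleets, fleets]
    off = fof.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    summary = {
        "conflicts": int((off < 0).sum()),
        "benefits": int((off > 0).sum()),
    }
    return fog, fof, summary
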