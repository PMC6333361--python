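"""Steady-state mass-balance solver and flow accounting.

Each living group *i* obeys the master balance

    B_i · (P/B)_i · EE_i  =  Σ_j B_j · (Q/B)_j · DC_ij  +  Y_i + NM_i + BA_i

production used in the system equals predation by all consumers *j*
plus fishery catches, net migration and biomass accumulation.  With
exactly one unknown per living group (its ``B`` or its ``EE``) the
master equations form a square linear system, which is solved directly;
groups whose parameters are all given contribute no equation and their
residual is reported as a consistency diagnostic instead.

From the solved parameters every flow follows: the consumption matrix
``T[i, j] = B_j·QB_j·DC_ij``, respiration as the assimilation remainder
``R = Q − P − U``, predation/other mortality rates and the detritus
budgets.  All flows are t·km⁻²·yr⁻¹.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import ModelDefinition, ValidationError, validate

RESIDUAL_TOL = 1e-8


class BalanceError(ValueError):
    """The master-equation system cannot be solved sensibly."""


@dataclass
class BalancedModel:
    """A fully determined model plus all derived flows.

    ``groups`` has one row per group (model order) with columns
    ``type, domain, B, PB, QB, EE, GS, BA, NM, P, Q, R, U, M0, M2``.
    ``T`` is the prey × consumer consumption-flow matrix and
    ``imports`` the per-consumer inflow from outside the system.
    ``Y`` (and ``landings``/``discards``) are group × fleet catches,
    ``F`` the corresponding fishing-mortality rates, ``detritus`` the
    per-pool budget and ``diagnostics`` the per-living-group residuals
    and flags.
    """

    definition: ModelDefinition
    groups: pd.DataFrame
    T: pd.DataFrame
    imports: pd.Series
    Y: pd.DataFrame
    landings: pd.DataFrame
    discards: pd.DataFrame
    F: pd.DataFrame
    detritus: pd.DataFrame
    diagnostics: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def codes(self) -> list[str]:
        return list(self.groups.index)

    @property
    def living_codes(self) -> list[str]:
        return list(self.groups.index[self.groups["type"] != "detritus"])

    @property
    def consumer_codes(self) -> list[str]:
        return list(self.groups.index[self.groups["type"] == "consumer"])

    @property
    def producer_codes(self) -> list[str]:
        return list(self.groups.index[self.groups["type"] == "producer"])

    @property
    def detritus_codes(self) -> list[str]:
        return list(self.groups.index[self.groups["type"] == "detritus"])


def _is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def solve_balance(model: ModelDefinition, *, tol: float = RESIDUAL_TOL) -> BalancedModel:
    """Solve the master equations and populate a :class:`BalancedModel`.

    The unknown of each living group (missing ``B`` or missing ``EE``)
    enters the equations linearly — unknown ``EE_i`` multiplied by the
    known ``B_i·PB_i``, unknown ``B_j`` by its known ``PB_j·EE_j`` on
    the production side and by ``QB_j·DC_ij`` inside every prey's
    predation sum — so one direct dense solve determines them all.  A
    rank-deficient system falls back to the minimum-norm least-squares
    solution with a rank warning.

    Raises :class:`BalanceError` on a singular system or a non-positive
    solved biomass.  ``EE`` outside [0, 1] is flagged in the
    diagnostics, not raised, so inputs can be iterated.
    """
    report = validate(model)
    report.raise_if_invalid()
    warnings = list(report.warnings)

    model = model.copy()
    codes = model.codes
    living = model.living
    consumers = model.consumers
    dc = model.diet.dc

    qb = {g.code: (g.consumption_rate() if g.is_consumer else 0.0) for g in model.groups}

    # total catch per group
    y_total = pd.Series(0.0, index=codes)
    for f in model.fleets:
        y_total = y_total.add(f.catch().reindex(codes).fillna(0.0))

    unknowns: list[tuple[str, str]] = []  # (group code, "B" | "EE")
    for g in living:
        b_missing, ee_missing = _is_nan(g.B), _is_nan(g.EE)
        if b_missing and ee_missing:
            raise BalanceError(f"{g.code}: under-determined (both B and EE missing)")
        if b_missing:
            unknowns.append((g.code, "B"))
        elif ee_missing:
            unknowns.append((g.code, "EE"))

    var_index = {code: k for k, (code, _) in enumerate(unknowns)}
    n = len(unknowns)
    if n:
        A = np.zeros((n, n))
        b = np.zeros(n)
        eq_groups = [model.group(code) for code, _ in unknowns]
        for r, gi in enumerate(eq_groups):
            const = -(y_total[gi.code] + gi.NM + gi.BA)
            # production side B_i PB_i EE_i
            if gi.code in var_index:
                kind = unknowns[var_index[gi.code]][1]
                if kind == "EE":
                    A[r, var_index[gi.code]] += gi.B * gi.PB
                else:
                    A[r, var_index[gi.code]] += gi.PB * gi.EE
            else:  # pragma: no cover - equations exist only for unknown groups
                const += gi.B * gi.PB * gi.EE
            # predation side − Σ_j B_j QB_j DC_ij
            if gi.code in dc.index:
                for gj in consumers:
                    frac = float(dc.at[gi.code, gj.code])
                    if frac == 0.0:
                        continue
                    if gj.code in var_index and unknowns[var_index[gj.code]][1] == "B":
                        A[r, var_index[gj.code]] -= qb[gj.code] * frac
                    else:
                        const -= gj.B * qb[gj.code] * frac
            b[r] = -const
        x, rank_warning = _solve_linear(A, b, unknowns)
        if rank_warning:
            warnings.append(rank_warning)
        for (code, kind), val in zip(unknowns, x):
            g = model.group(code)
            if kind == "B":
                if val <= 0:
                    raise BalanceError(f"{code}: solved biomass {val:.6g} is not positive")
                g.B = float(val)
            else:
                g.EE = float(val)

    return _assemble(model, qb, tol=tol, warnings=warnings)


def _solve_linear(A: np.ndarray, b: np.ndarray, unknowns) -> tuple[np.ndarray, str | None]:
    n = len(b)
    x, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank == n:
        return np.linalg.solve(A, b), None
    # rank deficient: accept the minimum-norm solution only if it satisfies
    # every equation, otherwise the groups' balances are inconsistent
    resid = A @ x - b
    if np.max(np.abs(resid)) > 1e-6:
        worst = [unknowns[k][0] for k in np.argsort(-np.abs(resid))[:3]]
        raise BalanceError(
            "singular master-equation system; dependent groups include: " + ", ".join(worst)
        )
    return x, f"rank-deficient system (rank {rank} < {n}); minimum-norm solution reported"


def _assemble(
    model: ModelDefinition,
    qb: dict[str, float],
    *,
    tol: float,
    warnings: list[str],
) -> BalancedModel:
    codes = model.codes
    rows = {}
    for g in model.groups:
        B = g.B if not _is_nan(g.B) else 0.0
        if g.group_type == "detritus":
            rows[g.code] = dict(
                type=g.group_type, domain=g.domain, B=g.B, PB=0.0, QB=0.0,
                EE=math.nan, GS=0.0, BA=g.BA, NM=g.NM,
                P=0.0, Q=0.0, R=0.0, U=0.0, M0=0.0, M2=0.0,
            )
            continue
        Q = B * qb[g.code] if g.is_consumer else 0.0
        P = B * g.PB
        U = g.unassimilated_fraction() * Q
        R = Q - P - U if g.is_consumer else 0.0
        rows[g.code] = dict(
            type=g.group_type, domain=g.domain, B=B, PB=g.PB, QB=qb[g.code],
            EE=g.EE, GS=g.unassimilated_fraction(), BA=g.BA, NM=g.NM,
            P=P, Q=Q, R=R, U=U, M0=g.PB * (1.0 - g.EE), M2=0.0,
        )
    groups = pd.DataFrame.from_dict(rows, orient="index").reindex(codes)

    T, imports = compute_flows_from(model, groups)
    predation = T.sum(axis=1).reindex(codes).fillna(0.0)
    groups["M2"] = np.where(groups["B"] > 0, predation / groups["B"].replace(0, np.nan), 0.0)
    groups["M2"] = groups["M2"].fillna(0.0)

    fleet_names = model.fleet_names
    landings = pd.DataFrame({f.name: f.landings.reindex(codes).fillna(0.0) for f in model.fleets})
    discards = pd.DataFrame({f.name: f.discards.reindex(codes).fillna(0.0) for f in model.fleets})
    if not fleet_names:
        landings = pd.DataFrame(index=codes)
        discards = pd.DataFrame(index=codes)
    Y = landings.add(discards, fill_value=0.0) if fleet_names else pd.DataFrame(index=codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = Y.div(groups["B"].replace(0, np.nan), axis=0).fillna(0.0) if fleet_names else Y.copy()

    diagnostics = _diagnostics(model, groups, T, Y, tol=tol, warnings=warnings)
    bal = BalancedModel(
        definition=model,
        groups=groups,
        T=T,
        imports=imports,
        Y=Y,
        landings=landings,
        discards=discards,
        F=F,
        detritus=pd.DataFrame(),
        diagnostics=diagnostics,
        warnings=warnings,
    )
    bal.detritus = detritus_budget(bal)
    return bal


def compute_flows_from(
    model: ModelDefinition, groups: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Consumption flows ``T[i, j] = B_j·QB_j·DC_ij`` plus import inflows."""
    codes = list(groups.index)
    consumers = [g.code for g in model.consumers]
    q = (groups.loc[consumers, "B"] * groups.loc[consumers, "QB"]).astype(float)
    T = model.diet.dc.reindex(index=codes, columns=consumers).fillna(0.0).mul(q, axis=1)
    imports = model.diet.imports.reindex(consumers).fillna(0.0) * q
    return T, imports


def compute_flows(balanced: BalancedModel) -> tuple[pd.DataFrame, pd.Series]:
    """Recompute the flow matrix and import inflows of a balanced model."""
    return compute_flows_from(balanced.definition, balanced.groups)


def _diagnostics(
    model: ModelDefinition,
    groups: pd.DataFrame,
    T: pd.DataFrame,
    Y: pd.DataFrame,
    *,
    tol: float,
    warnings: list[str],
) -> pd.DataFrame:
    rows = []
    y_total = Y.sum(axis=1) if len(Y.columns) else pd.Series(0.0, index=groups.index)
    predation = T.sum(axis=1)
    for g in model.living:
        r = groups.loc[g.code]
        residual = r["B"] * r["PB"] * r["EE"] - predation[g.code] - y_total[g.code] - g.NM - g.BA
        flags = []
        if r["EE"] > 1.0 + 1e-12:
            flags.append("EE>1")
        if r["EE"] < -1e-12:
            flags.append("EE<0")
        if g.is_consumer and r["R"] < -1e-12:
            flags.append("negative_respiration")
            warnings.append(f"{g.code}: negative respiration {r['R']:.4g}")
        if abs(residual) > tol:
            flags.append("residual")
        rows.append(dict(code=g.code, EE=r["EE"], residual=residual, flags=";".join(flags)))
    return pd.DataFrame(rows).set_index("code")


def detritus_budget(balanced: BalancedModel) -> pd.DataFrame:
    """Per-pool detritus budget: inflow, outflow, export and pseudo-EE.

    inflow  = Σ_i fate[i, d]·(U_i + M0_i·B_i) + discards routed to d
    outflow = Σ_j T[d, j]          (consumption of the pool)
    export  = inflow − outflow     (negative ⇒ flagged imbalance)
    """
    model = balanced.definition
    pools = [g.code for g in model.detritus_pools]
    if not pools:
        return pd.DataFrame(columns=["inflow", "outflow", "export", "EE"])
    fate = model.resolved_detritus_fate()
    g = balanced.groups
    living = balanced.living_codes
    losses = (g.loc[living, "U"] + g.loc[living, "M0"] * g.loc[living, "B"]).astype(float)
    inflow = fate.mul(losses, axis=0).sum(axis=0).reindex(pools).fillna(0.0)
    for f in model.fleets:
        total_disc = float(f.discards.sum())
        if total_disc > 0:
            inflow = inflow.add(f.discard_fate.reindex(pools).fillna(0.0) * total_disc)
    outflow = balanced.T.loc[pools].sum(axis=1)
    export = inflow - outflow
    with np.errstate(divide="ignore", invalid="ignore"):
        ee = (outflow / inflow.replace(0, np.nan)).astype(float)
    budget = pd.DataFrame({"inflow": inflow, "outflow": outflow, "export": export, "EE": ee})
    for d, row in budget.iterrows():
        if row["export"] < -1e-9:
            balanced.warnings.append(
                f"detritus pool {d}: consumption exceeds inflow by {-row['export']:.4g}"
            )
    return budget
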