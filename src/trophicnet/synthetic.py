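"""Balanced-by-construction synthetic food webs.

The generator builds layered, domain-labelled webs that exercise every
analysis stage with known ground truth and no external data.  Groups
are placed on trophic layers (producers and detritus at layer 0,
consumers at layers 1..L); each consumer samples prey from lower layers
with a given connectance and Dirichlet diet weights; rates are drawn
from plausible ranges that decrease up the web; and biomasses are
assigned greedily so that no prey's ecotrophic efficiency can exceed
the configured ceiling — each consumer's intake is capped by the
remaining EE-capacity of its prey, so the emitted web balances by
construction with EE ∈ (0, 1] for every living group (strictly positive
as long as fleets catch the apex groups nothing eats).  Fleets take at
most half of each target's unconsumed production, keeping F < Z.

The emitted :class:`~trophicnet.model_io.ModelDefinition` has every EE
blanked: recovering them (or any hidden biomass) is the balance
solver's job, which is what makes these webs useful test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_balance import solve_balance
from .model_io import (
    DietMatrix,
    FleetSpec,
    GroupSpec,
    ModelDefinition,
)


class WebGenerationError(ValueError):
    """The configuration cannot produce a feasible web."""


#: diet shares are quantized to multiples of 2^-30 (~1e-9): every share
#: and every partial sum is then exactly representable in float64, so
#: diet columns sum to 1 exactly under any summation order
_DIET_UNITS = 1 << 30


def _quantize_diet(shares: dict[str, float], imp: float) -> dict[str, float]:
    imp_u = int(round(imp * _DIET_UNITS))
    total_u = _DIET_UNITS - imp_u
    keys = list(shares)
    s = sum(shares.values())
    units = [int(round(shares[k] / s * total_u)) for k in keys]
    units[max(range(len(units)), key=lambda i: units[i])] += total_u - sum(units)
    out = {k: u / _DIET_UNITS for k, u in zip(keys, units) if u > 0}
    if imp_u:
        out["import"] = imp_u / _DIET_UNITS
    return out


@dataclass
class WebConfig:
    """Parameters of the synthetic web generator.

    Counts are per domain for consumers/producers; ``connectance`` is
    the probability that an eligible lower-layer group enters a
    consumer's diet; ``ee_range`` bounds the ecotrophic efficiencies the
    construction aims for (the upper bound is a hard guarantee, the
    lower one best-effort); ``import_prob``/``import_range`` control the
    diet fraction taken outside the system; ``gs`` is the unassimilated
    fraction of consumption.  A single integer ``seed`` drives one
    pseudo-random stream; no global state is touched.
    """

    n_consumers: dict[str, int] = field(
        default_factory=lambda: {"benthic": 5, "demersal": 5, "pelagic": 5}
    )
    n_producers: dict[str, int] = field(
        default_factory=lambda: {"benthic": 2, "pelagic": 2}
    )
    n_detritus: int = 2
    n_fleets: int = 2
    n_layers: int = 3
    connectance: float = 0.4
    ee_range: tuple[float, float] = (0.2, 0.9)
    import_prob: float = 0.1
    import_range: tuple[float, float] = (0.1, 0.6)
    gs: float = 0.2
    seed: int = 0

    def validated(self) -> "WebConfig":
        if sum(self.n_producers.values()) < 1:
            raise WebGenerationError("need at least one producer")
        if self.n_detritus < 1:
            raise WebGenerationError("need at least one detritus pool")
        lo, hi = self.ee_range
        if not (0.0 < lo < hi < 1.0):
            raise WebGenerationError("ee_range must satisfy 0 < lo < hi < 1")
        if not (0.0 < self.connectance <= 1.0):
            raise WebGenerationError("connectance must lie in (0, 1]")
        if self.n_layers < 1:
            raise WebGenerationError("need at least one consumer layer")
        return self


# PB ranges (yr^-1): producers fast, consumers slowing with layer
PRODUCER_PB = (10.0, 200.0)
CONSUMER_PB_TOP = 5.0
CONSUMER_PB_FLOOR = 0.2
PQ_RANGE = (0.1, 0.35)


def _consumer_pb_range(layer: int, n_layers: int) -> tuple[float, float]:
    t = (layer - 1) / max(1, n_layers - 1)
    hi = CONSUMER_PB_TOP * (0.3**t)
    lo = max(CONSUMER_PB_FLOOR, hi / 6.0)
    return lo, hi


def _detritus_meta(n: int) -> list[tuple[str, str, str]]:
    pools = []
    base = [
        ("DET_B", "benthic detritus", "benthic"),
        ("DET_S", "suspended particulate detritus", "demersal"),
        ("DET_C", "carrion detritus", "benthic"),
    ]
    for k in range(n):
        if k < len(base):
            pools.append(base[k])
        else:
            pools.append((f"DET{k + 1}", f"detritus pool {k + 1}", "benthic"))
    return pools


def _build_meta(config: WebConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for domain in sorted(config.n_producers):
        for k in range(config.n_producers[domain]):
            rows.append(
                dict(
                    code=f"P{domain[0].upper()}{k + 1}",
                    name=f"{domain} producer {k + 1}",
                    type="producer",
                    domain=domain,
                    layer=0,
                )
            )
    for domain in sorted(config.n_consumers):
        n = config.n_consumers[domain]
        for k in range(n):
            # spread consumers over layers, at least one per low layer
            layer = 1 + (k % config.n_layers) if n >= config.n_layers else 1 + int(
                rng.integers(0, config.n_layers)
            )
            rows.append(
                dict(
                    code=f"C{domain[0].upper()}{k + 1}",
                    name=f"{domain} consumer layer {layer}",
                    type="consumer",
                    domain=domain,
                    layer=layer,
                )
            )
    for code, name, domain in _detritus_meta(config.n_detritus):
        rows.append(dict(code=code, name=name, type="detritus", domain=domain, layer=0))
    return pd.DataFrame(rows)


def generate_web(config: WebConfig) -> ModelDefinition:
    """Generate a balanced-by-construction web; deterministic given the seed.

    The construction is retried with an incremented sub-seed (the web is
    regenerated from scratch) in the rare event that the direct-impact
    matrix of the solved web has spectral radius ≥ 1, so the emitted web
    always supports a convergent impact expansion.
    """
    model, _ = generate_web_with_truth(config)
    return model


def generate_web_with_truth(config: WebConfig) -> tuple[ModelDefinition, pd.DataFrame]:
    """As :func:`generate_web`, also returning the ground-truth table.

    The truth table has one row per group with its layer and the true
    ``B`` and ``EE`` implied by the construction (EE is blanked in the
    emitted model).
    """
    config = config.validated()
    from .mti import net_impact_matrix  # local import to avoid a cycle

    last_radius = math.nan
    for attempt in range(60):
        rng = np.random.default_rng(int(config.seed) + 1_000_003 * attempt)
        meta = _build_meta(config, rng)
        model, truth = assemble_from_meta(meta, config, rng, n_fleets=config.n_fleets)
        balanced = solve_balance(model)
        q = net_impact_matrix(balanced)
        radius = float(np.max(np.abs(np.linalg.eigvals(q.to_numpy()))))
        if radius < 1.0:
            truth = truth.join(balanced.diagnostics["EE"].rename("EE_check"), how="left")
            return model, truth
        last_radius = radius
    raise WebGenerationError(
        f"could not generate a web with spectral radius < 1 (last was {last_radius:.4g})"
    )


def assemble_from_meta(
    meta: pd.DataFrame,
    config: WebConfig,
    rng: np.random.Generator,
    *,
    n_fleets: int = 0,
    fleet_targets: list[tuple[str, set[str]]] | None = None,
    forced_imports: dict[str, float] | None = None,
    forced_nm: dict[str, float] | None = None,
) -> tuple[ModelDefinition, pd.DataFrame]:
    """Assemble a balanced web over an explicit group structure.

    ``meta`` has columns ``code, name, type, domain, layer`` in the
    desired model order.  ``fleet_targets`` optionally fixes fleet names
    and target groups (apex groups nobody eats are still added so every
    living group keeps EE > 0); ``forced_imports`` pins the diet import
    fraction of chosen consumers; ``forced_nm`` sets net migration.
    """
    forced_imports = forced_imports or {}
    forced_nm = forced_nm or {}
    lo, hi = config.ee_range

    groups: dict[str, GroupSpec] = {}
    for _, m in meta.iterrows():
        if m["type"] == "producer":
            pb = float(rng.uniform(*PRODUCER_PB))
            groups[m["code"]] = GroupSpec(
                code=m["code"], name=m["name"], group_type="producer",
                domain=m["domain"], PB=pb, GS=0.0,
            )
        elif m["type"] == "consumer":
            pb = float(rng.uniform(*_consumer_pb_range(int(m["layer"]), config.n_layers)))
            pq = float(rng.uniform(*PQ_RANGE))
            groups[m["code"]] = GroupSpec(
                code=m["code"], name=m["name"], group_type="consumer",
                domain=m["domain"], PB=pb, QB=pb / pq, PQ=pq, GS=config.gs,
            )
        else:
            groups[m["code"]] = GroupSpec(
                code=m["code"], name=m["name"], group_type="detritus",
                domain=m["domain"], B=float(rng.uniform(10, 50)), PB=math.nan, EE=math.nan,
            )
    for code, nm in forced_nm.items():
        groups[code].NM = float(nm)

    codes = list(meta["code"])
    layer_of = dict(zip(meta["code"], meta["layer"]))
    type_of = dict(zip(meta["code"], meta["type"]))
    producers = [c for c in codes if type_of[c] == "producer"]
    consumers = [c for c in codes if type_of[c] == "consumer"]
    detritus = [c for c in codes if type_of[c] == "detritus"]

    # producer biomasses: the base of the pyramid
    for c in producers:
        groups[c].B = float(rng.uniform(10, 40))

    # EE-capacity caps: hard ceiling on how much of each group's production
    # consumers may take; detritus pools are capped by the guaranteed
    # minimum inflow from producers' unconsumed production
    cap: dict[str, float] = {}
    for c in producers:
        cap[c] = hi * groups[c].B * groups[c].PB
    pool_for = _default_pool_for_domain(groups, detritus)
    for d in detritus:
        cap[d] = 0.0
    for c in producers:
        cap[pool_for[groups[c].domain]] += (1.0 - hi) * groups[c].B * groups[c].PB

    diet = _sample_diets(config, rng, meta, cap, forced_imports)

    # biomasses layer by layer, greedily respecting prey caps
    demand = {c: 0.0 for c in codes}
    prev_layer_b = sum(groups[c].B for c in producers)
    for layer in range(1, config.n_layers + 1):
        members = [c for c in consumers if layer_of[c] == layer]
        if not members:
            continue
        layer_demand: dict[str, dict[str, float]] = {}
        for j in members:
            col = diet[j]
            prey = [p for p, w in col.items() if w > 0 and p != "import"]
            avail = {p: cap[p] - demand[p] for p in prey}
            q_max = min(avail[p] / col[p] for p in prey)
            if q_max <= 0:
                raise WebGenerationError(f"layer {layer}: no prey capacity left for {j}")
            u = float(rng.uniform(0.15, 0.4))
            Q = q_max * u
            groups[j].B = Q / groups[j].QB
            layer_demand[j] = {p: Q * col[p] for p in prey}
            for p in prey:
                demand[p] += Q * col[p]
        layer_b = sum(groups[j].B for j in members)
        if layer_b > prev_layer_b:
            # enforce the biomass pyramid: shrink the whole layer
            factor = 0.95 * prev_layer_b / layer_b
            for j in members:
                groups[j].B *= factor
                for p, v in layer_demand[j].items():
                    demand[p] += v * (factor - 1.0)
            layer_b *= factor
        for j in members:
            cap[j] = hi * groups[j].B * groups[j].PB
        prev_layer_b = layer_b

    fleets = _build_fleets(
        config, rng, groups, diet, demand, detritus, consumers,
        n_fleets=n_fleets, fleet_targets=fleet_targets,
    )

    catch = {c: 0.0 for c in codes}
    for f in fleets:
        tot = f.catch()
        for c in codes:
            catch[c] += float(tot.get(c, 0.0))

    # net migration is an absolute rate; rescale the whole web (EE, TL and
    # MTI are invariant under a uniform biomass/catch rescaling) so any
    # forced inward migration stays a minor term of its group's budget
    k_scale = 1.0
    for c, nm in forced_nm.items():
        if nm < 0 and (demand[c] + catch[c]) > 0:
            k_scale = max(k_scale, 2.0 * (-nm) / (demand[c] + catch[c]))
    if k_scale > 1.0:
        for g in groups.values():
            if not math.isnan(g.B):
                g.B *= k_scale
        for f in fleets:
            f.landings *= k_scale
            f.discards *= k_scale
        for c in codes:
            demand[c] *= k_scale
            catch[c] *= k_scale
    truth_rows = []
    for c in codes:
        g = groups[c]
        if g.is_living:
            ee = (demand[c] + catch[c] + g.NM + g.BA) / (g.B * g.PB)
        else:
            ee = math.nan
        truth_rows.append(dict(code=c, layer=layer_of[c], B=g.B, EE=ee))
    truth = pd.DataFrame(truth_rows).set_index("code")

    # emit with EE blanked: the solver must recover every EE
    dc = pd.DataFrame(0.0, index=codes, columns=consumers)
    imports = pd.Series(0.0, index=consumers)
    for j in consumers:
        for p, w in diet[j].items():
            if p == "import":
                imports[j] = w
            else:
                dc.loc[p, j] = w
    ordered = [groups[c] for c in codes]
    for g in ordered:
        if g.is_living:
            g.EE = math.nan
    model = ModelDefinition(ordered, DietMatrix(dc, imports), fleets, None)
    return model, truth


def _default_pool_for_domain(groups: dict[str, GroupSpec], detritus: list[str]) -> dict[str, str]:
    def is_carrion(d: str) -> bool:
        return groups[d].code.upper() == "DC" or "carrion" in groups[d].name.lower()

    ordinary = [d for d in detritus if not is_carrion(d)] or list(detritus)
    benthic_pool = next((d for d in ordinary if groups[d].domain == "benthic"), ordinary[0])
    suspended_pool = next(
        (d for d in ordinary if groups[d].domain in ("pelagic", "demersal")), ordinary[0]
    )
    return {
        "benthic": benthic_pool,
        "demersal": benthic_pool,
        "pelagic": suspended_pool,
    }


def _sample_diets(
    config: WebConfig,
    rng: np.random.Generator,
    meta: pd.DataFrame,
    cap: dict[str, float],
    forced_imports: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Prey sets and Dirichlet diet weights; columns sum to 1 exactly."""
    layer_of = dict(zip(meta["code"], meta["layer"]))
    type_of = dict(zip(meta["code"], meta["type"]))
    codes = list(meta["code"])
    consumers = [c for c in codes if type_of[c] == "consumer"]
    diet: dict[str, dict[str, float]] = {}
    preyed: set[str] = set()
    for j in sorted(consumers, key=lambda c: layer_of[c]):
        # prey come from strictly lower layers; detritus pools that can
        # receive no inflow (cap 0) are not offered as food
        candidates = [
            p
            for p in codes
            if layer_of[p] < layer_of[j]
            and (type_of[p] != "detritus" or cap.get(p, 0.0) > 0)
        ]
        if not candidates:
            raise WebGenerationError(f"layer {layer_of[j]}: no feasible prey for {j}")
        chosen = [p for p in candidates if rng.random() < config.connectance]
        # keep diets diverse: a single-prey diet eaten by the prey's sole
        # predator forms a ±1 interaction pair whose impact expansion sits
        # on the unit circle, so draw at least two prey when possible
        while len(chosen) < min(2, len(candidates)):
            extra = candidates[int(rng.integers(0, len(candidates)))]
            if extra not in chosen:
                chosen.append(extra)
        # low layers lean on detritus, as bacteria, deposit feeders and
        # zooplankton do; detritus is also the web's damping sink, since
        # consuming it harms nothing
        pools = [p for p in candidates if type_of[p] == "detritus"]
        add_prob = 0.8 if layer_of[j] <= 2 else 0.5
        for p in pools:
            if p not in chosen and rng.random() < add_prob:
                chosen.append(p)
        weights = rng.dirichlet(2.0 * np.ones(len(chosen)))
        if len(chosen) > 1:
            weights = 0.6 * weights + 0.4 / len(chosen)  # bound the top share
        det_idx = [k for k, p in enumerate(chosen) if type_of[p] == "detritus"]
        if det_idx:
            # low layers lean on detritus heavily, upper layers scavenge a
            # little; either way detritus consumption harms nothing
            if layer_of[j] <= 2:
                det_share = float(rng.uniform(0.3, 0.6))
            else:
                det_share = float(rng.uniform(0.1, 0.25))
            w_det = weights[det_idx].sum()
            live_idx = [k for k in range(len(chosen)) if k not in det_idx]
            if 0 < w_det < det_share and live_idx:
                weights[det_idx] *= det_share / w_det
                weights[live_idx] *= (1.0 - det_share) / max(1e-12, weights[live_idx].sum())
        imp = 0.0
        if forced_imports and j in forced_imports:
            imp = float(forced_imports[j])
        elif rng.random() < config.import_prob:
            imp = float(rng.uniform(*config.import_range))
        diet[j] = _quantize_diet(
            {p: float(w) for p, w in zip(chosen, weights)}, imp
        )
        preyed.update(p for p in diet[j] if p != "import")
    # every non-top group should have a predator so its EE is positive;
    # attach orphans to a random consumer of a higher layer
    top = config.n_layers
    for p in codes:
        if p in preyed or type_of[p] == "detritus":
            continue
        if type_of[p] == "consumer" and layer_of[p] >= top:
            continue  # apex: fleets will take care of it
        eligible = [j for j in consumers if layer_of[j] > layer_of[p]]
        if not eligible:
            continue
        j = eligible[int(rng.integers(0, len(eligible)))]
        col = dict(diet[j])
        imp = col.pop("import", 0.0)
        shares = {p2: 0.9 * v for p2, v in col.items()}
        shares[p] = shares.get(p, 0.0) + 0.1 * sum(col.values())
        diet[j] = _quantize_diet(shares, imp)
    return diet


def _build_fleets(
    config: WebConfig,
    rng: np.random.Generator,
    groups: dict[str, GroupSpec],
    diet: dict[str, dict[str, float]],
    demand: dict[str, float],
    detritus: list[str],
    consumers: list[str],
    *,
    n_fleets: int = 0,
    fleet_targets: list[tuple[str, set[str]]] | None = None,
) -> list[FleetSpec]:
    if fleet_targets is not None:
        names = [name for name, _ in fleet_targets]
        targets_per_fleet = [set(t) for _, t in fleet_targets]
    else:
        if n_fleets < 1:
            return []
        names = [f"FLEET{k + 1}" for k in range(n_fleets)]
        targets_per_fleet = [set() for _ in range(n_fleets)]
    if not names:
        return []

    apex = [c for c in consumers if not any(c in diet[j] for j in consumers if j != c)]
    covered = set().union(*targets_per_fleet) if targets_per_fleet else set()
    for c in (a for a in apex if a not in covered):
        # every apex group must be caught, or its EE is zero; spreading each
        # over all fleets keeps any single fleet from dominating its removal
        # (a sole remover is a ±1 interaction pair in the impact matrix)
        for targets in targets_per_fleet:
            targets.add(c)
    if fleet_targets is None:
        extra_pool = [c for c in consumers if c not in apex]
        for k in range(len(names)):
            if not extra_pool:
                break
            # broad, overlapping catch portfolios keep each fleet's catch
            # composition diffuse
            n_extra = max(2, int(round(0.6 * len(extra_pool))))
            pick = rng.choice(extra_pool, size=min(n_extra, len(extra_pool)), replace=False)
            targets_per_fleet[k].update(str(c) for c in pick)

    carrion = next(
        (d for d in detritus if "carrion" in groups[d].name.lower() or d.upper() == "DC"),
        detritus[0],
    )

    # total catch per group: at most half its unconsumed production, and at
    # least enough to offset any inward migration so EE stays positive
    total_catch: dict[str, float] = {}
    fleets_on: dict[str, list[int]] = {}
    for k, targets in enumerate(targets_per_fleet):
        for c in targets:
            fleets_on.setdefault(c, []).append(k)
    for c, ks in fleets_on.items():
        g = groups[c]
        slack = g.B * g.PB - demand[c]
        # catches are kept a modest fraction of predation pressure so no
        # fleet dominates the removal of a preyed-upon group; apex groups
        # (no predation) get light catches so they cannot dominate any
        # fleet's catch composition either
        if demand[c] > 0.0:
            cap_c = float(rng.uniform(0.3, 0.5)) * demand[c]
        else:
            cap_c = float(rng.uniform(0.02, 0.08)) * 0.5 * slack
        floor = 2.0 * max(0.0, -g.NM - demand[c])
        total_catch[c] = min(0.5 * slack, max(cap_c, floor))

    fleets = []
    for k, name in enumerate(names):
        landings = pd.Series(0.0, index=list(groups))
        discards = pd.Series(0.0, index=list(groups))
        for c, ks in fleets_on.items():
            if k not in ks:
                continue
            share = total_catch[c] / len(ks)
            dr = float(rng.uniform(0.0, 0.4))
            landings[c] = share * (1.0 - dr)
            discards[c] = share * dr
        fate = pd.Series({d: 1.0 if d == carrion else 0.0 for d in detritus})
        fleets.append(FleetSpec(name, landings, discards, fate))
    return fleets


def perturb_for_recovery(
    model: ModelDefinition,
    hide: dict[str, str] | str = "random",
    *,
    seed: int = 0,
) -> tuple[ModelDefinition, pd.DataFrame]:
    """Hide one of B/EE per living group, keeping the truth alongside.

    ``hide`` maps group codes to ``"B"`` or ``"EE"`` (groups not listed
    keep B known / EE hidden); ``"random"`` draws the choice per group
    from ``seed``.  The input model is first solved so every parameter
    is known; the returned model has exactly one unknown per living
    group and the returned table records the hidden true values for a
    recovery test harness.
    """
    balanced = solve_balance(model)
    rng = np.random.default_rng(seed)
    living = [g.code for g in model.living]
    if hide == "random":
        hide = {c: ("B" if rng.random() < 0.5 else "EE") for c in living}
    bad = {c: h for c, h in hide.items() if h not in ("B", "EE")}
    if bad:
        code, h = next(iter(bad.items()))
        raise ValueError(f"{code}: cannot hide {h!r}; hide exactly one of B or EE")

    out = model.copy()
    rows = []
    for g in out.groups:
        if not g.is_living:
            continue
        solved = balanced.groups.loc[g.code]
        choice = hide.get(g.code, "EE")
        if choice == "B":
            truth_val = float(solved["B"])
            g.B = math.nan
            g.EE = float(solved["EE"])
        else:
            truth_val = float(solved["EE"])
            g.EE = math.nan
            g.B = float(solved["B"])
        rows.append(dict(code=g.code, hidden=choice, value=truth_val))
    return out, pd.DataFrame(rows).set_index("code")
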