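"""Model definition containers and delimited-table input/output.

A model lives in a directory of UTF-8 CSV files:

``groups.csv``
    one row per functional group, in model order; columns ``code``,
    ``name``, ``type`` (consumer/producer/detritus), ``domain``
    (benthic/demersal/pelagic), ``B``, ``PB``, ``QB``, ``PQ``, ``EE``,
    ``GS``, ``BA``, ``NM``.  Missing values are empty cells, never 0:
    an empty ``B`` or ``EE`` marks the group's unknown for the balance
    solver, while 0 is a legitimate value.
``diet.csv``
    prey (rows) × consumer (columns) diet fractions, first column the
    prey code; an optional final ``import`` row holds the diet fraction
    taken outside the modelled system.
``fleets_landings.csv`` / ``fleets_discards.csv``
    group (rows) × fleet (columns) catches in t·km⁻²·yr⁻¹.
``detritus_fate.csv`` (optional)
    living group (rows) × detritus pool (columns): fractions of
    non-harvest losses (unassimilated food + other mortality) routed to
    each pool.
``discard_fate.csv`` (optional)
    fleet (rows) × detritus pool (columns): where discards sink.

Group order is file order and is preserved in every derived matrix, so
row/column indexing is reproducible across the whole analysis chain.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_TYPES = ("consumer", "producer", "detritus")
DOMAINS = ("benthic", "demersal", "pelagic")

#: column order of groups.csv; also the canonical field order of GroupSpec
GROUP_COLUMNS = [
    "code",
    "name",
    "type",
    "domain",
    "B",
    "PB",
    "QB",
    "PQ",
    "EE",
    "GS",
    "BA",
    "NM",
]

IMPORT_ROW = "import"

DEFAULT_GS = 0.2


class ValidationError(ValueError):
    """A model definition violates a structural invariant."""


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class GroupSpec:
    """One functional group of the web.

    Rates are annual: ``PB`` (production/biomass) and ``QB``
    (consumption/biomass) in yr⁻¹, ``B`` in t·km⁻².  ``PQ`` is the
    gross-efficiency alternative to ``QB`` (``QB = PB/PQ``).  ``EE`` is
    the ecotrophic efficiency, the fraction of production used within
    the system; for living groups exactly one of ``B``/``EE`` may be
    left missing and is solved by the balance.  ``GS`` is the
    unassimilated fraction of consumption, ``BA`` biomass accumulation
    and ``NM`` net migration (emigration − immigration), both in
    t·km⁻²·yr⁻¹.
    """

    code: str
    name: str = ""
    group_type: str = "consumer"
    domain: str = "pelagic"
    B: float = math.nan
    PB: float = math.nan
    QB: float = math.nan
    PQ: float = math.nan
    EE: float = math.nan
    GS: float = math.nan
    BA: float = 0.0
    NM: float = 0.0

    @property
    def is_living(self) -> bool:
        return self.group_type != "detritus"

    @property
    def is_consumer(self) -> bool:
        return self.group_type == "consumer"

    def consumption_rate(self) -> float:
        """QB, deriving it from PB/PQ when QB itself is absent."""
        if not _missing(self.QB):
            return self.QB
        if not _missing(self.PQ) and self.PQ > 0 and not _missing(self.PB):
            return self.PB / self.PQ
        return math.nan

    def unassimilated_fraction(self) -> float:
        if not _missing(self.GS):
            return self.GS
        return DEFAULT_GS if self.is_consumer else 0.0


@dataclass
class DietMatrix:
    """Diet composition: prey × consumer fractions plus an import row.

    ``dc`` is indexed by prey code with one column per consumer;
    ``imports`` holds, per consumer, the diet fraction taken outside
    the system.  Each consumer column satisfies
    ``dc[:, j].sum() + imports[j] == 1`` within ``DIET_TOL``.
    """

    dc: pd.DataFrame
    imports: pd.Series

    DIET_TOL = 1e-6

    def column(self, consumer: str) -> pd.Series:
        return self.dc[consumer]

    def copy(self) -> "DietMatrix":
        return DietMatrix(self.dc.copy(), self.imports.copy())


@dataclass
class FleetSpec:
    """A fleet segment: landings and discards per group, discard routing."""

    name: str
    landings: pd.Series
    discards: pd.Series
    discard_fate: pd.Series  # index = detritus pool codes, sums to 1

    def catch(self) -> pd.Series:
        return self.landings.add(self.discards, fill_value=0.0)

    def copy(self) -> "FleetSpec":
        return FleetSpec(
            self.name,
            self.landings.copy(),
            self.discards.copy(),
            self.discard_fate.copy(),
        )


@dataclass
class ModelDefinition:
    """An (unbalanced) food-web model: groups, diets, fleets, detritus fate."""

    groups: list[GroupSpec]
    diet: DietMatrix
    fleets: list[FleetSpec] = field(default_factory=list)
    detritus_fate: pd.DataFrame | None = None  # living group × detritus pool

    # -- index helpers ---------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return [g.code for g in self.groups]

    @property
    def living(self) -> list[GroupSpec]:
        return [g for g in self.groups if g.is_living]

    @property
    def consumers(self) -> list[GroupSpec]:
        return [g for g in self.groups if g.is_consumer]

    @property
    def detritus_pools(self) -> list[GroupSpec]:
        return [g for g in self.groups if g.group_type == "detritus"]

    @property
    def fleet_names(self) -> list[str]:
        return [f.name for f in self.fleets]

    def group(self, code: str) -> GroupSpec:
        for g in self.groups:
            if g.code == code:
                return g
        raise KeyError(code)

    def domain_of(self) -> pd.Series:
        return pd.Series({g.code: g.domain for g in self.groups})

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            [dataclasses.replace(g) for g in self.groups],
            self.diet.copy(),
            [f.copy() for f in self.fleets],
            None if self.detritus_fate is None else self.detritus_fate.copy(),
        )

    # -- defaults --------------------------------------------------------
    def resolved_detritus_fate(self) -> pd.DataFrame:
        """Detritus-fate matrix, with the domain-based default when absent.

        Default routing: benthic and demersal groups send non-harvest
        losses to the first benthic detritus pool; pelagic groups to the
        first pelagic/demersal ("suspended") pool.  With a single pool
        everything goes there.
        """
        pools = [g.code for g in self.detritus_pools]
        living = [g.code for g in self.living]
        if self.detritus_fate is not None:
            return self.detritus_fate.loc[living, pools]
        if not pools:
            return pd.DataFrame(index=living, columns=[], dtype=float)
        # ordinary (non-carrion) pools receive the physiological losses;
        # the carrion pool is reserved for discards
        ordinary = [
            g for g in self.detritus_pools
            if g.code.upper() != "DC" and "carrion" not in g.name.lower()
        ] or self.detritus_pools
        benthic_pool = next(
            (g.code for g in ordinary if g.domain == "benthic"), ordinary[0].code
        )
        suspended_pool = next(
            (g.code for g in ordinary if g.domain in ("pelagic", "demersal")),
            ordinary[0].code,
        )
        fate = pd.DataFrame(0.0, index=living, columns=pools)
        for g in self.living:
            pool = suspended_pool if g.domain == "pelagic" else benthic_pool
            fate.loc[g.code, pool] = 1.0
        return fate

    def default_discard_pool(self) -> str | None:
        """Carrion pool if identifiable, else first benthic pool, else first."""
        pools = self.detritus_pools
        if not pools:
            return None
        for g in pools:
            if g.code.upper() == "DC" or "carrion" in g.name.lower():
                return g.code
        for g in pools:
            if g.domain == "benthic":
                return g.code
        return pools[0].code


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise ValidationError("; ".join(self.errors))


# ---------------------------------------------------------------------------
# validation


def validate(model: ModelDefinition) -> ValidationReport:
    """Check every structural invariant of a model definition.

    Pure function: errors are collected, never raised.  Errors block
    balancing; warnings flag implausible but legal input (e.g. a
    production/consumption ratio outside the 0.1–0.35 band typical of
    balanced aquatic webs).
    """
    rep = ValidationReport()
    codes = model.codes
    seen: set[str] = set()
    for c in codes:
        if c in seen:
            rep.errors.append(f"duplicate group code {c!r}")
        seen.add(c)

    for g in model.groups:
        if g.group_type not in GROUP_TYPES:
            rep.errors.append(f"{g.code}: unknown group type {g.group_type!r}")
        if g.domain not in DOMAINS:
            rep.errors.append(f"{g.code}: unknown domain {g.domain!r}")
        if not g.is_living:
            continue
        if _missing(g.PB) or g.PB <= 0:
            rep.errors.append(f"{g.code}: living group needs PB > 0")
        if _missing(g.B) and _missing(g.EE):
            rep.errors.append(f"{g.code}: under-determined group (both B and EE missing)")
        if not _missing(g.B) and g.B <= 0:
            rep.errors.append(f"{g.code}: B must be > 0 when given")
        if not _missing(g.EE) and not (0.0 <= g.EE <= 1.0):
            rep.warnings.append(f"{g.code}: EE={g.EE:g} outside [0, 1]")
        gs = g.unassimilated_fraction()
        if not (0.0 <= gs < 1.0):
            rep.errors.append(f"{g.code}: GS={gs:g} outside [0, 1)")
        if g.is_consumer:
            if math.isnan(g.consumption_rate()):
                rep.errors.append(f"{g.code}: consumer needs QB or PQ")
            elif not _missing(g.PQ) and not (0.05 <= g.PQ <= 0.5):
                rep.warnings.append(
                    f"{g.code}: PQ={g.PQ:g} outside plausible range [0.05, 0.5]"
                )
            elif (
                not _missing(g.QB)
                and not _missing(g.PB)
                and g.QB > 0
                and not (0.05 <= g.PB / g.QB <= 0.9)
            ):
                rep.warnings.append(
                    f"{g.code}: implied P/Q={g.PB / g.QB:.3g} implausible"
                )
        else:
            if not _missing(g.QB) and g.QB != 0:
                rep.errors.append(f"{g.code}: non-consumer must not have QB")

    _validate_diet(model, rep)
    _validate_fleets(model, rep)
    _validate_fate(model, rep)
    return rep


def _validate_diet(model: ModelDefinition, rep: ValidationReport) -> None:
    dc, imports = model.diet.dc, model.diet.imports
    codes = set(model.codes)
    consumer_codes = {g.code for g in model.consumers}
    for prey in dc.index:
        if prey not in codes:
            rep.errors.append(f"diet: unresolvable prey code {prey!r}")
    for col in dc.columns:
        if col not in codes:
            rep.errors.append(f"diet: unresolvable consumer code {col!r}")
            continue
        colsum = float(dc[col].sum()) + float(imports.get(col, 0.0))
        if col in consumer_codes:
            if (dc[col] < 0).any() or imports.get(col, 0.0) < 0:
                rep.errors.append(f"diet: negative fraction in column {col!r}")
            if abs(colsum - 1.0) > DietMatrix.DIET_TOL:
                rep.errors.append(
                    f"diet: column {col!r} sums to {colsum:.6g}, expected 1"
                )
        elif colsum != 0.0:
            rep.errors.append(f"diet: non-consumer column {col!r} must be all zero")
    for g in model.consumers:
        if g.code not in dc.columns:
            rep.errors.append(f"diet: consumer {g.code!r} has no diet column")


def _validate_fleets(model: ModelDefinition, rep: ValidationReport) -> None:
    codes = set(model.codes)
    pools = {g.code for g in model.detritus_pools}
    for f in model.fleets:
        for series, what in ((f.landings, "landings"), (f.discards, "discards")):
            bad = [c for c in series.index if c not in codes]
            if bad:
                rep.errors.append(f"fleet {f.name}: unresolvable group {bad[0]!r} in {what}")
            if (series < 0).any():
                rep.errors.append(f"fleet {f.name}: negative {what}")
        if float(f.discards.sum()) > 0 and pools:
            if abs(float(f.discard_fate.sum()) - 1.0) > 1e-9:
                rep.errors.append(f"fleet {f.name}: discard fate does not sum to 1")
            if any(p not in pools for p in f.discard_fate.index):
                rep.errors.append(f"fleet {f.name}: discard fate names unknown pool")


def _validate_fate(model: ModelDefinition, rep: ValidationReport) -> None:
    if model.detritus_fate is None:
        return
    fate = model.detritus_fate
    living = [g.code for g in model.living]
    pools = [g.code for g in model.detritus_pools]
    missing_rows = [c for c in living if c not in fate.index]
    if missing_rows:
        rep.errors.append(f"detritus fate: missing row for {missing_rows[0]!r}")
        return
    if any(p not in pools for p in fate.columns):
        rep.errors.append("detritus fate: column is not a detritus pool")
        return
    sums = fate.loc[living].sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        rep.errors.append(
            f"detritus fate: row {bad.index[0]!r} sums to {bad.iloc[0]:.6g}, expected 1"
        )


# ---------------------------------------------------------------------------
# reading


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing table {path.name}")
    return pd.read_csv(path, float_precision="round_trip", **kw)


def read_model(path: str | Path) -> ModelDefinition:
    """Read a model directory and return a validated :class:`ModelDefinition`.

    Raises :class:`ValidationError` naming the offending row/column if a
    required table is missing or an invariant fails.
    """
    path = Path(path)
    gdf = _read_csv(path / "groups.csv")
    required = {"code", "type", "domain", "PB"}
    miss = required - set(gdf.columns)
    if miss:
        raise ValidationError(f"groups.csv: missing column {sorted(miss)[0]!r}")
    groups = []
    for _, row in gdf.iterrows():
        groups.append(
            GroupSpec(
                code=str(row["code"]),
                name=str(row.get("name", "")) if not _missing(row.get("name")) else "",
                group_type=str(row["type"]),
                domain=str(row["domain"]),
                B=float(row.get("B", math.nan)) if "B" in gdf else math.nan,
                PB=float(row["PB"]) if not _missing(row["PB"]) else math.nan,
                QB=float(row.get("QB", math.nan)) if "QB" in gdf else math.nan,
                PQ=float(row.get("PQ", math.nan)) if "PQ" in gdf else math.nan,
                EE=float(row.get("EE", math.nan)) if "EE" in gdf else math.nan,
                GS=float(row.get("GS", math.nan)) if "GS" in gdf else math.nan,
                BA=_zero_if_missing(row.get("BA", 0.0)),
                NM=_zero_if_missing(row.get("NM", 0.0)),
            )
        )
    codes = [g.code for g in groups]

    ddf = _read_csv(path / "diet.csv", index_col=0)
    ddf = ddf.fillna(0.0).astype(float)
    consumers = [g.code for g in groups if g.is_consumer]
    if IMPORT_ROW in ddf.index:
        imports = ddf.loc[IMPORT_ROW].reindex(consumers).fillna(0.0)
        ddf = ddf.drop(index=IMPORT_ROW)
    else:
        imports = pd.Series(0.0, index=consumers)
    dc = ddf.reindex(index=codes, columns=consumers, fill_value=0.0)
    dc.index.name = None
    dc.columns.name = None
    imports.name = None
    # keep unresolvable names visible to validation rather than dropping them
    stray_rows = [r for r in ddf.index if r not in codes]
    stray_cols = [c for c in ddf.columns if c not in codes]
    if stray_rows:
        raise ValidationError(f"diet.csv: unresolvable prey code {stray_rows[0]!r}")
    if stray_cols:
        raise ValidationError(f"diet.csv: unresolvable consumer code {stray_cols[0]!r}")
    diet = DietMatrix(dc, imports)

    fleets = _read_fleets(path, groups)
    fate = None
    fate_path = path / "detritus_fate.csv"
    if fate_path.exists():
        fate = pd.read_csv(fate_path, index_col=0, float_precision="round_trip").fillna(0.0).astype(float)

    model = ModelDefinition(groups, diet, fleets, fate)
    validate(model).raise_if_invalid()
    return model


def _zero_if_missing(x) -> float:
    return 0.0 if _missing(x) else float(x)


def _read_fleets(path: Path, groups: Sequence[GroupSpec]) -> list[FleetSpec]:
    landings_path = path / "fleets_landings.csv"
    discards_path = path / "fleets_discards.csv"
    if not landings_path.exists() and not discards_path.exists():
        return []
    codes = [g.code for g in groups]
    zero = pd.DataFrame(0.0, index=codes, columns=[])
    ldf = (
        pd.read_csv(landings_path, index_col=0, float_precision="round_trip").fillna(0.0).astype(float)
        if landings_path.exists()
        else zero
    )
    ddf = (
        pd.read_csv(discards_path, index_col=0, float_precision="round_trip").fillna(0.0).astype(float)
        if discards_path.exists()
        else zero
    )
    names = list(dict.fromkeys(list(ldf.columns) + list(ddf.columns)))
    dfate_path = path / "discard_fate.csv"
    dfate = (
        pd.read_csv(dfate_path, index_col=0, float_precision="round_trip").fillna(0.0).astype(float)
        if dfate_path.exists()
        else None
    )
    pools = [g.code for g in groups if g.group_type == "detritus"]
    default_pool = None
    for g in groups:
        if g.group_type == "detritus" and (
            g.code.upper() == "DC" or "carrion" in g.name.lower()
        ):
            default_pool = g.code
            break
    if default_pool is None:
        default_pool = next(
            (g.code for g in groups if g.group_type == "detritus" and g.domain == "benthic"),
            pools[0] if pools else None,
        )
    fleets = []
    for name in names:
        landings = ldf[name].reindex(codes).fillna(0.0) if name in ldf else pd.Series(0.0, index=codes)
        discards = ddf[name].reindex(codes).fillna(0.0) if name in ddf else pd.Series(0.0, index=codes)
        if dfate is not None and name in dfate.index:
            fate = dfate.loc[name]
        elif default_pool is not None:
            fate = pd.Series({p: 1.0 if p == default_pool else 0.0 for p in pools})
        else:
            fate = pd.Series(dtype=float)
        fleets.append(FleetSpec(name, landings, discards, fate))
    return fleets


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    # repr() is the shortest text that parses back to the same float64;
    # together with round-trip parsing this makes write→read an identity
    if _missing(x):
        return ""
    return repr(float(x))


def write_model(model: ModelDefinition, path: str | Path) -> list[Path]:
    """Write a model definition as the documented CSV directory layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for g in model.groups:
        rows.append(
            {
                "code": g.code,
                "name": g.name,
                "type": g.group_type,
                "domain": g.domain,
                "B": g.B,
                "PB": g.PB,
                "QB": g.QB,
                "PQ": g.PQ,
                "EE": g.EE,
                "GS": g.GS,
                "BA": g.BA,
                "NM": g.NM,
            }
        )
    gdf = pd.DataFrame(rows, columns=GROUP_COLUMNS)
    written.append(write_results(gdf, path / "groups.csv", index=False))

    consumers = [g.code for g in model.consumers]
    ddf = model.diet.dc[consumers].copy()
    ddf.loc[IMPORT_ROW] = model.diet.imports.reindex(consumers).fillna(0.0)
    ddf.index.name = "prey"
    written.append(write_results(ddf, path / "diet.csv"))

    if model.fleets:
        codes = model.codes
        landings = pd.DataFrame({f.name: f.landings.reindex(codes) for f in model.fleets})
        discards = pd.DataFrame({f.name: f.discards.reindex(codes) for f in model.fleets})
        landings.index.name = discards.index.name = "code"
        written.append(write_results(landings, path / "fleets_landings.csv"))
        written.append(write_results(discards, path / "fleets_discards.csv"))
        pools = [g.code for g in model.detritus_pools]
        if pools:
            dfate = pd.DataFrame(
                {f.name: f.discard_fate.reindex(pools).fillna(0.0) for f in model.fleets}
            ).T
            dfate.index.name = "fleet"
            written.append(write_results(dfate, path / "discard_fate.csv"))
    if model.detritus_fate is not None:
        fate = model.detritus_fate.copy()
        fate.index.name = "code"
        written.append(write_results(fate, path / "detritus_fate.csv"))
    return written


def write_results(table: pd.DataFrame, path: str | Path, *, index: bool = True) -> Path:
    """Write a result table as CSV with deterministic numeric text.

    Floats are rendered with 17 significant digits so that
    ``read_table(write_results(x)) == x`` bit-for-bit on float64.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_fmt)
    out.to_csv(path, index=index)
    return path


def read_table(path: str | Path, *, index_col: int | None = 0) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(Path(path), index_col=index_col, float_precision="round_trip")
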