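import numpy as np
import pandas as pd
import pytest

from trophicnet.mass_balance import solve_balance
from trophicnet.model_io import GroupSpec
from trophicnet.synthetic import generate_web
from trophicnet.trophic import omnivory, system_statistics, trophic_levels

from conftest import make_model, web_config


def _mixed_feeder():
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=10, PB=10, EE=0.5, GS=0),
        GroupSpec("H", "", "consumer", "pelagic", B=1, PB=1, QB=5, EE=0.5, GS=0.2),
        GroupSpec("X", "", "consumer", "pelagic", B=0.1, PB=1, QB=5, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    return make_model(groups, {("P", "H"): 1.0, ("P", "X"): 0.5, ("H", "X"): 0.5})


def test_trophic_level_definitions(toy_chain):
    """Producers and detritus sit at exactly 1; a chain climbs by 1."""
    b = solve_balance(toy_chain)
    tl = trophic_levels(b)
    assert tl["P"] == 1.0
    assert tl["H"] == pytest.approx(2.0)
    assert tl["C"] == pytest.approx(3.0)


def test_mixed_diet_trophic_level_and_omnivory():
    """50% TL-1 prey + 50% TL-2 prey → TL 2.5, OI 0.25."""
    b = solve_balance(_mixed_feeder())
    tl = trophic_levels(b)
    assert tl["X"] == pytest.approx(2.5)
    assert tl["D"] == 1.0
    oi, _ = omnivory(b, tl)
    assert oi["H"] == 0.0  # single prey: zero variance
    assert oi["X"] == pytest.approx(0.25)


def test_pure_importer_gets_conventional_level():
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=10, PB=10, EE=0, GS=0),
        GroupSpec("C", "", "consumer", "pelagic", B=1, PB=2, QB=10, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    model = make_model(groups, {}, imports={"C": 1.0})
    b = solve_balance(model)
    tl = trophic_levels(b)
    assert tl["C"] == pytest.approx(2.0)
    assert any("entirely imported" in w for w in b.warnings)


def test_import_conventions_differ_for_heavy_importer():
    """Renormalizing keeps a mostly-importing predator at its in-system
    trophic position; counting imports as TL-1 food drags it down."""
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=100, PB=10, GS=0),
        GroupSpec("H", "", "consumer", "pelagic", B=2, PB=1, QB=5, EE=0.5, GS=0.2),
        GroupSpec("T", "", "consumer", "pelagic", B=0.1, PB=0.5, QB=3, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    model = make_model(
        groups, {("P", "H"): 1.0, ("H", "T"): 0.3}, imports={"T": 0.7}
    )
    b = solve_balance(model)
    tl_renorm = trophic_levels(b, import_convention="renormalize")
    tl_low = trophic_levels(b, import_convention="import_tl_one")
    assert tl_renorm["T"] == pytest.approx(3.0)
    assert tl_low["T"] == pytest.approx(1 + 0.3 * 2 + 0.7 * 1)
    assert tl_low["T"] < tl_renorm["T"]


@pytest.mark.parametrize("seed", [4, 11])
def test_linear_solve_matches_fixed_point_iteration(seed):
    """The TL linear system agrees with naive iteration to 1e-10."""
    b = solve_balance(generate_web(web_config(seed=seed)))
    tl = trophic_levels(b)
    dc = b.definition.diet.dc.reindex(columns=b.consumer_codes).fillna(0.0)
    sums = dc.sum(axis=0)
    W = dc.div(sums.where(sums > 0, 1.0), axis=1)
    guess = pd.Series(1.0, index=b.codes)
    for _ in range(1000):
        nxt = pd.Series(1.0, index=b.codes)
        for j in b.consumer_codes:
            nxt[j] = 1.0 + float((W[j] * guess.reindex(W.index)).sum())
        if (nxt - guess).abs().max() < 1e-13:
            break
        guess = nxt
    assert (tl - guess).abs().max() < 1e-10


def test_omnivory_invariant_under_prey_split():
    """Splitting a prey into two same-TL prey with the same total share
    changes neither TL nor OI."""
    groups = [
        GroupSpec("P1", "", "producer", "pelagic", B=10, PB=10, EE=0.5, GS=0),
        GroupSpec("P2", "", "producer", "pelagic", B=10, PB=10, EE=0.5, GS=0),
        GroupSpec("H", "", "consumer", "pelagic", B=1, PB=1, QB=5, EE=0.5, GS=0.2),
        GroupSpec("X", "", "consumer", "pelagic", B=0.1, PB=1, QB=5, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    merged = make_model(groups, {("P1", "H"): 1.0, ("P1", "X"): 0.5, ("H", "X"): 0.5})
    split = make_model(
        groups,
        {("P1", "H"): 1.0, ("P1", "X"): 0.2, ("P2", "X"): 0.3, ("H", "X"): 0.5},
    )
    tl_m = trophic_levels(solve_balance(merged))
    tl_s = trophic_levels(solve_balance(split))
    assert tl_m["X"] == pytest.approx(tl_s["X"])
    bm, bs = solve_balance(merged), solve_balance(split)
    oi_m, _ = omnivory(bm, tl_m)
    oi_s, _ = omnivory(bs, tl_s)
    assert oi_m["X"] == pytest.approx(oi_s["X"])


def test_system_omnivory_is_a_weighted_mean():
    for seed in (6, 13):
        b = solve_balance(generate_web(web_config(seed=seed)))
        tl = trophic_levels(b)
        oi, soi = omnivory(b, tl)
        assert oi.min() - 1e-12 <= soi <= oi.max() + 1e-12
        assert (oi >= 0).all()


def test_system_totals_toy(toy_two_group):
    """Hand sums: production 10·10 + 1·2 = 102, consumption 1·10 = 10."""
    stats = system_statistics(solve_balance(toy_two_group))
    assert stats.total_production == pytest.approx(102.0)
    assert stats.total_consumption == pytest.approx(10.0)
    assert stats.net_primary_production == pytest.approx(100.0)


def test_throughput_identity():
    """TST = consumption + exports + respiration + flows into detritus,
    with each term recomputed independently from the flow tables."""
    b = solve_balance(generate_web(web_config(seed=31)))
    stats = system_statistics(b)
    living = b.living_codes
    q = float(b.groups.loc[living, "Q"].sum())
    r = float(b.groups.loc[living, "R"].sum())
    fd = float(b.detritus["inflow"].sum())
    ex = (
        float(b.landings.to_numpy().sum())
        + float(b.detritus["export"].sum())
        + float((b.groups.loc[living, "NM"] + b.groups.loc[living, "BA"]).sum())
    )
    assert stats.total_system_throughput == pytest.approx(q + r + fd + ex, abs=1e-9)


def test_all_producer_web_degenerate_ratios():
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=10, PB=10, EE=0, GS=0),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    stats = system_statistics(solve_balance(make_model(groups, {})))
    assert stats.total_consumption == 0.0
    assert np.isinf(stats.pp_over_r)
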