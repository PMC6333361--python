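import numpy as np
import pandas as pd
import pytest

from trophicnet.bpc import (
    cross_domain_flux,
    cross_domain_impact,
    default_flux_exclusion,
    exploitation,
)
from trophicnet.mass_balance import solve_balance
from trophicnet.model_io import FleetSpec, GroupSpec
from trophicnet.mti import impact_analysis
from trophicnet.synthetic import generate_web

from conftest import make_model, web_config


def _fished_pair():
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=100, PB=10, GS=0),
        GroupSpec("A", "", "consumer", "pelagic", B=1, PB=1, QB=5, GS=0.2),
        GroupSpec("B", "", "consumer", "benthic", B=1, PB=1, QB=5, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    codes = ["P", "A", "B", "D"]
    fleet = FleetSpec(
        "F1",
        landings=pd.Series([0, 0.2, 0.3, 0], index=codes),
        discards=pd.Series(0.0, index=codes),
        discard_fate=pd.Series({"D": 1.0}),
    )
    return make_model(
        groups, {("P", "A"): 1.0, ("P", "B"): 1.0}, fleets=[fleet]
    )


def test_exploitation_rates_and_cumulative():
    """Y=0.2,B=1,PB=1 → E=0.2; two groups at 0.2, 0.3 → CumE=0.5."""
    b = solve_balance(_fished_pair())
    table = exploitation(b)
    assert table.per_group.loc["A", "F"] == pytest.approx(0.2)
    assert table.per_group.loc["A", "E"] == pytest.approx(0.2)
    assert table.per_group.loc["B", "E"] == pytest.approx(0.3)
    assert table.per_group.loc["P", "E"] == 0.0  # unfished
    assert table.cum_e["F1"] == pytest.approx(0.5)


def test_cumulative_exploitation_additive_over_fleets():
    model = generate_web(web_config(seed=12))
    b = solve_balance(model)
    table = exploitation(b)
    np.testing.assert_allclose(
        table.contributions.sum(axis=1), table.per_group["E"], atol=1e-12
    )
    # in a balanced web no group is fished harder than it dies: E ≤ 1
    assert (table.per_group["E"] <= 1.0 + 1e-12).all()
    assert (table.cum_e >= table.contributions.max(axis=0) - 1e-12).all()


def test_single_domain_web_has_no_cross_domain_flux():
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=10, PB=10, GS=0),
        GroupSpec("C", "", "consumer", "pelagic", B=1, PB=2, QB=10, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "pelagic", B=1),
    ]
    b = solve_balance(make_model(groups, {("P", "C"): 1.0}))
    flux = cross_domain_flux(b)
    assert (flux["consumer_flux_other_domains"] == 0).all()
    assert (flux["source_flux_other_domains"] == 0).all()


def test_selective_cross_domain_sum():
    """A pelagic consumer eating 3 of benthic prey and 5 of pelagic prey
    exchanges exactly 3 with the other domains."""
    groups = [
        GroupSpec("BP", "", "producer", "benthic", B=100, PB=10, GS=0),
        GroupSpec("PP", "", "producer", "pelagic", B=100, PB=10, GS=0),
        GroupSpec("C", "", "consumer", "pelagic", B=1, PB=2, QB=8, EE=0, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    model = make_model(groups, {("BP", "C"): 3 / 8, ("PP", "C"): 5 / 8})
    b = solve_balance(model)
    flux = cross_domain_flux(b)
    assert flux.loc["C", "consumer_flux_other_domains"] == pytest.approx(3.0)
    assert flux.loc["BP", "source_flux_other_domains"] == pytest.approx(3.0)
    assert flux.loc["PP", "source_flux_other_domains"] == 0.0


def test_flux_partition_property():
    """With no exclusions: cross-domain intake + same-domain intake +
    import = total consumption, for every consumer."""
    b = solve_balance(generate_web(web_config(seed=21)))
    flux = cross_domain_flux(b, exclude=[])
    domain = b.groups["domain"]
    for j in b.consumer_codes:
        same = float(
            b.T.loc[[p for p in b.T.index if domain[p] == domain[j]], j].sum()
        )
        total = flux.loc[j, "consumer_flux_other_domains"] + same + float(b.imports[j])
        assert total == pytest.approx(float(b.groups.loc[j, "Q"]), abs=1e-9)


def test_merging_domains_zeroes_coupling():
    model = generate_web(web_config(seed=25))
    for g in model.groups:
        g.domain = "pelagic"
    b = solve_balance(model)
    flux = cross_domain_flux(b, exclude=[])
    assert (flux[["consumer_flux_other_domains", "source_flux_other_domains"]] == 0).all().all()
    impact = cross_domain_impact(impact_analysis(b), b)
    assert (impact[["impact_out_pos", "impact_out_neg", "impact_in_pos", "impact_in_neg"]] == 0).all().all()


def test_unknown_exclusion_code_rejected(toy_two_group):
    b = solve_balance(toy_two_group)
    with pytest.raises(ValueError, match="NOPE"):
        cross_domain_flux(b, exclude=["NOPE"])


def test_cross_domain_impact_signs_and_selection():
    """Three groups in three domains along a chain: the fields pick
    exactly the hand-selected entries of M, split by sign."""
    b = solve_balance(_fished_pair())
    im = impact_analysis(b)
    impact = cross_domain_impact(im, b)
    M = im.M
    # A (pelagic): other-domain living groups = {B} (benthic); P is pelagic
    assert impact.loc["A", "impact_out_pos"] == pytest.approx(max(M.loc["A", "B"], 0))
    assert impact.loc["A", "impact_out_neg"] == pytest.approx(min(M.loc["A", "B"], 0))
    assert impact.loc["A", "impact_in_pos"] == pytest.approx(max(M.loc["B", "A"], 0))
    assert (impact["impact_out_pos"] >= 0).all()
    assert (impact["impact_out_neg"] <= 0).all()


def test_zero_impact_matrix_gives_zero_fields(toy_two_group):
    b = solve_balance(toy_two_group)
    im = impact_analysis(b)
    im.M.loc[:, :] = 0.0
    impact = cross_domain_impact(im, b)
    assert (impact[["impact_out_pos", "impact_out_neg", "impact_in_pos", "impact_in_neg"]] == 0).all().all()


def test_default_exclusion_covers_low_trophic_groups(sos_balanced):
    excl = default_flux_exclusion(sos_balanced)
    for code in ("PS", "BD", "ZM", "BB", "SUP", "EUP"):
        assert code in excl
    for code in ("THU", "HAK4", "EPI", "MSC"):
        assert code not in excl
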