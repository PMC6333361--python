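import numpy as np
import pandas as pd
import pytest

from trophicnet.mass_balance import solve_balance
from trophicnet.model_io import FleetSpec, GroupSpec
from trophicnet.mti import ImpactError, fleet_views, impact_analysis, mti, net_impact_matrix
from trophicnet.synthetic import generate_web

from conftest import make_model, web_config


def neumann_sum(q: np.ndarray, tol: float = 1e-14, max_terms: int = 20000) -> np.ndarray:
    """Independent oracle: summed impact pathways Σ_{n≥1} qⁿ."""
    total = np.zeros_like(q)
    term = np.eye(len(q))
    for _ in range(max_terms):
        term = term @ q
        total += term
        if np.abs(term).max() < tol:
            return total
    raise AssertionError("Neumann series did not converge")


def brute_force_q(balanced) -> pd.DataFrame:
    """Element-wise reference construction of the direct-impact matrix,
    written as independent loops over the model's raw tables."""
    model = balanced.definition
    fleets = [f.name for f in model.fleets]
    comps = balanced.codes + fleets
    q = pd.DataFrame(0.0, index=comps, columns=comps)
    dc = model.diet.dc
    T, Y = balanced.T, balanced.Y
    g = balanced.groups

    fate = model.resolved_detritus_fate()
    for j in comps:  # j = impacted component
        # positive: who feeds j
        if j in balanced.consumer_codes:
            for i in balanced.codes:
                if i in dc.index and j in dc.columns:
                    q.loc[i, j] += float(dc.loc[i, j])
        elif j in balanced.detritus_codes:
            inflow = float(balanced.detritus.loc[j, "inflow"])
            if inflow > 0:
                for i in balanced.living_codes:
                    loss = float(g.loc[i, "U"] + g.loc[i, "M0"] * g.loc[i, "B"])
                    q.loc[i, j] += float(fate.loc[i, j]) * loss / inflow
                for f in model.fleets:
                    disc = float(f.discards.sum()) * float(f.discard_fate.get(j, 0.0))
                    q.loc[f.name, j] += disc / inflow
        elif j in fleets:
            tot = float(Y[j].sum())
            if tot > 0:
                for i in balanced.codes:
                    q.loc[i, j] += float(Y.loc[i, j]) / tot
        # negative: who removes j
        if j in balanced.living_codes:
            removal = float(T.loc[j].sum()) if j in T.index else 0.0
            removal += float(Y.loc[j].sum()) if len(fleets) else 0.0
            if removal > 0:
                for i in balanced.consumer_codes:
                    q.loc[i, j] -= float(T.loc[j, i]) / removal
                for f in fleets:
                    q.loc[f, j] -= float(Y.loc[j, f]) / removal
    np.fill_diagonal(q.values, 0.0)
    return q


def test_direct_impact_signs_for_simple_pair(toy_two_group):
    """Sole prey → predator gets +1; sole predator → prey gets −1."""
    b = solve_balance(toy_two_group)
    q = net_impact_matrix(b)
    assert q.loc["P", "C"] == pytest.approx(1.0)
    assert q.loc["C", "P"] == pytest.approx(-1.0)
    assert np.diag(q.to_numpy()).max() == 0.0


def test_fleet_direct_impacts():
    """A fleet taking all its catch from one group, causing 40% of that
    group's removal: q(fleet→group) = −0.4, q(group→fleet) = +1."""
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=100, PB=10, GS=0),
        GroupSpec("G", "", "consumer", "pelagic", B=10, PB=1, GS=0.2, QB=5, EE=1.0),
        GroupSpec("X", "", "consumer", "pelagic", B=1.2, PB=1, GS=0.2, QB=5, EE=0),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    # predation on G: X eats G: B_X·QB_X·DC = 1.2·5·1 = 6; catch 4 → 40%
    codes = ["P", "G", "X", "D"]
    fleet = FleetSpec(
        "F1",
        landings=pd.Series([0, 4.0, 0, 0], index=codes),
        discards=pd.Series(0.0, index=codes),
        discard_fate=pd.Series({"D": 1.0}),
    )
    model = make_model(groups, {("P", "G"): 1.0, ("G", "X"): 1.0}, fleets=[fleet])
    b = solve_balance(model)
    q = net_impact_matrix(b)
    assert q.loc["F1", "G"] == pytest.approx(-0.4)
    assert q.loc["G", "F1"] == pytest.approx(1.0)


def test_no_interactions_no_impacts():
    q = pd.DataFrame(0.0, index=["a", "b"], columns=["a", "b"])
    assert (mti(q).M.to_numpy() == 0).all()


def test_two_by_two_closed_form():
    """(I−q)⁻¹ − I for q=[[0,1],[−1,0]] is [[−½,½],[−½,−½]]."""
    q = pd.DataFrame([[0.0, 1.0], [-1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    im = mti(q)
    np.testing.assert_allclose(im.M.to_numpy(), [[-0.5, 0.5], [-0.5, -0.5]])
    assert im.spectral_radius == pytest.approx(1.0)
    assert im.warnings  # non-convergent pathway expansion is flagged


def test_singular_direct_impacts_rejected():
    q = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ImpactError):
        mti(q)


@pytest.mark.parametrize("seed", [2, 8])
def test_matrix_construction_matches_brute_force(seed):
    b = solve_balance(generate_web(web_config(seed=seed)))
    q = net_impact_matrix(b)
    ref = brute_force_q(b)
    np.testing.assert_allclose(q.to_numpy(), ref.to_numpy(), atol=1e-12)


@pytest.mark.parametrize("seed", [3, 14])
def test_total_impacts_match_neumann_series(seed):
    b = solve_balance(generate_web(web_config(seed=seed)))
    im = impact_analysis(b)
    assert im.spectral_radius < 1.0
    np.testing.assert_allclose(
        im.M.to_numpy(), neumann_sum(im.q.to_numpy()), atol=1e-8
    )


def test_cumulative_impact_vectors_are_off_diagonal_sums():
    b = solve_balance(generate_web(web_config(seed=5)))
    im = impact_analysis(b)
    off = im.M.to_numpy() - np.diag(np.diag(im.M.to_numpy()))
    np.testing.assert_allclose(im.epsilon.to_numpy(), off.sum(axis=1))
    np.testing.assert_allclose(im.suffered.to_numpy(), off.sum(axis=0))
    rss = impact_analysis(b, epsilon_definition="rss")
    np.testing.assert_allclose(rss.epsilon.to_numpy(), np.sqrt((off**2).sum(axis=1)))
    assert (rss.epsilon >= 0).all()


def test_impacts_invariant_under_biomass_rescaling():
    import math

    model = generate_web(web_config(seed=19))
    base = impact_analysis(solve_balance(model))
    scaled = model.copy()
    for g in scaled.groups:
        if not math.isnan(g.B):
            g.B *= 3.7
        g.NM *= 3.7
        g.BA *= 3.7
    for f in scaled.fleets:
        f.landings *= 3.7
        f.discards *= 3.7
    after = impact_analysis(solve_balance(scaled))
    np.testing.assert_allclose(after.M.to_numpy(), base.M.to_numpy(), atol=1e-10)


def test_fleet_views_empty_without_fleets(toy_two_group):
    im = impact_analysis(solve_balance(toy_two_group))
    fog, fof, summary = fleet_views(im)
    assert fog.empty and fof.empty
    assert summary == {"conflicts": 0, "benefits": 0}


def test_fleet_on_preys_fleet_is_beneficial():
    """A fleet thinning a predator indirectly benefits the prey and thus
    the fleet fishing the prey; checked against the pathway-sum oracle.

    The toy is deliberately diffuse (detritus-heavy grazer diets, an
    importing predator, light overlapping catches): concentrated chains
    put the impact expansion on the unit circle."""
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=1000, PB=10, GS=0),
        GroupSpec("G", "", "consumer", "pelagic", B=30, PB=2, QB=10, GS=0.2),
        GroupSpec("H", "", "consumer", "pelagic", B=30, PB=2, QB=10, GS=0.2),
        GroupSpec("X", "", "consumer", "pelagic", B=10, PB=1, QB=4, GS=0.2),
        GroupSpec("D", "", "detritus", "benthic", B=1),
    ]
    codes = ["P", "G", "H", "X", "D"]
    f_prey = FleetSpec("F_PREY", pd.Series([0, 4.0, 4.0, 1.0, 0], index=codes),
                       pd.Series(0.0, index=codes), pd.Series({"D": 1.0}))
    f_pred = FleetSpec("F_PRED", pd.Series([0, 1.0, 1.0, 2.0, 0], index=codes),
                       pd.Series(0.0, index=codes), pd.Series({"D": 1.0}))
    model = make_model(
        groups,
        {("P", "G"): 0.15, ("D", "G"): 0.85, ("P", "H"): 0.15, ("D", "H"): 0.85,
         ("G", "X"): 0.15, ("H", "X"): 0.15},
        imports={"X": 0.7},
        fleets=[f_prey, f_pred],
    )
    b = solve_balance(model)
    im = impact_analysis(b)
    fog, fof, summary = fleet_views(im)
    assert im.spectral_radius < 1.0
    ref = neumann_sum(im.q.to_numpy())
    comps = im.components
    k = comps.index("F_PRED")
    j = comps.index("F_PREY")
    assert ref[k, j] > 0  # predator removal benefits the prey's fleet
    assert fof.loc["F_PRED", "F_PREY"] == pytest.approx(ref[k, j])
    assert summary["benefits"] >= 1
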