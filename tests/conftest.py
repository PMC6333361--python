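import math

import pandas as pd
import pytest

from trophicnet.model_io import DietMatrix, FleetSpec, GroupSpec, ModelDefinition
from trophicnet.mass_balance import solve_balance
from trophicnet.synthetic import WebConfig, generate_web_with_truth
from trophicnet import strait_of_sicily as sos


def make_model(groups, diet, imports=None, fleets=(), fate=None):
    codes = [g.code for g in groups]
    consumers = [g.code for g in groups if g.group_type == "consumer"]
    dc = pd.DataFrame(0.0, index=codes, columns=consumers)
    for (prey, consumer), frac in diet.items():
        dc.loc[prey, consumer] = frac
    imp = pd.Series(0.0, index=consumers)
    for consumer, frac in (imports or {}).items():
        imp[consumer] = frac
    return ModelDefinition(list(groups), DietMatrix(dc, imp), list(fleets), fate)


@pytest.fixture
def toy_two_group():
    """Producer fully grazed by one consumer, plus a detritus pool."""
    groups = [
        GroupSpec("P", "producer", "producer", "pelagic", B=10, PB=10, GS=0),
        GroupSpec("C", "consumer", "consumer", "pelagic", B=1, PB=2, QB=10, EE=0, GS=0.2),
        GroupSpec("D", "detritus", "detritus", "benthic", B=1),
    ]
    return make_model(groups, {("P", "C"): 1.0})


@pytest.fixture
def toy_chain():
    """Producer → herbivore → carnivore with two coupled unknowns."""
    groups = [
        GroupSpec("P", "", "producer", "pelagic", B=100, PB=5, GS=0),
        GroupSpec("H", "", "consumer", "pelagic", PB=1, QB=5, EE=0.5, GS=0.2),
        GroupSpec("C", "", "consumer", "pelagic", B=0.5, PB=0.8, QB=3, EE=0, GS=0.2),
    ]
    return make_model(groups, {("P", "H"): 1.0, ("H", "C"): 1.0})


def web_config(seed: int, **overrides) -> WebConfig:
    """The 30-group, 3-fleet configuration used across the suite."""
    kw = dict(
        n_consumers={"benthic": 8, "demersal": 8, "pelagic": 8},
        n_producers={"benthic": 2, "pelagic": 2},
        n_detritus=2,
        n_fleets=3,
        seed=seed,
    )
    kw.update(overrides)
    return WebConfig(**kw)


@pytest.fixture
def small_web():
    model, truth = generate_web_with_truth(web_config(seed=42))
    return model, truth


@pytest.fixture(scope="session")
def sos_balanced():
    model = sos.load_fixture()
    return solve_balance(model)
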