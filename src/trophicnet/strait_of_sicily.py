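"""Strait-of-Sicily model structure with a SYNTHETIC parameterization.

The published Strait of Sicily ecosystem model aggregates ~1400 taxa
into 72 functional groups — 69 living plus 3 detritus pools, each
labelled benthic, demersal or pelagic — exploited by 18 fleet segments
(gear × vessel-size class).  That *structure* is public and is encoded
here: group codes, long names, domain labels, producer/detritus typing,
the 18 fleet segments with plausible target sets, the 70 % diet-import
convention for bluefin tuna (a seasonal visitor feeding mostly outside
the area) and the small swordfish immigration term (0.025 t·km⁻²·yr⁻¹)
that offsets its catches.

The numeric parameter values (biomasses, P/B, Q/B, diets, catches) of
the published model are NOT public; everything numeric produced by this
module is a synthetic stand-in drawn by the package's own web
generator over the real structure.  Use it for structural and
regression testing, never as a source of ecological numbers for the
real system.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import ModelDefinition, read_model
from .synthetic import WebConfig, assemble_from_meta

#: (code, long name, domain, type, trophic layer used by the generator)
GROUPS: list[tuple[str, str, str, str, int]] = [
    ("SB", "Seabirds", "pelagic", "consumer", 5),
    ("MM", "Marine mammals", "pelagic", "consumer", 5),
    ("TUR", "Sea turtles", "pelagic", "consumer", 4),
    ("XIP", "Sword fish", "pelagic", "consumer", 5),
    ("THU", "Bluefin tuna", "pelagic", "consumer", 5),
    ("LPL", "Large pelagic fish", "pelagic", "consumer", 5),
    ("MPL", "Medium pelagic fish", "pelagic", "consumer", 4),
    ("SPL", "Other small pelagic fish", "pelagic", "consumer", 3),
    ("HAK0", "European hake <6 cm", "demersal", "consumer", 3),
    ("HAK1", "European hake 6-12 cm", "demersal", "consumer", 3),
    ("HAK2", "European hake 12.1-22.0 cm", "demersal", "consumer", 4),
    ("HAK3", "European hake 22.1-41.0 cm", "demersal", "consumer", 4),
    ("HAK4", "European hake >41.0 cm", "demersal", "consumer", 5),
    ("MUL0", "Red mullet <8 cm", "demersal", "consumer", 3),
    ("MUL1", "Red mullet 8-12 cm", "demersal", "consumer", 3),
    ("MUL2", "Red mullet 12.1-17 cm", "demersal", "consumer", 3),
    ("MUL3", "Red mullet >17 cm", "demersal", "consumer", 4),
    ("TRA", "Horse mackerel", "demersal", "consumer", 4),
    ("PAG", "Pandora", "demersal", "consumer", 4),
    ("DFS", "Demersal fish (slope)", "demersal", "consumer", 4),
    ("DFH", "Demersal fish crustacean feeders (shelf)", "demersal", "consumer", 4),
    ("DSM", "Demersal fish mixed food (shelf)", "demersal", "consumer", 4),
    ("DSP", "Demersal fish piscivorous (shelf)", "demersal", "consumer", 5),
    ("DSR", "Demersal fish rocky (shelf)", "demersal", "consumer", 4),
    ("MSC", "Mesopelagic fish crustacean feeders (slope)", "demersal", "consumer", 3),
    ("MSG", "Mesopelagic fish jelly feeders (slope)", "demersal", "consumer", 3),
    ("MSP", "Mesopelagic fish piscivorous (slope)", "demersal", "consumer", 4),
    ("RSH", "Rays and skates (shelf)", "demersal", "consumer", 4),
    ("RSS", "Rays and skates (slope)", "demersal", "consumer", 4),
    ("SSH", "Sharks (shelf)", "demersal", "consumer", 5),
    ("SSS", "Sharks (slope)", "demersal", "consumer", 5),
    ("ENG", "European anchovy", "pelagic", "consumer", 3),
    ("SAR", "European pilchard", "pelagic", "consumer", 3),
    ("EPI", "Epipelagic fish", "pelagic", "consumer", 3),
    ("CEBH", "Cephalopods benthic (shelf)", "demersal", "consumer", 4),
    ("CEBS", "Cephalopods benthic (slope)", "demersal", "consumer", 4),
    ("CEPH", "Cephalopods pelagic (shelf)", "demersal", "consumer", 4),
    ("CEPS", "Cephalopods pelagic (slope)", "demersal", "consumer", 4),
    ("DNS", "Decapods natant (slope)", "demersal", "consumer", 3),
    ("DNH", "Decapods natant (shelf)", "demersal", "consumer", 3),
    ("DRS", "Decapods reptant (slope)", "demersal", "consumer", 3),
    ("DRH", "Decapods reptant (shelf)", "demersal", "consumer", 3),
    ("ARF", "Giant red shrimp", "demersal", "consumer", 3),
    ("PWL", "Deep water rose shrimp", "demersal", "consumer", 3),
    ("SUP", "Suprabenthos", "benthic", "consumer", 2),
    ("O", "Macrobenthos omnivore", "benthic", "consumer", 2),
    ("FF", "Macrobenthos filter-feeder", "benthic", "consumer", 2),
    ("DF", "Macrobenthos deposit-feeder", "benthic", "consumer", 2),
    ("C", "Macrobenthos carnivore", "benthic", "consumer", 2),
    ("PAR", "Macrobenthos parasite", "benthic", "consumer", 2),
    ("SCA", "Macrobenthos scavenger", "benthic", "consumer", 2),
    ("H", "Macrobenthos herbivore", "benthic", "consumer", 2),
    ("GRA", "Macrobenthos grazer", "benthic", "consumer", 2),
    ("SF", "Macrobenthos suspension-feeder", "benthic", "consumer", 2),
    ("PF", "Macrobenthos particulate-feeder", "benthic", "consumer", 2),
    ("BO", "Meiobenthos", "benthic", "consumer", 1),
    ("EUP", "Euphausiacea", "pelagic", "consumer", 2),
    ("ZG", "Gelatinous zooplankton", "pelagic", "consumer", 2),
    ("ZL", "Large zooplankton", "pelagic", "consumer", 2),
    ("ZM", "Mesozooplankton", "pelagic", "consumer", 2),
    ("ZS", "Microzooplankton", "pelagic", "consumer", 1),
    ("PB", "Pelagic bacteria", "pelagic", "consumer", 1),
    ("BB", "Sediment bacteria", "benthic", "consumer", 1),
    ("PS", "Pico-phytoplankton", "pelagic", "producer", 0),
    ("DFL", "Dinoflagellates", "pelagic", "producer", 0),
    ("PL", "Diatom", "pelagic", "producer", 0),
    ("MB", "Microphytobenthos", "benthic", "producer", 0),
    ("SG", "Seagrass", "benthic", "producer", 0),
    ("MA", "Macroalgae", "benthic", "producer", 0),
    ("DC", "Detritus Carrion", "benthic", "detritus", 0),
    ("SPOM", "Suspended Particulate Organic Matter", "demersal", "detritus", 0),
    ("BD", "Benthic Detritus", "benthic", "detritus", 0),
]

#: the 18 fleet segments (vessel-size class . gear) with plausible target
#: and bycatch group sets (trawls sweep broad demersal/benthic bycatch,
#: nets entangle turtles and mammals, longlines hook seabirds and sharks)
FLEETS: list[tuple[str, set[str]]] = [
    ("1.GNS", {"DSM", "DSR", "PAG", "MUL3", "RSH", "TUR", "DSP", "SSH"}),
    ("1.LLD", {"XIP", "LPL", "THU", "SB", "TUR"}),
    ("1.LTL", {"LPL", "MPL", "THU"}),
    ("1.LH", {"CEPH", "CEBH", "MPL", "DSR"}),
    ("1.MIS", {"DSM", "DNH", "CEBH", "SPL", "PAG", "DSR"}),
    ("1.PS", {"ENG", "SAR", "SPL", "EPI", "MPL"}),
    ("2.FPO", {"DRH", "CEBH", "DSR", "DNH", "SCA"}),
    ("2.GNS", {"DSM", "DSP", "PAG", "MUL3", "RSH", "SSH", "TUR", "MM", "DFH"}),
    ("2.LLD", {"XIP", "THU", "LPL", "SSS", "SSH", "SB", "TUR"}),
    ("2.MIS", {"DSM", "DFH", "DNH", "TRA", "CEPH", "PAG"}),
    ("2.OTB_D", {"HAK1", "HAK2", "HAK3", "MUL1", "MUL2", "MUL3", "PAG", "DFH",
                 "DSM", "RSH", "DRH", "DNH", "CEBH", "TRA", "O", "C", "SCA", "SF"}),
    ("2.OTB_DWS", {"ARF", "PWL", "DNS", "DRS", "CEBS", "HAK3", "DFS", "MSC", "RSS"}),
    ("2.OTB_MDD", {"HAK1", "HAK2", "HAK3", "HAK4", "MUL0", "MUL1", "MUL2", "PWL",
                   "DNS", "TRA", "CEBH", "RSS", "DFS", "DFH", "DRH", "O", "SCA"}),
    ("2.OTM", {"TRA", "HAK1", "HAK2", "SPL", "MPL", "EPI", "CEPH"}),
    ("2.PTM", {"ENG", "SAR", "SPL", "TRA", "EPI"}),
    ("2.PS", {"ENG", "SAR", "SPL", "MPL", "EPI", "MM"}),
    ("3.OTM", {"TRA", "SPL", "ENG", "SAR", "HAK2", "MPL", "CEPH"}),
    ("3.OTB_MDDW", {"ARF", "PWL", "HAK2", "HAK3", "HAK4", "DNS", "DRS", "RSS",
                    "CEBS", "DFS", "MSC", "MSP", "MSG", "C", "SCA", "O"}),
]

#: bluefin tuna resides in the area ~4 months a year: 70 % of its diet
#: is taken outside the system
FORCED_IMPORTS = {"THU": 0.7}

#: swordfish immigration (net migration is emigration − immigration)
FORCED_NM = {"XIP": -0.025}

FIXTURE_SEED = 7


def structure() -> pd.DataFrame:
    """The 72-group structure as a ``code,name,type,domain,layer`` frame."""
    return pd.DataFrame(
        [dict(code=c, name=n, domain=d, type=t, layer=l) for c, n, d, t, l in GROUPS]
    )


def generate(seed: int = FIXTURE_SEED) -> ModelDefinition:
    """Generate the synthetic stand-in parameterization over the structure."""
    config = WebConfig(
        n_detritus=3,
        n_layers=5,
        connectance=0.25,
        ee_range=(0.2, 0.9),
        import_prob=0.05,
        import_range=(0.1, 0.5),
        gs=0.2,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    model, _ = assemble_from_meta(
        structure(),
        config,
        rng,
        fleet_targets=FLEETS,
        forced_imports=FORCED_IMPORTS,
        forced_nm=FORCED_NM,
    )
    return model


def fixture_path() -> Path:
    """Directory of the shipped synthetic stand-in CSVs."""
    return Path(str(resources.files("trophicnet") / "data" / "sos_synthetic"))


def load_fixture() -> ModelDefinition:
    """Read the shipped synthetic Strait-of-Sicily stand-in model."""
    return read_model(fixture_path())
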