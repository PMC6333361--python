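"""Regenerate the shipped synthetic Strait-of-Sicily stand-in fixture.

The fixture is fully determined by the structure tables and seed in
``trophicnet.strait_of_sicily``; this script writes the CSVs into the
package data directory.  Run from the repository root:

    python scripts/build_sos_synthetic_fixture.py
"""

from pathlib import Path

from trophicnet import strait_of_sicily as sos
from trophicnet.model_io import write_model

out = Path(__file__).resolve().parents[1] / "src" / "trophicnet" / "data" / "sos_synthetic"
model = sos.generate(sos.FIXTURE_SEED)
files = write_model(model, out)
for f in files:
    print(f"{f} ({f.stat().st_size} bytes)")
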