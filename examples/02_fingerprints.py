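"""Parse and round-trip 881-bit drug substructure fingerprints.

Generates a sparse random fingerprint, writes it in both supported table
dialects (plain 0/1 string and PubChem-style base64), and reads them back.
"""

import tempfile
from pathlib import Path

import numpy as np

from dtiforest import (
    parse_fingerprint_table,
    synth_fingerprint,
    write_fingerprint_table,
)

fp = synth_fingerprint(density=0.1, seed=42, drug_id="D042")
print(f"fingerprint: {fp.bits.size} bits, popcount {fp.popcount} "
      f"(~10% of 881 expected for density 0.1)")

with tempfile.TemporaryDirectory() as tmp:
    for dialect in ("plain01", "pubchem_base64"):
        path = Path(tmp) / f"{dialect}.tsv"
        write_fingerprint_table({"D042": fp}, path, dialect=dialect)
        back = parse_fingerprint_table(path, dialect=dialect)
        same = bool(np.array_equal(back["D042"].bits, fp.bits))
        print(f"{dialect}: round-trip identical = {same}")
# Each set bit marks the presence of one dictionary substructure in the drug.
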