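"""Annotate a small ligand library and apply the Lipinski–Veber filter.

Drug-likeness for orally available molecules: 150 < MW < 500 g/mol,
logP < 5, TPSA < 150 Å², fewer than 5 H-bond donors and 10 acceptors, at
most 7 rotatable bonds, and no reactive aldehydes or thiols ("clean").
"""

from pgpscreen import (LigandLibrary, LigandRecord, compute_properties,
                       lipinski_veber_filter)

lib = LigandLibrary([
    LigandRecord("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    LigandRecord("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    LigandRecord("ethanol", "CCO"),                    # too small
    LigandRecord("benzaldehyde", "c1ccccc1C=O"),       # reactive + too small
    LigandRecord("decylbenzamide", "O=C(N)c1ccccc1CCCCCCCCCC"),  # too floppy
])

lib = compute_properties(lib)
for r in lib:
    print(f"{r.ligand_id:>14}: MW {r.mw:6.1f}  logP {r.logp:5.2f}  "
          f"TPSA {r.tpsa:5.1f}  HBD {r.hbd}  HBA {r.hba}  rot {r.rot_bonds}  "
          f"aldehyde={r.has_aldehyde}")

filtered = lipinski_veber_filter(lib)
history = filtered.provenance["filters"][-1]
print(f"\nretained {history['after']}/{history['before']}: "
      f"{', '.join(filtered.ids())}")
print("rejections per criterion:",
      {k: v for k, v in history["rejected_by"].items() if v})
# Each rejected molecule is counted under every criterion it fails, so the
# counts can exceed the number of removed records.
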