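"""Chi angles, rotamer assignment and the flexible/rigid call for one residue.

Builds a leucine at its mt rotamer (holo) and tp rotamer (apo), measures the
chi torsions back from coordinates, assigns both against the library and
classifies the apo->holo change.
"""
from rotaflex.rotamer import (assign_rotamer, classify_flexibility,
                              compute_chis, load_rotamer_library)
from rotaflex.structio import ChemistryTables
from rotaflex.synthetic import build_residue

tables = ChemistryTables.load()
library = load_rotamer_library()["LEU"]

holo_leu = build_residue("LEU", [-65.0, 175.0])   # mt
apo_leu = build_residue("LEU", [-177.0, 65.0])    # tp

for form, res in (("apo", apo_leu), ("holo", holo_leu)):
    chis = compute_chis(res, tables)
    asn = assign_rotamer(chis, library)
    print(f"{form:5s} chi = {[round(v, 1) for v in chis.values]}"
          f" -> rotamer {asn.rotamer_id} (max dev {max(asn.deviations):.1f} deg)")

call = classify_flexibility(assign_rotamer(compute_chis(apo_leu, tables), library),
                            assign_rotamer(compute_chis(holo_leu, tables), library))
print(f"call: {call.call}")
# Different rotamer ids mean the side chain crossed an energetic barrier on
# binding: this residue counts as flexible in the per-type statistics.
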