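"""Steric necessity of a side-chain movement, scored with the WALL penalty.

Plants a pocket whose lysine must move (sub-rotamer, <15 deg per torsion) to
avoid a 0.5 A overlap with the ligand pose, transplants the holo ligand into
the apo form and scores the clash.
"""
from rotaflex.curation import validate_pair
from rotaflex.steric import WallParameters, delta_wall
from rotaflex.synthetic import SyntheticPlan, generate_pair

plan = SyntheticPlan(small_shift=(3,), clash_residue=3, clash_depth=0.5, seed=7)
apo, holo, truth = generate_pair(plan)
pair = validate_pair(apo, holo, holo.ligands[0])

params = WallParameters()
site_delta, per_residue = delta_wall(pair)
print(f"site delta-WALL: {site_delta:.1f}  (critical above {params.site_threshold})")
for key in sorted(per_residue):
    v = per_residue[key]
    flag = " <- critical" if v > params.residue_threshold else ""
    if abs(v) > 1e-6 or flag:
        print(f"  residue {key[0]}{key[1]}: {v:8.1f}{flag}")
# A positive delta means the unbound conformation clashes with the ligand
# pose: without this side chain's small rotation, binding is sterically
# impossible -- the minimal-rotation regime.
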