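"""Hydrogen-bond rearrangement on binding: conserved / gain / loss calls.

Builds a sparse pocket with a planted glutamine-to-ligand bond (a gain: the
partner only exists in the bound form) and a water lost from an aspartate on
binding, then counts strong N/O...N/O bonds in both forms.
"""
from rotaflex.hbond import count_hbonds, hbond_delta, place_polar_hydrogens
from rotaflex.structio import ChemistryTables
from rotaflex.synthetic import HBondPlant, SyntheticPlan, generate_pair

tables = ChemistryTables.load()
plan = SyntheticPlan(
    n_residues=6, roster=("GLN", "LEU", "ASN", "VAL", "ASP", "LYS"),
    hbond_plants=(HBondPlant(0, "ligand", d_ha=2.0, theta=180.0),
                  HBondPlant(4, "water", presence="apo")),
    seed=3)
apo, holo, _ = generate_pair(plan)
lig = holo.ligands[0]

holo_counts = count_hbonds(place_polar_hydrogens(holo, lig, tables=tables),
                           lig, tables=tables)
apo_counts = count_hbonds(place_polar_hydrogens(apo, None, tables=tables),
                          None, tables=tables)

print(f"{'residue':10s} {'water':>12s} {'protein':>12s} {'ligand':>12s}")
for res in holo.residues:
    ac, hc = apo_counts[res.key], holo_counts[res.key]
    from rotaflex.hbond import HBondCounts
    delta = hbond_delta(HBondCounts(res.key, ac.water, ac.protein, ac.ligand), hc)
    print(f"{res.type}{res.seq_num:<6d} "
          f"{ac.water}->{hc.water} {delta.water:>9s} "
          f"{ac.protein}->{hc.protein} {delta.protein:>9s} "
          f"{ac.ligand}->{hc.ligand} {delta.ligand:>9s}")
# Gln gains its planted ligand bond; Asp loses its water; residues with no
# bonds in either form are conserved by definition.
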