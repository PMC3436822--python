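"""Structure model and PDB input/output.

The in-memory model partitions every coordinate record of a PDB file into
exactly one of three groups: protein residues (ATOM records), ligand
instances (HETATM groups that are not water) and waters.  Parsing is done
with gemmi; writing uses the fixed-column PDB format so that round trips
preserve names, coordinates (3 decimals), occupancies and B-factors.

The module also houses the chemistry tables used throughout: van der Waals
and covalent radii, chi torsion definitions, hydrogen-bond donor/acceptor
roles and the crystallization-buffer exclusion list.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from ._restopo import (BACKBONE_ATOMS, STANDARD_RESIDUES, heavy_atom_names,
                       side_chain_atom_names)

_DATA_DIR = Path(__file__).parent / "data"

#: Common crystallization-buffer components excluded as subject ligands.
BUFFER_LIGANDS = frozenset({"SO4", "PO4", "GOL", "NH4", "CIT", "MPD", "TRS", "MES"})

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model

@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    bfactor: float = 15.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    type: str
    chain_id: str
    seq_num: int
    icode: str = ""
    atoms: list = field(default_factory=list)
    has_altloc: bool = False   # any alternate conformation seen in the file

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_num}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def side_chain_heavy_atoms(self) -> list:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]

    @property
    def is_complete(self) -> bool:
        """Backbone N, CA, C, O all present."""
        names = {a.name for a in self.atoms}
        return all(b in names for b in BACKBONE_ATOMS)

    def missing_heavy_atoms(self) -> list[str]:
        names = {a.name for a in self.atoms}
        return [n for n in heavy_atom_names(self.type) if n not in names]

    def missing_side_chain_atoms(self) -> list[str]:
        names = {a.name for a in self.atoms}
        return [n for n in side_chain_atom_names(self.type) if n not in names]

    def copy(self) -> "Residue":
        r = copy.copy(self)
        r.atoms = [a.copy() for a in self.atoms]
        return r


@dataclass
class LigandInstance:
    het_code: str
    chain_id: str = "A"
    seq_num: int = 1
    atoms: list = field(default_factory=list)
    connectivity: list = field(default_factory=list)  # (atom_name, atom_name)

    def __post_init__(self):
        if not self.atoms:
            return
        names = {a.name for a in self.atoms}
        for a, b in self.connectivity:
            if a not in names or b not in names:
                raise ValueError(f"connectivity references unknown atom {a}-{b}")

    @property
    def key(self) -> tuple:
        return (self.het_code, self.chain_id, self.seq_num)

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)

    def copy(self) -> "LigandInstance":
        lig = copy.copy(self)
        lig.atoms = [a.copy() for a in self.atoms]
        lig.connectivity = list(self.connectivity)
        return lig


@dataclass
class StructureModel:
    pdb_id: str = "XXXX"
    resolution: float | None = None
    residues: list = field(default_factory=list)
    ligands: list = field(default_factory=list)
    waters: list = field(default_factory=list)

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when known")

    @property
    def chains(self) -> dict:
        out: dict[str, list] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def residue(self, key: tuple) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def ligand(self, het_code: str, chain_id: str | None = None,
               seq_num: int | None = None) -> LigandInstance | None:
        for lig in self.ligands:
            if lig.het_code != het_code:
                continue
            if chain_id is not None and lig.chain_id != chain_id:
                continue
            if seq_num is not None and lig.seq_num != seq_num:
                continue
            return lig
        return None

    def protein_heavy_atoms(self) -> list[tuple]:
        """(residue, atom) pairs over all non-hydrogen protein atoms."""
        return [(r, a) for r in self.residues for a in r.heavy_atoms()]

    def copy(self) -> "StructureModel":
        return StructureModel(
            pdb_id=self.pdb_id,
            resolution=self.resolution,
            residues=[r.copy() for r in self.residues],
            ligands=[lig.copy() for lig in self.ligands],
            waters=[w.copy() for w in self.waters],
        )


# ---------------------------------------------------------------------------
# chemistry tables

def _read_tsv(name: str) -> list[dict]:
    rows = []
    header = None
    with open(_DATA_DIR / name) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rows.append(dict(zip(header, parts)))
    return rows


@dataclass
class ChemistryTables:
    """Radii, chi definitions, donor/acceptor roles and buffer exclusions."""

    vdw_radii: dict
    covalent_radii: dict
    chi_atoms: dict            # residue type -> ordered list of 4-atom tuples
    donor_acceptor: dict       # (residue type, atom name) -> donor|acceptor|both
    buffer_codes: frozenset = BUFFER_LIGANDS

    _instance = None

    @classmethod
    def load(cls, buffer_codes=None) -> "ChemistryTables":
        if cls._instance is None:
            vdw = {r["element"].upper(): float(r["radius"])
                   for r in _read_tsv("vdw_radii.tsv")}
            cov = {r["element"].upper(): float(r["radius"])
                   for r in _read_tsv("covalent_radii.tsv")}
            chi: dict[str, list] = {}
            for r in sorted(_read_tsv("chi_atoms.tsv"),
                            key=lambda x: (x["residue"], int(x["chi"]))):
                chi.setdefault(r["residue"], []).append(
                    (r["a1"], r["a2"], r["a3"], r["a4"]))
            da = {(r["residue"], r["atom"]): r["role"]
                  for r in _read_tsv("donors_acceptors.tsv")}
            cls._instance = cls(vdw, cov, chi, da)
        if buffer_codes is not None:
            return replace(cls._instance,
                           buffer_codes=frozenset(c.upper() for c in buffer_codes))
        return cls._instance

    def vdw_radius(self, element: str) -> float:
        r = self.vdw_radii.get(element.upper())
        if r is None:
            r = 1.70  # carbon-like fallback for exotic elements
        return r

    def covalent_radius(self, element: str) -> float:
        r = self.covalent_radii.get(element.upper())
        if r is None:
            r = 0.76
        return r

    def n_chis(self, res_type: str) -> int:
        return len(self.chi_atoms.get(res_type.upper(), []))


def is_buffer_ligand(het_code: str, tables: ChemistryTables | None = None) -> bool:
    """True when the 3-letter chemical component id is a common buffer molecule."""
    codes = tables.buffer_codes if tables is not None else BUFFER_LIGANDS
    return het_code.strip().upper() in codes


# ---------------------------------------------------------------------------
# PDB reading

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip().upper()
    if el:
        return el
    name = atom.name.strip()
    return name[0].upper() if name else "C"


def read_pdb(path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Protein residues come from ATOM records (standard amino acids are always
    protein even when flagged HETATM, e.g. in modified-entity files); every
    non-water HETATM group becomes one :class:`LigandInstance`; water oxygens
    are collected separately.  For alternate locations the highest-occupancy
    conformer is kept (altloc 'A' on ties) and the residue is flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path} contains no coordinate records")
    st.setup_entities()
    model = st[0]

    out = StructureModel(pdb_id=(st.name or path.stem)[:4].upper() or "XXXX",
                         resolution=float(st.resolution) if st.resolution > 0 else None)
    n_atoms = 0
    for chain in model:
        for res in chain:
            def _alt(at):
                # gemmi encodes a blank altloc as '\0'
                return at.altloc if at.altloc not in ("", "\0", " ") else ""

            groups: dict[str, list[gemmi.Atom]] = {}
            has_alt = any(_alt(at) for at in res)
            for at in res:
                groups.setdefault(at.name, []).append(at)
            picked = []
            for name, ats in groups.items():
                best = sorted(ats, key=lambda a: (-a.occ, _alt(a)))[0]
                picked.append(best)
            atoms = [Atom(name=a.name, element=_element_of(a),
                          position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                          bfactor=float(a.b_iso),
                          occupancy=float(min(max(a.occ, 0.0), 1.0)),
                          altloc=_alt(a),
                          is_hetero=res.het_flag == "H")
                     for a in picked]
            n_atoms += len(atoms)
            rname = res.name.strip().upper()
            if rname in WATER_CODES:
                out.waters.extend(a for a in atoms if a.element == "O")
            elif rname in STANDARD_RESIDUES and res.het_flag != "H":
                out.residues.append(Residue(
                    type=rname, chain_id=chain.name, seq_num=res.seqid.num,
                    icode=(res.seqid.icode.strip() if res.seqid.icode else ""),
                    atoms=atoms, has_altloc=has_alt))
            else:
                out.ligands.append(LigandInstance(
                    het_code=rname, chain_id=chain.name, seq_num=res.seqid.num,
                    atoms=atoms,
                    connectivity=perceive_connectivity(atoms)))
    if n_atoms == 0:
        raise PDBParseError(f"{path} contains no atoms")
    return out


def perceive_connectivity(atoms, tables: ChemistryTables | None = None) -> list:
    """Distance-based bond perception: d <= r_cov_i + r_cov_j + 0.4 A."""
    tables = tables or ChemistryTables.load()
    bonds = []
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            cut = tables.covalent_radius(a.element) + tables.covalent_radius(b.element) + 0.4
            if np.linalg.norm(a.position - b.position) <= cut:
                bonds.append((a.name, b.name))
    return bonds


# ---------------------------------------------------------------------------
# PDB writing

def _fmt_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-char elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _coord_line(record: str, serial: int, name: str, altloc: str, resname: str,
                chain: str, seqnum: int, icode: str, a: Atom) -> str:
    x, y, z = a.position
    return (f"{record:<6s}{serial:>5d} {_fmt_atom_name(name, a.element)}"
            f"{altloc or ' ':1s}{resname:>3s} {chain:1s}{seqnum:>4d}"
            f"{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}")


def write_pdb(structure: StructureModel, path) -> None:
    """Write the model in fixed-column PDB format (deterministic output)."""
    lines = []
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {structure.resolution:.2f} ANGSTROMS.")
    serial = 1
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        for a in res.atoms:
            lines.append(_coord_line("ATOM", serial, a.name, a.altloc, res.type,
                                     res.chain_id, res.seq_num, res.icode, a))
            serial += 1
    if structure.residues:
        lines.append("TER")
    for lig in structure.ligands:
        for a in lig.atoms:
            lines.append(_coord_line("HETATM", serial, a.name, a.altloc,
                                     lig.het_code, lig.chain_id, lig.seq_num, "", a))
            serial += 1
    for i, w in enumerate(structure.waters, start=1):
        lines.append(_coord_line("HETATM", serial, "O", "", "HOH", "W", i, "", w))
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# acidic-hydrogen stripping

_CARBOXYL_OXYGENS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


def _ligand_acidic_oxygens(lig: LigandInstance) -> set:
    """Oxygens of phosphate (P-O) and carboxylate (O-C-O) groups, found by
    walking the ligand connectivity."""
    neigh: dict[str, set] = {}
    for a, b in (lig.connectivity or perceive_connectivity(lig.atoms)):
        neigh.setdefault(a, set()).add(b)
        neigh.setdefault(b, set()).add(a)
    elem = {a.name: a.element.upper() for a in lig.atoms}
    acidic = set()
    for name, el in elem.items():
        if el != "O":
            continue
        for nb in neigh.get(name, ()):  # P-O oxygen
            if elem.get(nb) == "P":
                acidic.add(name)
            if elem.get(nb) == "C":     # carboxyl carbon: C bonded to >=2 O
                n_ox = sum(1 for x in neigh.get(nb, ()) if elem.get(x) == "O")
                if n_ox >= 2:
                    acidic.add(name)
    return acidic


def strip_acidic_hydrogens(structure: StructureModel) -> StructureModel:
    """Remove hydrogens on carboxylate and phosphate oxygens.

    These groups are predominantly deprotonated at physiological pH; any
    modelled hydrogen on Asp/Glu carboxylates, C-terminal carboxylates or
    ligand carboxyl/phosphate oxygens (identified through connectivity) is
    dropped.  Everything else is preserved; a structure without hydrogens is
    returned unchanged (as a copy).
    """
    out = structure.copy()
    for res in out.residues:
        targets = set(_CARBOXYL_OXYGENS.get(res.type, set()))
        if res.atom("OXT") is not None:      # C-terminal carboxylate
            targets |= {"O", "OXT"}
        if not targets:
            continue
        tpos = [res.atom(t).position for t in targets if res.atom(t) is not None]
        res.atoms = [
            a for a in res.atoms
            if not (a.is_hydrogen and any(np.linalg.norm(a.position - p) < 1.3
                                          for p in tpos))
        ]
    for lig in out.ligands:
        acidic = _ligand_acidic_oxygens(lig)
        if not acidic:
            continue
        apos = [a.position for a in lig.atoms if a.name in acidic]
        lig.atoms = [
            a for a in lig.atoms
            if not (a.is_hydrogen and any(np.linalg.norm(a.position - p) < 1.3
                                          for p in apos))
        ]
        names = {a.name for a in lig.atoms}
        lig.connectivity = [(x, y) for x, y in lig.connectivity
                            if x in names and y in names]
    return out
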