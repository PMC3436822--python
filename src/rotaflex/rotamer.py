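"""Side-chain chi angles, rotamer assignment and flexibility statistics.

A residue's side-chain conformation is summarised by its chi torsions and
classified against a backbone-independent rotamer library: a library rotamer
is admissible when every observed chi lies within the rotamer's admission
window (default +/-30 deg, boundary inclusive) of the modal value.  A side
chain matching no rotamer is non-rotameric (NR).  A binding-site residue is
"flexible" when its apo and holo assignments differ (including exactly one
NR), "rigid" when they agree; the both-NR case is excluded because two NR
conformations cannot be placed in distinct energetic wells.

All angular arithmetic is circular; the terminal torsions of two-fold
symmetric groups (Asp chi2, Glu chi3, Phe/Tyr chi2) are compared modulo 180
degrees so that equivalent atom namings never register as movement.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import structio
from .geometry import GeometryError, circular_difference, dihedral
from .structio import ChemistryTables, Residue

#: terminal chi torsions of 2-fold symmetric groups: (residue type, chi index)
SYMMETRIC_CHI = frozenset({("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)})

#: residue types with no rotatable side-chain bond, never analysed
NO_CHI_TYPES = frozenset({"GLY", "ALA"})

#: excluded from flexibility statistics: Gly/Ala have no chi, Pro's chis are
#: ring-constrained (movement forces backbone change)
EXCLUDED_TYPES = frozenset({"GLY", "ALA", "PRO"})

DEFAULT_HALF_WIDTH = 30.0
NR = "NR"

_LIBRARY_PATH = Path(__file__).parent / "data" / "rotamer_library.tsv"


class IncompleteChiError(ValueError):
    pass


def symmetry_period(res_type: str, chi_index: int) -> float:
    return 180.0 if (res_type.upper(), chi_index) in SYMMETRIC_CHI else 360.0


def normalize_chi(res_type: str, chi_index: int, value: float) -> float:
    """Wrap a chi value into (-180, 180], or (-90, 90] for symmetric torsions."""
    period = symmetry_period(res_type, chi_index)
    v = float(value) % period
    if v > period / 2.0:
        v -= period
    if v <= -period / 2.0:
        v += period
    return v


# ---------------------------------------------------------------------------
# library

@dataclass(frozen=True)
class RotamerDefinition:
    res_type: str
    rotamer_id: str
    means: tuple            # degrees, one per chi
    half_widths: tuple      # admission half-width per chi
    frequency: float

    def __post_init__(self):
        if any(hw <= 0 for hw in self.half_widths):
            raise ValueError("half-widths must be positive")


def load_rotamer_library(path=None) -> dict[str, list[RotamerDefinition]]:
    """Read the rotamer table, keyed by residue type.

    Columns: residue, rotamer, chis (comma-separated means), half_widths
    (comma-separated, empty for the +/-30 default) and frequency.
    """
    path = Path(path) if path is not None else _LIBRARY_PATH
    lib: dict[str, list[RotamerDefinition]] = {}
    header = None
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        res = row["residue"].upper()
        means = [normalize_chi(res, i, float(v))
                 for i, v in enumerate(row["chis"].split(","), start=1)]
        hw_field = row.get("half_widths", "").strip()
        if hw_field:
            hws = [float(v) if v.strip() else DEFAULT_HALF_WIDTH
                   for v in hw_field.split(",")]
            hws += [DEFAULT_HALF_WIDTH] * (len(means) - len(hws))
        else:
            hws = [DEFAULT_HALF_WIDTH] * len(means)
        lib.setdefault(res, []).append(RotamerDefinition(
            res_type=res, rotamer_id=row["rotamer"], means=tuple(means),
            half_widths=tuple(hws), frequency=float(row["frequency"])))
    return lib


# ---------------------------------------------------------------------------
# chi computation

@dataclass
class ChiVector:
    residue_key: tuple
    res_type: str
    values: list            # degrees; NaN where a defining atom is missing
    complete: bool

    def __len__(self):
        return len(self.values)


def compute_chis(residue: Residue, tables: ChemistryTables | None = None) -> ChiVector:
    """Chi torsions of a residue from its canonical atom quadruples.

    A missing atom invalidates that chi and all deeper ones (they share the
    missing branch); symmetric terminal torsions are normalised to (-90, 90].
    """
    tables = tables or ChemistryTables.load()
    quads = tables.chi_atoms.get(residue.type.upper())
    if not quads:
        raise ValueError(f"residue type {residue.type} has no chi definitions")
    values: list[float] = []
    broken = False
    for i, quad in enumerate(quads, start=1):
        atoms = [residue.atom(n) for n in quad]
        if broken or any(a is None for a in atoms):
            values.append(math.nan)
            broken = True
            continue
        try:
            ang = dihedral(*(a.position for a in atoms))
        except GeometryError:
            values.append(math.nan)
            broken = True
            continue
        values.append(normalize_chi(residue.type, i, ang))
    complete = not any(math.isnan(v) for v in values)
    return ChiVector(residue.key, residue.type.upper(), values, complete)


def chi_deviation(res_type: str, chi_index: int, observed: float, mean: float) -> float:
    """Absolute circular deviation, honouring 2-fold symmetric torsions."""
    period = symmetry_period(res_type, chi_index)
    return abs(circular_difference(observed, mean, period))


# ---------------------------------------------------------------------------
# assignment

@dataclass
class RotamerAssignment:
    residue_key: tuple
    res_type: str
    rotamer_id: str          # library id or "NR"
    deviations: tuple = ()   # per-chi |delta| from the assigned means
    quality_ok: bool = True  # may be cleared later by quality_filter

    @property
    def is_nr(self) -> bool:
        return self.rotamer_id == NR


def assign_rotamer(chis: ChiVector,
                   library: list[RotamerDefinition]) -> RotamerAssignment:
    """Assign the library rotamer whose admission window contains the chis.

    Every rotamer with all per-chi deviations within its half-widths
    (inclusive) is a candidate; with no candidate the side chain is NR; with
    several, the nearest by maximum per-chi deviation wins (ties broken by
    higher library frequency, then rotamer id).
    """
    if not chis.complete:
        raise IncompleteChiError(f"incomplete chi vector for {chis.residue_key}")
    candidates = []
    for rot in library:
        if len(rot.means) != len(chis.values):
            continue
        devs = tuple(chi_deviation(chis.res_type, i + 1, chis.values[i], rot.means[i])
                     for i in range(len(rot.means)))
        if all(d <= hw for d, hw in zip(devs, rot.half_widths)):
            candidates.append((max(devs), -rot.frequency, rot.rotamer_id, rot, devs))
    if not candidates:
        return RotamerAssignment(chis.residue_key, chis.res_type, NR)
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, rot, devs = candidates[0]
    return RotamerAssignment(chis.residue_key, chis.res_type, rot.rotamer_id, devs)


# ---------------------------------------------------------------------------
# quality filtering (targets NR conformations only)

B_FACTOR_LIMIT = 40.0


def side_chain_quality_ok(residue: Residue) -> bool:
    """True unless any side-chain heavy atom has B > 40, occupancy < 1 or an
    alternate conformation."""
    for a in residue.side_chain_heavy_atoms():
        if a.bfactor > B_FACTOR_LIMIT or a.occupancy < 1.0 or a.altloc:
            return False
    if residue.has_altloc:
        return False
    return True


def quality_filter(apo_residue: Residue, holo_residue: Residue,
                   apo_assignment: RotamerAssignment,
                   holo_assignment: RotamerAssignment) -> bool:
    """Keep the observation unless an NR side chain fails the quality checks.

    Rotameric side chains are never removed by this filter; an NR assignment
    backed by poor electron density (high B, partial occupancy, alternates)
    is unreliable and the whole apo/holo observation is excluded.
    """
    if apo_assignment.is_nr and not side_chain_quality_ok(apo_residue):
        return False
    if holo_assignment.is_nr and not side_chain_quality_ok(holo_residue):
        return False
    return True


# ---------------------------------------------------------------------------
# flexibility classification

FLEXIBLE = "flexible"
RIGID = "rigid"
EXCLUDED_NR_NR = "excluded_NR_NR"
EXCLUDED_QUALITY = "excluded_quality"


@dataclass
class FlexibilityCall:
    residue_key: tuple
    res_type: str
    apo_rotamer: str
    holo_rotamer: str
    call: str


def classify_flexibility(apo: RotamerAssignment,
                         holo: RotamerAssignment,
                         quality_ok: bool = True) -> FlexibilityCall:
    """Rigid if both forms share a rotamer, flexible if they differ (or
    exactly one is NR); both-NR observations are excluded."""
    if not quality_ok:
        call = EXCLUDED_QUALITY
    elif apo.is_nr and holo.is_nr:
        call = EXCLUDED_NR_NR
    elif apo.rotamer_id == holo.rotamer_id:
        call = RIGID
    else:
        call = FLEXIBLE
    return FlexibilityCall(holo.residue_key, holo.res_type,
                           apo.rotamer_id, holo.rotamer_id, call)


# ---------------------------------------------------------------------------
# probability of change (per residue type)

@dataclass
class ProbabilityEstimate:
    res_type: str
    n_changed: int
    n_total: int
    p: float
    error: float


def flexibility_probability(n_changed: int, n_total: int,
                            res_type: str = "") -> ProbabilityEstimate:
    """P = N_R / N_T with the binomial standard error sqrt(P(1-P)/N_T)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_changed <= n_total:
        raise ValueError("n_changed must lie in [0, n_total]")
    p = n_changed / n_total
    err = math.sqrt(p * (1.0 - p) / n_total)
    return ProbabilityEstimate(res_type, n_changed, n_total, p, err)


def probability_scale(calls) -> dict[str, ProbabilityEstimate]:
    """Per-residue-type change probabilities from flexibility calls.

    Excluded calls (both-NR, quality) do not count; Gly/Ala/Pro never appear.
    """
    counts: dict[str, list[int]] = {}
    for c in calls:
        if c.res_type in EXCLUDED_TYPES:
            continue
        if c.call not in (FLEXIBLE, RIGID):
            continue
        n = counts.setdefault(c.res_type, [0, 0])
        n[1] += 1
        if c.call == FLEXIBLE:
            n[0] += 1
    return {t: flexibility_probability(nr, nt, t)
            for t, (nr, nt) in sorted(counts.items())}


# ---------------------------------------------------------------------------
# dihedral-threshold comparison (the older 60-degree criterion)

def delta_chi_flexible(apo_chis: ChiVector, holo_chis: ChiVector,
                       threshold: float = 60.0) -> bool:
    """True when any circular |delta chi| reaches the threshold (inclusive).

    The same 2-fold symmetry conventions used for rotamer assignment apply,
    so both methods see identical angular differences.
    """
    if len(apo_chis) != len(holo_chis):
        raise ValueError("mismatched chi vector lengths")
    for i, (a, h) in enumerate(zip(apo_chis.values, holo_chis.values), start=1):
        if math.isnan(a) or math.isnan(h):
            continue
        if chi_deviation(apo_chis.res_type, i, a, h) >= threshold:
            return True
    return False


def max_delta_chi(apo_chis: ChiVector, holo_chis: ChiVector) -> float:
    if len(apo_chis) != len(holo_chis):
        raise ValueError("mismatched chi vector lengths")
    best = 0.0
    for i, (a, h) in enumerate(zip(apo_chis.values, holo_chis.values), start=1):
        if math.isnan(a) or math.isnan(h):
            continue
        best = max(best, chi_deviation(apo_chis.res_type, i, a, h))
    return best


# ---------------------------------------------------------------------------
# disulfides

def disulfide_cys_keys(structure: structio.StructureModel,
                       cutoff: float = 2.5) -> set:
    """Keys of Cys residues whose SG is within the disulfide distance of
    another Cys SG; these are conformationally locked and excluded."""
    cys = [(r.key, r.atom("SG")) for r in structure.residues if r.type == "CYS"]
    cys = [(k, a) for k, a in cys if a is not None]
    locked = set()
    for i, (ki, ai) in enumerate(cys):
        for kj, aj in cys[i + 1:]:
            if np.linalg.norm(ai.position - aj.position) < cutoff:
                locked.add(ki)
                locked.add(kj)
    return locked
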