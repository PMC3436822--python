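"""Geometric kernels: torsion angles, rigid-body superposition, accessible
surface area, atomic contacts and ligand burial.

All coordinates are in Angstrom, all angles in degrees.  Solvent accessible
surface area (SASA) is computed with a deterministic Shrake–Rupley sphere
sampling (fixed point lattice), which makes every area reproducible to the
last bit for a given sample count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_PROBE = 1.4
DEFAULT_SASA_POINTS = 960


class GeometryError(ValueError):
    """Degenerate geometric input (coincident/collinear points, rank deficiency)."""


# ---------------------------------------------------------------------------
# torsions

def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Raises :class:`GeometryError` when consecutive points coincide or three
    consecutive points are collinear (the torsion is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-8:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise GeometryError("collinear points in dihedral")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    if a <= -180.0:
        a += 360.0
    return a


def circular_difference(a: float, b: float, period: float = 360.0) -> float:
    """Smallest signed difference a-b on a circle of the given period.

    Result lies in (-period/2, period/2].  ``period=180`` implements the
    two-fold-symmetric comparison used for terminal chi angles of Asp, Glu,
    Phe and Tyr.
    """
    d = (float(a) - float(b)) % period
    if d > period / 2.0:
        d -= period
    if d <= -period / 2.0:
        d += period
    return d


# ---------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise GeometryError(f"rotation determinant {det} != +1")

    def apply(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


def superpose(ref_coords, mov_coords) -> tuple[Transform, float]:
    """Least-squares rigid superposition (Kabsch/SVD) of mov onto ref.

    Returns the proper-rotation transform T minimising ``|ref - T(mov)|`` and
    the post-fit RMSD in Angstrom.  Requires >= 3 non-degenerate point pairs.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("coordinate sets must be matched N x 3 arrays")
    if ref.shape[0] < 3:
        raise GeometryError("superposition requires at least 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    a = ref - ref_c
    b = mov - mov_c
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    # guard against numerically rank-deficient (collinear) point sets
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("rank-deficient (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mov_c
    t = Transform(rot, trans)
    diff = ref - t.apply(mov)
    rmsd = float(np.sqrt((diff ** 2).sum() / ref.shape[0]))
    return t, rmsd


def rmsd(a, b) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum() / a.shape[0]))


# ---------------------------------------------------------------------------
# solvent accessible surface

@dataclass
class SurfaceReport:
    per_atom: np.ndarray      # A^2 per input atom
    probe: float              # A

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(coords, radii, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_SASA_POINTS) -> SurfaceReport:
    """Shrake–Rupley accessible surface area.

    For each atom a lattice of ``n_points`` test points is placed on the
    sphere of radius ``r_i + probe``; a point is accessible when it lies
    outside every neighbouring atom's probe-expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = coords.shape[0]
    areas = np.zeros(n)
    if n == 0:
        return SurfaceReport(areas, probe)
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = float(radii.max())
    for i in range(n):
        ri = radii[i] + probe
        neighbours = tree.query_ball_point(coords[i], ri + rmax + probe)
        neighbours = [j for j in neighbours if j != i]
        pts = coords[i] + ri * unit
        if neighbours:
            nc = coords[neighbours]
            nr = radii[neighbours] + probe
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
            free = int((~buried).sum())
        else:
            free = n_points
        areas[i] = 4.0 * np.pi * ri * ri * free / n_points
    return SurfaceReport(areas, probe)


# ---------------------------------------------------------------------------
# contacts and burial

@dataclass
class ContactSet:
    """Atom pairs in probe-mediated contact plus residue-level aggregation."""

    pairs: list = field(default_factory=list)       # (residue_key, atom_name, ligand_atom_index)
    per_residue: dict = field(default_factory=dict)  # residue_key -> n contacting atom pairs

    @property
    def residues(self) -> list:
        return sorted(self.per_residue)


def contact_pairs(protein_coords, protein_radii, ligand_coords, ligand_radii,
                  probe: float = DEFAULT_PROBE) -> np.ndarray:
    """Index pairs (i protein, j ligand) with d <= r_i + r_j + 2*probe."""
    pc = np.asarray(protein_coords, dtype=float)
    lc = np.asarray(ligand_coords, dtype=float)
    if pc.size == 0 or lc.size == 0:
        return np.empty((0, 2), dtype=int)
    pr = np.asarray(protein_radii, dtype=float)
    lr = np.asarray(ligand_radii, dtype=float)
    d = np.sqrt(((pc[:, None, :] - lc[None, :, :]) ** 2).sum(axis=2))
    cut = pr[:, None] + lr[None, :] + 2.0 * probe
    idx = np.argwhere(d <= cut)
    return idx


def fraction_buried(free_sasa: float, bound_sasa: float,
                    convention: str = "buried") -> float:
    """Ligand burial fraction Fc from free and in-complex ligand SASA.

    ``convention='buried'`` (default) returns 1 - SAS_b/SAS_f, the fraction of
    the free-ligand surface lost on binding; ``convention='printed_ratio'``
    returns the literal ratio SAS_b/SAS_f.
    """
    if free_sasa <= 0:
        raise ValueError("free-ligand SASA is zero; burial fraction undefined")
    ratio = bound_sasa / free_sasa
    if convention == "buried":
        return float(min(1.0, max(0.0, 1.0 - ratio)))
    if convention == "printed_ratio":
        return float(ratio)
    raise ValueError(f"unknown Fc convention {convention!r}")
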