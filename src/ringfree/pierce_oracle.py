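"""Geometric ground truth for ring piercing and chirality.

The long-bond symptom is only a proxy; this module provides the direct
geometric tests.  A bond pierces a ring when its segment crosses the ring
face, tested against a fan triangulation about the ring centroid — a
watertight construction that handles both planar aromatics and puckered
hexose chairs.  Chirality is measured as the sign of the signed volume of a
stereocenter's ordered substituent tetrahedron, and preserved during repair
through harmonic improper-dihedral restraints targeted at the geometry of
the input structure (the tool must preserve stereochemistry, not impose an
idealized one: a silently flipped center is far harder to detect later than
a stretched bond).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .charmm_io import MolecularSystem
from .errors import GeometryError
from .topology_graph import Ring, build_graph, enumerate_small_rings

__all__ = [
    "RingPiercingEvent",
    "ChiralCenter",
    "ImproperRestraint",
    "segment_triangle_intersect",
    "find_piercings",
    "detect_chiral_centers",
    "chirality_sign",
    "generate_chirality_restraints",
    "write_restraints",
]

_TRI_AREA_EPS = 1e-8  # A^2, degenerate-triangle threshold
_EDGE_EPS = 1e-9      # barycentric slack: closed triangle, watertight fans


@dataclass(frozen=True)
class RingPiercingEvent:
    """A bond threaded through a small ring."""

    bond: tuple[int, int]
    ring: Ring
    point: np.ndarray  # intersection with the ring fan, Angstrom

    def __post_init__(self) -> None:
        if self.bond[0] in self.ring or self.bond[1] in self.ring:
            raise ValueError("piercing bond shares an atom with the pierced ring")


@dataclass
class ChiralCenter:
    """A potential stereocenter: 4 pairwise-distinguishable substituents.

    ``substituents`` are ordered by ascending atom index; ``sign`` is the
    sign of det[r2-r1, r3-r1, r4-r1] over that order in the coordinates the
    center was detected from.
    """

    center: int
    substituents: tuple[int, int, int, int]
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("chirality sign must be +1 or -1")


@dataclass(frozen=True)
class ImproperRestraint:
    """Harmonic improper-dihedral restraint: k*(phi - target)^2."""

    atoms: tuple[int, int, int, int]
    k: float           # kcal/mol/rad^2
    target: float      # radians, measured in the input structure


def segment_triangle_intersect(p0, p1, t0, t1, t2):
    """Does the closed segment p0-p1 cross the closed triangle (t0, t1, t2)?

    Returns ``(hit, point)`` with the intersection point when hit.  Uses the
    plane-crossing sign test plus barycentric coordinates with a small
    inclusive slack, so fans sharing edges are watertight.  Segments lying
    in the triangle plane do not count as crossings.
    """
    p0, p1, t0, t1, t2 = (np.asarray(v, dtype=float) for v in (p0, p1, t0, t1, t2))
    e1, e2 = t1 - t0, t2 - t0
    n = np.cross(e1, e2)
    area2 = np.linalg.norm(n)
    if area2 / 2.0 <= _TRI_AREA_EPS:
        raise GeometryError("degenerate triangle (area below threshold)")
    d0 = float(np.dot(p0 - t0, n))
    d1 = float(np.dot(p1 - t0, n))
    if d0 == d1:
        return False, None  # parallel (or in-plane) segment
    if (d0 > 0 and d1 > 0) or (d0 < 0 and d1 < 0):
        return False, None
    s = d0 / (d0 - d1)
    point = p0 + s * (p1 - p0)
    # barycentric test in the triangle plane
    v = point - t0
    d11 = float(np.dot(e1, e1))
    d12 = float(np.dot(e1, e2))
    d22 = float(np.dot(e2, e2))
    dv1 = float(np.dot(v, e1))
    dv2 = float(np.dot(v, e2))
    det = d11 * d22 - d12 * d12
    b1 = (d22 * dv1 - d12 * dv2) / det
    b2 = (d11 * dv2 - d12 * dv1) / det
    if b1 >= -_EDGE_EPS and b2 >= -_EDGE_EPS and b1 + b2 <= 1.0 + _EDGE_EPS:
        return True, point
    return False, None


def _ring_fan(coords: np.ndarray, ring: Ring):
    """Fan triangles of a ring about its centroid."""
    pts = coords[list(ring.atoms)]
    centroid = pts.mean(axis=0)
    n = len(pts)
    for k in range(n):
        yield centroid, pts[k], pts[(k + 1) % n]


def find_piercings(
    system: MolecularSystem, rings: list[Ring] | None = None
) -> list[RingPiercingEvent]:
    """All (bond, ring) pairs where the bond segment crosses the ring face.

    Bonds sharing an atom with a ring are skipped for that ring.  Rings
    default to the system's own small-ring enumeration.  Event order is
    deterministic: rings in canonical order, bonds in topology order.
    """
    if system.coords is None:
        raise ValueError("system has no coordinates")
    if rings is None:
        rings = enumerate_small_rings(build_graph(system))
    coords = system.coords
    events = []
    for ring in rings:
        members = set(ring.atoms)
        for i, j in system.bonds:
            if i in members or j in members:
                continue
            for t0, t1, t2 in _ring_fan(coords, ring):
                hit, point = segment_triangle_intersect(coords[i], coords[j], t0, t1, t2)
                if hit:
                    events.append(RingPiercingEvent(bond=(i, j), ring=ring, point=point))
                    break
    return events


def chirality_sign(substituent_coords) -> int:
    """Sign of det[r2-r1, r3-r1, r4-r1] for 4 ordered substituent positions.

    Raises :class:`GeometryError` when the substituents are coplanar within
    1e-6 A^3 — the center is geometrically degenerate and has no sign.
    """
    r = np.asarray(substituent_coords, dtype=float)
    if r.shape != (4, 3) or not np.all(np.isfinite(r)):
        raise ValueError("need 4 finite substituent coordinates")
    vol = float(np.linalg.det(np.stack([r[1] - r[0], r[2] - r[0], r[3] - r[0]])))
    if abs(vol) < 1e-6:
        raise GeometryError("substituents coplanar: stereocenter degenerate")
    return 1 if vol > 0 else -1


def _branch_signature(system: MolecularSystem, adjacency, center: int, nb: int):
    """First-shell signature of the substituent branch rooted at *nb*."""
    types = system.types
    shell = tuple(sorted(types[x] for x in adjacency[nb] if x != center))
    return (types[nb], shell)


def detect_chiral_centers(system: MolecularSystem) -> list[ChiralCenter]:
    """Potential stereocenters: 4 bonded neighbors, all branches distinguishable.

    Distinguishability is judged at the first shell (neighbor type plus the
    types around it).  This over-includes relative to full CIP perception,
    which is safe: a restraint on a non-center is harmless, while a missed
    center can silently invert.  A methane-like carbon with four identical
    hydrogens is not returned.  The reference sign comes from the current
    coordinates, with substituents ordered by ascending atom index.
    """
    if system.coords is None:
        raise ValueError("system has no coordinates")
    adjacency: dict[int, list[int]] = {i: [] for i in range(system.n_atoms)}
    for i, j in system.bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    centers = []
    for c in range(system.n_atoms):
        nbs = sorted(adjacency[c])
        if len(nbs) != 4:
            continue
        sigs = [_branch_signature(system, adjacency, c, nb) for nb in nbs]
        if len(set(sigs)) != 4:
            continue
        try:
            sign = chirality_sign(system.coords[nbs])
        except GeometryError:
            continue  # planar as-built center carries no usable reference
        centers.append(ChiralCenter(center=c, substituents=tuple(nbs), sign=sign))
    return centers


def measure_improper(coords: np.ndarray, quad: tuple[int, int, int, int]) -> float:
    """Dihedral angle (radians) of the 4-atom quadruple in *coords*."""
    p = coords[list(quad)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    x = float(np.dot(m, n))
    y = float(np.dot(np.cross(m, n), b2 / b2n))
    return float(np.arctan2(y, x))


def generate_chirality_restraints(
    centers: list[ChiralCenter],
    system: MolecularSystem,
    k: float = 50.0,
) -> list[ImproperRestraint]:
    """One harmonic improper restraint per center, targeting its input geometry.

    The restrained quadruple is the center's four index-ordered substituents
    (s1, s2, s3, s4): their dihedral changes sign under reflection and
    involves every atom whose rearrangement could invert the measured
    chirality sign, so a harmonic well at the value measured in the input
    structure resists inversion however it is attempted.  (A quadruple built
    from the center plus three substituents would leave the fourth
    substituent free to swing through the plane unrestrained.)
    """
    if system.coords is None:
        raise ValueError("system has no coordinates")
    restraints = []
    for c in centers:
        quad = c.substituents
        target = measure_improper(system.coords, quad)
        restraints.append(ImproperRestraint(atoms=quad, k=k, target=target))
    return restraints


def write_restraints(restraints: list[ImproperRestraint], path: str | Path) -> None:
    """Serialize restraints: one improper per line — 4 indices, k, target (deg)."""
    lines = ["# i j k l  k_kcal_mol_rad2  target_deg"]
    for r in restraints:
        a = " ".join(str(v) for v in r.atoms)
        lines.append(f"{a} {r.k:.3f} {np.degrees(r.target):.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
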