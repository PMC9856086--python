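"""Deterministic generators of small pierced and clean test systems.

These stand in for the large externally-built systems the repair workflow is
aimed at (ring-pierced polymers, glycosylated proteins): an aromatic
six-ring with a two-carbon unit threaded through it, a para-linked
multi-ring toy polymer with engineered piercings, and a chiral
glyco-peptide toy.  Every fixture carries a
manifest (intended piercing and stereocenter counts) that is verified by
the geometric oracle at build time, and resolves completely against the
embedded minimal parameter set, which is round-tripped through the real
CHARMM parameter parser.

All geometry is explicit and seeded; a tiny coordinate jitter (0.02 A)
breaks the exact symmetries of the constructions so that deterministic
minimization does not start on a saddle point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .charmm_io import Atom, MolecularSystem, ParameterSet, parse_parameter_text
from .pierce_oracle import detect_chiral_centers, find_piercings

__all__ = [
    "FixtureBundle",
    "embedded_minimal_params",
    "EMBEDDED_PARAMETER_TEXT",
    "make_pierced_benzene_ethane",
    "make_toy_polymer",
    "make_glyco_peptide_toy",
    "make_strained_glyco_toy",
]

_MASS = {
    "CA": 12.011, "CT": 12.011, "C": 12.011,
    "HA": 1.008, "HT": 1.008, "HO": 1.008, "HN": 1.008,
    "OH": 15.999, "OR": 15.999, "OS": 15.999, "O": 15.999,
    "NH": 14.007,
}

# chemically reasonable minimal CHARMM-style parameter text; aromatic and
# aliphatic carbons, hydroxyl/ether/ester-like oxygens, amide nitrogen
EMBEDDED_PARAMETER_TEXT = """\
* minimal self-contained parameter set for the shipped fixtures
*

BONDS
CA CA  305.000  1.3750
CA HA  340.000  1.0800
CA CT  230.000  1.4900
CT CT  222.500  1.5300
CT HT  309.000  1.1110
CT OH  428.000  1.4200
OH HO  545.000  0.9600
CT OR  360.000  1.4150
CT OS  340.000  1.4300
CT NH  320.000  1.4300
NH HN  440.000  0.9970
C  CT  250.000  1.4900
C  O   620.000  1.2300
C  NH  370.000  1.3450

ANGLES
CA CA CA  40.00  120.00
CA CA HA  30.00  120.00
CA CA CT  45.00  120.00
CA CT CA  50.00  112.00
CA CT HT  45.00  109.50
CT CT CT  58.00  111.00
CT CT HT  33.40  110.10
HT CT HT  35.00  107.00
CT CT OR  45.00  110.00
CT OR CT  60.00  112.00
CT CT OH  45.00  110.50
CT CT OS  45.00  110.00
CT OS CT  60.00  112.00
CT OH HO  55.00  106.00
HT CT OH  45.00  109.50
HT CT OR  45.00  109.50
HT CT OS  45.00  109.50
OS CT OR  45.00  110.00
NH CT OH  45.00  109.50
CT NH HN  35.00  118.00
C  NH CT  50.00  121.00
C  NH HN  34.00  119.00
HN NH HN  30.00  107.00
NH CT C   50.00  110.00
NH CT CT  45.00  110.00
NH CT HT  38.00  109.50
C  CT HT  40.00  109.50
C  CT CT  45.00  111.00
CT C  O   45.00  121.00
CT C  NH  50.00  116.50
O  C  NH  60.00  122.50

DIHEDRALS
X CA CA X  3.100  2  180.00
X CA CT X  0.100  3    0.00
X CT CT X  0.160  3    0.00
X CT OH X  0.140  3    0.00
X CT OR X  0.250  3    0.00
X CT OS X  0.250  3    0.00
X CT NH X  0.100  3    0.00
X C  CT X  0.050  6  180.00
X C  NH X  2.500  2  180.00

NONBONDED
CA  0.0  -0.0700  1.9924
HA  0.0  -0.0300  1.3582
CT  0.0  -0.0800  2.0600
HT  0.0  -0.0240  1.3400
OH  0.0  -0.1521  1.7700
HO  0.0  -0.0460  0.2245
OR  0.0  -0.1000  1.6500
OS  0.0  -0.1000  1.6500
NH  0.0  -0.2000  1.8500
HN  0.0  -0.0460  0.2245
C   0.0  -0.1100  2.0000
O   0.0  -0.1200  1.7000

END
"""


def embedded_minimal_params() -> ParameterSet:
    """Parse the embedded parameter text through the real parameter parser."""
    return parse_parameter_text(EMBEDDED_PARAMETER_TEXT)


@dataclass
class FixtureBundle:
    """A self-validating fixture: system, parameters and intent manifest."""

    system: MolecularSystem
    params: ParameterSet
    manifest: dict

    def validate(self) -> None:
        """Verify the manifest against the geometric oracle and parameters."""
        self.params.validate_system(self.system)
        n_pierce = len(find_piercings(self.system))
        if n_pierce != self.manifest["piercings"]:
            raise AssertionError(
                f"fixture declares {self.manifest['piercings']} piercings "
                f"but the oracle finds {n_pierce}"
            )
        n_chiral = len(detect_chiral_centers(self.system))
        if n_chiral < self.manifest["chiral_centers"]:
            raise AssertionError(
                f"fixture declares >= {self.manifest['chiral_centers']} "
                f"stereocenters but only {n_chiral} detected"
            )


# --------------------------------------------------------------------------
# construction helpers
# --------------------------------------------------------------------------

class _Builder:
    """Incremental atom/bond accumulator with automatic angle/dihedral lists."""

    def __init__(self):
        self.names: list[str] = []
        self.types: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.segids: list[str] = []
        self.charges: list[float] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, name, type_, xyz, charge=0.0, resname="TOY", resid=1,
            segid="TOY") -> int:
        self.names.append(name)
        self.types.append(type_)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.segids.append(segid)
        self.charges.append(charge)
        self.coords.append(np.asarray(xyz, dtype=float))
        return len(self.names) - 1

    def bond(self, i: int, j: int) -> None:
        self.bonds.append((i, j))

    def build(self, jitter: float = 0.0, rng: np.random.Generator | None = None
              ) -> MolecularSystem:
        coords = np.array(self.coords)
        if jitter > 0:
            rng = rng if rng is not None else np.random.default_rng(0)
            coords = coords + rng.normal(0.0, jitter, size=coords.shape)
        adjacency: dict[int, list[int]] = {i: [] for i in range(len(self.names))}
        for i, j in self.bonds:
            adjacency[i].append(j)
            adjacency[j].append(i)
        angles = []
        for j in range(len(self.names)):
            nbs = sorted(adjacency[j])
            for a in range(len(nbs)):
                for b in range(a + 1, len(nbs)):
                    angles.append((nbs[a], j, nbs[b]))
        dihedrals = []
        for j, k in self.bonds:
            for i in sorted(adjacency[j]):
                if i == k:
                    continue
                for l in sorted(adjacency[k]):
                    if l == j or l == i:
                        continue
                    dihedrals.append((i, j, k, l))
        atoms = [
            Atom(index=i, name=self.names[i], resname=self.resnames[i],
                 resid=self.resids[i], segid=self.segids[i], type=self.types[i],
                 charge=self.charges[i], mass=_MASS[self.types[i]])
            for i in range(len(self.names))
        ]
        return MolecularSystem(
            atoms=atoms, bonds=self.bonds, angles=angles, dihedrals=dihedrals,
            impropers=[], coords=coords,
        )


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _add_benzene(b: _Builder, center, normal, radius=1.375, h_radius=2.455,
                 resid=1, segid="RING", skip_h=(), phase=0.0):
    """A regular aromatic six-ring in the plane normal to *normal*.

    Returns the 6 ring-carbon indices (vertex k at angle ``phase + 60 k``).
    ``skip_h`` lists vertices that carry a substituent instead of hydrogen.
    """
    normal = _unit(normal)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(normal)))] = 1.0
    e1 = _unit(seed - np.dot(seed, normal) * normal)
    e2 = np.cross(normal, e1)
    center = np.asarray(center, dtype=float)
    carbons = []
    for k in range(6):
        ang = phase + np.radians(60.0 * k)
        d = np.cos(ang) * e1 + np.sin(ang) * e2
        carbons.append(
            b.add(f"C{k + 1}", "CA", center + radius * d, charge=-0.115,
                  resname="BEN", resid=resid, segid=segid)
        )
    for k in range(6):
        b.bond(carbons[k], carbons[(k + 1) % 6])
    for k in range(6):
        if k in skip_h:
            continue
        ang = phase + np.radians(60.0 * k)
        d = np.cos(ang) * e1 + np.sin(ang) * e2
        h = b.add(f"H{k + 1}", "HA", center + h_radius * d, charge=0.115,
                  resname="BEN", resid=resid, segid=segid)
        b.bond(carbons[k], h)
    return carbons


# --------------------------------------------------------------------------
# fixture: pierced benzene + ethane
# --------------------------------------------------------------------------

def make_pierced_benzene_ethane() -> FixtureBundle:
    """An aromatic six-ring with a two-carbon bond threaded through it.

    The ring sits in the xy-plane at the origin; the C-C unit runs along z
    with its midpoint at the ring centroid and a length 0.57 A beyond its
    equilibrium (1.53 A), the canonical long-bond symptom of a piercing.
    """
    b = _Builder()
    _add_benzene(b, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0), resid=1, segid="RING")

    half = 1.05  # C-C length 2.10 = b0 + 0.57
    c_lo = b.add("C1", "CT", (0.0, 0.0, -half), charge=-0.27, resname="ETH",
                 resid=2, segid="ETHA")
    c_hi = b.add("C2", "CT", (0.0, 0.0, half), charge=-0.27, resname="ETH",
                 resid=2, segid="ETHA")
    b.bond(c_lo, c_hi)
    sin_t, cos_t = np.sin(np.radians(109.47)), -np.cos(np.radians(109.47))
    for carbon, zsign, phis in (
        (c_hi, 1.0, (90.0, 210.0, 330.0)),
        (c_lo, -1.0, (30.0, 150.0, 270.0)),
    ):
        base = b.coords[carbon]
        for phi in phis:
            d = np.array(
                [sin_t * np.cos(np.radians(phi)), sin_t * np.sin(np.radians(phi)),
                 zsign * cos_t]
            )
            h = b.add(f"H{phi:.0f}", "HT", base + 1.111 * d, charge=0.09,
                      resname="ETH", resid=2, segid="ETHA")
            b.bond(carbon, h)

    system = b.build(jitter=0.02, rng=np.random.default_rng(2024))
    bundle = FixtureBundle(
        system=system,
        params=embedded_minimal_params(),
        manifest={
            "piercings": 1,
            "chiral_centers": 0,
            "notes": "ethane C-C threaded through an aromatic six-ring",
        },
    )
    bundle.validate()
    return bundle


# --------------------------------------------------------------------------
# fixture: para-linked toy polymer with engineered piercings
# --------------------------------------------------------------------------

def make_toy_polymer(n_units: int, n_piercings: int, seed: int = 0) -> FixtureBundle:
    """A chain of aromatic six-rings joined by CH2 linkers.

    ``n_piercings`` linker bonds are threaded through rings of units two
    further down the chain: for each engineered piercing the entire
    downstream remainder of the chain is repositioned rigidly so that the
    target ring encloses the linker-bond midpoint.  Every placement scans a
    deterministic set of orientations until the geometric oracle confirms
    exactly the intended cumulative piercing count, so collateral bonds
    never thread anything by accident.  Feasibility requires
    ``n_piercings <= n_units - 2`` (each piercing consumes the ring two
    units past its linker).
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if n_piercings < 0 or (n_piercings > 0 and n_piercings > n_units - 2):
        raise ValueError(
            "infeasible request: need 0 <= n_piercings <= n_units - 2"
        )

    spacing = 5.558
    b = _Builder()
    ring_carbons = []
    for u in range(n_units):
        skip = set()
        if u < n_units - 1:
            skip.add(0)  # east vertex carries the linker
        if u > 0:
            skip.add(3)  # west vertex
        carbons = _add_benzene(
            b, (spacing * u, 0.0, 0.0), (0.0, 0.0, 1.0), resid=u + 1,
            segid="POLY", skip_h=skip,
        )
        ring_carbons.append(carbons)
    linker_ct = []
    for u in range(n_units - 1):
        ct = b.add("CL", "CT", (spacing * (u + 0.5), 0.0, 0.5), charge=-0.18,
                   resname="LNK", resid=u + 1, segid="LINK")
        for sign in (1.0, -1.0):
            h = b.add("HL", "HT",
                      b.coords[ct] + 1.111 * np.array([0.0, sign * 0.809, 0.588]),
                      charge=0.09, resname="LNK", resid=u + 1, segid="LINK")
            b.bond(ct, h)
        b.bond(ring_carbons[u][0], ct)      # east vertex of unit u
        b.bond(ct, ring_carbons[u + 1][3])  # west vertex of unit u+1
        linker_ct.append(ct)

    coords = np.array(b.coords)
    unit_atoms = [
        [i for i in range(len(b.names))
         if b.segids[i] == "POLY" and b.resids[i] == u + 1]
        for u in range(n_units)
    ]
    link_atoms = [
        [i for i in range(len(b.names))
         if b.segids[i] == "LINK" and b.resids[i] == u + 1]
        for u in range(n_units - 1)
    ]

    for k in range(n_piercings):
        w = k + 2  # pierced unit
        # threaded bond: unit k's east carbon to linker k's CH2 carbon
        p0 = coords[ring_carbons[k][0]]
        p1 = coords[linker_ct[k]]
        axis = _unit(p1 - p0)
        # rigid block: everything from linker k+1 onward
        block = [a for u in range(w, n_units) for a in unit_atoms[u]]
        block += [a for j in range(k + 1, n_units - 1) for a in link_atoms[j]]
        ring_center = coords[ring_carbons[w]].mean(axis=0)
        _, _, vt = np.linalg.svd(coords[ring_carbons[w]] - ring_center)
        normal = vt[-1]
        local = coords[block] - ring_center
        placed = None
        # scan crossing fraction along the bond, normal flip and in-plane roll
        for frac in (0.5, 0.35, 0.65, 0.25, 0.75):
            anchor = p0 + frac * (p1 - p0)
            for flip in (1.0, -1.0):
                for roll_deg in range(0, 360, 30):
                    rot1 = _rotation_between(normal, flip * axis)
                    rot2 = _axis_angle_rotation(axis, np.radians(roll_deg))
                    candidate = coords.copy()
                    candidate[block] = (local @ rot1.T) @ rot2.T + anchor
                    trial = _quick_system(b, candidate)
                    if len(find_piercings(trial)) == k + 1:
                        placed = candidate
                        break
                if placed is not None:
                    break
            if placed is not None:
                break
        if placed is None:
            raise ValueError(
                f"could not engineer piercing {k + 1} for ({n_units}, {n_piercings})"
            )
        coords = placed
    b.coords = [coords[i] for i in range(len(b.names))]

    system = b.build(jitter=0.02, rng=np.random.default_rng(seed))
    if len(find_piercings(system)) != n_piercings:
        raise ValueError("coordinate jitter broke an engineered piercing")
    bundle = FixtureBundle(
        system=system,
        params=embedded_minimal_params(),
        manifest={
            "piercings": n_piercings,
            "chiral_centers": 0,
            "notes": f"{n_units}-ring para-linked chain, {n_piercings} threaded linkers",
        },
    )
    bundle.validate()
    return bundle


def _ring_placement(local: np.ndarray, axis: np.ndarray, roll_deg: float):
    """Rigidly re-orient ring-local coordinates into the plane normal to *axis*."""
    # local frame of the ring: normal is smallest-variance direction
    _, _, vt = np.linalg.svd(local - local.mean(axis=0))
    old_normal = vt[-1]
    rot1 = _rotation_between(old_normal, axis)
    pts = local @ rot1.T
    roll = np.radians(roll_deg)
    rot2 = _axis_angle_rotation(axis, roll)
    return pts @ rot2.T


def _rotation_between(a, b):
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_angle_rotation(axis, angle):
    axis = _unit(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def _quick_system(b: _Builder, coords: np.ndarray) -> MolecularSystem:
    """Throwaway system (bonds only) for oracle checks during construction."""
    atoms = [
        Atom(index=i, name=b.names[i], resname=b.resnames[i], resid=b.resids[i],
             segid=b.segids[i], type=b.types[i], charge=b.charges[i],
             mass=_MASS[b.types[i]])
        for i in range(len(b.names))
    ]
    return MolecularSystem(atoms=atoms, bonds=list(b.bonds), coords=coords.copy())


# --------------------------------------------------------------------------
# fixture: chiral glyco-peptide toy
# --------------------------------------------------------------------------

def _add_hexose(b: _Builder, anchor_os: int, origin, direction, resid, segid,
                anomeric_strain: float = 0.0):
    """A hexopyranose-like chair (5 C + ring O, hydroxyls, exocyclic CH2OH).

    ``anchor_os`` is the glycosidic oxygen already in the builder; the ring's
    anomeric carbon bonds to it.  The sugar is built in a local frame and
    rigidly attached so the glycosidic oxygen lies along the anomeric
    carbon's tetrahedral heavy-substituent direction (a near-planar anomeric
    center would carry no usable chirality reference).

    ``anomeric_strain`` tilts the attachment away from that ideal direction,
    toward (and past) the ring plane: 0 is relaxed, values around 1.5 leave
    the anomeric center measurably chiral but under enough strain that the
    repair loop's biased stages will invert it unless it is restrained.
    Returns the list of all atom ids added.
    """
    attach_dir = _unit(direction)
    direction = np.array([0.0, 0.0, 1.0])  # local ring axis
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(direction, e1)
    center = np.zeros(3)
    r, pucker = 1.447, 0.25
    ring_types = ["CT", "CT", "CT", "CT", "CT", "OR"]  # C1..C5, O5
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    added = []
    ring_ids = []
    for k in range(6):
        ang = np.radians(60.0 * k)
        pos = (center + r * (np.cos(ang) * e1 + np.sin(ang) * e2)
               + ((-1) ** k) * pucker * direction)
        idx = b.add(ring_names[k], ring_types[k], pos, charge=0.1,
                    resname="HEX", resid=resid, segid=segid)
        ring_ids.append(idx)
        added.append(idx)
    for k in range(6):
        b.bond(ring_ids[k], ring_ids[(k + 1) % 6])
    c1, c2, c3, c4, c5, o5 = ring_ids
    b.bond(c1, anchor_os)

    centroid = center

    def substituent_dirs(atom_idx, nb1, nb2):
        p = b.coords[atom_idx]
        u1 = _unit(b.coords[nb1] - p)
        u2 = _unit(b.coords[nb2] - p)
        out = -_unit(u1 + u2)
        perp = _unit(np.cross(u1, u2))
        return _unit(out + perp), _unit(out - perp)

    def decorate(carbon, nb1, nb2, heavy: str | None):
        """Attach (optionally) a hydroxyl plus the ring hydrogen."""
        d_heavy, d_h = substituent_dirs(carbon, nb1, nb2)
        p = b.coords[carbon]
        ids = []
        if heavy == "OH":
            o = b.add("O" + b.names[carbon][1:], "OH", p + 1.42 * d_heavy,
                      charge=-0.4, resname="HEX", resid=resid, segid=segid)
            ho = b.add("HO" + b.names[carbon][1:], "HO",
                       b.coords[o] + 0.96 * _unit(b.coords[o] - centroid),
                       charge=0.3, resname="HEX", resid=resid, segid=segid)
            b.bond(carbon, o)
            b.bond(o, ho)
            ids += [o, ho]
        h = b.add("H" + b.names[carbon][1:], "HT", p + 1.111 * d_h, charge=0.09,
                  resname="HEX", resid=resid, segid=segid)
        b.bond(carbon, h)
        ids.append(h)
        return ids

    added += decorate(c1, o5, c2, None)      # anomeric: OS link + H
    added += decorate(c2, c1, c3, "OH")
    added += decorate(c3, c2, c4, "OH")
    added += decorate(c4, c3, c5, "OH")
    # C5 carries the exocyclic CH2OH chain plus its ring hydrogen
    d_heavy, d_h = substituent_dirs(c5, c4, o5)
    p5 = b.coords[c5]
    c6 = b.add("C6", "CT", p5 + 1.53 * d_heavy, charge=0.05, resname="HEX",
               resid=resid, segid=segid)
    b.bond(c5, c6)
    h5 = b.add("H5", "HT", p5 + 1.111 * d_h, charge=0.09, resname="HEX",
               resid=resid, segid=segid)
    b.bond(c5, h5)
    out6 = _unit(b.coords[c6] - p5)
    side = _unit(np.cross(out6, e1))
    o6 = b.add("O6", "OH", b.coords[c6] + 1.42 * _unit(out6 + 0.3 * side),
               charge=-0.4, resname="HEX", resid=resid, segid=segid)
    b.bond(c6, o6)
    ho6 = b.add("HO6", "HO", b.coords[o6] + 0.96 * out6, charge=0.3,
                resname="HEX", resid=resid, segid=segid)
    b.bond(o6, ho6)
    for sign in (1.0, -1.0):
        h6 = b.add("H6", "HT", b.coords[c6] + 1.111 * _unit(side * sign - 0.4 * out6),
                   charge=0.09, resname="HEX", resid=resid, segid=segid)
        b.bond(c6, h6)
        added.append(h6)
    added += [c6, h5, o6, ho6]

    # rigid attachment: map the anomeric carbon's heavy-substituent direction
    # onto the glycosidic bond so C1 ends up properly tetrahedral
    d_heavy_c1, d_h_c1 = substituent_dirs(c1, o5, c2)
    out_c1 = _unit(d_heavy_c1 + d_h_c1)
    link_local = _unit((1.0 - anomeric_strain) * d_heavy_c1
                       + anomeric_strain * out_c1)
    rot = _rotation_between(link_local, -attach_dir)
    c1_local = b.coords[c1].copy()
    c1_global = np.asarray(b.coords[anchor_os], dtype=float) + 1.43 * attach_dir
    for idx in set(added):
        b.coords[idx] = c1_global + rot @ (b.coords[idx] - c1_local)
    return added


def make_glyco_peptide_toy(seed: int = 0,
                            anomeric_strain: float = 0.0) -> FixtureBundle:
    """A three-residue peptide bearing two hexose rings, one of them pierced.

    The second sugar is repositioned so that the first glycosylated side
    chain's CB-OG bond threads its ring — the tangled-carbohydrate situation
    that makes stereocenter preservation during repair essential.  The toy
    carries >= 6 detectable stereocenters (ring carbons and alpha-carbons).
    """
    b = _Builder()
    segid = "GLYC"
    n_prev_c = None
    ca_ids, cb_info = [], []
    for res in range(3):
        x0 = 3.6 * res
        n = b.add("N", "NH", (x0, 0.0, 0.0), charge=-0.4, resname="RES",
                  resid=res + 1, segid=segid)
        if n_prev_c is not None:
            b.bond(n_prev_c, n)
            hn = b.add("HN", "HN", (x0 - 0.3, -0.9, 0.3), charge=0.3,
                       resname="RES", resid=res + 1, segid=segid)
            b.bond(n, hn)
        else:
            for dy, dz in ((-0.9, 0.3), (0.3, -0.9)):
                hn = b.add("HN", "HN", (x0 - 0.4, dy, dz), charge=0.3,
                           resname="RES", resid=res + 1, segid=segid)
                b.bond(n, hn)
        ca = b.add("CA", "CT", (x0 + 1.2, 0.8, 0.0), charge=0.07,
                   resname="RES", resid=res + 1, segid=segid)
        b.bond(n, ca)
        ha = b.add("HA", "HT", (x0 + 1.1, 1.5, -0.85), charge=0.09,
                   resname="RES", resid=res + 1, segid=segid)
        b.bond(ca, ha)
        c = b.add("C", "C", (x0 + 2.55, 0.35, 0.15), charge=0.51,
                  resname="RES", resid=res + 1, segid=segid)
        b.bond(ca, c)
        o = b.add("O", "O", (x0 + 2.95, -0.75, -0.1), charge=-0.51,
                  resname="RES", resid=res + 1, segid=segid)
        b.bond(c, o)
        cb = b.add("CB", "CT", (x0 + 1.35, 1.75, 1.2), charge=-0.05,
                   resname="RES", resid=res + 1, segid=segid)
        b.bond(ca, cb)
        if res == 0:
            # alanine-like methyl
            for k, (dy, dz) in enumerate(((0.9, 0.4), (-0.3, 1.0), (0.6, -0.6))):
                hb = b.add(f"HB{k + 1}", "HT",
                           b.coords[cb] + _unit((0.4, dy, dz)) * 1.111,
                           charge=0.09, resname="RES", resid=1, segid=segid)
                b.bond(cb, hb)
        else:
            for dy, dz in ((-0.75, 0.55), (0.85, -0.35)):
                hb = b.add("HB", "HT", b.coords[cb] + _unit((-0.5, dy, dz)) * 1.111,
                           charge=0.09, resname="RES", resid=res + 1, segid=segid)
                b.bond(cb, hb)
            og_dir = _unit((0.35, 0.55, 1.0))
            og = b.add("OG", "OS", b.coords[cb] + 1.43 * og_dir, charge=-0.3,
                       resname="RES", resid=res + 1, segid=segid)
            b.bond(cb, og)
            cb_info.append((cb, og))
        ca_ids.append(ca)
        n_prev_c = c

    # sugar 1 on residue 2, pointing +z; sugar 2 on residue 3
    ring1 = _add_hexose(b, cb_info[0][1], b.coords[cb_info[0][1]],
                        (0.2, 0.4, 1.0), resid=11, segid="SUG",
                        anomeric_strain=anomeric_strain)
    ring2 = _add_hexose(b, cb_info[1][1], b.coords[cb_info[1][1]],
                        (0.2, 0.4, 1.0), resid=12, segid="SUG",
                        anomeric_strain=anomeric_strain)
    ring2_all = [i for i in range(len(b.names))
                 if b.segids[i] == "SUG" and b.resids[i] == 12]

    # thread residue 2's CB-OG bond through sugar 2's ring
    coords = np.array(b.coords)
    cb2, og2 = cb_info[0]
    p0, p1 = coords[cb2], coords[og2]
    mid, axis = 0.5 * (p0 + p1), _unit(p1 - p0)
    ring2_ring_atoms = ring2[:6]
    local = coords[ring2_all] - coords[ring2_ring_atoms].mean(axis=0)
    placed = None
    for roll_deg in range(0, 360, 20):
        rot = _ring_placement(
            coords[ring2_ring_atoms] - coords[ring2_ring_atoms].mean(axis=0),
            axis, roll_deg,
        )
        # apply the same rigid transform to every sugar-2 atom
        _, _, vt = np.linalg.svd(
            coords[ring2_ring_atoms] - coords[ring2_ring_atoms].mean(axis=0)
        )
        rot1 = _rotation_between(vt[-1], axis)
        rot2 = _axis_angle_rotation(axis, np.radians(roll_deg))
        moved = (local @ rot1.T) @ rot2.T + mid
        candidate = coords.copy()
        candidate[ring2_all] = moved
        trial = _quick_system(b, candidate)
        if len(find_piercings(trial)) == 1:
            placed = candidate
            break
    if placed is None:
        raise ValueError("could not engineer the glyco-peptide piercing")
    b.coords = [placed[i] for i in range(len(b.names))]

    system = b.build(jitter=0.02, rng=np.random.default_rng(seed))
    if len(find_piercings(system)) != 1:
        raise ValueError("coordinate jitter broke the engineered piercing")
    bundle = FixtureBundle(
        system=system,
        params=embedded_minimal_params(),
        manifest={
            "piercings": 1,
            "chiral_centers": 6,
            "notes": "3-residue peptide, two hexoses, one pierced by CB-OG",
        },
    )
    bundle.validate()
    return bundle


ADVERSARIAL_ANOMERIC_STRAIN = 1.4


def make_strained_glyco_toy(seed: int = 0) -> FixtureBundle:
    """The glyco-peptide toy with both glycosidic attachments under strain.

    Each sugar's anomeric center is built tilted toward its ring plane: still
    unambiguously chiral, but poised so that the large forces of a biased
    repair stage will push it through planarity.  An unrestrained repair run
    on this fixture inverts at least one stereocenter; the default restrained
    run preserves every sign — the paired demonstration that the chirality
    restraints are load-bearing.
    """
    bundle = make_glyco_peptide_toy(
        seed=seed, anomeric_strain=ADVERSARIAL_ANOMERIC_STRAIN
    )
    bundle.manifest["notes"] = (
        "adversarial variant: strained anomeric attachments on both sugars"
    )
    return bundle
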