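"""CHARMM-format structure, parameter and run-configuration I/O.

This module owns the on-disk formats the tool touches:

* PSF topology files (standard and EXT column dialects, X-PLOR type names),
* PDB coordinate files (ATOM/HETATM records only),
* CHARMM parameter files (PRM/RTF/STR blocks: BONDS, ANGLES, DIHEDRALS,
  IMPROPER, NONBONDED),
* a flat key-value YAML run configuration.

Atom indexing is 0-based in memory; all file I/O uses the formats' native
1-based serials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, ParameterError, PDBError, PSFParseError

__all__ = [
    "Atom",
    "MolecularSystem",
    "ParameterSet",
    "RunConfig",
    "read_psf",
    "write_psf",
    "read_parameters",
    "read_pdb_coords",
    "write_pdb",
    "write_final_coords",
    "parse_run_config",
    "write_run_config",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """One particle of a molecular system.

    Attributes
    ----------
    index : int
        0-based atom index.
    name : str
        Atom name (e.g. ``CA``, ``HB1``).
    resname : str
        Residue name.
    resid : int
        Residue identifier.
    segid : str
        Segment identifier.
    type : str
        Force-field atom type string (X-PLOR style, taken verbatim).
    charge : float
        Partial charge in elementary charges.
    mass : float
        Mass in amu.
    """

    index: int
    name: str
    resname: str
    resid: int
    segid: str
    type: str
    charge: float
    mass: float


@dataclass
class MolecularSystem:
    """Atoms, bonded topology and coordinates of one simulation system.

    Coordinates are in Angstrom, stored as an ``(n_atoms, 3)`` float array,
    or ``None`` when only the topology has been loaded.  All topology tuples
    hold 0-based atom indices.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("system must contain at least one atom")
        for group, arity in (
            (self.bonds, 2),
            (self.angles, 3),
            (self.dihedrals, 4),
            (self.impropers, 4),
        ):
            for tup in group:
                if len(tup) != arity:
                    raise ValueError(f"topology tuple {tup} has wrong arity")
                for idx in tup:
                    if not 0 <= idx < n:
                        raise ValueError(
                            f"topology tuple {tup} references invalid atom {idx}"
                        )
        seen = set()
        for i, j in self.bonds:
            key = (min(i, j), max(i, j))
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ValueError(
                    f"coordinate shape {self.coords.shape} != ({n}, 3)"
                )
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("coordinates must be finite")

    # -- convenience -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def types(self) -> list[str]:
        return [a.type for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=[replace(a) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            impropers=list(self.impropers),
            coords=None if self.coords is None else self.coords.copy(),
        )


def _canon2(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _canon3(t: tuple[str, str, str]) -> tuple[str, ...]:
    return min(t, tuple(reversed(t)))


def _canon4(t: tuple[str, str, str, str]) -> tuple[str, ...]:
    return min(t, tuple(reversed(t)))


@dataclass
class ParameterSet:
    """Force-field parameter tables keyed by atom-type tuples.

    Lookups are invariant under reversal of the type tuple.  Dihedral entries
    are lists of ``(k_phi, n, delta_deg)`` terms (CHARMM multiplicities);
    wildcard middle-pair entries ``(X, b, c, X)`` are consulted when no exact
    quadruple matches.
    """

    bonds: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angles: dict[tuple[str, ...], tuple[float, float]] = field(default_factory=dict)
    dihedrals: dict[tuple[str, ...], list[tuple[float, int, float]]] = field(
        default_factory=dict
    )
    impropers: dict[tuple[str, ...], tuple[float, float]] = field(default_factory=dict)
    nonbonded: dict[str, tuple[float, float]] = field(default_factory=dict)

    # -- lookups (total or typed error) ------------------------------------
    def bond_param(self, t1: str, t2: str) -> tuple[float, float]:
        """Return ``(k_b, b0)`` for a type pair or raise :class:`ParameterError`."""
        try:
            return self.bonds[_canon2(t1, t2)]
        except KeyError:
            raise ParameterError(f"no bond parameters for type pair ({t1}, {t2})")

    def angle_param(self, t1: str, t2: str, t3: str) -> tuple[float, float]:
        try:
            return self.angles[_canon3((t1, t2, t3))]
        except KeyError:
            raise ParameterError(
                f"no angle parameters for type triple ({t1}, {t2}, {t3})"
            )

    def dihedral_param(
        self, t1: str, t2: str, t3: str, t4: str
    ) -> list[tuple[float, int, float]]:
        exact = _canon4((t1, t2, t3, t4))
        if exact in self.dihedrals:
            return self.dihedrals[exact]
        wild = _canon4(("X", t2, t3, "X"))
        if wild in self.dihedrals:
            return self.dihedrals[wild]
        raise ParameterError(
            f"no dihedral parameters for type quadruple ({t1}, {t2}, {t3}, {t4})"
        )

    def improper_param(self, t1: str, t2: str, t3: str, t4: str) -> tuple[float, float]:
        exact = _canon4((t1, t2, t3, t4))
        if exact in self.impropers:
            return self.impropers[exact]
        wild = _canon4((t1, "X", "X", t4))
        if wild in self.impropers:
            return self.impropers[wild]
        raise ParameterError(
            f"no improper parameters for type quadruple ({t1}, {t2}, {t3}, {t4})"
        )

    def nonbonded_param(self, t: str) -> tuple[float, float]:
        """Return ``(epsilon, rmin/2)`` for one atom type."""
        try:
            return self.nonbonded[t]
        except KeyError:
            raise ParameterError(f"no nonbonded parameters for type {t}")

    def validate_system(self, system: MolecularSystem) -> None:
        """Check that every lookup needed by *system* resolves."""
        types = system.types
        for t in set(types):
            self.nonbonded_param(t)
        for i, j in system.bonds:
            self.bond_param(types[i], types[j])
        for i, j, k in system.angles:
            self.angle_param(types[i], types[j], types[k])
        for i, j, k, l in system.dihedrals:
            self.dihedral_param(types[i], types[j], types[k], types[l])
        for i, j, k, l in system.impropers:
            self.improper_param(types[i], types[j], types[k], types[l])


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables of a repair run, with the tool's standard defaults.

    The convergence test asks that the most stretched bond exceed its
    equilibrium length by less than ``cutoff`` (0.4 Angstrom by default);
    ``window`` widens the per-iteration target set to every bond within that
    distance of the worst one.  The loop is capped at ``max_stages``
    minimization stages of ``steps_per_stage`` steps each.
    """

    structure: str | None = None
    coordinates: str | None = None
    parameters: list[str] = field(default_factory=list)
    cutoff: float = 0.4            # Angstrom, termination metric
    window: float = 0.1            # Angstrom, worst-bond selection window
    max_stages: int = 100
    steps_per_stage: int = 500
    dielectric: float = 80.0
    nonbonded_cutoff: float = 12.0  # Angstrom
    switch_on: float = 10.0         # Angstrom, switching onset
    chirality: bool = True
    chirality_k: float = 50.0       # kcal/mol/rad^2
    write_intermediates: bool = False
    seed: int = 1
    point_k: float = 10.0           # kcal/mol/A^2, perpendicular pulls
    separation_k: float = 10.0      # kcal/mol/A^2, center-of-mass bias
    separation_target: float = 10.0  # Angstrom
    hill_height: float = 20.0       # kcal/mol
    hill_radius: float = 4.0        # Angstrom
    softcore_delta: float = 2.5     # Angstrom, shifted-distance soft core
    perpendicular_distance: float = 10.0  # Angstrom
    neighborhood_radius: float = 4.0      # Angstrom, flagged/nearby selection
    gradient_tol: float = 1e-4
    label: str = "lbe"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be > 0")
        if self.window < 0:
            raise ConfigError("window must be >= 0")
        if self.max_stages < 1:
            raise ConfigError("max_stages must be >= 1")
        if self.steps_per_stage < 1:
            raise ConfigError("steps_per_stage must be >= 1")
        if self.dielectric < 1:
            raise ConfigError("dielectric must be >= 1")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            out[f.name] = getattr(self, f.name)
        return out


_REQUIRED_CONFIG_KEYS = ("structure", "coordinates", "parameters")


def parse_run_config(path: str | Path) -> RunConfig:
    """Parse a flat key-value run-configuration file.

    Unset keys take :class:`RunConfig` defaults; all paths are resolved
    relative to the configuration file.  Unknown keys produce a warning,
    missing required keys a :class:`ConfigError` naming them.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}")
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")

    known = {f.name for f in fields(RunConfig)}
    values = {}
    for key, val in raw.items():
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        values[key] = val

    missing = [k for k in _REQUIRED_CONFIG_KEYS if not values.get(k)]
    if missing:
        raise ConfigError(f"config {path} missing required keys: {', '.join(missing)}")

    base = path.parent
    values["structure"] = str((base / values["structure"]).resolve())
    values["coordinates"] = str((base / values["coordinates"]).resolve())
    params = values["parameters"]
    if isinstance(params, str):
        params = params.split()
    values["parameters"] = [str((base / p).resolve()) for p in params]
    if values.get("output_dir") is not None:
        values["output_dir"] = str((base / values["output_dir"]).resolve())
    return RunConfig(**values)


def write_run_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a :class:`RunConfig` back to a flat key-value file."""
    data = config.to_dict()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# --------------------------------------------------------------------------
# PSF
# --------------------------------------------------------------------------

def read_psf(path: str | Path) -> MolecularSystem:
    """Read a PSF topology file (standard or EXT dialect, autodetected).

    The returned system has no coordinates; use :func:`read_pdb_coords`.
    Counts of atoms/bonds/angles/dihedrals/impropers must equal the declared
    section counts or a :class:`PSFParseError` naming the line is raised.
    """
    path = Path(path)
    if not path.exists():
        raise PSFParseError(f"PSF file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].lstrip().startswith("PSF"):
        raise PSFParseError(f"{path}:1: not a PSF file (missing PSF header)")

    # locate section headers: "<count> !NAME..."
    sections: dict[str, tuple[int, int]] = {}  # name -> (count, line index)
    for ln, line in enumerate(lines):
        s = line.split("!", 1)
        if len(s) == 2 and s[0].strip().isdigit():
            name = s[1].split(":")[0].split()[0]
            sections[name] = (int(s[0].strip()), ln)

    for req in ("NATOM", "NBOND", "NTHETA", "NPHI", "NIMPHI"):
        if req not in sections:
            raise PSFParseError(f"{path}: missing !{req} section")

    n_atoms, atom_ln = sections["NATOM"]
    atoms: list[Atom] = []
    for k in range(n_atoms):
        ln = atom_ln + 1 + k
        if ln >= len(lines):
            raise PSFParseError(f"{path}:{ln + 1}: NATOM section truncated")
        tok = lines[ln].split()
        if len(tok) < 8:
            raise PSFParseError(f"{path}:{ln + 1}: unparseable atom line")
        try:
            serial = int(tok[0])
            resid = int("".join(c for c in tok[2] if c.isdigit() or c == "-") or 0)
            charge = float(tok[6])
            mass = float(tok[7])
        except ValueError:
            raise PSFParseError(f"{path}:{ln + 1}: unparseable numeric field")
        if serial != k + 1:
            raise PSFParseError(
                f"{path}:{ln + 1}: atom serial {serial} out of order (expected {k + 1})"
            )
        atoms.append(
            Atom(
                index=k,
                segid=tok[1],
                resid=resid,
                resname=tok[3],
                name=tok[4],
                type=tok[5],
                charge=charge,
                mass=mass,
            )
        )

    def read_index_section(name: str, arity: int) -> list[tuple[int, ...]]:
        count, header_ln = sections[name]
        needed = count * arity
        ints: list[int] = []
        ln = header_ln + 1
        while len(ints) < needed and ln < len(lines):
            line = lines[ln]
            if "!" in line and line.split("!", 1)[0].strip().isdigit():
                break  # ran into the next section header early
            for tok in line.split():
                try:
                    ints.append(int(tok))
                except ValueError:
                    raise PSFParseError(f"{path}:{ln + 1}: unparseable index {tok!r}")
            ln += 1
        if len(ints) < needed:
            raise PSFParseError(
                f"{path}:{header_ln + 1}: {name} declares {count} entries "
                f"but only {len(ints) // arity} are listed"
            )
        ints = ints[:needed]
        out = []
        for k in range(count):
            tup = tuple(v - 1 for v in ints[k * arity : (k + 1) * arity])
            for v in tup:
                if not 0 <= v < n_atoms:
                    raise PSFParseError(
                        f"{path}: {name} references atom serial {v + 1} "
                        f"outside 1..{n_atoms}"
                    )
            out.append(tup)
        return out

    bonds = [tuple(t) for t in read_index_section("NBOND", 2)]
    angles = [tuple(t) for t in read_index_section("NTHETA", 3)]
    dihedrals = [tuple(t) for t in read_index_section("NPHI", 4)]
    impropers = [tuple(t) for t in read_index_section("NIMPHI", 4)]
    return MolecularSystem(
        atoms=atoms, bonds=bonds, angles=angles, dihedrals=dihedrals,
        impropers=impropers,
    )


def write_psf(system: MolecularSystem, path: str | Path, ext: bool = False) -> None:
    """Write *system* as a PSF file in the standard or EXT column dialect."""
    path = Path(path)
    out = []
    out.append("PSF EXT" if ext else "PSF")
    out.append("")
    out.append(f"{1:>10d} !NTITLE" if ext else f"{1:>8d} !NTITLE")
    out.append(" REMARKS written by ringfree")
    out.append("")
    wid = 10 if ext else 8
    if ext:
        atom_fmt = "{:>10d} {:<8s} {:<8d} {:<8s} {:<8s} {:<6s} {:>10.6f} {:>13.4f} {:>11d}"
    else:
        atom_fmt = "{:>8d} {:<4s} {:<4d} {:<4s} {:<4s} {:<4s} {:>10.6f} {:>13.4f} {:>11d}"
    out.append(f"{system.n_atoms:>{wid}d} !NATOM")
    for a in system.atoms:
        out.append(
            atom_fmt.format(
                a.index + 1, a.segid, a.resid, a.resname, a.name, a.type,
                a.charge, a.mass, 0,
            )
        )
    out.append("")

    def index_section(name: str, tuples, arity: int, per_line: int):
        out.append(f"{len(tuples):>{wid}d} !{name}")
        flat = [v + 1 for tup in tuples for v in tup]
        stride = per_line * arity
        for k in range(0, len(flat), stride):
            out.append("".join(f"{v:>{wid}d}" for v in flat[k : k + stride]))
        out.append("")

    index_section("NBOND: bonds", system.bonds, 2, 4)
    index_section("NTHETA: angles", system.angles, 3, 3)
    index_section("NPHI: dihedrals", system.dihedrals, 4, 2)
    index_section("NIMPHI: impropers", system.impropers, 4, 2)
    index_section("NDON: donors", [], 1, 8)
    index_section("NACC: acceptors", [], 1, 8)
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# CHARMM parameter files
# --------------------------------------------------------------------------

_SECTION_KEYWORDS = {
    "BONDS": "BONDS",
    "ANGLES": "ANGLES",
    "THETAS": "ANGLES",
    "DIHEDRALS": "DIHEDRALS",
    "PHI": "DIHEDRALS",
    "IMPROPER": "IMPROPER",
    "IMPROPERS": "IMPROPER",
    "IMPHI": "IMPROPER",
    "NONBONDED": "NONBONDED",
    "CMAP": "SKIP",
    "NBFIX": "SKIP",
    "HBOND": "SKIP",
    "ATOMS": "SKIP",
    "MASS": "SKIP",
    "END": "END",
    "RETURN": "END",
}


def read_parameters(paths: list[str | Path]) -> ParameterSet:
    """Build a :class:`ParameterSet` from a list of CHARMM parameter files.

    Later files override earlier entries for the same key.  Comment lines
    (``!`` and ``*``) are ignored; CMAP/NBFIX/HBOND blocks are tolerated and
    skipped.  At least one file must contribute a BONDS block.
    """
    params = ParameterSet()
    saw_bonds = False
    for path in paths:
        saw_bonds |= _parse_parameter_file(Path(path), params)
    if not saw_bonds:
        raise ParameterError(
            "no BONDS block found in any parameter file: " + ", ".join(map(str, paths))
        )
    return params


def parse_parameter_text(text: str, params: ParameterSet | None = None) -> ParameterSet:
    """Parse CHARMM parameter blocks from an in-memory string."""
    params = params if params is not None else ParameterSet()
    _parse_parameter_lines(text.splitlines(), "<string>", params)
    return params


def _parse_parameter_file(path: Path, params: ParameterSet) -> bool:
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    return _parse_parameter_lines(path.read_text().splitlines(), str(path), params)


def _floats(tok, path, ln):
    try:
        return [float(t) for t in tok]
    except ValueError:
        raise ParameterError(f"{path}:{ln}: malformed numeric field in {tok}")


def _parse_parameter_lines(lines, path: str, params: ParameterSet) -> bool:
    section = None
    saw_bonds = False
    pending_continuation = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].rstrip()
        if not line.strip() or line.lstrip().startswith("*"):
            continue
        tok = line.split()
        head = tok[0].upper()
        if pending_continuation:
            pending_continuation = line.rstrip().endswith("-")
            continue
        if head in _SECTION_KEYWORDS:
            section = _SECTION_KEYWORDS[head]
            if section == "BONDS":
                saw_bonds = True
            if section == "NONBONDED":
                # option flags may continue over lines ending with '-'
                pending_continuation = line.rstrip().endswith("-")
            if section == "END":
                section = None
            continue
        if section is None or section == "SKIP":
            continue
        if section == "BONDS":
            if len(tok) < 4:
                raise ParameterError(f"{path}:{ln}: malformed bond line {raw!r}")
            kb, b0 = _floats(tok[2:4], path, ln)
            if b0 <= 0:
                raise ParameterError(f"{path}:{ln}: equilibrium length must be > 0")
            params.bonds[_canon2(tok[0], tok[1])] = (kb, b0)
        elif section == "ANGLES":
            if len(tok) < 5:
                raise ParameterError(f"{path}:{ln}: malformed angle line {raw!r}")
            kt, t0 = _floats(tok[3:5], path, ln)
            params.angles[_canon3((tok[0], tok[1], tok[2]))] = (kt, t0)
        elif section == "DIHEDRALS":
            if len(tok) < 7:
                raise ParameterError(f"{path}:{ln}: malformed dihedral line {raw!r}")
            kphi, n, delta = _floats(tok[4:7], path, ln)
            key = _canon4((tok[0], tok[1], tok[2], tok[3]))
            term = (kphi, int(n), delta)
            # multiple multiplicities for one quadruple accumulate within a
            # file; a later file's first entry for the key replaces the list
            existing = params.dihedrals.get(key)
            if existing is not None and (path, key) == getattr(
                params, "_last_dih", (None, None)
            ):
                existing.append(term)
            else:
                params.dihedrals[key] = [term]
            params._last_dih = (path, key)  # type: ignore[attr-defined]
        elif section == "IMPROPER":
            if len(tok) < 7:
                raise ParameterError(f"{path}:{ln}: malformed improper line {raw!r}")
            kpsi, _, psi0 = _floats(tok[4:7], path, ln)
            params.impropers[_canon4((tok[0], tok[1], tok[2], tok[3]))] = (kpsi, psi0)
        elif section == "NONBONDED":
            if len(tok) < 4:
                continue  # option line inside the block
            try:
                _, eps, rmin2 = (float(tok[1]), float(tok[2]), float(tok[3]))
            except ValueError:
                continue  # tolerated option line (cutnb, ctofnb, ...)
            params.nonbonded[tok[0]] = (abs(eps), rmin2)
    return saw_bonds


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def read_pdb_coords(path: str | Path, system: MolecularSystem) -> MolecularSystem:
    """Populate *system* coordinates from a PDB file, in file order.

    The number of ATOM/HETATM records must equal the system's atom count.
    Occupancy/beta columns may be absent.  Returns the same system object.
    """
    path = Path(path)
    if not path.exists():
        raise PDBError(f"PDB file not found: {path}")
    coords = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        except (ValueError, IndexError):
            raise PDBError(f"{path}:{ln}: unparseable coordinate columns")
        coords.append(xyz)
    if len(coords) != system.n_atoms:
        raise PDBError(
            f"{path}: {len(coords)} coordinate records but system has "
            f"{system.n_atoms} atoms"
        )
    system.coords = np.array(coords, dtype=float)
    system.validate()
    return system


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    """Write standard PDB ATOM records with 1-based serials."""
    if system.coords is None:
        raise PDBError("system has no coordinates to write")
    if not np.all(np.isfinite(system.coords)):
        raise PDBError("coordinates must be finite")
    if np.any(np.abs(system.coords) >= 10000.0):
        raise PDBError(
            "coordinate overflow of fixed PDB columns (|x| >= 10000 A); "
            "recenter the system or use a wider output format"
        )
    out = []
    for a, (x, y, z) in zip(system.atoms, system.coords):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        out.append(
            f"ATOM  {a.index + 1:>5d} {name:<4.4s} {a.resname:<4.4s}"
            f"{a.resid % 10000:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}"
            f"{0.0:>6.2f}{0.0:>6.2f}      {a.segid:<4.4s}"
        )
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def write_final_coords(system: MolecularSystem, outdir: str | Path, label: str = "lbe") -> Path:
    """Write the converged structure under a deterministic run-label name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{label}-opt.pdb"
    write_pdb(system, path)
    return path
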