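"""Force-field-aware long-bond detection.

A ring piercing cannot be observed directly from a bond list, but it leaves a
symptom: after minimization the threaded bond stays stretched far beyond its
force-field equilibrium length b0, because extending the bond is cheaper than
the Lennard-Jones cost of passing through the ring.  This module measures the
per-bond deviation ``length - b0``, flags bonds whose deviation exceeds a
cutoff (default 0.4 A), and selects the per-iteration repair targets: every
bond within a window (default 0.1 A) of the worst one.

Deviation is signed — compressed bonds are negative — but only positive
deviations are ever flagged; the symptom is exclusively stretching.  The
historic absolute length rule (flag any bond longer than 1.65 A) is kept as
an optional legacy mode, off by default, because it misfires on normal bonds
to large elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .charmm_io import MolecularSystem, ParameterSet

__all__ = [
    "BondRecord",
    "StretchReport",
    "bond_deviations",
    "largest_deviation",
    "select_target_bonds",
    "per_atom_deviation_field",
    "write_report",
]

LEGACY_ABSOLUTE_CUTOFF = 1.65  # Angstrom, historic fixed-length rule


@dataclass(frozen=True)
class BondRecord:
    """Measured state of one bond against its force-field equilibrium."""

    i: int
    j: int
    type_i: str
    type_j: str
    length: float
    b0: float

    @property
    def deviation(self) -> float:
        return self.length - self.b0

    @property
    def bond(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class StretchReport:
    """Per-bond deviations plus flagged and target subsets.

    ``flagged`` holds bonds with deviation >= cutoff (or beyond the legacy
    absolute length when that mode is enabled); ``targets`` the bonds within
    the selection window of the maximum.  Both are unset (empty) until the
    corresponding selector has run.
    """

    records: list[BondRecord]
    flagged: set[tuple[int, int]] = field(default_factory=set)
    targets: set[tuple[int, int]] = field(default_factory=set)

    @property
    def max_record(self) -> BondRecord:
        return largest_deviation(self)[0]

    @property
    def max_deviation(self) -> float:
        return largest_deviation(self)[1]


def bond_deviations(system: MolecularSystem, params: ParameterSet) -> StretchReport:
    """Measure every bond of *system* against the parameter table.

    Lengths are plain Euclidean distances (runs are non-periodic).  Raises a
    typed error naming the pair if a bond's type pair has no parameters.
    """
    if system.coords is None:
        raise ValueError("system has no coordinates")
    types = system.types
    records = []
    for i, j in system.bonds:
        _, b0 = params.bond_param(types[i], types[j])
        length = float(np.linalg.norm(system.coords[i] - system.coords[j]))
        records.append(
            BondRecord(i=i, j=j, type_i=types[i], type_j=types[j],
                       length=length, b0=b0)
        )
    return StretchReport(records=records)


def largest_deviation(report: StretchReport) -> tuple[BondRecord, float]:
    """Return the maximal-deviation record; ties break on the smaller bond.

    All-equilibrium systems return a zero (or negative) deviation rather
    than an error — a structure with no stretching is a valid measurement.
    """
    if not report.records:
        raise ValueError("empty stretch report")
    best = max(report.records, key=lambda r: (r.deviation, (-r.i, -r.j)))
    return best, best.deviation


def flag_stretched(
    report: StretchReport,
    cutoff: float,
    legacy_absolute: float | None = None,
) -> set[tuple[int, int]]:
    """Populate and return the flagged set: deviation >= cutoff.

    When *legacy_absolute* is given (e.g. 1.65), bonds longer than that
    absolute length are flagged as well, regardless of b0.
    """
    flagged = {
        r.bond
        for r in report.records
        if r.deviation >= cutoff
        or (legacy_absolute is not None and r.length > legacy_absolute)
    }
    report.flagged = flagged
    return flagged


def select_target_bonds(
    report: StretchReport, window: float = 0.1, cutoff: float = 0.4
) -> set[tuple[int, int]]:
    """Bonds within *window* of the most stretched bond, gated by *cutoff*.

    Empty when the maximum deviation is below the cutoff.  The window is
    closed at its boundary (deviation >= max - window).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    _, max_dev = largest_deviation(report)
    if max_dev < cutoff:
        report.targets = set()
        return set()
    targets = {r.bond for r in report.records if r.deviation >= max_dev - window}
    report.targets = targets
    return targets


def per_atom_deviation_field(
    report: StretchReport, threshold: float = 0.1
) -> dict[int, float]:
    """Sum of large bond deviations (>= threshold) incident to each atom.

    Atoms with no sufficiently stretched bond map to 0.  This is the
    per-atom field used to color structures by local strain.
    """
    atoms = {a for r in report.records for a in r.bond}
    out = {a: 0.0 for a in atoms}
    for r in report.records:
        if r.deviation >= threshold:
            out[r.i] += r.deviation
            out[r.j] += r.deviation
    return out


def write_report(report: StretchReport, system: MolecularSystem, path: str | Path) -> None:
    """Write one line per flagged bond: indices, names, types, length, b0, deviation."""
    lines = ["# i j name_i name_j type_i type_j length_A b0_A deviation_A"]
    flagged = report.flagged or set()
    for r in sorted(report.records, key=lambda r: -r.deviation):
        if r.bond not in flagged:
            continue
        ai, aj = system.atoms[r.i], system.atoms[r.j]
        lines.append(
            f"{r.i} {r.j} {ai.name} {aj.name} {r.type_i} {r.type_j} "
            f"{r.length:.4f} {r.b0:.4f} {r.deviation:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
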