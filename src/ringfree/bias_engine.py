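"""Construction, attachment and escalation of per-bond repair biases.

Each targeted long bond receives, for the next biased minimization stage:

* two harmonic point restraints pulling the bond's atoms toward *opposite*
  perpendicular targets — points 10 A from the bond midpoint in the plane
  normal to the bond vector, shearing the bond sideways out of the ring;
* a one-sided center-of-mass separation bias pushing the bond pair and the
  nearby ring neighborhood apart, up to 10 A;
* a Gaussian repulsive density hill at the bond midpoint that evacuates the
  tangled region (the bond's own atoms are exempt);
* soft-core flagging of the bond atoms and everything within the
  neighborhood radius of the midpoint, so atoms can pass through each other.

If the same bond remains the longest between successive workflow iterations
all of its force constants are doubled; a bond that stops being targeted has
its biases removed.  Escalation counters key on bond identity and survive
unperturbed verification rounds, so a piercing that re-reveals itself keeps
its escalation history.  The only stochastic element is the in-plane
direction of the perpendicular targets, drawn from the run's seeded
generator, so whole runs replay identically for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charmm_io import MolecularSystem, RunConfig
from .energy_min import EnergyModel
from .topology_graph import Ring, atoms_within, bonded_neighborhood

__all__ = [
    "BiasRecord",
    "BiasState",
    "perpendicular_target",
    "build_biases",
    "escalate",
    "clear_biases",
]


@dataclass
class BiasRecord:
    """Active biases and escalation history for one target bond."""

    bond: tuple[int, int]
    point_k: float
    separation_k: float
    hill_height: float
    counter: int = 1
    point_ids: tuple[int, ...] = ()
    point_targets: tuple = ()
    separation_id: int | None = None
    hill_id: int | None = None

    def __post_init__(self) -> None:
        if min(self.point_k, self.separation_k, self.hill_height) <= 0:
            raise ValueError("force constants must be strictly positive")
        if self.counter < 1:
            raise ValueError("escalation counter must be >= 1")


@dataclass
class BiasState:
    """All per-bond records, the flagged atom set and the run's generator."""

    rng: np.random.Generator
    records: dict[tuple[int, int], BiasRecord] = field(default_factory=dict)
    flagged: set[int] = field(default_factory=set)
    prev_longest: tuple[int, int] | None = None


def _canon_bond(bond) -> tuple[int, int]:
    i, j = bond
    return (i, j) if i < j else (j, i)


def perpendicular_target(
    bond: tuple[int, int],
    coords: np.ndarray,
    distance: float = 10.0,
    rng: np.random.Generator | None = None,
):
    """Opposite pull targets perpendicular to a bond.

    Both returned points lie in the plane through the bond midpoint normal
    to the bond vector, exactly *distance* from the midpoint, on opposite
    sides; the in-plane direction is uniform on the circle (drawn from
    *rng*).  Raises on a zero-length bond.
    """
    rng = rng if rng is not None else np.random.default_rng()
    i, j = bond
    a, b = coords[i], coords[j]
    axis = b - a
    norm = float(np.linalg.norm(axis))
    if norm < 1e-6:
        raise ValueError(f"bond {bond} has (near) zero length")
    u = axis / norm
    mid = 0.5 * (a + b)
    # deterministic in-plane frame: Gram-Schmidt against the least-aligned axis
    seed_axis = np.zeros(3)
    seed_axis[int(np.argmin(np.abs(u)))] = 1.0
    e1 = seed_axis - np.dot(seed_axis, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.cos(angle) * e1 + np.sin(angle) * e2
    target_a = mid + distance * direction
    target_b = mid - distance * direction
    return target_a, target_b


def build_biases(
    system: MolecularSystem,
    target_bonds,
    graph,
    rings: list[Ring],
    state: BiasState,
    model: EnergyModel,
    config: RunConfig,
) -> BiasState:
    """Attach the full bias battery for every target bond to *model*.

    Bonds with an existing record keep their (possibly escalated) force
    constants; new bonds start at the configured defaults with counter 1.
    Existing attached terms for a re-targeted bond are replaced, with fresh
    perpendicular directions drawn from the run generator.
    """
    targets = [_canon_bond(b) for b in sorted(_canon_bond(b) for b in target_bonds)]
    if not targets:
        raise ValueError("target bond set must be non-empty")
    ring_atoms = set()
    for ring in rings:
        ring_atoms.update(ring.atoms)

    for bond in targets:
        i, j = bond
        old = state.records.get(bond)
        if old is not None:
            _detach_record(model, old)
            record = old
        else:
            record = BiasRecord(
                bond=bond,
                point_k=config.point_k,
                separation_k=config.separation_k,
                hill_height=config.hill_height,
            )
            state.records[bond] = record

        mid = 0.5 * (system.coords[i] + system.coords[j])
        ta, tb = perpendicular_target(
            bond, system.coords, distance=config.perpendicular_distance,
            rng=state.rng,
        )
        pid_a = model.add_point_restraint(i, ta, record.point_k)
        pid_b = model.add_point_restraint(j, tb, record.point_k)
        record.point_ids = (pid_a, pid_b)
        record.point_targets = (ta, tb)

        near = atoms_within(system, mid, config.neighborhood_radius)
        near_ring = near & ring_atoms
        neighborhood = bonded_neighborhood(graph, near_ring, 2) - {i, j} if near_ring else set()
        if neighborhood:
            # push the neighborhood away along a seeded fallback direction if
            # the two centers start coincident (symmetric pierced geometries)
            record.separation_id = model.add_separation_bias(
                (i, j),
                sorted(neighborhood),
                system.masses,
                target=config.separation_target,
                k=record.separation_k,
                fallback_direction=(ta - mid) / config.perpendicular_distance,
            )
        else:
            record.separation_id = None

        record.hill_id = model.add_density_hill(
            mid, radius=config.hill_radius, height=record.hill_height,
            exempt=(i, j),
        )
        state.flagged |= {i, j} | near

    return state


def escalate(state: BiasState, current_longest) -> BiasState:
    """Double a record's constants when its bond stays the system's longest.

    Called once per biased iteration, before rebuilding biases.  Records for
    the same repeated longest bond escalate exponentially (k * 2^n after n
    repeats); any other record keeps its constants until its bond stops
    being targeted.
    """
    bond = _canon_bond(current_longest)
    if state.prev_longest is not None and bond == state.prev_longest:
        record = state.records.get(bond)
        if record is not None:
            record.point_k *= 2.0
            record.separation_k *= 2.0
            record.hill_height *= 2.0
            record.counter += 1
    state.prev_longest = bond
    return state


def drop_untargeted(state: BiasState, model: EnergyModel, target_bonds) -> None:
    """Remove biases and reset records for bonds no longer targeted."""
    targets = {_canon_bond(b) for b in target_bonds}
    for bond in list(state.records):
        if bond not in targets:
            _detach_record(model, state.records[bond])
            del state.records[bond]


def clear_biases(model: EnergyModel, state: BiasState) -> None:
    """Strip every bias term and empty the flagged set.

    Chirality restraints are retained — they certify the verification round
    too.  Escalation histories (force constants, counters) survive so a
    piercing that re-reveals its long bond resumes where it left off.
    """
    model.clear_all_biases()
    state.flagged.clear()
    for record in state.records.values():
        record.point_ids = ()
        record.point_targets = ()
        record.separation_id = None
        record.hill_id = None


def _detach_record(model: EnergyModel, record: BiasRecord) -> None:
    for bid in record.point_ids:
        if bid in model.point_restraints:
            model.remove_bias(bid)
    if record.separation_id is not None and record.separation_id in model.separation_biases:
        model.remove_bias(record.separation_id)
    if record.hill_id is not None and record.hill_id in model.hills:
        model.remove_bias(record.hill_id)
    record.point_ids = ()
    record.separation_id = None
    record.hill_id = None
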