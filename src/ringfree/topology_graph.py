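"""Graph view of the bonded topology.

Ring enumeration (smallest set of smallest rings, capped at size 7 — the
artifact targets small rings such as aromatics and hexoses, not macrocycles),
bonded neighborhoods and distance-based atom selections.  All selections are
non-periodic: repair runs happen outside any periodic unit cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .charmm_io import MolecularSystem

__all__ = [
    "Ring",
    "build_graph",
    "enumerate_small_rings",
    "atoms_within",
    "bonded_neighborhood",
]

MAX_RING_SIZE = 7


@dataclass(frozen=True)
class Ring:
    """An ordered small cycle of atom indices.

    Consecutive members (and last-first) are bonded; 3 <= size <= 7.
    """

    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not 3 <= n <= MAX_RING_SIZE:
            raise ValueError(f"ring size {n} outside 3..{MAX_RING_SIZE}")
        if len(set(self.atoms)) != n:
            raise ValueError("ring contains a repeated atom")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __contains__(self, atom: int) -> bool:
        return atom in self.atoms


def build_graph(system: MolecularSystem) -> nx.Graph:
    """Return an undirected graph whose edges are exactly the system's bonds."""
    g = nx.Graph()
    g.add_nodes_from(range(system.n_atoms))
    g.add_edges_from(system.bonds)
    return g


def _order_cycle(graph: nx.Graph, members: set[int]) -> tuple[int, ...] | None:
    """Order a cycle-basis node set into a bonded cycle, canonically.

    Starts at the smallest member and walks toward its smaller bonded
    neighbor, depth-first, requiring a Hamiltonian cycle over the set.
    """
    start = min(members)
    sub = {m: sorted(n for n in graph.neighbors(m) if n in members) for m in members}

    def dfs(path: list[int], visited: set[int]):
        if len(path) == len(members):
            return path if path[0] in sub[path[-1]] else None
        for nxt in sub[path[-1]]:
            if nxt not in visited:
                res = dfs(path + [nxt], visited | {nxt})
                if res is not None:
                    return res
        return None

    ordered = dfs([start], {start})
    if ordered is None:
        return None
    # canonical direction: second element is the smaller of the two neighbors
    if ordered[-1] < ordered[1]:
        ordered = [ordered[0]] + ordered[:0:-1]
    return tuple(ordered)


def enumerate_small_rings(graph: nx.Graph, max_size: int = MAX_RING_SIZE) -> list[Ring]:
    """Smallest set of smallest rings restricted to ``size <= max_size``.

    Each cycle of a minimum cycle basis is ordered into a bonded walk and
    returned sorted by its smallest member index (then lexicographically),
    so the result is deterministic for a given topology.
    """
    rings: list[Ring] = []
    for members in nx.minimum_cycle_basis(graph):
        if len(members) > max_size or len(members) < 3:
            continue
        ordered = _order_cycle(graph, set(members))
        if ordered is not None:
            rings.append(Ring(ordered))
    rings.sort(key=lambda r: r.atoms)
    return rings


def atoms_within(system: MolecularSystem, center, radius: float) -> set[int]:
    """Atoms whose coordinates lie within the closed ball of *radius* at *center*."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if system.coords is None:
        raise ValueError("system has no coordinates")
    center = np.asarray(center, dtype=float)
    d2 = np.sum((system.coords - center) ** 2, axis=1)
    return set(np.nonzero(d2 <= radius * radius)[0].tolist())


def bonded_neighborhood(graph: nx.Graph, seeds, depth: int) -> set[int]:
    """All atoms within *depth* bond hops of any seed, seeds included."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    seeds = set(seeds)
    for s in seeds:
        if s not in graph:
            raise ValueError(f"seed atom {s} not in graph")
    out = set(seeds)
    frontier = set(seeds)
    for _ in range(depth):
        nxt = set()
        for node in frontier:
            nxt.update(graph.neighbors(node))
        nxt -= out
        if not nxt:
            break
        out |= nxt
        frontier = nxt
    return out
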