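"""Lightweight classical energy model and deterministic minimizer.

Implements the CHARMM-style bonded terms (harmonic bonds ``k(b-b0)^2``,
harmonic angles, cosine dihedrals ``k(1+cos(n*phi-delta))``, harmonic
impropers), 12-6 Lennard-Jones with Lorentz-Berthelot-style CHARMM combining
(``rmin = rmin_i/2 + rmin_j/2``, ``eps = sqrt(eps_i*eps_j)``), and Coulomb
electrostatics screened by a relative dielectric, with smooth switching of
all nonbonded terms between the switching onset and the cutoff.  1-2 and 1-3
pairs are excluded; 1-4 pairs interact at full strength.  No periodicity and
no mesh electrostatics: repair runs happen in vacuum-like conditions with a
high dielectric.

Flagged atoms get a *soft-core* nonbonded treatment: every pair involving at
least one flagged atom interacts at the effective distance
``r_eff = sqrt(r^2 + delta^2)``, which keeps the energy finite at r = 0 and
lets tangled atoms pass through each other during biased minimization.  This
is a single "coupled-but-softened" state with one parameter — the repair
loop only needs a softened landscape, never an alchemical free energy.

The minimizer is a deterministic Polak-Ribiere conjugate-gradient descent
with an Armijo backtracking line search, so the energy trace is
non-increasing across accepted steps and identical inputs give identical
trajectories.

Extra restraint terms (harmonic point pulls, a one-sided center-of-mass
separation bias, Gaussian repulsive density hills, chirality impropers) hang
off the :class:`EnergyModel` and their forces are exact gradients too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .charmm_io import MolecularSystem, ParameterSet
from .errors import EnergyError
from .pierce_oracle import ImproperRestraint

__all__ = [
    "EnergyModel",
    "MinimizationResult",
    "EnergyEvaluator",
    "compute_energy_forces",
    "minimize",
]

COULOMB_CONST = 332.0636  # kcal/mol * A / e^2


# --------------------------------------------------------------------------
# model: toggles, physics constants and extra restraint terms
# --------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """Term toggles, nonbonded constants and attached bias terms."""

    use_bonds: bool = True
    use_angles: bool = True
    use_dihedrals: bool = True
    use_impropers: bool = True
    use_lj: bool = True
    use_coulomb: bool = True
    dielectric: float = 80.0
    cutoff: float = 12.0        # Angstrom
    switch_on: float = 10.0     # Angstrom
    softcore_delta: float = 2.5  # Angstrom

    # bias terms, each removable by id
    point_restraints: dict[int, tuple[int, np.ndarray, float]] = field(default_factory=dict)
    separation_biases: dict[int, dict] = field(default_factory=dict)
    hills: dict[int, dict] = field(default_factory=dict)
    improper_restraints: list[ImproperRestraint] = field(default_factory=list)
    _next_id: int = 0

    # -- bias management ---------------------------------------------------
    def _new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def add_point_restraint(self, atom: int, target, k: float) -> int:
        """Attach ``1/2 k |r_atom - target|^2``; returns a removal id."""
        if k <= 0:
            raise ValueError("force constant must be > 0")
        bid = self._new_id()
        self.point_restraints[bid] = (atom, np.asarray(target, dtype=float), float(k))
        return bid

    def add_separation_bias(
        self, group_a, group_b, masses, target: float = 10.0, k: float = 10.0,
        fallback_direction=None,
    ) -> int:
        """One-sided harmonic pushing two mass-weighted centers apart.

        Energy ``1/2 k (d - target)^2`` for center distance d < target, zero
        beyond — the bias pushes "up to" the target and never pulls back.
        ``fallback_direction`` disambiguates the gradient when the two
        centers coincide exactly (a measure-zero but constructible start).
        """
        group_a, group_b = tuple(group_a), tuple(group_b)
        if not group_a or not group_b:
            raise ValueError("separation-bias groups must be non-empty")
        if set(group_a) & set(group_b):
            raise ValueError("separation-bias groups must be disjoint")
        if k <= 0:
            raise ValueError("force constant must be > 0")
        bid = self._new_id()
        masses = np.asarray(masses, dtype=float)
        self.separation_biases[bid] = {
            "group_a": np.array(group_a, dtype=int),
            "group_b": np.array(group_b, dtype=int),
            "wa": masses[list(group_a)] / masses[list(group_a)].sum(),
            "wb": masses[list(group_b)] / masses[list(group_b)].sum(),
            "target": float(target),
            "k": float(k),
            "fallback": None if fallback_direction is None
            else np.asarray(fallback_direction, dtype=float),
        }
        return bid

    def add_density_hill(
        self, center, radius: float, height: float, exempt=()
    ) -> int:
        """Gaussian repulsive hill ``h * exp(-|r-c|^2 / (2 (radius/2)^2))``."""
        if radius <= 0 or height <= 0:
            raise ValueError("hill radius and height must be > 0")
        bid = self._new_id()
        self.hills[bid] = {
            "center": np.asarray(center, dtype=float),
            "sigma": radius / 2.0,
            "height": float(height),
            "exempt": frozenset(exempt),
        }
        return bid

    def remove_bias(self, bid: int) -> None:
        for table in (self.point_restraints, self.separation_biases, self.hills):
            if bid in table:
                del table[bid]
                return
        raise KeyError(f"no bias with id {bid}")

    def clear_all_biases(self) -> None:
        """Remove every point/separation/hill term; chirality impropers stay."""
        self.point_restraints.clear()
        self.separation_biases.clear()
        self.hills.clear()


@dataclass
class MinimizationResult:
    """Outcome of one bounded minimization."""

    system: MolecularSystem          # copy carrying the final coordinates
    energies: list[float]            # accepted-step energy trace (incl. start)
    termination: str                 # "budget" | "gradient_tolerance"
    steps_taken: int


# --------------------------------------------------------------------------
# evaluator
# --------------------------------------------------------------------------

class EnergyEvaluator:
    """Precompiled term tables for repeated evaluation on one topology.

    Building the pair list and parameter arrays once makes stage-by-stage
    minimization cheap; biases and the flagged set are read at call time so
    the repair loop can rewire them without recompiling.
    """

    def __init__(self, system: MolecularSystem, params: ParameterSet,
                 model: EnergyModel):
        self.system = system
        self.model = model
        self.n = system.n_atoms
        types = system.types
        self.masses = system.masses

        # bonded term arrays
        self.bond_idx = np.array(system.bonds, dtype=int).reshape(-1, 2)
        bp = [params.bond_param(types[i], types[j]) for i, j in system.bonds]
        self.bond_k = np.array([p[0] for p in bp])
        self.bond_b0 = np.array([p[1] for p in bp])

        self.angle_idx = np.array(system.angles, dtype=int).reshape(-1, 3)
        ap = [params.angle_param(types[i], types[j], types[k])
              for i, j, k in system.angles]
        self.angle_k = np.array([p[0] for p in ap])
        self.angle_t0 = np.radians([p[1] for p in ap])

        dih_idx, dih_k, dih_n, dih_d = [], [], [], []
        for quad in system.dihedrals:
            terms = params.dihedral_param(*(types[a] for a in quad))
            for kphi, n, delta in terms:
                dih_idx.append(quad)
                dih_k.append(kphi)
                dih_n.append(n)
                dih_d.append(np.radians(delta))
        self.dih_idx = np.array(dih_idx, dtype=int).reshape(-1, 4)
        self.dih_k = np.array(dih_k)
        self.dih_n = np.array(dih_n, dtype=float)
        self.dih_d = np.array(dih_d)

        self.imp_idx = np.array(system.impropers, dtype=int).reshape(-1, 4)
        ip = [params.improper_param(*(types[a] for a in system.impropers[m]))
              for m in range(len(system.impropers))]
        self.imp_k = np.array([p[0] for p in ip])
        self.imp_psi0 = np.radians([p[1] for p in ip])

        # nonbonded pair list: all i<j minus bond-graph distance <= 2
        excluded = set()
        adjacency: dict[int, set[int]] = {i: set() for i in range(self.n)}
        for i, j in system.bonds:
            adjacency[i].add(j)
            adjacency[j].add(i)
            excluded.add((min(i, j), max(i, j)))
        for j in range(self.n):
            for i, k in itertools.combinations(sorted(adjacency[j]), 2):
                excluded.add((i, k))
        pairs = [
            (i, j)
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if (i, j) not in excluded
        ]
        self.pair_i = np.array([p[0] for p in pairs], dtype=int)
        self.pair_j = np.array([p[1] for p in pairs], dtype=int)
        eps = np.array([params.nonbonded_param(t)[0] for t in types])
        rmin2 = np.array([params.nonbonded_param(t)[1] for t in types])
        self.pair_eps = np.sqrt(eps[self.pair_i] * eps[self.pair_j])
        self.pair_rmin = rmin2[self.pair_i] + rmin2[self.pair_j]
        q = system.charges
        self.pair_qq = (
            COULOMB_CONST * q[self.pair_i] * q[self.pair_j] / model.dielectric
        )

    # -- switching function ------------------------------------------------
    def _switch(self, r: np.ndarray):
        ron, roff = self.model.switch_on, self.model.cutoff
        ron2, roff2 = ron * ron, roff * roff
        denom = (roff2 - ron2) ** 3
        s = np.ones_like(r)
        ds = np.zeros_like(r)
        mid = (r > ron) & (r < roff)
        rm = r[mid]
        rm2 = rm * rm
        s[mid] = (roff2 - rm2) ** 2 * (roff2 + 2 * rm2 - 3 * ron2) / denom
        ds[mid] = 12.0 * rm * (roff2 - rm2) * (ron2 - rm2) / denom
        s[r >= roff] = 0.0
        return s, ds

    # -- main evaluation ---------------------------------------------------
    def energy_forces(self, coords: np.ndarray, flagged=frozenset(),
                      with_forces: bool = True, check: bool = True):
        """Total energy (kcal/mol) and per-atom forces (kcal/mol/A).

        With ``check`` (the default) a non-finite total raises
        :class:`EnergyError` naming the worst pair; line searches pass
        ``check=False`` and treat non-finite trials as rejected steps.
        """
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            return self._energy_forces(coords, flagged, with_forces, check)

    def _energy_forces(self, coords, flagged, with_forces, check):
        x = np.asarray(coords, dtype=float).reshape(self.n, 3)
        m = self.model
        energy = 0.0
        forces = np.zeros_like(x) if with_forces else None

        def add_force(idx, f):
            if with_forces:
                np.add.at(forces, idx, f)

        # bonds: k (b - b0)^2
        if m.use_bonds and len(self.bond_idx):
            rij = x[self.bond_idx[:, 0]] - x[self.bond_idx[:, 1]]
            b = np.linalg.norm(rij, axis=1)
            db = b - self.bond_b0
            energy += float(np.sum(self.bond_k * db * db))
            if with_forces:
                coef = (2.0 * self.bond_k * db / np.maximum(b, 1e-12))[:, None]
                add_force(self.bond_idx[:, 0], -coef * rij)
                add_force(self.bond_idx[:, 1], coef * rij)

        # angles: k (theta - theta0)^2
        if m.use_angles and len(self.angle_idx):
            i, j, k = self.angle_idx.T
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos = np.sum(u * v, axis=1) / (nu * nv)
            cos = np.clip(cos, -1.0, 1.0)
            theta = np.arccos(cos)
            dt = theta - self.angle_t0
            energy += float(np.sum(self.angle_k * dt * dt))
            if with_forces:
                sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-12))
                dEdt = 2.0 * self.angle_k * dt
                # d(theta)/dri and /drk
                gi = -(v / (nu * nv)[:, None] - (cos / nu**2)[:, None] * u) / sin[:, None]
                gk = -(u / (nu * nv)[:, None] - (cos / nv**2)[:, None] * v) / sin[:, None]
                add_force(i, -dEdt[:, None] * gi)
                add_force(k, -dEdt[:, None] * gk)
                add_force(j, dEdt[:, None] * (gi + gk))

        # proper dihedrals: k (1 + cos(n phi - delta))
        if m.use_dihedrals and len(self.dih_idx):
            phi, grads = _dihedral_phi_grad(x, self.dih_idx, with_forces)
            energy += float(np.sum(self.dih_k * (1.0 + np.cos(self.dih_n * phi - self.dih_d))))
            if with_forces:
                dEdphi = -self.dih_k * self.dih_n * np.sin(self.dih_n * phi - self.dih_d)
                for col, g in enumerate(grads):
                    add_force(self.dih_idx[:, col], -dEdphi[:, None] * g)

        # impropers: harmonic k (psi - psi0)^2
        if m.use_impropers and len(self.imp_idx):
            phi, grads = _dihedral_phi_grad(x, self.imp_idx, with_forces)
            dpsi = _wrap_angle(phi - self.imp_psi0)
            energy += float(np.sum(self.imp_k * dpsi * dpsi))
            if with_forces:
                dEdphi = 2.0 * self.imp_k * dpsi
                for col, g in enumerate(grads):
                    add_force(self.imp_idx[:, col], -dEdphi[:, None] * g)

        # chirality restraints (harmonic impropers attached to the model)
        if m.improper_restraints:
            quads = np.array([r.atoms for r in m.improper_restraints], dtype=int)
            ks = np.array([r.k for r in m.improper_restraints])
            targets = np.array([r.target for r in m.improper_restraints])
            phi, grads = _dihedral_phi_grad(x, quads, with_forces)
            dpsi = _wrap_angle(phi - targets)
            energy += float(np.sum(ks * dpsi * dpsi))
            if with_forces:
                dEdphi = 2.0 * ks * dpsi
                for col, g in enumerate(grads):
                    add_force(quads[:, col], -dEdphi[:, None] * g)

        # nonbonded: switched 12-6 LJ + screened Coulomb, soft-core on flags
        if (m.use_lj or m.use_coulomb) and len(self.pair_i):
            rij = x[self.pair_i] - x[self.pair_j]
            r2 = np.sum(rij * rij, axis=1)
            r = np.sqrt(r2)
            within = r < m.cutoff
            if np.any(within):
                idx = np.nonzero(within)[0]
                rw = r[idx]
                if flagged:
                    fmask = np.zeros(self.n, dtype=bool)
                    fmask[list(flagged)] = True
                    soft = fmask[self.pair_i[idx]] | fmask[self.pair_j[idx]]
                else:
                    soft = np.zeros(len(idx), dtype=bool)
                rho = rw.copy()
                if np.any(soft):
                    rho[soft] = np.sqrt(rw[soft] ** 2 + m.softcore_delta**2)
                s, ds = self._switch(rw)
                v = np.zeros_like(rw)
                dvdrho = np.zeros_like(rw)
                if m.use_lj:
                    ratio6 = (self.pair_rmin[idx] / rho) ** 6
                    vlj = self.pair_eps[idx] * (ratio6 * ratio6 - 2.0 * ratio6)
                    v += vlj
                    dvdrho += -12.0 * self.pair_eps[idx] * (ratio6 * ratio6 - ratio6) / rho
                if m.use_coulomb:
                    vel = self.pair_qq[idx] / rho
                    v += vel
                    dvdrho += -vel / rho
                energy += float(np.sum(s * v))
                if with_forces:
                    dEdr = ds * v + s * dvdrho * (rw / rho)
                    coef = (dEdr / np.maximum(rw, 1e-12))[:, None]
                    add_force(self.pair_i[idx], -coef * rij[idx])
                    add_force(self.pair_j[idx], coef * rij[idx])

        # point restraints: 1/2 k |r - target|^2
        for atom, target, k in m.point_restraints.values():
            d = x[atom] - target
            energy += 0.5 * k * float(np.dot(d, d))
            if with_forces:
                forces[atom] -= k * d

        # one-sided center-of-mass separation biases
        for bias in m.separation_biases.values():
            ca = bias["wa"] @ x[bias["group_a"]]
            cb = bias["wb"] @ x[bias["group_b"]]
            dvec = ca - cb
            d = float(np.linalg.norm(dvec))
            if d >= bias["target"]:
                continue
            energy += 0.5 * bias["k"] * (d - bias["target"]) ** 2
            if with_forces:
                if d > 1e-6:
                    unit = dvec / d
                elif bias["fallback"] is not None:
                    unit = bias["fallback"]
                else:
                    unit = np.array([1.0, 0.0, 0.0])
                g = bias["k"] * (d - bias["target"]) * unit  # dE/d(ca)
                forces[bias["group_a"]] -= bias["wa"][:, None] * g
                forces[bias["group_b"]] += bias["wb"][:, None] * g

        # Gaussian repulsive density hills
        for hill in m.hills.values():
            sel = np.array(
                [a for a in range(self.n) if a not in hill["exempt"]], dtype=int
            )
            dr = x[sel] - hill["center"]
            d2 = np.sum(dr * dr, axis=1)
            e = hill["height"] * np.exp(-d2 / (2.0 * hill["sigma"] ** 2))
            energy += float(np.sum(e))
            if with_forces:
                np.add.at(forces, sel, (e / hill["sigma"] ** 2)[:, None] * dr)

        if check and not np.isfinite(energy):
            raise EnergyError(self._diagnose_nonfinite(x, flagged))
        return energy, forces

    def _diagnose_nonfinite(self, x, flagged):
        rij = x[self.pair_i] - x[self.pair_j]
        r = np.linalg.norm(rij, axis=1)
        worst = int(np.argmin(r))
        return (
            "non-finite energy; worst nonbonded pair "
            f"({int(self.pair_i[worst])}, {int(self.pair_j[worst])}) at "
            f"r = {r[worst]:.2e} A"
            + ("" if flagged else " — consider a soft-core (flagged) stage")
        )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return a - 2.0 * np.pi * np.round(a / (2.0 * np.pi))


def _dihedral_phi_grad(x: np.ndarray, idx: np.ndarray, with_grads: bool):
    """Vectorized dihedral angles and (optionally) analytic gradients.

    Returns ``phi`` of shape (m,) and, when requested, a list of four
    (m, 3) arrays: d(phi)/dr for each of the quadruple's atoms.
    """
    p0, p1, p2, p3 = (x[idx[:, c]] for c in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    mvec = np.cross(b1, b2)
    nvec = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    nb2 = np.maximum(nb2, 1e-12)
    xcomp = np.sum(mvec * nvec, axis=1)
    ycomp = np.sum(np.cross(mvec, nvec) * (b2 / nb2[:, None]), axis=1)
    phi = np.arctan2(ycomp, xcomp)
    if not with_grads:
        return phi, None
    m2 = np.maximum(np.sum(mvec * mvec, axis=1), 1e-12)
    n2 = np.maximum(np.sum(nvec * nvec, axis=1), 1e-12)
    g0 = -(nb2 / m2)[:, None] * mvec
    g3 = (nb2 / n2)[:, None] * nvec
    c12 = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
    c32 = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = c12 * g0 - (1.0 + c32) * g3
    return phi, [g0, g1, g2, g3]


# --------------------------------------------------------------------------
# public helpers
# --------------------------------------------------------------------------

def compute_energy_forces(
    system: MolecularSystem,
    params: ParameterSet,
    model: EnergyModel,
    flagged=frozenset(),
):
    """One-shot energy and forces for *system* under *model*."""
    ev = EnergyEvaluator(system, params, model)
    return ev.energy_forces(system.coords, flagged=flagged)


def minimize(
    system: MolecularSystem,
    params: ParameterSet,
    model: EnergyModel,
    steps: int,
    flagged=frozenset(),
    gtol: float = 1e-4,
    evaluator: EnergyEvaluator | None = None,
    max_displacement: float = 0.2,
) -> MinimizationResult:
    """Deterministic conjugate-gradient minimization with a step budget.

    Polak-Ribiere(+) directions with an Armijo backtracking line search; the
    first trial step is capped so no atom moves more than
    ``max_displacement`` Angstrom at once.  The energy trace over accepted
    steps is non-increasing.  The input system is not mutated; the result
    carries a coordinate-updated copy.
    """
    if steps < 1:
        raise ValueError("step budget must be >= 1")
    if system.coords is None:
        raise ValueError("system has no coordinates")
    ev = evaluator or EnergyEvaluator(system, params, model)
    flagged = frozenset(flagged)
    x = system.coords.copy()

    energy, forces = ev.energy_forces(x, flagged=flagged)
    if not np.isfinite(energy):
        raise EnergyError("non-finite energy at entry")
    grad = -forces
    direction = forces.copy()
    energies = [energy]
    alpha_prev = None
    termination = "budget"
    steps_taken = 0

    for _ in range(steps):
        gmax = float(np.max(np.abs(grad)))
        if gmax < gtol:
            termination = "gradient_tolerance"
            break
        dmax = float(np.max(np.abs(direction)))
        if dmax <= 0:
            termination = "gradient_tolerance"
            break
        alpha_cap = max_displacement / dmax
        alpha = min(alpha_prev * 2.0, alpha_cap) if alpha_prev else alpha_cap
        gd = float(np.sum(grad * direction))  # directional derivative (< 0 wanted)
        if gd >= 0:
            direction = forces.copy()
            gd = -float(np.sum(grad * grad))
            dmax = float(np.max(np.abs(direction)))
            alpha = max_displacement / max(dmax, 1e-12)

        accepted = False
        for _bt in range(30):
            e_trial, _ = ev.energy_forces(x + alpha * direction, flagged=flagged,
                                          with_forces=False, check=False)
            if np.isfinite(e_trial) and e_trial <= energy + 1e-4 * alpha * gd:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # no descent along CG direction: one steepest-descent rescue
            direction = forces.copy()
            gd = -float(np.sum(grad * grad))
            alpha = max_displacement / max(float(np.max(np.abs(direction))), 1e-12)
            for _bt in range(30):
                e_trial, _ = ev.energy_forces(x + alpha * direction, flagged=flagged,
                                              with_forces=False, check=False)
                if np.isfinite(e_trial) and e_trial <= energy + 1e-4 * alpha * gd:
                    accepted = True
                    break
                alpha *= 0.5
        if not accepted:
            termination = "gradient_tolerance"  # stalled at numerical floor
            break

        x = x + alpha * direction
        steps_taken += 1
        alpha_prev = alpha
        e_new, f_new = ev.energy_forces(x, flagged=flagged)
        g_new = -f_new
        beta = max(
            0.0,
            float(np.sum(g_new * (g_new - grad)) / max(np.sum(grad * grad), 1e-300)),
        )
        direction = f_new + beta * direction
        grad = g_new
        forces = f_new
        energy = e_new
        energies.append(energy)

    out = system.copy()
    out.coords = x
    return MinimizationResult(
        system=out, energies=energies, termination=termination,
        steps_taken=steps_taken,
    )
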