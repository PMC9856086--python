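"""Energy model correctness: closed forms, exact gradients, minimizer."""

import numpy as np
import pytest

from ringfree.charmm_io import Atom, MolecularSystem, parse_parameter_text
from ringfree.energy_min import (
    EnergyEvaluator,
    EnergyModel,
    compute_energy_forces,
    minimize,
)
from ringfree.errors import EnergyError
from ringfree.pierce_oracle import ImproperRestraint


def _pair_system(r, eps=0.1, rmin2=2.0, q=0.0, bond=False, kb=300.0, b0=1.5):
    prm = (
        f"BONDS\nCT CT {kb} {b0}\n"
        f"NONBONDED\nCT 0.0 -{eps} {rmin2}\nEND\n"
    )
    params = parse_parameter_text(prm)
    atoms = [Atom(i, f"C{i}", "TOY", 1, "T", "CT", q, 12.011) for i in range(2)]
    system = MolecularSystem(
        atoms=atoms,
        bonds=[(0, 1)] if bond else [],
        coords=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
    )
    return system, params


def _numeric_forces(ev, x, flagged=frozenset(), h=1e-5):
    num = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            ep, _ = ev.energy_forces(xp, flagged=flagged, with_forces=False)
            em, _ = ev.energy_forces(xm, flagged=flagged, with_forces=False)
            num[i, d] = -(ep - em) / (2 * h)
    return num


class TestClosedForms:
    def test_lj_minimum_energy_is_minus_epsilon(self):
        system, params = _pair_system(r=4.0, eps=0.1, rmin2=2.0)
        model = EnergyModel(use_coulomb=False)
        energy, _ = compute_energy_forces(system, params, model)
        assert energy == pytest.approx(-0.1, rel=1e-10)

    def test_softcore_energy_at_contact_equals_value_at_delta(self):
        system, params = _pair_system(r=0.0, eps=0.1, rmin2=2.0)
        delta = 2.5
        model = EnergyModel(use_coulomb=False, softcore_delta=delta)
        energy, _ = compute_energy_forces(system, params, model, flagged={0, 1})
        ref_system, _ = _pair_system(r=delta, eps=0.1, rmin2=2.0)
        ref, _ = compute_energy_forces(ref_system, params, model)
        assert np.isfinite(energy)
        assert energy == pytest.approx(ref, rel=1e-10)

    def test_overlap_without_softcore_raises_and_advises(self):
        system, params = _pair_system(r=0.0)
        with pytest.raises(EnergyError, match="soft-core"):
            compute_energy_forces(system, params, EnergyModel(use_coulomb=False))

    def test_softcore_converges_to_standard_as_delta_vanishes(self):
        system, params = _pair_system(r=4.2, eps=0.1, rmin2=2.0)
        plain, _ = compute_energy_forces(system, params,
                                         EnergyModel(use_coulomb=False))
        errors = []
        for delta in (1.0, 0.1, 0.01):
            model = EnergyModel(use_coulomb=False, softcore_delta=delta)
            soft, _ = compute_energy_forces(system, params, model,
                                            flagged={0, 1})
            errors.append(abs(soft - plain))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-4

    def test_switching_zeroes_nonbonded_beyond_cutoff(self):
        system, params = _pair_system(r=12.5, eps=0.5, rmin2=3.0, q=0.5)
        energy, _ = compute_energy_forces(system, params, EnergyModel())
        assert energy == 0.0


class TestGradients:
    def test_all_terms_match_central_differences(self, glyco_bundle):
        """Analytic forces equal the negative numerical gradient to 1e-4
        relative on a realistic system with every term and bias active."""
        system = glyco_bundle.system
        model = EnergyModel()
        model.add_point_restraint(5, (3.0, -1.0, 2.0), 12.0)
        model.add_separation_bias((12, 13), (0, 1, 2, 3), system.masses,
                                  target=10.0, k=10.0)
        model.add_density_hill(system.coords.mean(axis=0), radius=4.0,
                               height=20.0, exempt=(12, 13))
        model.improper_restraints = [
            ImproperRestraint(atoms=(0, 3, 5, 8), k=50.0, target=0.4)
        ]
        ev = EnergyEvaluator(system, glyco_bundle.params, model)
        flagged = frozenset({10, 11, 12, 13})
        _, forces = ev.energy_forces(system.coords, flagged=flagged)
        numeric = _numeric_forces(ev, system.coords.copy(), flagged=flagged)
        scale = np.abs(numeric).max()
        assert np.abs(forces - numeric).max() / scale < 1e-4

    def test_unbiased_energy_is_rigid_motion_invariant(self, benzene_bundle):
        from ringfree.fixtures import _axis_angle_rotation

        system = benzene_bundle.system.copy()
        model = EnergyModel()
        e0, _ = compute_energy_forces(system, benzene_bundle.params, model)
        rot = _axis_angle_rotation((0.3, -0.5, 0.81), 1.1)
        system.coords = system.coords @ rot.T + np.array([3.0, -7.0, 11.0])
        e1, _ = compute_energy_forces(system, benzene_bundle.params, model)
        assert e1 == pytest.approx(e0, rel=1e-9)


class TestBiasTerms:
    def test_point_restraint_minimizes_to_target(self):
        system, params = _pair_system(r=40.0)  # far apart: no interaction
        model = EnergyModel(use_lj=False, use_coulomb=False)
        model.add_point_restraint(0, (5.0, 0.0, 0.0), 10.0)
        res = minimize(system, params, model, steps=500)
        assert np.allclose(res.system.coords[0], (5.0, 0.0, 0.0), atol=1e-3)

    def test_point_restraint_energy_linear_in_k(self):
        system, params = _pair_system(r=40.0)
        for k, expected in ((10.0, 0.5 * 10 * 4.0), (20.0, 0.5 * 20 * 4.0)):
            model = EnergyModel(use_lj=False, use_coulomb=False)
            model.add_point_restraint(0, (2.0, 0.0, 0.0), k)
            energy, _ = compute_energy_forces(system, params, model)
            assert energy == pytest.approx(expected)

    def test_separation_bias_zero_at_target_distance(self):
        system, params = _pair_system(r=10.0)
        model = EnergyModel(use_lj=False, use_coulomb=False)
        model.add_separation_bias((0,), (1,), system.masses, target=10.0, k=10.0)
        energy, _ = compute_energy_forces(system, params, model)
        assert energy == 0.0

    def test_separation_bias_arithmetic(self):
        system, params = _pair_system(r=4.0)
        model = EnergyModel(use_lj=False, use_coulomb=False)
        model.add_separation_bias((0,), (1,), system.masses, target=10.0, k=10.0)
        energy, _ = compute_energy_forces(system, params, model)
        assert energy == pytest.approx(0.5 * 10 * 36.0)

    def test_separation_bias_drives_groups_to_target(self):
        system, params = _pair_system(r=4.0)
        model = EnergyModel(use_lj=False, use_coulomb=False)
        model.add_separation_bias((0,), (1,), system.masses, target=10.0, k=10.0)
        res = minimize(system, params, model, steps=500)
        d = np.linalg.norm(res.system.coords[0] - res.system.coords[1])
        assert d == pytest.approx(10.0, abs=1e-3)

    def test_separation_bias_rejects_overlapping_groups(self):
        system, params = _pair_system(r=4.0)
        model = EnergyModel()
        with pytest.raises(ValueError):
            model.add_separation_bias((0, 1), (1,), system.masses)

    def test_hill_peak_tail_and_exemption(self):
        system, params = _pair_system(r=50.0)
        model = EnergyModel(use_lj=False, use_coulomb=False)
        model.add_density_hill((0.0, 0.0, 0.0), radius=4.0, height=20.0,
                               exempt=(1,))
        energy, _ = compute_energy_forces(system, params, model)
        assert energy == pytest.approx(20.0)  # atom 0 at the peak; 1 exempt
        model2 = EnergyModel(use_lj=False, use_coulomb=False)
        model2.add_density_hill((200.0, 0.0, 0.0), radius=4.0, height=20.0)
        tail, _ = compute_energy_forces(system, params, model2)
        assert tail < 1e-6

    def test_biases_removable_by_id(self):
        model = EnergyModel()
        bid = model.add_point_restraint(0, (0, 0, 0), 5.0)
        model.remove_bias(bid)
        assert model.point_restraints == {}
        with pytest.raises(KeyError):
            model.remove_bias(bid)


class TestMinimizer:
    def test_bonded_pair_relaxes_to_equilibrium(self):
        system, params = _pair_system(r=2.0, bond=True, kb=300.0, b0=1.5)
        model = EnergyModel(use_lj=False, use_coulomb=False)
        res = minimize(system, params, model, steps=500)
        length = np.linalg.norm(res.system.coords[1] - res.system.coords[0])
        assert length == pytest.approx(1.5, abs=1e-3)

    def test_zero_step_budget_rejected(self):
        system, params = _pair_system(r=2.0, bond=True)
        with pytest.raises(ValueError):
            minimize(system, params, EnergyModel(), steps=0)

    def test_energy_trace_non_increasing(self, benzene_plain_min):
        trace = benzene_plain_min.energies
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_deterministic_given_identical_inputs(self, benzene_bundle):
        model = EnergyModel()
        a = minimize(benzene_bundle.system, benzene_bundle.params, model, steps=50)
        b = minimize(benzene_bundle.system, benzene_bundle.params, model, steps=50)
        assert np.array_equal(a.system.coords, b.system.coords)
        assert a.energies == b.energies

    def test_input_system_not_mutated(self, benzene_bundle):
        before = benzene_bundle.system.coords.copy()
        minimize(benzene_bundle.system, benzene_bundle.params, EnergyModel(),
                 steps=20)
        assert np.array_equal(benzene_bundle.system.coords, before)

    def test_pierced_fixture_is_a_local_minimum_with_a_long_bond(
        self, benzene_plain_min, benzene_bundle
    ):
        """Plain minimization cannot unthread the ring: the threaded C-C
        stays stretched far beyond the 0.4 A convergence cutoff."""
        from ringfree.pierce_oracle import find_piercings
        from ringfree.stretch_detect import bond_deviations, largest_deviation

        report = bond_deviations(benzene_plain_min.system, benzene_bundle.params)
        rec, dev = largest_deviation(report)
        assert rec.bond == (12, 13)
        assert dev >= 0.4
        assert len(find_piercings(benzene_plain_min.system)) == 1
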