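"""Geometric piercing detection and chirality measurement."""

import numpy as np
import pytest

from ringfree.errors import GeometryError
from ringfree.pierce_oracle import (
    chirality_sign,
    detect_chiral_centers,
    find_piercings,
    generate_chirality_restraints,
    measure_improper,
    segment_triangle_intersect,
    write_restraints,
)


def _moller_trumbore(p0, p1, t0, t1, t2, eps=1e-9):
    """Independent oracle: Moller-Trumbore ray-triangle intersection,
    restricted to the segment parameter range."""
    d = p1 - p0
    e1, e2 = t1 - t0, t2 - t0
    pvec = np.cross(d, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) < 1e-14:
        return False
    inv = 1.0 / det
    tvec = p0 - t0
    u = float(np.dot(tvec, pvec)) * inv
    if u < -eps or u > 1 + eps:
        return False
    qvec = np.cross(tvec, e1)
    v = float(np.dot(d, qvec)) * inv
    if v < -eps or u + v > 1 + eps:
        return False
    s = float(np.dot(e2, qvec)) * inv
    return -eps <= s <= 1 + eps


class TestSegmentTriangle:
    def test_segment_through_triangle_interior(self):
        hit, point = segment_triangle_intersect(
            (0, 0, -1), (0, 0, 1), (2, 0, 0), (-1, 1.5, 0), (-1, -1.5, 0)
        )
        assert hit
        assert np.allclose(point, (0, 0, 0), atol=1e-12)

    def test_segment_entirely_on_one_side(self):
        hit, _ = segment_triangle_intersect(
            (0, 0, 1.5), (0, 0, 3.0), (2, 0, 0), (-1, 1.5, 0), (-1, -1.5, 0)
        )
        assert not hit

    def test_degenerate_triangle_is_an_error(self):
        with pytest.raises(GeometryError):
            segment_triangle_intersect(
                (0, 0, -1), (0, 0, 1), (0, 0, 0), (1, 0, 0), (2, 0, 0)
            )

    def test_agrees_with_independent_oracle_on_random_cases(self, rng):
        agree = 0
        trials = 10_000
        for _ in range(trials):
            pts = rng.uniform(-2, 2, size=(5, 3))
            p0, p1, t0, t1, t2 = pts
            if np.linalg.norm(np.cross(t1 - t0, t2 - t0)) / 2 <= 1e-8:
                agree += 1
                continue
            ours, _ = segment_triangle_intersect(p0, p1, t0, t1, t2)
            agree += ours == _moller_trumbore(p0, p1, t0, t1, t2)
        assert agree == trials

    def test_fan_is_watertight_across_shared_edges(self, rng):
        """A segment crossing a fan-triangulated hexagon registers on at
        least one triangle even when it passes exactly over a shared edge."""
        hexagon = np.array(
            [[np.cos(a), np.sin(a), 0.0]
             for a in np.radians(np.arange(0, 360, 60))]
        )
        centroid = hexagon.mean(axis=0)
        for k in range(6):
            # cross exactly over the centroid-to-vertex spoke
            target = 0.5 * (centroid + hexagon[k])
            p0 = target + (0, 0, 1.0)
            p1 = target - (0, 0, 1.0)
            hits = 0
            for t in range(6):
                hit, _ = segment_triangle_intersect(
                    p0, p1, centroid, hexagon[t], hexagon[(t + 1) % 6]
                )
                hits += hit
            assert hits >= 1


class TestFindPiercings:
    def test_benzene_ethane_fixture_reports_the_threaded_bond(self, benzene_bundle):
        events = find_piercings(benzene_bundle.system)
        assert len(events) == 1
        assert events[0].bond == (12, 13)
        assert events[0].ring.size == 6

    def test_polymer_fixture_reports_three_events(self, polymer_bundle):
        assert len(find_piercings(polymer_bundle.system)) == 3

    def test_clean_fixture_reports_none(self, clean_bundle):
        assert find_piercings(clean_bundle.system) == []

    def test_resolved_fixture_reports_none(self, benzene_run):
        assert find_piercings(benzene_run.system) == []

    def test_invariant_under_rigid_motion(self, benzene_bundle, rng):
        from ringfree.fixtures import _axis_angle_rotation

        system = benzene_bundle.system.copy()
        rot = _axis_angle_rotation(rng.normal(size=3), 1.234)
        system.coords = system.coords @ rot.T + np.array([5.0, -3.0, 2.0])
        events = find_piercings(system)
        assert len(events) == 1 and events[0].bond == (12, 13)

    def test_bonds_sharing_a_ring_atom_are_skipped(self, benzene_bundle):
        for ev in find_piercings(benzene_bundle.system):
            assert not (set(ev.bond) & set(ev.ring.atoms))


class TestChirality:
    def test_sign_of_reference_tetrahedron(self):
        # det[(-1,1,0), (-1,0,1), (-2,-1,-1)] = -4 < 0
        subs = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, -1, -1)]
        assert chirality_sign(subs) == -1

    def test_mirror_image_flips_sign(self):
        subs = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, -1, -1)], float)
        mirrored = subs * np.array([-1, 1, 1])
        assert chirality_sign(mirrored) == -chirality_sign(subs)

    def test_sign_invariant_under_rotation(self, rng):
        from ringfree.fixtures import _axis_angle_rotation

        subs = rng.normal(size=(4, 3))
        rot = _axis_angle_rotation(rng.normal(size=3), 0.77)
        assert chirality_sign(subs @ rot.T) == chirality_sign(subs)

    def test_coplanar_substituents_are_an_error(self):
        with pytest.raises(GeometryError):
            chirality_sign([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])

    def test_methane_like_center_not_returned(self):
        from ringfree.charmm_io import Atom, MolecularSystem

        atoms = [Atom(0, "C", "MET", 1, "M", "CT", 0.0, 12.011)] + [
            Atom(i, f"H{i}", "MET", 1, "M", "HT", 0.0, 1.008) for i in range(1, 5)
        ]
        coords = np.array(
            [[0, 0, 0], [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
        )
        system = MolecularSystem(atoms=atoms, bonds=[(0, i) for i in range(1, 5)],
                                 coords=coords)
        assert detect_chiral_centers(system) == []

    def test_glyco_toy_centers_detected(self, glyco_bundle):
        centers = detect_chiral_centers(glyco_bundle.system)
        assert len(centers) >= 6
        # alpha-carbons (N, C=O, side chain, H) are among them
        names = {glyco_bundle.system.atoms[c.center].name for c in centers}
        assert "CA" in names and "C1" in names

    def test_mirror_image_flips_every_center(self, glyco_bundle):
        system = glyco_bundle.system.copy()
        before = detect_chiral_centers(system)
        system.coords = system.coords * np.array([-1.0, 1.0, 1.0])
        after = {c.center: c.sign for c in detect_chiral_centers(system)}
        assert len(after) == len(before)
        for c in before:
            assert after[c.center] == -c.sign


class TestRestraints:
    def test_no_centers_no_restraints(self, benzene_bundle):
        assert generate_chirality_restraints([], benzene_bundle.system) == []

    def test_one_restraint_per_detected_center(self, glyco_bundle):
        centers = detect_chiral_centers(glyco_bundle.system)
        restraints = generate_chirality_restraints(centers, glyco_bundle.system)
        assert len(restraints) == len(centers)
        for r, c in zip(restraints, centers):
            assert set(r.atoms) == set(c.substituents)
            measured = measure_improper(glyco_bundle.system.coords, r.atoms)
            assert r.target == pytest.approx(measured)

    def test_restraint_file_format(self, glyco_bundle, tmp_path):
        centers = detect_chiral_centers(glyco_bundle.system)
        restraints = generate_chirality_restraints(centers, glyco_bundle.system,
                                                   k=50.0)
        path = tmp_path / "extra.txt"
        write_restraints(restraints, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(restraints)
        fields = lines[0].split()
        assert len(fields) == 6  # 4 indices, k, target in degrees

    def test_restrained_repair_preserves_signs_unrestrained_does_not(
        self, strained_glyco_bundle, strained_run_restrained,
        strained_run_unrestrained
    ):
        """Paired runs on the deliberately strained glyco variant: the
        restraints are load-bearing for stereochemistry."""
        centers = detect_chiral_centers(strained_glyco_bundle.system)

        def flips(result):
            return sum(
                1 for c in centers
                if chirality_sign(result.system.coords[list(c.substituents)])
                != c.sign
            )

        assert flips(strained_run_restrained) == 0
        assert flips(strained_run_unrestrained) >= 1
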