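"""SASA, complementarity, leaflet spacing, RMSD and B-factor summaries."""

import math

import numpy as np
import pytest

from memraft.geometry import kabsch
from memraft.io_core import Selection
from memraft.surfaces import (
    SasaParams,
    bfactor_summary,
    ca_rmsd,
    contact_area,
    leaflet_spacing,
    sasa,
    sasa_structure,
)
from memraft.synthetic import gen_sphere_cluster

from conftest import monte_carlo_sasa, toy_structure, two_sphere_sasa

PROBE = 0.14


class TestSasa:
    def test_single_sphere_closed_form(self):
        a = sasa(np.zeros((1, 3)), np.array([0.2]))
        assert a.sum() == pytest.approx(4 * math.pi * 0.34 ** 2, rel=0.005)

    def test_far_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        radii = np.array([0.2, 0.3])
        a = sasa(coords, radii)
        iso = 4 * math.pi * (radii + PROBE) ** 2
        np.testing.assert_allclose(a, iso, rtol=0.005)

    def test_two_overlapping_spheres_cap_formula(self):
        """Overlap burial matches the spherical-cap closed form."""
        r1, r2, d = 0.2, 0.25, 0.45
        a = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([r1, r2]))
        exp1, exp2 = two_sphere_sasa(r1, r2, d, PROBE)
        assert a[0] == pytest.approx(exp1, rel=0.02)
        assert a[1] == pytest.approx(exp2, rel=0.02)

    def test_random_cluster_vs_monte_carlo_oracle(self, rng):
        coords = rng.uniform(0, 1.2, size=(20, 3))
        radii = rng.uniform(0.12, 0.25, size=20)
        mine = sasa(coords, radii)
        oracle = monte_carlo_sasa(coords, radii, PROBE, 20_000, rng)
        assert abs(mine.sum() - oracle.sum()) / oracle.sum() < 0.02

    def test_rotation_translation_invariance(self, rng):
        coords = rng.uniform(0, 1, size=(10, 3))
        radii = rng.uniform(0.15, 0.2, size=10)
        base = sasa(coords, radii).sum()
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=3).as_matrix()
        moved = sasa(coords @ R.T + np.array([3.0, -2.0, 7.0]), radii).sum()
        assert moved == pytest.approx(base, rel=0.01)

    def test_identical_overlapping_atoms_finite(self):
        a = sasa(np.zeros((2, 3)), np.array([0.2, 0.2]))
        assert np.all(np.isfinite(a))

    def test_monotone_burial_on_approach(self):
        totals = [
            sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([0.2, 0.2])).sum()
            for d in (1.0, 0.6, 0.4, 0.2, 0.05)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(totals, totals[1:]))

    def test_structure_radius_metadata_used(self):
        cluster = gen_sphere_cluster([0.2], [(0, 0, 0)])
        a = sasa_structure(cluster)
        assert a.sum() == pytest.approx(4 * math.pi * 0.34 ** 2, rel=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((2, 3)), np.array([0.2]))
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([-0.1]))
        with pytest.raises(ValueError):
            SasaParams(n_points=4)


def half_shell_cage(n=160, shell_r=0.5, atom_r=0.15):
    """A lipid sphere engulfed between two half-shells ('tetramers')."""
    idx = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    th = 2 * np.pi * idx / golden
    z = 1 - 2 * (idx + 0.5) / n
    r = np.sqrt(1 - z * z)
    shell = np.column_stack([r * np.cos(th), r * np.sin(th), z]) * shell_r
    coords = np.vstack([[0.0, 0, 0], shell])
    radii = np.concatenate([[0.2], np.full(n, atom_r)])
    upper = 1 + np.flatnonzero(shell[:, 2] >= 0)
    lower = 1 + np.flatnonzero(shell[:, 2] < 0)
    return coords, radii, np.array([0]), upper, lower


class TestComplementarity:
    def test_isolated_lipid_zero(self):
        coords, radii, lip, t1, t2 = half_shell_cage()
        coords = coords.copy()
        coords[0] = [30.0, 0, 0]
        res = contact_area(coords, radii, lip, t1, t2)
        assert res.ratio == pytest.approx(0.0, abs=1e-6)

    def test_engulfed_lipid_near_one(self):
        coords, radii, lip, t1, t2 = half_shell_cage()
        res = contact_area(coords, radii, lip, t1, t2)
        assert res.ratio >= 0.95
        assert res.ratio <= 1.0 + 1e-12

    def test_partial_contact_splits_between_tetramers(self):
        # lipid touching only tetramer 1
        coords = np.array([[0.0, 0, 0], [0.45, 0, 0], [5.0, 0, 0]])
        radii = np.array([0.2, 0.2, 0.2])
        res = contact_area(coords, radii, np.array([0]), np.array([1]),
                           np.array([2]))
        assert res.a_contact_1 > 0
        assert res.a_contact_2 == pytest.approx(0.0, abs=1e-6)
        _, exp = two_sphere_sasa(0.2, 0.2, 0.45, PROBE)
        buried = 4 * math.pi * 0.34 ** 2 - exp
        assert res.a_contact_1 == pytest.approx(buried, rel=0.05)

    def test_ratio_bounds_on_random_configurations(self, rng):
        """ratio stays in [0, 1] over random sphere configurations."""
        for _ in range(40):
            coords = rng.uniform(0, 1.5, size=(9, 3))
            radii = rng.uniform(0.12, 0.25, size=9)
            res = contact_area(coords, radii, np.arange(1), np.arange(1, 5),
                               np.arange(5, 9))
            assert -1e-9 <= res.ratio <= 1.0 + 1e-9

    def test_disjointness_enforced(self):
        coords, radii, lip, t1, t2 = half_shell_cage()
        with pytest.raises(ValueError, match="disjoint"):
            contact_area(coords, radii, lip, np.concatenate([lip, t1]), t2)
        with pytest.raises(ValueError, match="empty"):
            contact_area(coords, radii, np.array([], dtype=int), t1, t2)


class TestLeafletSpacing:
    def test_symmetric_planes(self):
        """P planes at +-18.4 A give the 36.8 A spacing scale."""
        coords = [(0, 0, 1.84), (1, 0, 1.84), (0, 0, -1.84), (1, 0, -1.84)]
        s = toy_structure(coords, names=["P"] * 4, resnames=["SM"] * 4)
        assert leaflet_spacing(s, "P") == pytest.approx(36.8)

    def test_single_atom_per_leaflet(self):
        s = toy_structure([(0, 0, 1.0), (0, 0, -1.0)], names=["P", "P"])
        assert leaflet_spacing(s, "P") == pytest.approx(20.0)

    def test_one_empty_leaflet_raises(self):
        s = toy_structure([(0, 0, 1.0), (0, 0, 2.0)], names=["P", "P"])
        with pytest.raises(ValueError):
            leaflet_spacing(s, "P", split_z=0.0)

    def test_amide_markers_selected_by_name(self):
        coords = [(0, 0, 1.57), (0, 0, -1.57), (0, 0, 1.84), (0, 0, -1.84)]
        s = toy_structure(coords, names=["N", "N", "P", "P"],
                          resnames=["SM"] * 4)
        assert leaflet_spacing(s, "N") == pytest.approx(31.4)
        assert leaflet_spacing(s, "P") == pytest.approx(36.8)


class TestCaRmsd:
    def ca_structure(self, coords, chain="A"):
        n = len(coords)
        return toy_structure(coords, names=["CA"] * n, resnames=["ALA"] * n,
                             resids=list(range(1, n + 1)), chains=[chain] * n)

    def test_identical_structures_zero(self, rng):
        coords = rng.normal(size=(30, 3))
        s = self.ca_structure(coords)
        assert ca_rmsd(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_fits_to_zero(self, rng):
        coords = rng.normal(size=(30, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=4).as_matrix()
        a = self.ca_structure(coords)
        b = self.ca_structure(coords @ R.T + 2.0)
        assert ca_rmsd(a, b, fit=True) <= 1e-6
        assert ca_rmsd(a, b, fit=True) <= ca_rmsd(a, b, fit=False)

    def test_translation_without_fit(self, rng):
        coords = rng.normal(size=(10, 3))
        a = self.ca_structure(coords)
        b = self.ca_structure(coords + np.array([0.3, 0, 0]))  # 3 A shift
        assert ca_rmsd(a, b, fit=False) == pytest.approx(3.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = self.ca_structure(rng.normal(size=(12, 3)))
        b = self.ca_structure(rng.normal(size=(12, 3)))
        assert ca_rmsd(a, b) == pytest.approx(ca_rmsd(b, a), abs=1e-9)

    def test_too_few_matched_pairs(self, rng):
        a = self.ca_structure(rng.normal(size=(2, 3)))
        b = self.ca_structure(rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            ca_rmsd(a, b)


class TestBfactorSummary:
    def test_moments(self):
        s = toy_structure([(0, 0, 0)] * 3, bfactors=[10.0, 20.0, 30.0])
        mean, sd, table = bfactor_summary(s, Selection(indices=[0, 1, 2]))
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(np.std([10, 20, 30]))
        assert len(table) == 3

    def test_constant_bfactors(self):
        s = toy_structure([(0, 0, 0)] * 4, bfactors=[30.0] * 4)
        mean, sd, _ = bfactor_summary(s, Selection(indices=np.arange(4)))
        assert (mean, sd) == (30.0, 0.0)

    def test_empty_selection_raises(self):
        s = toy_structure([(0, 0, 0)])
        with pytest.raises(ValueError, match="empty"):
            bfactor_summary(s, Selection(indices=[]))
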