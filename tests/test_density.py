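"""Gaussian-spread density maps: algebra, invariances and writers."""

import math

import numpy as np
import pytest

from memraft.density_maps import (
    DensityGrid,
    SpreadingParams,
    combine_maps,
    fit_and_accumulate_monomers,
    spread_density,
    threshold_and_mask,
    write_ccp4,
    write_dx,
)
from memraft.io_core import Selection
from memraft.synthetic import MembraneSpec, gen_membrane_trajectory

from conftest import toy_trajectory

ONE_GAUSS = SpreadingParams.single_gaussian(1.0, 0.15)


def static_atom_traj(pos=(2.0, 2.0, 2.0), n_frames=1, box=(4, 4, 4)):
    frames = np.tile(np.asarray(pos, float), (n_frames, 1, 1))
    return toy_trajectory(frames, box=box, times=np.arange(n_frames, dtype=float))


class TestSpreadDensity:
    def test_time_average_independent_of_frame_count(self):
        g1 = spread_density(static_atom_traj(n_frames=1), Selection(indices=[0]),
                            spacing=0.1, params=ONE_GAUSS)
        g10 = spread_density(static_atom_traj(n_frames=10), Selection(indices=[0]),
                             spacing=0.1, params=ONE_GAUSS)
        np.testing.assert_allclose(g10.values, g1.values)
        peak = np.unravel_index(np.argmax(g1.values), g1.shape)
        np.testing.assert_allclose(np.array(peak) * 0.1, [2.0, 2.0, 2.0])

    def test_integral_matches_gaussian_closed_form(self):
        """Grid sum x voxel volume equals A (2 pi)^{3/2} w^3 within 1%."""
        amp, w = 1.0, 0.15
        g = spread_density(static_atom_traj(), Selection(indices=[0]),
                           spacing=0.05,
                           params=SpreadingParams.single_gaussian(amp, w))
        analytic = amp * (2 * math.pi) ** 1.5 * w ** 3
        assert g.integral() == pytest.approx(analytic, rel=0.01)

    def test_linearity_over_disjoint_selections(self):
        frames = np.array([[[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]])
        traj = toy_trajectory(frames, box=(4, 4, 4))
        both = spread_density(traj, Selection(indices=[0, 1]), 0.1, ONE_GAUSS)
        a = spread_density(traj, Selection(indices=[0]), 0.1, ONE_GAUSS)
        b = spread_density(traj, Selection(indices=[1]), 0.1, ONE_GAUSS)
        np.testing.assert_allclose(both.values, a.values + b.values, atol=1e-14)

    def test_translation_equivariance(self):
        shift = np.array([0.3, -0.2, 0.5])
        t1 = static_atom_traj()
        t2 = toy_trajectory(t1.coords + shift, box=(4, 4, 4))
        g1 = spread_density(t1, Selection(indices=[0]), 0.1, ONE_GAUSS,
                            origin=(0, 0, 0), shape=(40, 40, 40))
        g2 = spread_density(t2, Selection(indices=[0]), 0.1, ONE_GAUSS,
                            origin=tuple(shift), shape=(40, 40, 40))
        np.testing.assert_allclose(g2.values, g1.values, atol=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spread_density(static_atom_traj(), Selection(indices=[]), 0.1)


class TestMonomerAccumulation:
    def test_identity_transform_when_already_in_reference(self, membrane):
        _, traj, _ = membrane
        import memraft as mr

        prot = mr.select(traj.topology, "resname PRT")
        nq = len(prot) // 4
        monomers = [Selection(indices=prot.indices[k * nq:(k + 1) * nq])
                    for k in range(4)]
        oxy = mr.select(traj.topology, "resname CHL1 and name O3")
        sub = toy_trajectory(traj.coords[:5], box=tuple(traj.boxes[0]),
                             names=[a.name for a in traj.topology.atoms],
                             resnames=[a.resname for a in traj.topology.atoms])
        refs = [traj.coords[0, m.indices] for m in monomers]
        grids = fit_and_accumulate_monomers(sub, monomers[:1], refs[:1], oxy,
                                            spacing=0.25, params=ONE_GAUSS)
        # protein static: monomer 0 fit is the identity, map equals plain spread
        plain = spread_density(sub, oxy, spacing=0.25, params=ONE_GAUSS)
        np.testing.assert_allclose(grids[0].values, plain.values, atol=1e-9)

    def test_rigid_rotation_invariance(self):
        """Rotating all inputs rigidly leaves the accumulated map unchanged."""
        rng = np.random.default_rng(5)
        fit_atoms = rng.normal(size=(6, 3))
        dens_atom = np.array([[0.8, -0.4, 0.2]])
        base = np.vstack([fit_atoms, dens_atom])
        frames = [base]
        for angle in (0.7, 2.1):
            c, s = math.cos(angle), math.sin(angle)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            frames.append(base @ R.T)
        traj = toy_trajectory(np.array(frames))
        grids = fit_and_accumulate_monomers(
            traj, [Selection(indices=np.arange(6))], [fit_atoms],
            Selection(indices=[6]), spacing=0.1, params=ONE_GAUSS,
            origin=(-3, -3, -3), shape=(60, 60, 60),
        )
        static = toy_trajectory(np.tile(base, (3, 1, 1)))
        ref_grid = fit_and_accumulate_monomers(
            static, [Selection(indices=np.arange(6))], [fit_atoms],
            Selection(indices=[6]), spacing=0.1, params=ONE_GAUSS,
            origin=(-3, -3, -3), shape=(60, 60, 60),
        )
        # agreement is limited by the 4-width kernel truncation: a voxel at
        # the window edge carries up to exp(-8) of the peak amplitude
        np.testing.assert_allclose(grids[0].values, ref_grid[0].values,
                                   atol=math.exp(-8))

    def test_fourfold_symmetric_system_gives_fourfold_map(self, membrane):
        """Summed per-monomer maps of a fourfold system are fourfold symmetric."""
        _, traj, _ = membrane
        import memraft as mr

        prot = mr.select(traj.topology, "resname PRT")
        nq = len(prot) // 4
        monomers = [Selection(indices=prot.indices[k * nq:(k + 1) * nq])
                    for k in range(4)]
        oxy = mr.select(traj.topology, "resname CHL1 and name O3")
        sub = toy_trajectory(traj.coords[:60], box=tuple(traj.boxes[0]))
        ref = traj.coords[0, monomers[0].indices]
        # grid centered on the fourfold axis so a 90-degree rotation maps
        # voxel centers onto voxel centers
        grids = fit_and_accumulate_monomers(sub, monomers, [ref] * 4, oxy,
                                            spacing=0.2, params=ONE_GAUSS,
                                            origin=(0.1, 0.1, 0.0),
                                            shape=(50, 50, 45))
        total = combine_maps(grids, "sum")
        A = total.values
        asym = max(
            np.abs(A - np.rot90(A, k=k, axes=(0, 1))).max() for k in (1, 2, 3)
        )
        n_chol = len(oxy)
        shot_noise = A.max() / math.sqrt(sub.n_frames * n_chol)
        assert asym < 3 * shot_noise


class TestMapAlgebra:
    def grid(self, values):
        return DensityGrid(origin=np.zeros(3), spacing=0.1,
                           values=np.asarray(values, float))

    def test_sum_and_difference(self, rng):
        v = rng.random((4, 4, 4))
        g = self.grid(v)
        doubled = combine_maps([g, g], "sum")
        np.testing.assert_allclose(doubled.values, 2 * v)
        zero = combine_maps([g, g], "difference")
        assert zero.sigma == 0.0
        np.testing.assert_allclose(zero.values, 0.0)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            combine_maps([self.grid(rng.random((4, 4, 4))),
                          self.grid(rng.random((5, 4, 4)))])

    def test_threshold_noop_and_zero_grid(self):
        g = self.grid(np.zeros((3, 3, 3)))
        out = threshold_and_mask(g, n_sigma=5.0)
        np.testing.assert_allclose(out.values, 0.0)
        v = np.arange(27.0).reshape(3, 3, 3)
        out2 = threshold_and_mask(self.grid(v), n_sigma=0.0)
        np.testing.assert_allclose(out2.values, v)

    def test_surviving_voxels_decrease_with_threshold(self):
        g = spread_density(static_atom_traj(), Selection(indices=[0]),
                           0.1, ONE_GAUSS)
        counts = [
            int(np.count_nonzero(threshold_and_mask(g, n).values))
            for n in (0.5, 1, 2, 5, 10, 20)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_protein_proximity_mask(self):
        g = spread_density(static_atom_traj(), Selection(indices=[0]),
                           0.1, ONE_GAUSS)
        near = threshold_and_mask(g, 0.0, protein_coords=np.array([[2.0, 2.0, 2.0]]),
                                  max_distance=0.3)
        far = threshold_and_mask(g, 0.0, protein_coords=np.array([[0.0, 0.0, 0.0]]),
                                 max_distance=0.3)
        assert near.values.max() > 0
        assert np.count_nonzero(far.values) < np.count_nonzero(near.values)


class TestWriters:
    def test_dx_roundtrip(self, tmp_path, rng):
        from gridData import Grid

        g = DensityGrid(origin=np.array([0.5, 0.0, -0.2]), spacing=0.1,
                        values=rng.random((5, 6, 7)))
        path = str(tmp_path / "map.dx")
        write_dx(g, path)
        back = Grid(path)
        np.testing.assert_allclose(back.grid, g.values, rtol=1e-6)

    def test_ccp4_roundtrip(self, tmp_path, rng):
        import gemmi

        g = DensityGrid(origin=np.zeros(3), spacing=0.1,
                        values=rng.random((8, 8, 8)))
        path = str(tmp_path / "map.ccp4")
        write_ccp4(g, path)
        m = gemmi.read_ccp4_map(path)
        np.testing.assert_allclose(np.asarray(m.grid), g.values, atol=1e-6)
        assert m.grid.unit_cell.a == pytest.approx(8 * 0.1 * 10.0)
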