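"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from memraft.io_core import AtomRecord, Structure, Trajectory


def toy_structure(coords, names=None, resnames=None, resids=None, chains=None,
                  elements=None, box=None, bfactors=None, radii=None) -> Structure:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["X"] * n
    resnames = resnames or ["UNK"] * n
    resids = resids if resids is not None else list(range(1, n + 1))
    chains = chains or ["A"] * n
    elements = elements or ["C"] * n
    bfactors = bfactors if bfactors is not None else [0.0] * n
    radii = radii if radii is not None else [None] * n
    atoms = [
        AtomRecord(i + 1, names[i], resnames[i], resids[i], chains[i],
                   elements[i], coords[i], bfactor=bfactors[i], radius=radii[i])
        for i in range(n)
    ]
    return Structure(atoms=atoms, box=None if box is None else np.asarray(box))


def toy_trajectory(frames, box=None, times=None, **kwargs) -> Trajectory:
    """Build a Trajectory from an (F, N, 3) array; topology from frame 0."""
    frames = np.asarray(frames, dtype=float)
    top = toy_structure(frames[0], box=box, **kwargs)
    boxes = None if box is None else np.tile(np.asarray(box, float), (len(frames), 1))
    if times is None:
        times = np.arange(len(frames), dtype=float)
    return Trajectory(topology=top, coords=frames, boxes=boxes, times=times)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def monte_carlo_sasa(coords, radii, probe, n_samples, rng) -> np.ndarray:
    """Per-atom SASA by uniform sampling of each expanded sphere.

    Independent of any mesh/lattice machinery: sample ``n_samples`` points
    uniformly on every atom's probe-expanded sphere and keep the fraction
    not inside any other expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    n = len(coords)
    areas = np.empty(n)
    for i in range(n):
        v = rng.standard_normal((n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + expanded[i] * v
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * exposed.mean()
    return areas


def two_sphere_sasa(r1, r2, d, probe):
    """Closed-form accessible areas of two (possibly overlapping) spheres."""
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d >= R1 + R2:
        return full1, full2
    # spherical-cap burial: cap height from the radical plane
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    a1 = full1 - 2 * math.pi * R1 * max(0.0, h1)
    a2 = full2 - 2 * math.pi * R2 * max(0.0, h2)
    return max(a1, 0.0), max(a2, 0.0)


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of partitions."""
    from itertools import combinations

    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    n, m = len(x), len(y)
    assert len(set(pooled)) == n + m, "oracle requires untied data"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = [
        u_stat(comb, [v for v in pooled if v not in comb])
        for comb in combinations(pooled, n)
    ]
    us = np.array(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def membrane():
    """A medium-length synthetic membrane with its ground truth."""
    from memraft.synthetic import MembraneSpec, gen_membrane_trajectory

    spec = MembraneSpec(n_frames=600, seed=11)
    traj, truth = gen_membrane_trajectory(spec)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
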