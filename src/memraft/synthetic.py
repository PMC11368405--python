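"""Synthetic membranes, force-probe traces, contact series and sphere clusters.

Every generator carries its ground truth alongside the data so downstream
stages (insertion depth, tilt, contact statistics, detachment detection,
density maps, SASA) can be validated without running molecular dynamics.

The membrane generator emulates the statistical structure of an
aquaporin-in-sphingomyelin/cholesterol system: a static (optionally exactly
fourfold-symmetric) protein cylinder, sphingomyelin pseudo-lipids carrying
phosphate (P) and amide-nitrogen (N) marker atoms on well-defined leaflet
planes, and cholesterol pseudo-lipids carrying hydroxyl-oxygen (O3) and ring
(C3, C17) marker atoms whose insertion depth and tilt follow stationary
mean-reverting (Ornstein-Uhlenbeck) processes.  Chemistry beyond these
labeled anchors is deliberately absent; downstream operations only read the
anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .force_probe import ForceTrace
from .io_core import AtomRecord, Structure, Trajectory

__all__ = [
    "MembraneSpec",
    "ForceTraceSpec",
    "ContactSeriesSpec",
    "gen_membrane_trajectory",
    "gen_force_trace",
    "gen_contact_series",
    "gen_sphere_cluster",
]

M_PER_S_TO_NM_PER_PS = 1e-3  # 1 m/s == 1 nm/ns


@dataclass
class ProteinSpec:
    """A static pseudo-protein: rings of beads on a cylinder surface."""

    radius: float = 2.0          # nm
    n_pseudoatoms: int = 48
    fourfold_symmetric: bool = True
    half_height: float = 1.5     # nm, beads span +- this about the midplane


@dataclass
class MembraneSpec:
    """Conditions for a synthetic bilayer patch.

    Defaults emulate a 128-lipid membrane at a roughly 2:1
    sphingomyelin:cholesterol ratio with the cholesterol hydroxyl sitting
    0.6 nm below the extracellular phosphate plane (depth -0.60 +- 0.16 nm)
    at a modest tilt (20 +- 8 degrees).
    """

    box: tuple[float, float, float] = (10.0, 10.0, 9.0)   # nm
    n_sm_per_leaflet: int = 42
    n_chol_per_leaflet: int = 22
    protein: ProteinSpec | None = field(default_factory=ProteinSpec)
    depth_mean: float = -0.60    # nm, hydroxyl O below the phosphate plane
    depth_sd: float = 0.16       # nm
    tilt_mean: float = 20.0      # deg, ring axis vs the membrane normal
    tilt_sd: float = 8.0         # deg
    relaxation_time: float = 100.0       # ps, OU relaxation of depth and tilt
    lateral_diffusion: float = 1e-5      # nm^2/ps, in-plane random walk
    dt: float = 100.0            # ps between frames
    n_frames: int = 1000
    seed: int = 0
    phosphate_half_spacing: float = 1.84  # nm, P planes at midplane +- this
    amide_offset: float = 0.25   # nm, amide N sits this far inside the P plane
    flip_events: tuple = ()      # (chol_resid, frame) leaflet-flip injections

    def validate(self) -> None:
        if any(b <= 0 for b in self.box):
            raise ValueError("box edges must be positive")
        if self.depth_sd < 0 or self.tilt_sd < 0:
            raise ValueError("depth_sd and tilt_sd must be >= 0")
        if self.relaxation_time <= 0 or self.dt <= 0 or self.n_frames < 1:
            raise ValueError("relaxation_time, dt and n_frames must be positive")
        if self.n_sm_per_leaflet < 0 or self.n_chol_per_leaflet < 0:
            raise ValueError("lipid counts must be non-negative")


@dataclass
class ForceTraceSpec:
    """Conditions for a synthetic constant-velocity pulling trace.

    The force ramps at the effective loading rate ``k_s * V_pull`` with
    exponentially-correlated (AR(1)) noise until the detachment time, then
    relaxes to baseline; the center-of-mass distance fluctuates about ``d0``
    before detachment and afterwards rises linearly, first exceeding
    ``cutoff`` exactly ``cutoff_crossing_delay`` after detachment.
    ``f_true = k_s * V_pull * t_det`` is enforced.
    """

    v_pull: float = 0.02                 # m/s
    k_s: float = 500.0                   # kJ/mol/nm^2, harmonic spring
    f_true: float = 1500.0               # kJ/mol/nm, planted detachment force
    t_det: float | None = None           # ps; derived from f_true if omitted
    noise_sd: float = 50.0               # kJ/mol/nm
    noise_correlation_time: float = 50.0  # ps
    d0: float = 5.0                      # nm, pre-detachment COM distance
    d_noise_sd: float = 0.03             # nm
    cutoff: float = 7.3                  # nm, crossing cutoff of the d_COM trace
    cutoff_crossing_delay: float = 200.0  # ps after t_det
    relax_time: float = 200.0            # ps, post-detachment force decay
    dt: float = 10.0                     # ps
    duration: float | None = None        # ps; default t_det + delay + 1000
    seed: int = 0
    condition: str = "synthetic"
    replica: int = 0

    def loading_rate(self) -> float:
        """Effective loading rate in kJ/mol/nm per ps."""
        return self.k_s * self.v_pull * M_PER_S_TO_NM_PER_PS

    def resolve(self) -> "ForceTraceSpec":
        r = self.loading_rate()
        if r <= 0:
            raise ValueError("v_pull and k_s must be positive")
        t_det = self.t_det
        if t_det is None:
            t_det = self.f_true / r
        elif abs(self.f_true - r * t_det) > 1e-6 * max(1.0, self.f_true):
            raise ValueError(
                f"inconsistent spec: f_true={self.f_true} != loading_rate*t_det={r * t_det}"
            )
        duration = self.duration
        if duration is None:
            duration = t_det + self.cutoff_crossing_delay + 1000.0
        if duration < t_det:
            raise ValueError("duration shorter than the detachment time")
        out = ForceTraceSpec(**{**asdict(self), "t_det": t_det, "duration": duration})
        return out


@dataclass
class ContactSeriesSpec:
    """Independent two-state (on/off) Markov chains sampled at timestep dt."""

    n_pairs: int = 50
    k_on: float = 0.005          # per ps
    k_off: float = 0.01          # per ps
    dt: float = 1.0              # ps
    n_frames: int = 10_000
    seed: int = 0
    initial_state: int | None = None   # None -> stationary draw

    def validate(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")
        if self.k_on == 0 and self.k_off == 0 and self.initial_state is None:
            raise ValueError("with both rates zero an initial_state is required")
        if self.n_pairs < 1 or self.n_frames < 1 or self.dt <= 0:
            raise ValueError("n_pairs, n_frames and dt must be positive")

    @property
    def stationary_occupancy(self) -> float:
        if self.k_on == 0 and self.k_off == 0:
            return float(self.initial_state)
        return self.k_on / (self.k_on + self.k_off)


# ---------------------------------------------------------------------------
# membrane trajectory
# ---------------------------------------------------------------------------

def _ou_series(rng, mean, sd, tau, dt, n_frames, x0=None):
    """Exact-discretization OU path started from the stationary law."""
    from scipy.signal import lfilter

    a = math.exp(-dt / tau)
    s = sd * math.sqrt(max(0.0, 1.0 - a * a))
    w = s * rng.standard_normal(n_frames)
    w[0] = (sd * rng.standard_normal() if x0 is None else x0 - mean)
    return mean + lfilter([1.0], [1.0, -a], w)


def _lattice_sites(box, n_needed, exclusion_radius, min_spacing=0.45):
    """Jitter-free square lattice sites avoiding a central exclusion disc."""
    lx, ly = box[0], box[1]
    m = max(1, math.ceil(math.sqrt(n_needed)))
    center = np.array([lx / 2, ly / 2])
    while True:
        spacing = min(lx, ly) / m
        if spacing < min_spacing:
            raise ValueError(
                f"cannot pack {n_needed} lipids per leaflet in a "
                f"{lx:.1f}x{ly:.1f} nm box at >=0.45 nm spacing"
            )
        xs = (np.arange(m) + 0.5) * (lx / m)
        ys = (np.arange(m) + 0.5) * (ly / m)
        pts = np.array([(x, y) for x in xs for y in ys])
        keep = np.linalg.norm(pts - center, axis=1) > exclusion_radius
        sites = pts[keep]
        if len(sites) >= n_needed:
            return sites[:n_needed]
        m += 1


def _protein_coords(spec: ProteinSpec, center_xy, z_center) -> np.ndarray:
    n = spec.n_pseudoatoms
    if spec.fourfold_symmetric:
        n_quarter = max(1, round(n / 4))
        per_ring = 3
        n_rings = max(1, math.ceil(n_quarter / per_ring))
        zs = np.linspace(-spec.half_height, spec.half_height, n_rings)
        quarter = []
        i = 0
        for ring, z in enumerate(zs):
            for j in range(per_ring):
                if i >= n_quarter:
                    break
                phi = (j + 0.5 * (ring % 2)) * (math.pi / 2) / per_ring
                quarter.append((phi, z))
                i += 1
        coords = []
        for k in range(4):
            rot = k * math.pi / 2
            for phi, z in quarter:
                coords.append(
                    (
                        center_xy[0] + spec.radius * math.cos(phi + rot),
                        center_xy[1] + spec.radius * math.sin(phi + rot),
                        z_center + z,
                    )
                )
        return np.array(coords)
    phis = np.linspace(0, 2 * math.pi, n, endpoint=False)
    zs = spec.half_height * np.sin(3 * phis)
    return np.column_stack(
        [
            center_xy[0] + spec.radius * np.cos(phis),
            center_xy[1] + spec.radius * np.sin(phis),
            z_center + zs,
        ]
    )


def gen_membrane_trajectory(spec: MembraneSpec):
    """Generate a membrane trajectory with known depth/tilt statistics.

    Returns ``(trajectory, ground_truth)`` where ``ground_truth`` records the
    spec, the per-lipid identities and leaflets, and any injected flip-flop
    events.  Identical specs (including seed) give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    zc = lz / 2.0
    h = spec.phosphate_half_spacing
    z_planes = {+1: zc + h, -1: zc - h}

    excl = 0.0
    protein_xyz = np.zeros((0, 3))
    if spec.protein is not None and spec.protein.n_pseudoatoms > 0:
        protein_xyz = _protein_coords(spec.protein, (lx / 2, ly / 2), zc)
        excl = spec.protein.radius + 0.5

    atoms: list[AtomRecord] = []
    serial = 1
    for xyz in protein_xyz:
        atoms.append(
            AtomRecord(serial, "BB", "PRT", len(atoms) + 1, "P", "C", xyz)
        )
        serial += 1

    # lipid bookkeeping: one entry per lipid with marker-atom indices
    lipids = []
    resid = 1000
    n_per_leaflet = spec.n_sm_per_leaflet + spec.n_chol_per_leaflet
    flip_map: dict[int, list[int]] = {}
    for leaflet in (+1, -1):
        if n_per_leaflet == 0:
            continue
        sites = _lattice_sites(spec.box, n_per_leaflet, excl)
        order = rng.permutation(n_per_leaflet)
        kinds = ["SM"] * spec.n_sm_per_leaflet + ["CHL1"] * spec.n_chol_per_leaflet
        for site_i, kind in zip(order, kinds):
            xy = sites[site_i]
            resid += 1
            if kind == "SM":
                idx_p = len(atoms)
                atoms.append(AtomRecord(serial, "P", "SM", resid, "M", "P",
                                        (xy[0], xy[1], z_planes[leaflet])))
                serial += 1
                atoms.append(AtomRecord(serial, "N", "SM", resid, "M", "N",
                                        (xy[0], xy[1],
                                         z_planes[leaflet] - leaflet * spec.amide_offset)))
                serial += 1
                lipids.append({"resid": resid, "kind": "SM", "leaflet": leaflet,
                               "atom0": idx_p})
            else:
                idx_o = len(atoms)
                base = (xy[0], xy[1], z_planes[leaflet])
                for nm in ("O3", "C3", "C17"):
                    el = "O" if nm == "O3" else "C"
                    atoms.append(AtomRecord(serial, nm, "CHL1", resid, "M", el, base))
                    serial += 1
                lipids.append({"resid": resid, "kind": "CHL1", "leaflet": leaflet,
                               "atom0": idx_o})
    for chol_resid, frame in spec.flip_events:
        flip_map.setdefault(int(chol_resid), []).append(int(frame))

    topology = Structure(atoms=atoms, box=np.array(spec.box))
    n_atoms = len(atoms)
    F = spec.n_frames
    coords = np.empty((F, n_atoms, 3))
    coords[:, : len(protein_xyz), :] = protein_xyz[None, :, :]

    step_sd = math.sqrt(2.0 * spec.lateral_diffusion * spec.dt)
    for lip in lipids:
        xy0 = np.array(atoms[lip["atom0"]].coords[:2])
        steps = rng.standard_normal((F - 1, 2)) * step_sd if F > 1 else np.zeros((0, 2))
        xy = np.vstack([xy0, xy0 + np.cumsum(steps, axis=0)])
        xy[:, 0] %= lx
        xy[:, 1] %= ly
        leaf = lip["leaflet"]
        if lip["kind"] == "SM":
            zp = np.full(F, z_planes[leaf])
            zn = zp - leaf * spec.amide_offset
            i0 = lip["atom0"]
            coords[:, i0, 0] = xy[:, 0]
            coords[:, i0, 1] = xy[:, 1]
            coords[:, i0, 2] = zp
            coords[:, i0 + 1, 0] = xy[:, 0]
            coords[:, i0 + 1, 1] = xy[:, 1]
            coords[:, i0 + 1, 2] = zn
        else:
            depth = _ou_series(rng, spec.depth_mean, spec.depth_sd,
                               spec.relaxation_time, spec.dt, F)
            tilt = _ou_series(rng, spec.tilt_mean, spec.tilt_sd,
                              spec.relaxation_time, spec.dt, F)
            phi = rng.uniform(0, 2 * math.pi) + np.cumsum(
                np.concatenate([[0.0], rng.standard_normal(F - 1) * 0.2])
            )
            # leaflet sign per frame, with injected flips
            sign = np.full(F, leaf)
            for fframe in sorted(flip_map.get(lip["resid"], [])):
                sign[fframe:] *= -1
            z_o = np.where(sign > 0,
                           z_planes[+1] + depth,
                           z_planes[-1] - depth)
            # actual tilt vs +z: lower-leaflet lipids point downwards
            theta_actual = np.where(sign > 0, tilt, 180.0 - tilt)
            th = np.radians(theta_actual)
            u = np.column_stack(
                [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)]
            )
            o3 = np.column_stack([xy[:, 0], xy[:, 1], z_o])
            c3 = o3 - 0.15 * u
            c17 = c3 - 0.90 * u
            i0 = lip["atom0"]
            coords[:, i0, :] = o3
            coords[:, i0 + 1, :] = c3
            coords[:, i0 + 2, :] = c17
            lip["flips"] = flip_map.get(lip["resid"], [])

    boxes = np.tile(np.array(spec.box), (F, 1))
    times = np.arange(F) * spec.dt
    traj = Trajectory(topology=topology, coords=coords, boxes=boxes, times=times)
    truth = {
        "spec": asdict(spec),
        "lipids": [
            {k: v for k, v in lip.items() if k != "atom0"} | {"atom0": int(lip["atom0"])}
            for lip in lipids
        ],
        "depth_mean": spec.depth_mean,
        "depth_sd": spec.depth_sd,
        "tilt_mean": spec.tilt_mean,
        "tilt_sd": spec.tilt_sd,
        "n_flip_events": sum(len(v) for v in flip_map.values()),
        "seed": spec.seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# force-probe trace
# ---------------------------------------------------------------------------

def _ar1_noise(rng, sd, tau, dt, n):
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = math.exp(-dt / max(tau, 1e-12))
    s = sd * math.sqrt(max(0.0, 1.0 - a * a))
    w = s * rng.standard_normal(n)
    w[0] = sd * rng.standard_normal()
    return lfilter([1.0], [1.0, -a], w)


def gen_force_trace(spec: ForceTraceSpec):
    """Generate a pulling trace with a planted detachment event.

    Returns ``(trace, ground_truth)``; the ground truth stores the planted
    detachment force, time, and the exact cutoff-crossing time.
    """
    spec = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    n = len(times)
    r = spec.loading_rate()
    t_det = spec.t_det

    force = r * times
    post = times > t_det
    force[post] = spec.f_true * np.exp(-(times[post] - t_det) / spec.relax_time)
    force = force + _ar1_noise(rng, spec.noise_sd, spec.noise_correlation_time,
                               spec.dt, n)

    rise = (spec.cutoff - spec.d0) / spec.cutoff_crossing_delay
    d_com = np.where(times <= t_det, spec.d0,
                     spec.d0 + rise * (times - t_det))
    d_noise = _ar1_noise(rng, spec.d_noise_sd, spec.noise_correlation_time,
                         spec.dt, n)
    d_com = d_com + np.where(times <= t_det, d_noise, 0.0)

    trace = ForceTrace(
        times=times,
        force=force,
        d_com=d_com,
        v_pull=spec.v_pull,
        k_s=spec.k_s,
        replica=spec.replica,
        condition=spec.condition,
        presmoothed=(spec.noise_sd == 0 and spec.d_noise_sd == 0),
    )
    truth = {
        "f_true": spec.f_true,
        "t_det": t_det,
        "crossing_time": t_det + spec.cutoff_crossing_delay,
        "loading_rate": r,
        "seed": spec.seed,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# contact series
# ---------------------------------------------------------------------------

def gen_contact_series(spec: ContactSeriesSpec):
    """Sample independent two-state Markov chains; returns (matrix, truth).

    The boolean matrix has shape (n_pairs, n_frames).  Initial states are
    drawn from the stationary law unless ``initial_state`` pins them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_off_on = 1.0 - math.exp(-spec.k_on * spec.dt)
    p_on_off = 1.0 - math.exp(-spec.k_off * spec.dt)
    p_stat = spec.stationary_occupancy

    states = np.empty((spec.n_pairs, spec.n_frames), dtype=bool)
    if spec.initial_state is None:
        states[:, 0] = rng.random(spec.n_pairs) < p_stat
    else:
        states[:, 0] = bool(spec.initial_state)
    u = rng.random((spec.n_pairs, spec.n_frames - 1))
    for k in range(1, spec.n_frames):
        prev = states[:, k - 1]
        flip = np.where(prev, u[:, k - 1] < p_on_off, u[:, k - 1] < p_off_on)
        states[:, k] = prev ^ flip
    mean_on_run_frames = (
        math.inf if p_on_off == 0 else 1.0 / p_on_off
    )
    truth = {
        "stationary_occupancy": p_stat,
        "mean_on_run_frames": mean_on_run_frames,
        "mean_on_run_ps": mean_on_run_frames * spec.dt,
        "k_on": spec.k_on,
        "k_off": spec.k_off,
        "dt": spec.dt,
        "seed": spec.seed,
    }
    return states, truth


# ---------------------------------------------------------------------------
# sphere clusters (surface-area oracle fixtures)
# ---------------------------------------------------------------------------

def gen_sphere_cluster(radii, centers) -> Structure:
    """Pseudo-atom cluster with per-atom radii (nm) for surface-area tests."""
    radii = np.asarray(radii, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if len(radii) != len(centers):
        raise ValueError("radii and centers must have equal length")
    atoms = [
        AtomRecord(i + 1, f"S{i + 1}", "SPH", i + 1, "S", "C",
                   centers[i], radius=float(radii[i]))
        for i in range(len(radii))
    ]
    return Structure(atoms=atoms, box=None)
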