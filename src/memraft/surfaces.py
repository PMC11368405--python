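"""Surface areas, lipid-protein complementarity, and static-structure metrics.

Solvent-accessible surface areas (SASA) use the Shrake-Rupley rolling-probe
construction (probe radius 0.14 nm, 960 mesh points per atom by default).
Lipid-tetramer contact area follows the buried-surface identity

    A_Contact,i,m = 0.5 * (A_Tet,m + A_Lipid,i - A_Tet,m+Lipid,i)

for lipid i against tetramer m; the complementarity ratio
(A_Contact,i,1 + A_Contact,i,2) / A_Lipid,i runs from 0 (no contact) to 1
(lipid surface fully buried against the two proteins).

Also here: bilayer leaflet spacing from per-leaflet marker-atom planes,
C-alpha RMSD between matched structures, and B-factor summaries -- the
static measurements made on deposited coordinates, reported in Angstrom
as is crystallographic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch, superposed_rmsd
from .io_core import Selection, Structure, Trajectory, select

__all__ = [
    "SasaParams",
    "BONDI_RADII_NM",
    "sasa",
    "sasa_structure",
    "ComplementarityResult",
    "contact_area",
    "complementarity_series",
    "leaflet_spacing",
    "ca_rmsd",
    "bfactor_summary",
]

# Bondi-style van der Waals radii (nm); overridable per call.  Absolute SASA
# values depend strongly on this table, so cross-structure comparisons
# should state the radii used.
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
}
DEFAULT_RADIUS_NM = 0.170


@dataclass
class SasaParams:
    probe_radius: float = 0.14          # nm (water probe)
    n_points: int = 960                  # mesh points per atom
    radii: dict = field(default_factory=lambda: dict(BONDI_RADII_NM))

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 24:
            raise ValueError("need at least 24 surface points per atom")

    def radius_for(self, atom) -> float:
        if getattr(atom, "radius", None) is not None:
            return atom.radius
        return self.radii.get(atom.element.upper(), DEFAULT_RADIUS_NM)


def sasa(coords: np.ndarray, radii: np.ndarray,
         params: SasaParams | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (nm^2).

    ``coords`` (N, 3) and per-atom ``radii`` are in nm.  Deterministic for
    fixed parameters; areas of overlapping atoms are split by mesh-point
    ownership and remain finite.
    """
    import biotite.structure as struc

    params = params or SasaParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if len(radii) != len(coords):
        raise ValueError("radii must match coords")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords * 10.0
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "UNK")
    arr.atom_name = np.full(n, "C")
    arr.element = np.full(n, "C")
    areas = struc.sasa(
        arr,
        probe_radius=params.probe_radius * 10.0,
        vdw_radii=radii * 10.0,
        point_number=params.n_points,
        ignore_ions=False,
    )
    return np.nan_to_num(np.asarray(areas)) / 100.0  # A^2 -> nm^2


def sasa_structure(structure: Structure, params: SasaParams | None = None,
                   selection: Selection | None = None) -> np.ndarray:
    """Per-atom SASA of (a selection of) a Structure, radii from metadata or
    the element table."""
    params = params or SasaParams()
    idx = selection.indices if selection is not None else np.arange(structure.n_atoms)
    atoms = [structure.atoms[i] for i in idx]
    coords = np.array([a.coords for a in atoms])
    radii = np.array([params.radius_for(a) for a in atoms])
    return sasa(coords, radii, params)


@dataclass
class ComplementarityResult:
    a_lipid: float          # nm^2, isolated lipid SASA
    a_contact_1: float      # nm^2, buried against tetramer 1
    a_contact_2: float      # nm^2, buried against tetramer 2
    clamped: bool = False   # sampling negatives clamped to 0 / total capped

    @property
    def a_contact(self) -> float:
        """Total lipid surface covered by the two proteins (capped at A_Lipid).

        The buried-area identity averages the lipid's and the protein's
        buried surfaces; a strongly concave protein pocket can bury more of
        its own surface than the lipid has, so the total is capped at the
        lipid area (the quantity is a *covered lipid fraction*).
        """
        return min(self.a_contact_1 + self.a_contact_2, self.a_lipid)

    @property
    def ratio(self) -> float:
        return self.a_contact / self.a_lipid if self.a_lipid > 0 else 0.0


def _union_sasa_total(coords_list, radii_list, params) -> float:
    coords = np.vstack(coords_list)
    radii = np.concatenate(radii_list)
    return float(np.sum(sasa(coords, radii, params)))


def contact_area(
    coords: np.ndarray,
    radii: np.ndarray,
    lipid_idx: np.ndarray,
    tet1_idx: np.ndarray,
    tet2_idx: np.ndarray,
    params: SasaParams | None = None,
) -> ComplementarityResult:
    """Lipid-tetramer contact areas via the buried-SASA identity.

    Index arrays select the lipid and the two protein groups out of
    ``coords``/``radii`` (nm); the groups must be pairwise disjoint.
    """
    params = params or SasaParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sets = [np.asarray(lipid_idx), np.asarray(tet1_idx), np.asarray(tet2_idx)]
    if len(sets[0]) == 0:
        raise ValueError("empty lipid selection")
    for i in range(3):
        for j in range(i + 1, 3):
            if set(sets[i]) & set(sets[j]):
                raise ValueError("lipid/tetramer selections must be disjoint")
    a_lipid = _union_sasa_total([coords[sets[0]]], [radii[sets[0]]], params)
    clamped = False
    contacts = []
    for tet in sets[1:]:
        if len(tet) == 0:
            contacts.append(0.0)
            continue
        a_tet = _union_sasa_total([coords[tet]], [radii[tet]], params)
        a_both = _union_sasa_total(
            [coords[tet], coords[sets[0]]], [radii[tet], radii[sets[0]]], params
        )
        a_c = 0.5 * (a_tet + a_lipid - a_both)
        if a_c < 0:
            clamped = clamped or a_c < -1e-9
            a_c = 0.0
        contacts.append(a_c)
    if contacts[0] + contacts[1] > a_lipid:
        clamped = True
    return ComplementarityResult(
        a_lipid=a_lipid, a_contact_1=contacts[0], a_contact_2=contacts[1],
        clamped=clamped,
    )


def complementarity_series(
    traj: Trajectory,
    lipid_sel: Selection,
    tet1_sel: Selection,
    tet2_sel: Selection,
    params: SasaParams | None = None,
) -> list[ComplementarityResult]:
    """Per-frame lipid-protein complementarity over a trajectory."""
    params = params or SasaParams()
    radii = np.array([params.radius_for(a) for a in traj.topology.atoms])
    out = []
    for f in range(traj.n_frames):
        out.append(
            contact_area(traj.coords[f], radii, lipid_sel.indices,
                         tet1_sel.indices, tet2_sel.indices, params)
        )
    return out


def leaflet_spacing(
    structure: Structure,
    atom_name: str = "P",
    resname: str | None = None,
    split_z: float | None = None,
    mode: str = "plane_difference",
) -> float:
    """Distance between the two leaflets' marker-atom planes, in Angstrom.

    Atoms named ``atom_name`` (optionally restricted to ``resname``) are
    assigned to leaflets by their z relative to ``split_z`` (default: the
    mean z of the matching atoms).  ``plane_difference`` reports
    ``|mean z(upper) - mean z(lower)|``; ``mean_pairwise`` the mean of all
    upper-lower pairwise z separations (identical for equal-size leaflets
    but exposed because the defining phrase is ambiguous).
    """
    zs = np.array([
        a.coords[2] for a in structure.atoms
        if a.name == atom_name and (resname is None or a.resname == resname)
    ])
    if len(zs) < 2:
        raise ValueError(f"need atoms named {atom_name!r} in both leaflets")
    split = float(np.mean(zs)) if split_z is None else split_z
    upper = zs[zs >= split]
    lower = zs[zs < split]
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("one leaflet has no matching atoms")
    if mode == "plane_difference":
        spacing_nm = abs(upper.mean() - lower.mean())
    elif mode == "mean_pairwise":
        spacing_nm = float(np.mean(upper[:, None] - lower[None, :]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return spacing_nm * 10.0


def ca_rmsd(struct_a: Structure, struct_b: Structure, fit: bool = True) -> float:
    """C-alpha RMSD (Angstrom) over the (chain, resid) intersection.

    With ``fit`` an optimal proper-rotation superposition precedes the RMSD.
    """
    def ca_map(s):
        return {(a.chain, a.resid): a.coords for a in s.atoms if a.name == "CA"}

    ma, mb = ca_map(struct_a), ca_map(struct_b)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise ValueError("need at least 3 matched C-alpha pairs")
    xa = np.array([ma[k] for k in common])
    xb = np.array([mb[k] for k in common])
    return superposed_rmsd(xa, xb, fit=fit) * 10.0


def bfactor_summary(structure: Structure, selection: Selection):
    """Mean and s.d. of B-factors (A^2) plus a per-residue table.

    Returns ``(mean, sd, table)`` where ``table`` is a DataFrame with one
    row per residue (chain, resid, resname, mean_bfactor, n_atoms).
    """
    import pandas as pd

    if len(selection) == 0:
        raise ValueError("empty selection")
    rows = []
    values = []
    per_res: dict = {}
    for i in selection.indices:
        a = structure.atoms[i]
        values.append(a.bfactor)
        key = (a.chain, a.resid, a.resname)
        per_res.setdefault(key, []).append(a.bfactor)
    values = np.asarray(values, dtype=float)
    for (chain, resid, resname), bs in sorted(per_res.items()):
        rows.append({
            "chain": chain, "resid": resid, "resname": resname,
            "mean_bfactor": float(np.mean(bs)), "n_atoms": len(bs),
        })
    table = pd.DataFrame(rows)
    return float(values.mean()), float(values.std()), table
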