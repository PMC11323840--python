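"""Mapping fitted interaction-field functions onto protein surfaces.

Every backbone carbonyl of the protein carries the residue-local o-uvw frame
in which the fitted function E_X(r) was defined.  A laboratory-frame query
point is transformed into each nearby residue's frame, the function is
evaluated and clamped to [0, 1], and the highest per-residue strength wins
(that residue is recorded as the contributor).  Two hard rules apply:

* steric mask -- points within 2 A (default) of any protein heavy atom score 0;
* fitted domain -- the expansion is only trusted out to the sampled radius
  (7 A default); beyond it, in every residue frame, the strength is 0.

The same combination rule powers whole-box maps (:func:`map_protein_mif`),
single-point strengths at ligand halogen positions (:func:`strength_at_point`)
and the (theta, phi) orientation maps at fixed radius (:func:`theta_phi_map`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fitting import MIFResults
from .frames import Frame, build_residue_frame, halogen_bond_geometry, lab_to_molecular
from .grids import BoxGridValues, spherical_to_cartesian
from .structures_io import (
    Atom,
    Structure,
    protein_heavy_atom_coords,
    select_backbone_carbonyls,
    select_halogen_atoms,
    select_ligand_atoms,
)

__all__ = [
    "MapOptions",
    "MIFMap",
    "StrengthRecord",
    "residue_frames",
    "map_protein_mif",
    "strength_at_point",
    "ligand_site_mask",
    "theta_phi_map",
    "survey_halogen_bonds",
    "survey_to_csv",
]


@dataclass(frozen=True)
class MapOptions:
    """Mapping options: steric exclusion radius, trusted radial domain and
    optional ligand-site restriction (all angstrom)."""

    steric_radius: float = 2.0
    r_max_domain: float = 7.0
    r_min_domain: float = 0.0
    ligand_mask_radius: float | None = None


@dataclass
class MIFMap:
    """Box grid of strengths plus per-voxel contributing-residue bookkeeping.

    ``contributor`` holds an index into ``residue_ids`` per voxel (-1 where
    no residue contributes).
    """

    grid: BoxGridValues
    contributor: np.ndarray
    residue_ids: list[str]
    options: MapOptions = field(default_factory=MapOptions)

    def contributor_id(self, ijk) -> str | None:
        idx = int(self.contributor[tuple(ijk)])
        return None if idx < 0 else self.residue_ids[idx]


@dataclass(frozen=True)
class StrengthRecord:
    """One surveyed halogen bond: identity, geometry and mapped strength."""

    pdb_id: str
    chain: str
    residue: str
    ligand: str
    halogen_name: str
    d: float
    theta1: float
    theta2: float
    psi: float | None
    strength: float


def residue_frames(structure: Structure) -> list[tuple[str, Frame, dict[str, Atom]]]:
    """o-uvw frames for every complete backbone carbonyl."""
    out = []
    for rid, atoms in select_backbone_carbonyls(structure):
        frame = build_residue_frame(atoms["O"].xyz, atoms["C"].xyz, atoms["CA"].xyz)
        out.append((rid, frame, atoms))
    return out


def _clamped(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 0.0, 1.0)


def map_protein_mif(structure: Structure, fn: MIFResults, grid: BoxGridValues,
                    options: MapOptions = MapOptions(),
                    ligand_atoms: list[Atom] | None = None) -> MIFMap:
    """Evaluate the fitted function over a laboratory-frame box grid.

    Per voxel: the maximum clamped strength over all residue frames whose
    carbonyl oxygen lies within the trusted domain, zeroed inside the steric
    radius of any protein heavy atom.  With ``ligand_atoms`` and
    ``options.ligand_mask_radius`` set, only voxels near the ligand are
    evaluated (the rest stay 0), mirroring binding-site-focused maps.

    Raises
    ------
    ValueError
        If the structure has no complete backbone carbonyl.
    """
    frames = residue_frames(structure)
    if not frames:
        raise ValueError("structure has no complete backbone carbonyl residue")

    coords = grid.point_coordinates()
    n_pts = coords.shape[0]
    values = np.zeros(n_pts)
    contributor = np.full(n_pts, -1, dtype=np.int32)

    active = np.ones(n_pts, dtype=bool)
    if ligand_atoms is not None and options.ligand_mask_radius is not None:
        active = ligand_site_mask(grid, ligand_atoms, options.ligand_mask_radius).reshape(-1)

    heavy = protein_heavy_atom_coords(structure)
    if heavy.shape[0]:
        steric_tree = cKDTree(heavy)
        blocked = steric_tree.query_ball_point(coords, options.steric_radius)
        blocked_mask = np.fromiter((len(b) > 0 for b in blocked), dtype=bool, count=n_pts)
        active &= ~blocked_mask

    point_tree = cKDTree(coords)
    for res_idx, (_, frame, _) in enumerate(frames):
        cand = point_tree.query_ball_point(frame.origin, options.r_max_domain)
        cand = np.asarray([i for i in cand if active[i]], dtype=np.intp)
        if cand.size == 0:
            continue
        local = lab_to_molecular(frame, coords[cand])
        radii = np.linalg.norm(local, axis=1)
        in_domain = (radii >= options.r_min_domain) & (radii <= options.r_max_domain)
        if not np.any(in_domain):
            continue
        cand = cand[in_domain]
        strengths = _clamped(fn.evaluate(local[in_domain]))
        better = strengths > values[cand]
        upd = cand[better]
        values[upd] = strengths[better]
        contributor[upd] = res_idx

    grid_out = BoxGridValues(origin=grid.origin.copy(), spacing=grid.spacing,
                             dims=grid.dims, values=values.reshape(grid.dims))
    return MIFMap(grid=grid_out, contributor=contributor.reshape(grid.dims),
                  residue_ids=[rid for rid, _, _ in frames], options=options)


def strength_at_point(structure: Structure, fn: MIFResults, point_lab,
                      options: MapOptions = MapOptions()) -> tuple[float, str | None]:
    """Mapped strength and contributing residue at one laboratory-frame point.

    Applies the same max-over-residues rule, trusted-domain cutoff and steric
    mask as :func:`map_protein_mif`.
    """
    frames = residue_frames(structure)
    if not frames:
        raise ValueError("structure has no complete backbone carbonyl residue")
    point_lab = np.asarray(point_lab, dtype=float)

    heavy = protein_heavy_atom_coords(structure)
    if heavy.shape[0]:
        d_min = np.min(np.linalg.norm(heavy - point_lab, axis=1))
        if d_min <= options.steric_radius:
            return 0.0, None

    best, best_rid = 0.0, None
    for rid, frame, _ in frames:
        local = lab_to_molecular(frame, point_lab)
        r = float(np.linalg.norm(local))
        if r < options.r_min_domain or r > options.r_max_domain:
            continue
        s = float(_clamped(np.atleast_1d(fn.evaluate(local)))[0])
        if s > best:
            best, best_rid = s, rid
    return best, best_rid


def ligand_site_mask(grid: BoxGridValues, ligand_atoms: list[Atom],
                     radius: float = 4.0) -> np.ndarray:
    """Boolean voxel mask: True within ``radius`` of any ligand heavy atom.

    Raises
    ------
    ValueError
        If the ligand selection is empty.
    """
    if not ligand_atoms:
        raise ValueError("ligand selection is empty")
    heavy = np.array([a.xyz for a in ligand_atoms if a.element.upper() != "H"])
    mask = np.zeros(grid.dims, dtype=bool)
    if heavy.size == 0 or radius <= 0:
        return mask
    coords = grid.point_coordinates()
    tree = cKDTree(heavy)
    d, _ = tree.query(coords, k=1)
    return (d <= radius).reshape(grid.dims)


def theta_phi_map(fn: MIFResults, d: float, theta_step: float = 10.0,
                  phi_step: float = 10.0) -> np.ndarray:
    """Clamped strength over orientation space at fixed radius ``d``.

    Rows run over the polar angle theta (0..180 inclusive), columns over the
    azimuth phi ([0, 360) in ``phi_step`` increments).  theta = 180 - Theta2
    and phi = 180 + Psi link the axes to halogen-bond parameters.
    """
    if d <= 0:
        raise ValueError("radius d must be positive")
    thetas = np.arange(0.0, 180.0 + 0.5 * theta_step, theta_step)
    phis = np.arange(0.0, 360.0, phi_step)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    pts = spherical_to_cartesian(d, tt.ravel(), pp.ravel())
    vals = _clamped(fn.evaluate(pts))
    return vals.reshape(tt.shape)


def _nearest_carbon(ligand_atoms: list[Atom], halogen: Atom) -> Atom:
    carbons = [a for a in ligand_atoms if a.element.upper() == "C"]
    if not carbons:
        raise ValueError("ligand has no carbon atom to define the C-X axis")
    dists = [np.linalg.norm(a.xyz - halogen.xyz) for a in carbons]
    return carbons[int(np.argmin(dists))]


def survey_halogen_bonds(structure: Structure, fn: MIFResults, ligand_code: str,
                         options: MapOptions = MapOptions(),
                         halogen_elements=("CL", "BR", "I")) -> list[StrengthRecord]:
    """Evaluate mapped strengths at every ligand halogen and report the
    halogen-bond geometry against the contributing residue.

    The contributing residue is the argmax of the mapping rule at the halogen
    position; when no residue contributes (strength 0), the geometrically
    nearest carbonyl oxygen is used for the geometry columns.
    """
    ligand_atoms = select_ligand_atoms(structure, ligand_code)
    if not ligand_atoms:
        raise ValueError(f"no HETATM atoms with residue name {ligand_code!r}")
    halogens = select_halogen_atoms(ligand_atoms, elements=halogen_elements)
    frames = residue_frames(structure)
    if not frames:
        raise ValueError("structure has no complete backbone carbonyl residue")
    by_rid = {rid: atoms for rid, _, atoms in frames}

    records = []
    for hal in halogens:
        strength, rid = strength_at_point(structure, fn, hal.xyz, options)
        if rid is None:
            # nearest carbonyl oxygen defines the reported geometry
            dists = [np.linalg.norm(atoms["O"].xyz - hal.xyz) for _, _, atoms in frames]
            rid = frames[int(np.argmin(dists))][0]
        res_atoms = by_rid[rid]
        donor_c = _nearest_carbon(ligand_atoms, hal)
        geom = halogen_bond_geometry(
            donor_c.xyz, hal.xyz,
            res_atoms["N"].xyz, res_atoms["CA"].xyz, res_atoms["C"].xyz, res_atoms["O"].xyz,
        )
        chain, resname = rid.split(":", 1)
        records.append(StrengthRecord(
            pdb_id=structure.name, chain=chain, residue=resname,
            ligand=ligand_code.upper(), halogen_name=hal.name,
            d=geom.d, theta1=geom.theta1, theta2=geom.theta2, psi=geom.psi,
            strength=strength,
        ))
    return records


def survey_to_csv(records: list[StrengthRecord], path, protein: str = "") -> None:
    """Write survey records in the tabular layout used for bond surveys."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "protein": [protein] * len(records),
            "pdb_id": [r.pdb_id for r in records],
            "chain": [r.chain for r in records],
            "residue": [r.residue for r in records],
            "ligand": [r.ligand for r in records],
            "halogen": [r.halogen_name for r in records],
            "d": [round(r.d, 2) for r in records],
            "theta1": [round(r.theta1, 2) for r in records],
            "theta2": [round(r.theta2, 2) for r in records],
            "psi": [None if r.psi is None else round(r.psi, 2) for r in records],
            "strength": [round(r.strength, 2) for r in records],
        }
    )
    df.to_csv(path, index=False)
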