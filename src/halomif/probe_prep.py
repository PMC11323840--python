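"""Halobenzene probe placement for external quantum-chemistry energy stages.

For every spherical grid point the probe is rigidly moved so its halogen sits
on the grid point and its molecular axis M (along the C-X bond, ipso carbon
to halogen) points down the vector G_n from the grid point to the acceptor
carbonyl oxygen -- the sigma-hole faces the acceptor.  Only the geometry
preparation lives here; the interaction energies themselves come from
external software (or the synthetic surrogate).

The rotation taking M onto G_n leaves a torsion about the C-X axis free; the
minimal rotation (axis M x G_n) is used, so the ring plane keeps its initial
orientation as far as possible.  For the antiparallel case the probe is
flipped 180 degrees about the ring-plane normal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import GridPoint

__all__ = [
    "ProbeGeometry",
    "ProbePlacement",
    "make_halobenzene",
    "orient_probe",
    "export_qm_geometries",
    "read_xyz_blocks",
]

# bond lengths, angstrom
_RING_CC = 1.39
_CH = 1.08
_CX = {"F": 1.35, "CL": 1.74, "BR": 1.90, "I": 2.10}


@dataclass(frozen=True)
class ProbeGeometry:
    """Probe molecule: element symbols + coordinates and the C-X bond atoms."""

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    carbon_index: int
    halogen_index: int

    def __post_init__(self) -> None:
        if self.carbon_index == self.halogen_index:
            raise ValueError("carbon and halogen indices must differ")
        if np.linalg.norm(self.m_axis_raw) <= 0:
            raise ValueError("C-X distance must be positive")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a[0] for a in self.atoms)

    @property
    def m_axis_raw(self) -> np.ndarray:
        """Unnormalized molecular axis: halogen position minus ipso carbon."""
        c = self.coords
        return c[self.halogen_index] - c[self.carbon_index]


@dataclass(frozen=True)
class ProbePlacement:
    """Oriented probe at one grid point."""

    grid_point: GridPoint
    G_n: tuple[float, float, float]
    oriented_atoms: tuple[tuple[str, tuple[float, float, float]], ...]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.oriented_atoms], dtype=float)


def make_halobenzene(halogen: str = "Cl") -> ProbeGeometry:
    """Idealized planar halobenzene: hexagonal ring (C-C 1.39 A), five
    hydrogens, halogen on C1 along +x.  Ring lies in the z = 0 plane."""
    hx = halogen.upper()
    if hx not in _CX:
        raise ValueError(f"unsupported halogen: {halogen!r}")
    ring_r = _RING_CC  # hexagon circumradius equals its side length
    atoms: list[tuple[str, tuple[float, float, float]]] = []
    for i in range(6):
        ang = np.deg2rad(60.0 * i)
        atoms.append(("C", (ring_r * np.cos(ang), ring_r * np.sin(ang), 0.0)))
    # halogen on C1 (index 0), pointing outward along +x
    atoms.append((halogen.capitalize(), (ring_r + _CX[hx], 0.0, 0.0)))
    for i in range(1, 6):
        ang = np.deg2rad(60.0 * i)
        rr = ring_r + _CH
        atoms.append(("H", (rr * np.cos(ang), rr * np.sin(ang), 0.0)))
    return ProbeGeometry(atoms=tuple(atoms), carbon_index=0, halogen_index=6)


def _rotation_aligning(m_hat: np.ndarray, g_hat: np.ndarray, plane_normal: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector m_hat onto g_hat.

    Minimal rotation about m x g; exactly antiparallel vectors rotate 180
    degrees about the supplied plane normal (made perpendicular to m first).
    """
    axis = np.cross(m_hat, g_hat)
    s = np.linalg.norm(axis)
    c = float(np.dot(m_hat, g_hat))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 deg about a deterministic axis perpendicular to m
        n = plane_normal - np.dot(plane_normal, m_hat) * m_hat
        if np.linalg.norm(n) < 1e-12:  # normal degenerate w.r.t. m
            n = np.cross(m_hat, np.array([1.0, 0.0, 0.0]))
            if np.linalg.norm(n) < 1e-12:
                n = np.cross(m_hat, np.array([0.0, 1.0, 0.0]))
        n = n / np.linalg.norm(n)
        return 2.0 * np.outer(n, n) - np.eye(3)
    axis = axis / s
    angle = np.arctan2(s, c)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _ring_normal(probe: ProbeGeometry) -> np.ndarray:
    c = probe.coords
    # normal of the plane through the first three ring atoms
    n = np.cross(c[1] - c[0], c[2] - c[0])
    norm = np.linalg.norm(n)
    return n / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])


def orient_probe(probe: ProbeGeometry, grid_point: GridPoint, target_O) -> ProbePlacement:
    """Rigidly place ``probe`` at ``grid_point`` facing ``target_O``.

    After placement the halogen sits on the grid point and the C->X axis is
    parallel to G_n = target_O - grid_point.

    Raises
    ------
    ValueError
        If the grid point coincides with the target oxygen (zero-length G_n).
    """
    target_O = np.asarray(target_O, dtype=float)
    gp = np.asarray(grid_point.position, dtype=float)
    G = target_O - gp
    norm_G = np.linalg.norm(G)
    if norm_G < 1e-12:
        raise ValueError("grid point coincides with target oxygen: G_n undefined")
    g_hat = G / norm_G
    m = probe.m_axis_raw
    m_hat = m / np.linalg.norm(m)
    R = _rotation_aligning(m_hat, g_hat, _ring_normal(probe))
    coords = probe.coords
    x_old = coords[probe.halogen_index]
    rotated = (coords - x_old) @ R.T  # rotate about the halogen, then shift
    placed = rotated + gp
    atoms = tuple(
        (el, tuple(pos)) for el, pos in zip(probe.elements, placed)
    )
    return ProbePlacement(grid_point=grid_point, G_n=tuple(g_hat), oriented_atoms=atoms)


def export_qm_geometries(placements: list[ProbePlacement], target_model, path,
                         manifest_path=None) -> None:
    """Write one multi-block XYZ file (target + oriented probe per grid
    point) plus an optional manifest CSV mapping block index -> grid index.

    ``target_model`` is any object with ``atoms`` like ProbeGeometry's (an
    (element, xyz) sequence), e.g. the model amide in laboratory = molecular
    coordinates.
    """
    if not placements:
        raise ValueError("placements must be non-empty")
    path = Path(path)
    target_atoms = list(getattr(target_model, "atoms", target_model))
    with open(path, "w") as fh:
        for block_index, pl in enumerate(placements):
            n_atoms = len(target_atoms) + len(pl.oriented_atoms)
            fh.write(f"{n_atoms}\n")
            fh.write(f"block={block_index} n={pl.grid_point.n} "
                     f"r={pl.grid_point.r:.4f} theta={pl.grid_point.theta:.2f} "
                     f"phi={pl.grid_point.phi:.2f}\n")
            for el, (x, y, z) in list(target_atoms) + list(pl.oriented_atoms):
                fh.write(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["block_index", "grid_index"])
            for block_index, pl in enumerate(placements):
                writer.writerow([block_index, pl.grid_point.n])


def read_xyz_blocks(path) -> list[list[tuple[str, tuple[float, float, float]]]]:
    """Parse a multi-block XYZ file back into per-block atom lists."""
    blocks = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        atoms = []
        for line in lines[i + 2: i + 2 + n]:
            parts = line.split()
            atoms.append((parts[0], (float(parts[1]), float(parts[2]), float(parts[3]))))
        blocks.append(atoms)
        i += 2 + n
    return blocks
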