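"""Sampling grids: the spherical shell grid around the model amide and the
Cartesian box grids laid around whole proteins.

The spherical grid reproduces the interaction-field sampling protocol: radii
2-7 A in 0.5 A steps, polar and azimuth angles in 10 degree steps.  The
azimuth seam (360 == 0) and the poles (polar 0 and 180, where azimuth is
degenerate) are emitted once so no direction is double-weighted in the
least-squares fit.  Points are indexed radius-major, then polar, then azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SphericalGridSpec",
    "GridPoint",
    "BoxGridValues",
    "model_spherical_grid",
    "box_grid",
    "spherical_to_cartesian",
    "write_samples_csv",
    "read_samples_csv",
]

SAMPLE_CSV_COLUMNS = ["n", "u", "v", "w", "r", "theta", "phi", "energy"]


@dataclass(frozen=True)
class SphericalGridSpec:
    """Spherical sampling grid: radii in angstrom, angle steps in degrees."""

    r_min: float = 2.0
    r_max: float = 7.0
    r_step: float = 0.5
    polar_step: float = 10.0
    azimuth_step: float = 10.0

    def __post_init__(self) -> None:
        if self.r_min < 0:
            raise ValueError("r_min must be non-negative")
        if self.r_max < self.r_min:
            raise ValueError("r_max must be >= r_min")
        if min(self.r_step, self.polar_step, self.azimuth_step) <= 0:
            raise ValueError("steps must be positive")


@dataclass(frozen=True)
class GridPoint:
    """One sampling point: dense index, Cartesian molecular-frame position,
    and the generating spherical coordinates (r in A, theta/phi degrees)."""

    n: int
    position: tuple[float, float, float]
    r: float
    theta: float
    phi: float


@dataclass
class BoxGridValues:
    """Regular Cartesian box grid of strengths with value bookkeeping.

    ``values[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` (laboratory
    frame, angstrom).  Strengths live in [0, 1].
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.dims):
            raise ValueError("values shape must equal dims")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def point_coordinates(self) -> np.ndarray:
        """All grid-node laboratory coordinates, shape (n_points, 3),
        x fastest-varying last (C index order of ``values``)."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + idx * self.spacing


def spherical_to_cartesian(r, theta_deg, phi_deg):
    """Map (r, polar theta, azimuth phi) in degrees to (u, v, w).

    The polar axis is w; theta = 0 points along +w and phi is measured from
    +u toward +v.
    """
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    st = np.sin(th)
    return np.stack(
        [r * st * np.cos(ph), r * st * np.sin(ph), r * np.cos(th)], axis=-1
    )


def model_spherical_grid(spec: SphericalGridSpec = SphericalGridSpec()) -> list[GridPoint]:
    """Enumerate the spherical sampling grid.

    Radii run r_min..r_max inclusive; polar 0..180 inclusive; azimuth covers
    [0, 360).  At the poles only azimuth 0 is kept.  With the default spec
    this yields 11 shells x (17 x 36 + 2) = 6754 points.
    """
    n_r = int(round((spec.r_max - spec.r_min) / spec.r_step)) + 1
    radii = spec.r_min + spec.r_step * np.arange(n_r)
    n_th = int(round(180.0 / spec.polar_step)) + 1
    thetas = np.linspace(0.0, 180.0, n_th)
    n_ph = int(round(360.0 / spec.azimuth_step))
    phis = spec.azimuth_step * np.arange(n_ph)

    points: list[GridPoint] = []
    n = 0
    for r in radii:
        for theta in thetas:
            az = (0.0,) if theta in (0.0, 180.0) else phis
            for phi in az:
                pos = spherical_to_cartesian(float(r), float(theta), float(phi))
                points.append(
                    GridPoint(n=n, position=tuple(pos), r=float(r), theta=float(theta), phi=float(phi))
                )
                n += 1
    return points


def box_grid(center, n_per_axis: int, spacing: float) -> BoxGridValues:
    """Zero-initialized cubic box grid of ``n_per_axis**3`` points centred on
    ``center`` (laboratory frame)."""
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center = np.asarray(center, dtype=float)
    half = spacing * (n_per_axis - 1) / 2.0
    origin = center - half
    dims = (n_per_axis,) * 3
    return BoxGridValues(origin=origin, spacing=float(spacing), dims=dims, values=np.zeros(dims))


def grid_positions(points: list[GridPoint]) -> np.ndarray:
    """Stack GridPoint positions into an (N, 3) array."""
    return np.array([p.position for p in points], dtype=float)


def write_samples_csv(path, points: list[GridPoint], energies) -> None:
    """Write the sample exchange CSV (n, u, v, w, r, theta, phi, energy) that
    couples the external energy stage to fitting."""
    energies = np.asarray(energies, dtype=float)
    if len(energies) != len(points):
        raise ValueError("one energy per grid point required")
    df = pd.DataFrame(
        {
            "n": [p.n for p in points],
            "u": [p.position[0] for p in points],
            "v": [p.position[1] for p in points],
            "w": [p.position[2] for p in points],
            "r": [p.r for p in points],
            "theta": [p.theta for p in points],
            "phi": [p.phi for p in points],
            "energy": energies,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_samples_csv(path) -> pd.DataFrame:
    """Read a sample CSV; validates the column contract."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample file {Path(path)} missing columns: {missing}")
    return df
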