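"""Synthetic surrogate interaction fields for testing fitting and mapping.

Quantum-chemistry energy surfaces for the amide/halobenzene pair are produced
by external software and are not available at desk scale, so this module
generates datasets with the same qualitative anatomy: an anisotropic
halogen-bond well with a radial minimum near 3.0-3.3 A, an angular preference
concentrated in one hemisphere of the acceptor frame, a short-range repulsive
wall, and strengths normalized to [0, 1].

The closed form is deliberately an exponential-of-cosine angular weight times
a radial Gaussian well -- smooth, but NOT inside the Cartesian-Gaussian span,
so fitting it exercises genuine approximation rather than interpolation.

:func:`span_dataset` instead produces data exactly inside the basis span, the
input for exact-recovery oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgf_basis import CGFBasis, evaluate_basis
from .fitting import MIFSample, normalize_energies
from .grids import GridPoint

__all__ = ["SurrogateParams", "surrogate_mif", "span_dataset", "synthetic_bond_site"]


@dataclass(frozen=True)
class SurrogateParams:
    """Shape parameters of the surrogate halogen-bond well.

    d0            radial position of the energy minimum (A); 3.2 matches the
                  average O...I separation seen in protein/ligand surveys.
    depth         well depth (kcal/mol, negative); -3.92 is the iodobenzene
                  reference minimum.
    radial_width  Gaussian width of the radial well (A).
    hemisphere_bias  "north" concentrates the well at polar angles < 90 deg
                  (the typical C-X...O=C geometry, Theta2 > 90); "equator"
                  concentrates it around the equatorial belt (the
                  chlorobenzene-like pattern).
    angular_kappa concentration of the angular weight (dimensionless, >= 0);
                  larger = tighter lobe.
    azimuth_mod   mild azimuthal modulation depth in [0, 1) exercising the
                  torsional (phi) dependence of real fields.
    noise_sd      Gaussian noise added to normalized strengths.
    seed          RNG seed; identical seeds give identical datasets.
    """

    d0: float = 3.2
    depth: float = -3.92
    radial_width: float = 0.5
    hemisphere_bias: str = "north"
    angular_kappa: float = 4.0
    azimuth_mod: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth >= 0:
            raise ValueError("depth must be negative (an attractive well)")
        if self.radial_width <= 0:
            raise ValueError("radial_width must be positive")
        if self.hemisphere_bias not in ("north", "equator"):
            raise ValueError("hemisphere_bias must be 'north' or 'equator'")
        if self.angular_kappa < 0:
            raise ValueError("angular_kappa must be >= 0")
        if not 0.0 <= self.azimuth_mod < 1.0:
            raise ValueError("azimuth_mod must be in [0, 1)")


def _angular_weight(theta_rad: np.ndarray, phi_rad: np.ndarray, params: SurrogateParams) -> np.ndarray:
    """Smooth angular weight in (0, 1], concentrated per hemisphere_bias."""
    cos_t = np.cos(theta_rad)
    if params.hemisphere_bias == "north":
        base = np.exp(params.angular_kappa * (cos_t - 1.0))
    else:
        base = np.exp(-params.angular_kappa * cos_t**2)
    # gentle torsional preference peaking at phi = 0 (the Calpha side)
    azim = 1.0 - params.azimuth_mod * 0.5 * (1.0 - np.cos(phi_rad))
    return base * azim


def surrogate_mif(grid: list[GridPoint], params: SurrogateParams = SurrogateParams()) -> list[MIFSample]:
    """Generate surrogate samples on a spherical grid.

    Raw energies (kcal/mol): a radial Gaussian well centred at ``d0`` scaled
    by the angular weight, plus a steep repulsive wall inside
    ``d0 - 2 * radial_width``.  Raw energies are normalized to strengths
    (repulsive points -> 0, minimum -> 1); optional Gaussian noise is added
    to the strengths and the result re-clamped to [0, 1].
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    r = np.array([p.r for p in grid], dtype=float)
    theta = np.deg2rad([p.theta for p in grid])
    phi = np.deg2rad([p.phi for p in grid])

    well = params.depth * np.exp(-(((r - params.d0) / params.radial_width) ** 2))
    raw = well * _angular_weight(theta, phi, params)

    r_wall = params.d0 - 2.0 * params.radial_width
    inside = r < r_wall
    if np.any(inside):
        # steep positive wall dominating any attraction inside the core
        raw = raw + np.where(
            inside, abs(params.depth) * 10.0 * ((r_wall / np.maximum(r, 1e-6)) ** 12), 0.0
        )

    values = normalize_energies(raw)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
        values = np.clip(values, 0.0, 1.0)
    return [
        MIFSample(n=p.n, position=p.position, value=float(values[i]), raw_energy=float(raw[i]))
        for i, p in enumerate(grid)
    ]


def span_dataset(basis: CGFBasis, coefficients, grid: list[GridPoint]) -> list[MIFSample]:
    """Samples lying exactly in the basis span (no clamping, no noise)."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[0] != len(basis):
        raise ValueError("coefficient count must equal basis size")
    positions = np.array([p.position for p in grid], dtype=float)
    values = evaluate_basis(basis, positions) @ coefficients
    return [
        MIFSample(n=p.n, position=p.position, value=float(values[i]))
        for i, p in enumerate(grid)
    ]


def synthetic_bond_site(d: float, theta1: float, theta2: float, psi: float,
                        cx_bond: float = 1.8) -> dict[str, np.ndarray]:
    """SYNTHETIC coordinates realizing a given halogen-bond geometry.

    Builds an idealized planar amide fragment (N, CA, C, O; C=O 1.23 A,
    C-CA 1.52 A at 121 deg, C-N 1.33 A at 116 deg, all in the u-w plane)
    and places a halogen X plus its donor carbon so that the four
    halogen-bond parameters take exactly the requested values.  This is a
    synthetic stand-in for deposited crystal coordinates -- useful for
    checking that geometry computation and printed survey parameters are
    mutually consistent, not a reconstruction of any real structure.

    Parameters are in angstrom/degrees; ``cx_bond`` is the donor C-X bond
    length.  Returns a dict with keys N, CA, C, O, X, C_donor.
    """
    from .grids import spherical_to_cartesian

    O = np.zeros(3)
    C = np.array([0.0, 0.0, -1.23])
    # angles measured from the C->O (+w) direction; CA on the +u side,
    # N on the -u side, all exactly in the amide plane
    ang_ca = np.deg2rad(121.0)
    CA = C + 1.52 * np.array([np.sin(ang_ca), 0.0, np.cos(ang_ca)])
    ang_n = np.deg2rad(116.0)
    N = C + 1.33 * np.array([-np.sin(ang_n), 0.0, np.cos(ang_n)])

    theta = 180.0 - theta2
    phi = (180.0 + psi) % 360.0
    X = O + spherical_to_cartesian(d, theta, phi)

    e1 = (O - X) / np.linalg.norm(O - X)
    # deterministic perpendicular to e1 for the donor-carbon direction
    ref = np.array([0.0, 0.0, 1.0])
    perp = np.cross(e1, ref)
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(e1, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    t1 = np.deg2rad(theta1)
    C_donor = X + cx_bond * (np.cos(t1) * e1 + np.sin(t1) * perp)
    return {"N": N, "CA": CA, "C": C, "O": O, "X": X, "C_donor": C_donor}
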