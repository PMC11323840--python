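"""Shared fixtures: coarse grids, toy structures and prefit functions."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halomif.cgf_basis import enumerate_basis
from halomif.fitting import MIFModel, MIFResults
from halomif.grids import SphericalGridSpec, model_spherical_grid
from halomif.structures_io import Atom, Structure
from halomif.synthetic import SurrogateParams, surrogate_mif

# Table 2-style reference rows used by geometry checks:
# (pdb_id, chain, residue, ligand, d, theta1, theta2, psi, strength)
BOND_SURVEY_ROWS = [
    ("1IEI", "A", "Val47", "ZES", 3.15, 156.94, 98.87, -86.63, 0.85),
    ("1P5E", "A", "Leu83", "TBS", 2.90, 164.70, 131.98, 137.32, 0.59),
    ("1P5E", "A", "Ile10", "TBS", 3.24, 144.08, 110.05, -85.12, 0.96),
    ("1P5E", "A", "Glu81", "TBS", 3.01, 168.55, 154.87, -41.29, 0.67),
    ("1ETA", "1", "Ala109", "T44", 3.13, 149.45, 106.13, -89.20, 0.93),
    ("1HK4", "A", "Asn429", "T44", 3.21, 132.53, 113.58, -152.51, 0.00),
]


@pytest.fixture(scope="session")
def full_basis():
    return enumerate_basis()


@pytest.fixture(scope="session")
def paper_grid():
    return model_spherical_grid(SphericalGridSpec())


@pytest.fixture(scope="session")
def coarse_grid():
    """Small spherical grid (fast tests): 2-5 A / 1 A, 30 degree steps."""
    return model_spherical_grid(
        SphericalGridSpec(r_min=2.0, r_max=5.0, r_step=1.0, polar_step=30.0, azimuth_step=30.0)
    )


@pytest.fixture(scope="session")
def small_fit(coarse_grid):
    """Surrogate field fitted with a modest (degree <= 3) basis."""
    basis = enumerate_basis(max_degree=3)
    samples = surrogate_mif(coarse_grid, SurrogateParams())
    return MIFModel.from_samples(samples, basis=basis, probe="I").fit()


def amide_atoms(serial0: int, chain: str, resnum: int, resname: str = "GLY",
                rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)):
    """Atom records of one idealized planar amide residue, rigidly placed."""
    R = np.eye(3) if rotation is None else rotation
    t = np.asarray(translation, dtype=float)
    local = {
        "O": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.0, 0.0, -1.23]),
        "CA": np.array([1.30, 0.0, -2.01]),
        "N": np.array([-1.20, 0.0, -1.81]),
    }
    atoms = []
    for i, name in enumerate(("N", "CA", "C", "O")):
        pos = R @ local[name] + t
        atoms.append(Atom(serial=serial0 + i, name=name, element=name[0],
                          residue_name=resname, chain_id=chain,
                          residue_number=resnum, position=tuple(pos)))
    return atoms


@pytest.fixture
def single_residue_structure():
    return Structure(atoms=amide_atoms(1, "A", 1), name="toy1")


@pytest.fixture
def two_residue_structure():
    rot = Rotation.from_euler("zyx", [40.0, -25.0, 70.0], degrees=True).as_matrix()
    atoms = amide_atoms(1, "A", 1)
    atoms += amide_atoms(5, "A", 2, rotation=rot, translation=(6.0, 2.0, -1.0))
    return Structure(atoms=atoms, name="toy2")


AXIS_ALIGNED_PDB = """\
ATOM      1  N   GLY A   1      -1.200   0.000  -1.810  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.300   0.000  -2.010  1.00  0.00           C
ATOM      3  C   GLY A   1       0.000   0.000  -1.230  1.00  0.00           C
ATOM      4  O   GLY A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    5 CL1  LIG A 101       3.000   0.000   0.000  1.00  0.00          CL
HETATM    6  C7  LIG A 101       5.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def axis_aligned_pdb(tmp_path):
    """Toy PDB: residue frame axis-aligned, ligand Cl at (3, 0, 0).

    By construction d = 3.0, theta1 = 180, theta2 = 90 for the Cl...O pair.
    """
    path = tmp_path / "axis_aligned.pdb"
    path.write_text(AXIS_ALIGNED_PDB)
    return path
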