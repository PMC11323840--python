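"""Residue-local coordinate frames and halogen-bond geometric parameters.

Each backbone carbonyl defines a right-handed molecular frame (o-uvw): origin
at the carbonyl oxygen, w along the C->O bond, u in the O=C-Calpha plane
pointing toward the Calpha side, v = w x u.  A halogen bond to that carbonyl
is described by four parameters:

* d       -- O...X distance (A)
* theta1  -- donor-side angle C-X-O at the halogen (deg)
* theta2  -- acceptor-side angle X-O-C at the oxygen (deg)
* psi     -- torsion N-C-O-X about the C-O axis, signed, (-180, 180] (deg)

In the residue frame the halogen's spherical coordinates obey
theta = 180 - theta2 (polar) and phi = 180 + psi (azimuth, mod 360); the
northern hemisphere of the frame (w-component > 0) corresponds to
theta2 > 90, where typical C-X...O=C halogen bonds sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Frame",
    "HalogenBondGeometry",
    "DegenerateFrameError",
    "build_residue_frame",
    "lab_to_molecular",
    "molecular_to_lab",
    "halogen_bond_geometry",
    "dihedral_angle",
]

_COLLINEAR_TOL = 1e-6  # radians


class DegenerateFrameError(ValueError):
    """Raised when the defining atoms are coincident or collinear."""


@dataclass(frozen=True)
class Frame:
    """Residue molecular frame: origin (carbonyl O) and orthonormal axes."""

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    w_axis: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """Rows u, v, w: multiplies lab displacement vectors into (u,v,w)."""
        return np.stack([self.u_axis, self.v_axis, self.w_axis])


@dataclass(frozen=True)
class HalogenBondGeometry:
    """Halogen-bond geometry; angles in degrees, distance in angstrom.

    ``psi`` is None when the torsion is undefined (collinear frame); the
    derived azimuth ``phi`` is then None as well.
    """

    d: float
    theta1: float
    theta2: float
    psi: float | None

    @property
    def theta(self) -> float:
        """Polar angle in the residue frame: 180 - theta2."""
        return 180.0 - self.theta2

    @property
    def phi(self) -> float | None:
        """Azimuth in the residue frame: 180 + psi, wrapped to [0, 360)."""
        if self.psi is None:
            return None
        return (180.0 + self.psi) % 360.0


def _unit(vec: np.ndarray, what: str = "vector") -> np.ndarray:
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise DegenerateFrameError(f"zero-length {what}")
    return vec / norm


def build_residue_frame(O, C, CA) -> Frame:
    """Construct the o-uvw frame from carbonyl O, carbonyl C and Calpha.

    w = unit(O - C); u is the component of (CA - C) perpendicular to w,
    normalized, so u.(CA - C) > 0; v = w x u closes a right-handed triad.

    Raises
    ------
    DegenerateFrameError
        If O == C or the three atoms are collinear (angle < 1e-6 rad).
    """
    O = np.asarray(O, dtype=float)
    C = np.asarray(C, dtype=float)
    CA = np.asarray(CA, dtype=float)
    w = _unit(O - C, "C->O axis")
    ca_dir = CA - C
    perp = ca_dir - np.dot(ca_dir, w) * w
    # sin(angle between CA-C and w) ~ |perp| / |ca_dir|
    if np.linalg.norm(ca_dir) < 1e-12 or np.linalg.norm(perp) < _COLLINEAR_TOL * np.linalg.norm(ca_dir):
        raise DegenerateFrameError("O, C, CA are collinear or coincident")
    u = perp / np.linalg.norm(perp)
    v = np.cross(w, u)
    return Frame(origin=O, u_axis=u, v_axis=v, w_axis=w)


def lab_to_molecular(frame: Frame, p_lab) -> np.ndarray:
    """Laboratory coordinates -> (u, v, w) components in the residue frame.

    Accepts a single 3-vector or an (N, 3) array.
    """
    p = np.asarray(p_lab, dtype=float)
    return (p - frame.origin) @ frame.rotation.T


def molecular_to_lab(frame: Frame, p_mol) -> np.ndarray:
    """Inverse of :func:`lab_to_molecular`."""
    p = np.asarray(p_mol, dtype=float)
    return p @ frame.rotation + frame.origin


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(p1, p2, p3, p4) -> float | None:
    """Signed torsion p1-p2-p3-p4 in degrees, IUPAC convention, (-180, 180].

    Returns None when either bonded triple is collinear (torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return None
    b2u = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2u)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def halogen_bond_geometry(C_donor, X, N, CA, C, O) -> HalogenBondGeometry:
    """Halogen-bond parameters for donor carbon/halogen against one residue.

    Parameters
    ----------
    C_donor : 3-vector
        Carbon covalently bound to the halogen (ipso carbon of a halobenzene).
    X : 3-vector
        Halogen position.
    N, CA, C, O : 3-vectors
        Backbone atoms of the acceptor residue.
    """
    C_donor, X, N, CA, C, O = (np.asarray(p, dtype=float) for p in (C_donor, X, N, CA, C, O))
    d = float(np.linalg.norm(O - X))
    if d < 1e-9:
        raise ValueError("halogen coincides with acceptor oxygen")
    theta1 = _angle_deg(C_donor - X, O - X)
    theta2 = _angle_deg(X - O, C - O)
    psi = dihedral_angle(N, C, O, X)
    return HalogenBondGeometry(d=d, theta1=theta1, theta2=theta2, psi=psi)
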