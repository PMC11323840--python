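"""Cartesian Gaussian function (CGF) basis for molecular-interaction-field expansion.

A CGF is the primitive ``g(u, v, w) = u^k v^l w^m exp(-alpha r^2)`` with
``r^2 = u^2 + v^2 + w^2``.  The degree ``k + l + m`` labels the angular type in
the usual quantum-chemistry letters: s (0), p (1), d (2), f (3), g (4), h (5),
i (6), j (7).  A degree-``L`` shell contains ``(L+1)(L+2)/2`` monomials.

The default basis couples every monomial of degree 0..7 with four width
exponents per degree (``DEFAULT_ALPHA_TABLE``), giving 4 x 120 = 480 functions.
Coordinates are residue-frame (o-uvw) positions in angstrom, so alpha carries
units of 1/angstrom^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CGFSpec",
    "CGFBasis",
    "DEFAULT_ALPHA_TABLE",
    "DEGREE_LETTERS",
    "enumerate_basis",
    "evaluate_basis",
]

DEGREE_LETTERS = "spdfghij"

# Four width exponents (1/A^2) per angular degree s..j.
DEFAULT_ALPHA_TABLE: dict[int, tuple[float, float, float, float]] = {
    0: (0.03, 0.08, 0.13, 0.18),
    1: (0.03, 0.08, 0.13, 0.18),
    2: (0.056, 0.106, 0.156, 0.206),
    3: (0.083, 0.133, 0.183, 0.233),
    4: (0.111, 0.161, 0.211, 0.261),
    5: (0.139, 0.189, 0.239, 0.289),
    6: (0.167, 0.217, 0.267, 0.317),
    7: (0.194, 0.244, 0.294, 0.344),
}


@dataclass(frozen=True)
class CGFSpec:
    """One Cartesian Gaussian: monomial exponents (k, l, m) and width alpha."""

    k: int
    l: int
    m: int
    alpha: float

    def __post_init__(self) -> None:
        if min(self.k, self.l, self.m) < 0:
            raise ValueError("monomial exponents must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def degree(self) -> int:
        return self.k + self.l + self.m

    @property
    def letter(self) -> str:
        return DEGREE_LETTERS[self.degree] if self.degree < len(DEGREE_LETTERS) else f"L{self.degree}"

    def __call__(self, point: Sequence[float]) -> float:
        u, v, w = point
        r2 = u * u + v * v + w * w
        return (u ** self.k) * (v ** self.l) * (w ** self.m) * np.exp(-self.alpha * r2)


@dataclass(frozen=True)
class CGFBasis:
    """Ordered collection of CGFs; deterministic order fixes coefficient files.

    Ordering is lexicographic in (degree, k, l, m), then by alpha index within
    the degree's exponent row.
    """

    functions: tuple[CGFSpec, ...]
    alpha_table: dict[int, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_ALPHA_TABLE))

    def __post_init__(self) -> None:
        keys = [(f.k, f.l, f.m, f.alpha) for f in self.functions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (k, l, m, alpha) in basis")

    def __len__(self) -> int:
        return len(self.functions)

    def __iter__(self):
        return iter(self.functions)

    def __getitem__(self, i: int) -> CGFSpec:
        return self.functions[i]

    def to_json(self) -> str:
        entries = [
            {"degree": f.degree, "k": f.k, "l": f.l, "m": f.m, "alpha": f.alpha}
            for f in self.functions
        ]
        return json.dumps({"functions": entries}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CGFBasis":
        data = json.loads(text)
        funcs = tuple(
            CGFSpec(e["k"], e["l"], e["m"], e["alpha"]) for e in data["functions"]
        )
        return cls(functions=funcs)


def _monomials(degree: int) -> list[tuple[int, int, int]]:
    """All (k, l, m) with k + l + m == degree, lexicographic in (k, l, m)."""
    out = []
    for k in range(degree, -1, -1):
        for l in range(degree - k, -1, -1):
            out.append((k, l, degree - k - l))
    return sorted(out)


def enumerate_basis(
    max_degree: int = 7,
    alpha_table: dict[int, Sequence[float]] | None = None,
) -> CGFBasis:
    """Build the CGF basis: every monomial of each degree with each of that
    degree's width exponents.

    With the defaults (degrees 0..7, four alphas per degree) the basis holds
    480 functions: 1+3+6+10+15+21+28+36 = 120 monomials per exponent column.

    Raises
    ------
    KeyError
        If ``alpha_table`` has no row for some degree <= ``max_degree``.
    """
    table = dict(DEFAULT_ALPHA_TABLE) if alpha_table is None else {k: tuple(v) for k, v in alpha_table.items()}
    funcs: list[CGFSpec] = []
    for degree in range(max_degree + 1):
        if degree not in table:
            raise KeyError(f"alpha table has no row for degree {degree}")
        for klm in _monomials(degree):
            for alpha in table[degree]:
                funcs.append(CGFSpec(*klm, alpha=float(alpha)))
    return CGFBasis(functions=tuple(funcs), alpha_table={k: tuple(v) for k, v in table.items()})


def evaluate_basis(basis: CGFBasis, points: np.ndarray) -> np.ndarray:
    """Evaluate every basis function at one or many molecular-frame points.

    Parameters
    ----------
    basis : CGFBasis
    points : array, shape (3,) or (N, 3)
        Positions (u, v, w) in angstrom.

    Returns
    -------
    array, shape (len(basis),) or (N, len(basis))
        ``g_i = u^k v^l w^m exp(-alpha r^2)`` in basis order.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError("points must have three components (u, v, w)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    max_pow = max((max(f.k, f.l, f.m) for f in basis), default=0)
    # power tables: pow_u[:, k] = u^k
    pow_u = np.ones((pts.shape[0], max_pow + 1))
    pow_v = np.ones_like(pow_u)
    pow_w = np.ones_like(pow_u)
    for p in range(1, max_pow + 1):
        pow_u[:, p] = pow_u[:, p - 1] * pts[:, 0]
        pow_v[:, p] = pow_v[:, p - 1] * pts[:, 1]
        pow_w[:, p] = pow_w[:, p - 1] * pts[:, 2]
    r2 = np.einsum("ij,ij->i", pts, pts)
    exp_cache: dict[float, np.ndarray] = {}
    out = np.empty((pts.shape[0], len(basis)))
    for i, f in enumerate(basis):
        damp = exp_cache.get(f.alpha)
        if damp is None:
            damp = exp_cache.setdefault(f.alpha, np.exp(-f.alpha * r2))
        out[:, i] = pow_u[:, f.k] * pow_v[:, f.l] * pow_w[:, f.m] * damp
    return out[0] if single else out
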