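"""Least-squares Gaussian expansion of molecular interaction fields.

The interaction field of the model amide with a halobenzene probe is a set of
samples (r_n, E_n): grid position in the molecular frame plus a normalized
bond strength in [0, 1].  The field is approximated as

    E_X(r) = sum_i c_i g_i(r),      g_i = u^k v^l w^m exp(-alpha r^2)

with coefficients chosen to minimize the squared residual

    Delta = sum_n (E_n - E_X(r_n))^2 .

Setting dDelta/dc = 0 yields the normal equations A c = B with
A_ji = sum_n g_j(r_n) g_i(r_n) and B_j = sum_n g_j(r_n) E_n, solved by
truncated SVD (minimum-norm solution when A is rank deficient).

The user-facing surface is :class:`MIFModel` / :class:`MIFResults`:

>>> model = MIFModel(strengths, positions, basis)
>>> res = model.fit()
>>> res.rsquared, res.delta
>>> res.evaluate(points)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cgf_basis import CGFBasis, enumerate_basis, evaluate_basis
from .grids import GridPoint, read_samples_csv

__all__ = [
    "MIFSample",
    "NormalEquations",
    "NormalizationError",
    "MIFModel",
    "MIFResults",
    "normalize_energies",
    "assemble_normal_equations",
    "solve_coefficients",
    "fit_mif",
    "evaluate_mif",
]


class NormalizationError(ValueError):
    """Raised when no attractive (negative) energy exists to normalize by."""


@dataclass(frozen=True)
class MIFSample:
    """One interaction-field sample: grid index, molecular-frame position (A),
    optional raw energy (kcal/mol) and normalized strength in [0, 1]."""

    n: int
    position: tuple[float, float, float]
    value: float
    raw_energy: float | None = None


@dataclass(frozen=True)
class NormalEquations:
    """The least-squares system A c = B over the basis."""

    A: np.ndarray
    B: np.ndarray


def normalize_energies(raw) -> np.ndarray:
    """Normalize raw interaction energies (kcal/mol) to strengths in [0, 1].

    The most stable (most negative) energy maps to 1; other attractive points
    scale linearly; repulsive points (E >= 0) are set to 0.

    Raises
    ------
    NormalizationError
        If no energy is attractive (min >= 0).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("at least one energy required")
    e_min = raw.min()
    if e_min >= 0:
        raise NormalizationError("no attractive (negative) energy; normalization undefined")
    out = np.where(raw < 0, raw / e_min, 0.0)
    return out


def assemble_normal_equations(positions, values, basis: CGFBasis) -> NormalEquations:
    """Build A_ji = sum_n g_j g_i and B_j = sum_n g_j E_n from samples."""
    G = evaluate_basis(basis, np.atleast_2d(np.asarray(positions, dtype=float)))
    values = np.asarray(values, dtype=float)
    A = G.T @ G
    A = 0.5 * (A + A.T)  # enforce exact symmetry against rounding
    B = G.T @ values
    return NormalEquations(A=A, B=B)


def solve_coefficients(eqs: NormalEquations, rcond: float = 1e-10) -> np.ndarray:
    """Minimum-norm least-squares solution of A c = B via truncated SVD.

    Singular values below ``rcond * sigma_max`` are discarded; for a
    full-rank, well-conditioned A this is the exact solve.
    """
    A, B = eqs.A, eqs.B
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite entries in the normal equations")
    c, *_ = np.linalg.lstsq(A, B, rcond=rcond)
    return c


class MIFModel:
    """Gaussian-expansion model of an interaction field.

    Parameters
    ----------
    values : array, shape (N,)
        Normalized strengths (default) or raw energies (kcal/mol) at the
        sample positions.
    positions : array, shape (N, 3)
        Molecular-frame sample positions (u, v, w) in angstrom.
    basis : CGFBasis, optional
        Defaults to the full 480-function basis.
    probe : str
        Probe label: "Cl", "Br", "I" or "custom".
    normalized : bool
        When False, ``values`` are raw kcal/mol and are normalized on
        construction; the reference minimum is stored as ``e_min``.
    """

    def __init__(self, values, positions, basis: CGFBasis | None = None,
                 probe: str = "custom", normalized: bool = True,
                 e_min: float | None = None):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        values = np.asarray(values, dtype=float)
        if positions.shape[0] != values.shape[0]:
            raise ValueError("values and positions must have the same length")
        if values.size == 0:
            raise ValueError("at least one sample required")
        if not normalized:
            e_min = float(np.min(values))
            values = normalize_energies(values)
        self.endog = values
        self.positions = positions
        self.basis = basis if basis is not None else enumerate_basis()
        self.probe = probe
        self.e_min = e_min

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_samples(cls, samples: list[MIFSample], basis: CGFBasis | None = None,
                     probe: str = "custom") -> "MIFModel":
        positions = np.array([s.position for s in samples], dtype=float)
        values = np.array([s.value for s in samples], dtype=float)
        raws = [s.raw_energy for s in samples]
        e_min = float(min(r for r in raws if r is not None)) if any(r is not None for r in raws) else None
        return cls(values, positions, basis=basis, probe=probe, e_min=e_min)

    @classmethod
    def from_csv(cls, path, basis: CGFBasis | None = None, probe: str = "custom",
                 normalized: bool = False) -> "MIFModel":
        """Build from the sample exchange CSV (columns n,u,v,w,r,theta,phi,energy).

        By default the ``energy`` column is treated as raw kcal/mol and
        normalized; pass ``normalized=True`` if it already holds strengths.
        """
        df = read_samples_csv(path)
        positions = df[["u", "v", "w"]].to_numpy(dtype=float)
        return cls(df["energy"].to_numpy(dtype=float), positions, basis=basis,
                   probe=probe, normalized=normalized)

    # -- estimation -------------------------------------------------------
    def fit(self, rcond: float = 1e-10, method: str = "svd") -> "MIFResults":
        """Estimate the expansion coefficients.

        ``method="svd"`` (default) minimizes the residual directly on the
        design matrix via SVD least squares; with a redundant basis this is
        the numerically stable route (it avoids squaring the condition
        number).  ``method="normal"`` assembles and solves the classic
        normal equations A c = B.  Both minimize the same Delta; they differ
        only in floating-point robustness.
        """
        G = evaluate_basis(self.basis, self.positions)
        if method == "svd":
            coef, *_ = np.linalg.lstsq(G, self.endog, rcond=rcond)
        elif method == "normal":
            eqs = assemble_normal_equations(self.positions, self.endog, self.basis)
            coef = solve_coefficients(eqs, rcond=rcond)
        else:
            raise ValueError(f"unknown fit method: {method!r}")
        fitted = G @ coef
        resid = self.endog - fitted
        delta = float(resid @ resid)
        tss = float(np.sum((self.endog - self.endog.mean()) ** 2))
        rsq = 1.0 - delta / tss if tss > 0 else (1.0 if delta < 1e-12 else 0.0)
        return MIFResults(model=self, params=coef, delta=delta, rsquared=rsq,
                          rcond=rcond)


@dataclass
class MIFResults:
    """Fitted interaction-field function E_X(r) with diagnostics.

    ``params`` are the expansion coefficients in basis order; ``delta`` is the
    residual sum of squares of the fit and ``rsquared`` the coefficient of
    determination against the sample variance.
    """

    model: MIFModel
    params: np.ndarray
    delta: float
    rsquared: float
    rcond: float = 1e-10

    @property
    def basis(self) -> CGFBasis:
        return self.model.basis

    @property
    def probe(self) -> str:
        return self.model.probe

    @property
    def e_min(self) -> float | None:
        return self.model.e_min

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def evaluate(self, points) -> np.ndarray | float:
        """Raw function value sum_i c_i g_i at molecular-frame point(s);
        clamping to [0, 1] is the mapping stage's job."""
        g = evaluate_basis(self.basis, points)
        return g @ self.params

    def summary(self) -> str:
        e_min = "n/a" if self.e_min is None else f"{self.e_min:.3f} kcal/mol"
        lines = [
            "Interaction-field Gaussian expansion",
            "=" * 44,
            f"probe:               {self.probe}",
            f"basis functions:     {len(self.basis)}",
            f"samples:             {self.nobs}",
            f"residual sum sq (D): {self.delta:.6g}",
            f"r-squared:           {self.rsquared:.4f}",
            f"reference e_min:     {e_min}",
            f"svd cutoff (rcond):  {self.rcond:g}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Serialize basis + coefficients + diagnostics to JSON."""
        payload = {
            "probe": self.probe,
            "e_min_kcal_mol": self.e_min,
            "fit_report": {
                "delta": self.delta,
                "r_squared": self.rsquared,
                "n_samples": self.nobs,
                "rcond": self.rcond,
            },
            "basis": [
                {"degree": f.degree, "k": f.k, "l": f.l, "m": f.m, "alpha": f.alpha}
                for f in self.basis
            ],
            "coefficients": [float(c) for c in self.params],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "MIFResults":
        data = json.loads(Path(path).read_text())
        from .cgf_basis import CGFSpec

        basis = CGFBasis(functions=tuple(
            CGFSpec(e["k"], e["l"], e["m"], e["alpha"]) for e in data["basis"]
        ))
        coef = np.asarray(data["coefficients"], dtype=float)
        if len(coef) != len(basis):
            raise ValueError("coefficient count does not match basis size")
        report = data.get("fit_report", {})
        # reconstruct a stub model carrying metadata; samples are not stored
        model = MIFModel.__new__(MIFModel)
        model.endog = np.zeros(int(report.get("n_samples", 0)))
        model.positions = np.zeros((int(report.get("n_samples", 0)), 3))
        model.basis = basis
        model.probe = data.get("probe", "custom")
        model.e_min = data.get("e_min_kcal_mol")
        return cls(model=model, params=coef,
                   delta=float(report.get("delta", np.nan)),
                   rsquared=float(report.get("r_squared", np.nan)),
                   rcond=float(report.get("rcond", 1e-10)))

    def plot_theta_phi(self, d: float = 3.0, theta_step: float = 2.0,
                       phi_step: float = 2.0, ax=None):
        """Heat map of clamped strength over (polar, azimuth) at radius d."""
        from .mapping import theta_phi_map

        grid = theta_phi_map(self, d=d, theta_step=theta_step, phi_step=phi_step)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(grid, origin="lower", aspect="auto",
                       extent=(0, 360, 0, 180), vmin=0, vmax=1, cmap="viridis")
        ax.set_xlabel("azimuth phi (deg)")
        ax.set_ylabel("polar theta (deg)")
        ax.figure.colorbar(im, ax=ax, label="strength")
        return ax


# -- functional wrappers (pipeline style) ---------------------------------

def fit_mif(samples: list[MIFSample], basis: CGFBasis | None = None,
            rcond: float = 1e-10, probe: str = "custom") -> MIFResults:
    """Assemble and solve the normal equations for a sample list."""
    return MIFModel.from_samples(samples, basis=basis, probe=probe).fit(rcond=rcond)


def evaluate_mif(fn: MIFResults, point) -> np.ndarray | float:
    """Raw expansion value at molecular-frame point(s)."""
    return fn.evaluate(point)


def samples_from_grid(points: list[GridPoint], values, raw=None) -> list[MIFSample]:
    """Pair grid points with strengths (and optionally raw energies)."""
    values = np.asarray(values, dtype=float)
    out = []
    for i, p in enumerate(points):
        out.append(MIFSample(n=p.n, position=p.position, value=float(values[i]),
                             raw_energy=None if raw is None else float(raw[i])))
    return out
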