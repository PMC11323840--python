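# Methods

## Scope and overall procedure

`halomif` approximates the interaction field between a backbone-like amide
acceptor and a halobenzene probe as a linear combination of Cartesian
Gaussian functions (CGFs), and evaluates the fitted function around the
backbone carbonyls of whole proteins.  The package covers sampling-grid
generation, probe placement for an external energy stage, energy
normalization, the least-squares expansion, protein-surface mapping, bond
geometry analysis and all file I/O.  It does **not** compute interaction
energies itself: those come either from external quantum-chemistry software
(through the exported XYZ geometries and the sample-CSV contract) or from the
built-in synthetic surrogate.

## Coordinate frames and bond geometry

Every standard amino-acid residue with a complete N/CA/C/O backbone defines a
right-handed orthonormal frame: origin at the carbonyl oxygen, `w` along
C→O, `u` the component of CA−C perpendicular to `w` (so `u·(CA−C) > 0`),
`v = w × u`.  The sign conventions are chosen so that:

* the "northern" hemisphere (positive `w`) corresponds to the acceptor-side
  angle Θ₂ > 90°, where typical C–X⋯O=C bonds sit;
* for a halogen at the queried point, its spherical coordinates in the frame
  satisfy θ = 180 − Θ₂ exactly and φ = 180 + Ψ (mod 360), with Ψ the
  N–C–O–X torsion in the standard IUPAC sign convention.  The φ identity is
  exact for a planar amide and holds to crystallographic accuracy for real
  residues; it is verified numerically in the test suite.

Torsions for collinear atom triples are undefined and reported as `None`
rather than an arbitrary number.  Frame construction refuses collinear or
coincident O/C/CA inputs (tolerance 1e-6 rad).

## Sampling grids

The model-molecule grid is spherical: radii 2–7 Å inclusive in 0.5 Å steps,
polar angle 0–180° inclusive and azimuth [0°, 360°) in 10° steps.  The
azimuth seam (360° ≡ 0°) is excluded and pole rings are collapsed to a
single point per shell, because duplicated positions would double-weight
those directions in the least-squares fit.  This yields
11 × (17 × 36 + 2) = 6754 points, indexed radius-major, then polar, then
azimuth.  Protein maps use a cubic box grid (default 150 nodes/axis at
0.5 Å = 3,375,000 points) centred on the protein.

## Energy normalization

Raw probe/amide energies (kcal/mol) become dimensionless strengths:
`E/E_min` for attractive points (the most stable point scores exactly 1) and
0 for repulsive points.  Normalization is undefined — and raises — when no
energy is attractive.  Fitting operates on strengths by default; raw-energy
fitting is available (`normalized=False`) but off by default, since the
mapped quantity of interest is the normalized strength.

## The Gaussian expansion and its solution

The basis couples every monomial `u^k v^l w^m` of total degree 0–7 with four
width exponents per degree (s/p: 0.03, 0.08, 0.13, 0.18 Å⁻²; rising by
degree up to j: 0.194, 0.244, 0.294, 0.344 Å⁻²), 480 functions in all,
ordered lexicographically in (degree, k, l, m) then width for reproducible
coefficient files.  Widths are interpreted in Å⁻² with coordinates in Å,
consistent with the 2–7 Å sampling domain.

The coefficients minimize Δ = Σₙ (Eₙ − E_X(rₙ))².  `MIFModel.fit()` solves
the problem by SVD least squares **on the design matrix** (`method="svd"`,
relative cutoff `rcond = 1e-10`); assembling and solving the normal
equations A c = B is provided as `method="normal"` and as standalone
operations.  The design-matrix route is the default because the full basis
is strongly redundant on the 6754-point grid: the design matrix has
numerical rank 448 of 480 in double precision (condition number ~4e18).
Solving through A squares that conditioning and, at the default cutoff,
leaves residuals around 1e-3 even for data lying exactly in the basis span,
whereas the design-matrix solve recovers such data to Δ ≈ 1e-21.

A practical consequence of the redundancy: the *fitted field* is always
well determined, but *individual coefficients* are identifiable only when
the chosen basis is numerically full-rank on the sampling grid.  With the
full 480-function basis, minimum-norm least squares returns the projection
of any generating coefficient vector onto the identifiable subspace; exact
coefficient recovery should only be expected for reduced bases (the test
suite demonstrates recovery to <1e-6 on a random 20-function sub-basis and
documents the full-basis behaviour).

Fit diagnostics are the residual sum of squares Δ and r² against the sample
variance, both computed on the (normalized) fitting data.

## Probe placement

The bundled probe geometries are idealized planar halobenzenes (ring C–C
1.39 Å, C–H 1.08 Å, C–X 1.74/1.90/2.10 Å for Cl/Br/I).  At each grid point
the probe is rigidly moved so the halogen sits on the point and the C→X axis
points along the vector to the acceptor oxygen (σ-hole toward the acceptor).
The residual torsion about the C–X axis is fixed by using the *minimal*
rotation (axis M × Gₙ); an exactly antiparallel starting orientation is
resolved by a 180° flip about the ring-plane normal.  Rotations are proper
(chirality preserved) and idempotent to 1e-9 Å.

## Protein-surface mapping

For each query point (voxel or single position):

1. candidate residues are those whose carbonyl O lies within the trusted
   radial domain (7 Å default) of the point — beyond the sampled domain the
   expansion is extrapolation and is defined as 0;
2. the point is transformed into each candidate frame, E_X evaluated and
   clamped to [0, 1] (negative overshoot → 0, >1 → 1);
3. the maximum over residues is taken and that residue recorded as the
   contributor;
4. points within the steric radius (2 Å default) of any protein heavy atom
   are forced to 0 regardless; hydrogens are ignored (absent from most
   X-ray structures).

An optional ligand-site restriction (default radius 4 Å when enabled)
confines evaluation to the neighbourhood of a bound ligand.  Candidate
search uses k-d trees; an exhaustive per-voxel loop serves as the test
oracle.  Orientation (θ, φ) maps at fixed radius use the same clamped
evaluation on a spherical coordinate lattice.

The bond survey evaluates the mapped strength at each ligand halogen and
reports d, Θ₁, Θ₂, Ψ against the contributing residue (or the nearest
carbonyl when no residue contributes); the donor carbon is taken as the
ligand carbon closest to the halogen.

## Synthetic surrogate data

Real probe/amide energy surfaces require external QM software, so the
surrogate generator emulates their anatomy in closed form: a radial Gaussian
well (default minimum d₀ = 3.2 Å — the average O⋯I separation in
protein/ligand surveys — depth −3.92 kcal/mol, width 0.5 Å) modulated by a
smooth exponential-of-cosine angular weight concentrated in the northern
hemisphere (or around the equator for the chlorine-like pattern,
concentration κ = 4), a mild azimuthal modulation (depth 0.3) exercising the
torsional dependence, and a steep r⁻¹² repulsive wall inside d₀ − 2·width so
the repulsive→0 normalization branch is exercised.  Optional Gaussian noise
is added to the normalized strengths and re-clamped.  The closed form lies
near, but not inside, the CGF span, so fitting it is genuine approximation;
the 480-function fit reaches r² ≈ 0.998 noise-free.

What the surrogate does *not* emulate: real electronic-structure effects
(charge transfer, dispersion anisotropy, probe-ring torsional fine
structure), secondary minima, or basis-set artefacts.  Passing tests
therefore validate the fitting/mapping machinery and conventions, not the
physical accuracy of any particular field.

`synthetic_bond_site` synthesizes coordinates (idealized planar amide plus a
halogen and donor carbon) that realize a prescribed (d, Θ₁, Θ₂, Ψ); it is a
synthetic stand-in for deposited crystal coordinates, used to verify that
geometry measurement reproduces surveyed worked examples to their printed
precision (±0.02).  It validates conventions, not crystallography.

## Numerical choices and limitations

* SVD cutoff 1e-10 (relative) throughout; altering it trades smoothing
  against fidelity for redundant bases.
* Altloc resolution: highest occupancy, ties → altloc 'A', then
  alphabetical; only model 1 of multi-model entries is used by default.
* Volumetric formats: Gaussian cube (bohr, one dummy atom), OpenDX
  (ångström) and long-format CSV; all round-trip below 1e-6.
* Cube/DX/CSV values are strengths in [0, 1]; writers do not rescale.
* Map boundaries are hard cutoffs (steric 2 Å, domain 7 Å); fields change
  steeply near them, so strengths for borderline contacts are sensitive to
  small coordinate changes.  No switching-function smoothing is applied.
* Problem sizes used by the test suite and the acceptance script: the full
  6754-point grid and 480-function basis for fitting checks, and 8³–9³
  voxel toy maps with one- and two-residue structures for mapping oracles —
  chosen so every check runs the genuine protocol sizes where it matters
  (fitting) and exhaustively verifiable sizes where brute force is the
  oracle (mapping).
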