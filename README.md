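# halomif

Halogen-bond molecular interaction fields on protein surfaces via Cartesian
Gaussian expansion.

## The problem

Halogen bonds — contacts between the σ-hole of a covalently bound Cl/Br/I and
an electron-rich acceptor — are valuable design handles in structure-based
drug design, but classical force fields miss their strong anisotropy, and
quantum-mechanical evaluation of a full protein is out of reach.  In protein/
ligand complexes these bonds form overwhelmingly against **backbone carbonyl
oxygens**, whose local environment is well modelled by a small amide.  That
opens a shortcut:

1. sample the interaction field of a small amide model with a halobenzene
   probe once (externally, at QM level — or with this package's synthetic
   surrogate),
2. approximate that field by a smooth closed-form function, and
3. stamp the function onto every backbone carbonyl of a protein of interest.

`halomif` implements steps 2 and 3, plus all the geometry, grid and I/O
machinery around them, for users working on halogen-bond-aware ligand design
and structural bioinformatics.

## The model

Each residue carries a local frame *o-uvw*: origin at the carbonyl O, *w*
along C→O, *u* in the O=C–Cα plane (toward Cα), *v = w × u*.  A halogen bond
is described by the distance *d*(O–X), angles Θ₁(C–X–O) and Θ₂(X–O–C), and
torsion Ψ(N–C–O–X); in the residue frame the halogen sits at polar angle
θ = 180 − Θ₂ and azimuth φ = 180 + Ψ.

Interaction energies sampled on a spherical grid around the amide
(r = 2–7 Å in 0.5 Å steps, 10° angle steps; 6754 points) are normalized to
*strengths*: E/E_min for attractive points (so the global minimum scores 1),
0 for repulsive points.  The strength field is then expanded as

    E_X(r) = Σᵢ cᵢ gᵢ(r),   gᵢ = u^k v^l w^m exp(−α r²)

over Cartesian Gaussian functions of degrees 0–7 (s through j types), four
width exponents per degree — 480 functions in total.  The coefficients
minimize the squared residual Δ = Σₙ (E_n − E_X(rₙ))², solved as an SVD
least-squares problem (the normal-equation route A c = B is also available).

Mapping onto a protein evaluates E_X in every nearby residue's frame, clamps
to [0, 1], and takes the **maximum over residues** per grid point, with two
hard rules: points within 2 Å of any protein heavy atom score 0, and the
function is trusted only inside its 7 Å sampling domain.

## Worked example

```python
import numpy as np
from halomif import (MIFModel, SurrogateParams, surrogate_mif,
                     model_spherical_grid, enumerate_basis, theta_phi_map)

grid = model_spherical_grid()                      # 2-7 A, 10 deg steps
samples = surrogate_mif(grid, SurrogateParams())   # synthetic I-like field
model = MIFModel.from_samples(samples, basis=enumerate_basis(), probe="I")
res = model.fit()
print(res.summary())
```

```
Interaction-field Gaussian expansion
============================================
probe:               I
basis functions:     480
samples:             6754
residual sum sq (D): 0.211872
r-squared:           0.9976
reference e_min:     -3.340 kcal/mol
svd cutoff (rcond):  1e-10
```

The fit reproduces the surrogate field with r² = 0.998 over all 6754 samples.
An orientation map at fixed radius shows where, around a carbonyl, the probe
binds:

```python
tp = theta_phi_map(res, d=3.2, theta_step=30, phi_step=60)
print(np.array_str(tp, precision=2, suppress_small=True))
```

```
[[0.94 0.94 0.94 0.94 0.94 0.94]
 [0.68 0.62 0.5  0.44 0.5  0.62]
 [0.16 0.15 0.13 0.12 0.13 0.15]
 [0.03 0.03 0.03 0.02 0.03 0.03]
 [0.01 0.01 0.   0.   0.   0.01]
 [0.   0.   0.   0.   0.   0.  ]
 [0.   0.   0.   0.   0.   0.  ]]
```

Rows are polar angle θ (0°…180°), columns azimuth φ: this surrogate field is
concentrated in the northern hemisphere (θ < 90°, i.e. Θ₂ > 90°), the
signature geometry of C–X⋯O=C halogen bonds.  `res.save("coeffs.json")`
persists the function; `map_protein_mif` / `strength_at_point` evaluate it on
a PDB structure, and `survey_halogen_bonds` reports per-halogen strength and
geometry (d, Θ₁, Θ₂, Ψ) against the contributing residue.

The same pipeline is scriptable from the shell:

```bash
halomif synth --out samples.csv
halomif fit --samples samples.csv --probe I --out coeffs.json
halomif map --pdb protein.pdb --coefficients coeffs.json --ligand LIG --out map.dx
halomif geometry --pdb protein.pdb --coefficients coeffs.json --ligand LIG --out survey.csv
```

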