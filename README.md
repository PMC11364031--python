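# edtaam

Aspherical (multipole/TAAM) and charged scattering factors for kinematical
refinement of small-molecule crystal structures against 3D electron
diffraction (3D ED) data.

## The problem

Electron diffraction is sensitive to atomic charge: the electron form
factor follows from the X-ray one through the Mott–Bethe formula,

    f^e(s) = (m₀e² / 8πε₀h²) · (Z − f^x(s)) / s²,      s = sin θ / λ,

so a net charge q makes f^e diverge as C·q/s² at low resolution.  Assigning
metals their *formal* oxidation state (e.g. Fe³⁺ in a coordination complex)
therefore grossly overestimates their low-angle scattering, while the
standard neutral independent atom model (IAM) ignores charge and bonding
asphericity altogether.  The transferable aspherical atom model (TAAM)
describes each atom with Hansen–Coppens pseudoatom parameters —

    ρ_atom = ρ_core + P_val κ³ ρ_val(κr) + Σ_lm P_lm κ′³ R_l(κ′r) y_lm(r̂),
    f = f_core + P_val f_val(κ) + (deformation terms)

— capturing partial charges and directional bonding, and improves
kinematical refinement against 3D ED data, predominantly in the
low-resolution shell where charge effects live.

`edtaam` implements this entire computational chain for people working on
electron crystallography of metal complexes: form-factor construction
(neutral/charged IAM, partial-charge combinations, Hansen–Coppens
multipoles, Mott–Bethe conversion, 4-Gaussian parametrization, .tsc
tables), kinematical F² least-squares refinement with the SHELX-style
weighting scheme and riding hydrogens, resolution-shell and
displacement-ellipsoid diagnostics, Fourier difference maps with
fractal-dimension analysis, multipole refinement against theoretical
structure factors with atom-type databanks, grid-based Bader charges, and
a synthetic FeAcAc-like test system that makes every stage testable with
no external data.

## Worked example

```python
import numpy as np
from edtaam.synthetic import (SimulationSpec, make_benchmark_pair,
                              truth_multipole_models)
from edtaam.pipeline import ComparisonConfig, run_comparison, standard_variants

spec = SimulationSpec(seed=1)                  # Pbca, a,b,c = 15.35, 13.56, 16.50
refl, start, truth = make_benchmark_pair(spec) # d_min 0.85 A, ~92% complete
st = truth["structure"]
models, rots = truth_multipole_models(st)
report = run_comparison(
    start, refl,
    standard_variants(st, models, rots, include=("iam", "iam-fe3", "taam")),
    ComparisonConfig(), reference=st)
for v in report.variants:
    print(f"{v.name:8s} R1 {100*v.result.r1_strong:5.2f}%  "
          f"low-res {100*v.shells[0]['r1_strong']:5.2f}%  "
          f"high-res {100*v.shells[1]['r1_strong']:5.2f}%  "
          f"fractal width {v.fractal_width:.3f}")
```

Output (seed 1):

```
iam      R1  6.40%  low-res 10.90%  high-res  4.86%  fractal width 0.248
iam-fe3  R1  6.64%  low-res 11.61%  high-res  4.94%  fractal width 0.263
taam     R1  3.44%  low-res  2.45%  high-res  3.77%  fractal width 0.104
```

Reading it: the data were simulated from an aspherical ground truth with a
small partial charge on the metal.  Refining with matched aspherical (TAAM)
factors roughly halves R1 relative to neutral IAM, the improvement is
concentrated in the 8.65–2.0 Å shell (10.5% → 2.4%) rather than the
2.0–0.85 Å shell (4.8% → 3.8%), formally charged Fe³⁺/O⁰·⁵⁻ IAM factors fit
*worse* than neutral ones, and the TAAM residual map has a much narrower
fractal-dimension curve — the qualitative fingerprints of aspherical
refinement against electron diffraction data.

A CLI mirrors the library: `edtaam synth`, `edtaam compare`,
`edtaam mott-bethe --element Fe --charge 3`, `edtaam fit-gaussians`,
`edtaam sf`, `edtaam tsc`, `edtaam bader`.

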