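# Methods

This note documents the models, conventions and numerical choices behind
`edtaam`.  Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external results.

## Scattering-factor models

**Conventions.** The momentum-transfer variable is `s = sin(θ)/λ` in Å⁻¹
throughout; radial Fourier transforms use the kernel `q = 4πs`; resolution
`d` relates to `s` by `s = 1/(2d)`.  Reciprocal vectors passed to aspherical
form factors are the usual Cartesian `d*` vectors with `|d*| = 1/d = 2s`.

**Neutral IAM.** Neutral-atom spherical factors come from the analytic
tables exposed by `gemmi`: the 4-Gaussian X-ray parametrization
(`xray_iam`) and the 5-Gaussian electron parametrization (`electron_iam`).

**Slater-model atoms and ions.** Charged species are not covered by those
neutral tables, so the package builds spherical densities as superpositions
of single-ζ Slater shells, `ρ_{n,ζ}(r) ∝ r^{2n−2} e^{−2ζr}`, with exponents
computed from Slater's screening rules — a deterministic function of the
electron configuration, so no transcribed coefficient table is needed.
Cations lose electrons outermost-first (4s before 3d for Fe); anions gain
them in the outermost open shell.  The shell scattering factor has the
closed form `f(q) = α^{2n+1}/(2n)! · Im[(2n−1)!/(α−iq)^{2n}]/q` with
`α = 2ζ`.  Single-ζ atoms deviate from the Hartree–Fock-quality neutral
tables by up to ~1.3 e for Fe at low `s`; within the synthetic study every
spherical reference is drawn from the same Slater family, so comparative
statistics isolate charge and asphericity rather than basis-set quality.

**Mott–Bethe conversion.** `f^e(s) = C·(Z − f^x(s))/s²` with
`C = m₀e²/(8πε₀h²)` evaluated from CODATA constants at import time
(≈ 0.023934 Å for `s` in Å⁻¹).  For neutral species the removable
singularity below `s = 0.01 Å⁻¹` is handled by a quadratic series
extrapolation fitted at `s = 0.01` and `0.02`; ions genuinely diverge as
`C·q/s²` and evaluation below the cutoff raises an error.  Applied to the
tabulated neutral X-ray factors, the conversion reproduces the electron
tabulation to ≤ ~1% for C, O and Fe over `s ∈ [0.05, 1.2]` Å⁻¹ (the
acceptance script reports the measured maximum).  Hydrogen is excluded from
that check: `Z − f^x` is a difference of nearly equal numbers for H, and
the X-ray fit error is amplified ~25-fold — a property of the fitted
tables, not of the conversion, which is verified separately against the
exact analytic hydrogen factor.

**Gaussian fits.** `fit_gaussians` is a Levenberg–Marquardt fit of
`Σ aᵢ e^{−bᵢs²} (+ c)` run from three deterministic width ladders, keeping
the best; non-convergence is flagged in the returned report.  Ionic
electron curves cannot be represented by Gaussians near `s = 0`; following
the convention of electron ion-factor tables the analytic `C·q/s²` term is
subtracted before fitting and stored in the `coulomb_q` field, restored on
evaluation.

**Hansen–Coppens pseudoatoms.** A pseudoatom is
`ρ = ρ_core + P_val κ³ ρ_val(κr) + Σ_{lm} P_lm κ′³ R_l(κ′r) y_lm(r̂)` with
`R_l` the normalized Slater deformation radial function (default powers
n_l = 2,2,3,4 for first-row atoms, 1,2 for H, 4 for Fe; default exponents
twice the valence ζ) and `y_lm` **orthonormal real spherical harmonics** —
the package's own databank normalization, stated here because population
values are only meaningful together with their angular normalization.
The form factor follows term by term; order-l Fourier–Bessel transforms are
evaluated in closed form from `F(n) = n!/(α−iq)^{n+1}`, switching to an
adaptive power series below `q < 0.2α` to avoid cancellation (validated to
~1e−13 against adaptive quadrature for l ≤ 4).  Electron factors apply
Mott–Bethe to the full complex X-ray factor.  For Fe the 4s² electrons are
frozen into the core and the 3d shell is the refinable valence density
(`P_core = 20`, `P_val = 6` for the neutral atom).  l_max defaults are
hexadecapole for the metal, octupole for C/N/O/F, dipole for H.

**Local frames.** Pseudoatom axes are built deterministically from bonded
neighbours (bonds: distance < 1.15 × sum of covalent radii): z toward the
highest-priority neighbour (largest Z, then shortest distance, then label),
x orthogonalized toward the next, y completing a right-handed frame.
Symmetry copies scatter with rotated reciprocal vectors `hR`, which is
equivalent to rotating the pseudoatom density.

## Structure factors and refinement

`F(h) = Σ_ops Σ_sites occ · f(hR) · T(hR) · e^{2πi[(hR)·x + h·t]}` with the
Debye–Waller factor in the CIF U_ij convention,
`T = exp(−2π² Σ U_ij h_i h_j a*_i a*_j)` (reciprocal cell lengths, stated
explicitly because β/U conventions differ between programs).  The engine is
verified against a naive no-symmetry double loop at 1e−10, and Friedel
symmetry, Pbca systematic absences and the table-versus-inline form-factor
route are property-tested.

Refinement minimizes `Σ w (F_o² − k|F_c|²)²` over the scale, non-H
coordinates and U_ij (or U_iso), with
`w = 1/[σ²(F_o²) + (aP)² + bP]`, `P = (max(F_o²,0) + 2F_c²)/3` (negative
intensities floored inside P).  Levenberg–Marquardt with analytic
derivatives of `|F|²`; form factors are frozen during refinement (the .tsc
convention), weights are recomputed between a small number of outer cycles
(default 2–3).  Hydrogens ride on their parents with fixed fractional
offsets normalized to neutron-derived distances (methyl C–H 1.077 Å,
sp²/secondary 1.083/1.092 Å) and `U_iso(H) = 1.2·U_eq(parent)` (1.5 for
methyl); the U_eq tie uses trace/3, exact for the orthogonal cells
exercised here.  Convergence: relative objective change < 1e−9 or the
scipy LM step criteria; the analytic Jacobian is checked against finite
differences in the suite.  On noise-free synthetic data the engine recovers
perturbed coordinates to < 1e−4 Å (machine precision in practice).

**Statistics.** R1 is reported on |F| over the `F_o > 4σ(F_o)` subset (and
over all data), with `F = sqrt(max(F²,0))` and `σ(F) = σ(F²)/2F` floored at
`sqrt(σ(F²))` for weak reflections — the cut convention is stated because
F²→F error propagation is not unique.  GooF is
`sqrt(Σw(F_o²−kF_c²)²/(n−p))`.  Shell R1 freezes all parameters and the
global scale and re-partitions by d.  Displacement-ellipsoid R1/R3 ratios
are sqrt-eigenvalue ratios of the Cartesian-transformed U tensor; model
RMSDs are over Cartesian coordinates and bond lengths of non-H atoms.

**Extinction.** When enabled (the X-ray-style path; off for electron
data), a single isotropic scalar x damps the calculated intensities as
`F_c² → F_c²/(1 + x F_c²)` and is refined alongside the other parameters.

**Esds.** Parameter standard uncertainties come from the weighted normal
matrix at convergence, `cov = (JᵀJ)⁻¹ · χ²/(n−p)`; on noisy synthetic data
with a matched model the coordinate deviations from ground truth are
consistent with these esds (median |Δ|/esd < 2, >90% within 4).

**Weight optimization.** `(a, b)` are adjusted by a Nelder–Mead search (three
deterministic starts, ≤200 iterations) that flattens per-bin goodness of
fit (10 calculated-intensity bins plus 5 resolution bins) around 1.  On
data whose noise exactly matches σ the optimum is a ≈ b ≈ 0; an injected
`(aP)²` variance inflation is recovered within ~0.03.  If the search fails
to converge the pipeline falls back to fixed `(a, b) = (0.2, 0)`.

## Difference maps and fractal analysis

Maps are synthesized as `ρ(x) = (1/V) Σ_h ΔF(h) e^{−2πih·x}` by FFT over
one unit cell (default grid spacing d_min/4 per axis), with Friedel mates
completed by hermitian symmetry and F(000) excluded.  Observed-minus-model
coefficients are `(|F_o| − |F_c|)e^{iφ_c}` — phases always from the current
model.  Electron-diffraction maps carry the potential-difference unit tag
1/Å² and X-ray maps e/Å³; the unit is a tag, never a rescale.  Parseval
consistency and random-point agreement with a direct triple sum are tested.
The fractal-dimension diagnostic is `d_f(ρ₀) = ln N(ρ₀)/ln N_total` over
101 equal-width bins symmetrized about zero (zero-count bins omitted); the
summary "width" is the span of populated levels.  On Gaussian noise the
width scales with σ; in the synthetic study the aspherical-model residual
map is roughly 2.4× narrower than the spherical-model one.

## Bader integration

Grids are molecular (non-periodic) boxes.  Basins are found by the
deterministic on-grid (near-grid) steepest-ascent rule over 26 neighbours
with slope `(ρ_nb − ρ_self)/dist`, ties broken by fixed neighbour order, and
resolved by pointer doubling; no trajectory-correction refinement is
applied — accuracy is controlled by grid spacing, and the analytic
two-Gaussian fixtures recover populations to ~5e−3 e at 0.15 Å spacing.
Maxima are attributed to the nearest nucleus within a 1.0 Å capture radius;
others are reported as non-nuclear attractors and pooled as unassigned.
Inner-core shells (Fe 1s decays on ~0.01 Å) cannot be integrated by
midpoint sampling at any affordable spacing, so `density_on_grid`
renormalizes each atom's discrete sum to its analytic electron count by
distributing the deficit over the near-nucleus neighbourhood (≤ 0.25 Å),
weighted by the atom's own density; grid totals are then exact by
construction and the correction stays interior to the atom's basin.

## Multipole refinement and databanks

Theoretical structure-factor targets live in an artificial P1 box
(default 30 Å cube) with static atoms.  Valence-only targets subtract the
frozen-core factors analytically; the flag is recorded on the set.  The
fit is least squares on stacked real/imaginary parts over the selected
parameters (P_val, κ, κ′, individual P_lm); refinement against
self-generated targets is an exact fixed point, and perturbed populations
are recovered to < 1e−4 e.  Fitting the *spherical-only* (κ-formalism)
model class to an aspherical target leaves a residual R of ~2% on the
synthetic molecule — the measure of asphericity the κ formalism cannot
absorb.  Atom types are keyed by element plus sorted first- and
second-shell bonded-element signatures, which distinguishes carbonyl,
central and methyl carbon and groups all six chelating O of the synthetic
molecule; databanks store per-type arithmetic means of P_val, κ, κ′ and
P_lm (frames assumed equivalently defined by the deterministic local-axes
rule) as versioned JSON, with a spherical-neutral fallback for unmatched
types.

## The synthetic study

The generator emulates a tris-chelate iron(III) acetylacetonate crystal:
an idealized FeC₁₅H₂₁O₆ molecule (octahedral Fe–O 1.99 Å, planar chelate
rings solved from bond-length/angle constraints, staggered methyls) packed
into the orthorhombic Pbca cell a = 15.35, b = 13.56, c = 16.50 Å (Z = 8).
The rigid-body placement was found once by maximizing the minimum
intermolecular contact (2.09 Å) and frozen as module constants for
reproducibility; the search routine is retained.  Anisotropic ADPs with
controllable anisotropy (default eigenvalue spread ±50%, seeded random
orientations) exercise the ellipsoid statistics; hydrogen U_iso follows
the riding convention so the generator is consistent with the refinement
constraint.

Reflections cover 8.65–0.85 Å with 92% completeness;
`σ(F²) = t·sqrt(F² + g(F²)²)` with g = 0.02 and t chosen so the mean I/σ
is 8.4, then Gaussian noise of that σ is added (a `noise_scale` of 0
returns exact intensities).  Every output is a deterministic function of
(spec, seed).

The aspherical ground truth assigns hand-set generator constants: valence
populations giving Fe +0.4, O −0.30 and carbonyl C +0.28 (hydrogens absorb
the balance, keeping the molecule neutral), κ contraction on O (0.97) and
H (1.15), O lone-pair dipole/quadrupole, and bonding octupoles on C.  The
metal's *population* charge is deliberately far below the formal +3: the
effective spherical scattering of a coordinated metal lies between the
neutral atom and a low formal charge, which is precisely why formally
charged IAM factors overestimate low-angle scattering.  The Bader charges
of this same density are much larger than the population charges
(Fe ≈ +2.5, O ≈ −1.1, carbonyl C ≈ +0.7) because zero-flux basins assign
bonding density to the electronegative atoms — the package computes both
quantities and the distinction matters when comparing them.

What the synthetic study does *not* emulate: dynamical (multiple)
scattering, which in experiments raises absolute R factors to the 15–40%
range; frame-level data reduction artefacts; and Hartree–Fock-quality
atomic densities (single-ζ shells are used throughout).  Passing the
comparative tests therefore demonstrates the machinery and the *orderings*
(aspherical < neutral spherical ≤ formally charged spherical, improvement
concentrated at low resolution, narrower residual-map fractal curves), not
the absolute experimental R values, which are refinement statistics on
deposited data and can only be reproduced from those files.

## Problem sizes

The default test and acceptance runs use the full reflection envelope
(~2700 unique reflections, 199 parameters, 43-atom asymmetric unit), a
13.5 Å cube at 0.08 Å spacing for Bader integration (~4.8M voxels), and a
30 Å box to d = 2.0 Å (~7000 reflections) for multipole fitting; unit
tests use reduced resolutions of the same systems.
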