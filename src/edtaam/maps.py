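"""Fourier difference maps, peak statistics and fractal-dimension curves.

Synthesis convention:  rho(x) = (1/V) sum_h dF(h) exp(-2 pi i h.x)  on a
regular grid over one unit cell; F(000) is excluded by default.  For an
electron-diffraction map built from Mott-Bethe amplitudes (Angstrom) the
values carry the potential-difference unit 1/Angstrom^2 used in this field;
for X-ray amplitudes (electrons) they are e/Angstrom^3.  The unit is a tag
on the grid, never a silent rescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import UnitCell

__all__ = ["DensityGrid", "difference_map", "map_extrema",
           "fractal_dimension_plot"]


@dataclass
class DensityGrid:
    values: np.ndarray          # (na, nb, nc) scalar field
    cell: UnitCell | None = None
    origin: np.ndarray | None = None   # Cartesian origin for molecular grids
    spacing: np.ndarray | None = None  # Cartesian spacing for molecular grids
    periodic: bool = True
    unit: str = "e/A^3"

    @property
    def shape(self):
        return self.values.shape


def difference_map(hkl, delta_f, cell: UnitCell, grid_shape,
                   expand_friedel: bool = True, unit: str = "1/A^2"
                   ) -> DensityGrid:
    """Inverse Fourier synthesis of complex coefficients on a unit-cell grid.

    ``hkl`` must cover the reflection set to be synthesized (already
    symmetry-expanded); Friedel mates are completed automatically by
    hermitian symmetry unless present.  Coefficients at (000) are excluded.
    """
    hkl = np.atleast_2d(np.asarray(hkl, int))
    delta_f = np.asarray(delta_f, complex)
    shape = tuple(int(n) for n in grid_shape)
    A = np.zeros(shape, dtype=complex)
    seen = set()
    for h, f in zip(hkl, delta_f):
        key = tuple(int(v) for v in h)
        if key == (0, 0, 0):
            continue
        idx = tuple(k % n for k, n in zip(key, shape))
        A[idx] = f
        seen.add(key)
    for h, f in zip(hkl, delta_f):
        key = tuple(int(v) for v in h)
        if key == (0, 0, 0):
            continue
        mate = tuple(-v for v in key)
        if mate in seen:
            # both members supplied: check hermitian consistency
            idx_m = tuple(k % n for k, n in zip(mate, shape))
            if not np.isclose(A[idx_m], np.conj(f), atol=1e-6 * (1 + abs(f))):
                raise ValueError(
                    f"coefficients at {key} and {mate} are not hermitian "
                    "conjugates; a real map cannot be synthesized")
        elif expand_friedel:
            idx_m = tuple(k % n for k, n in zip(mate, shape))
            A[idx_m] = np.conj(f)
    # rho(n/N) = (1/V) sum_h F(h) exp(-2 pi i h.n/N) == (1/V) * N * ifft-like;
    # numpy fftn computes sum_k A_k exp(-2 pi i k.n/N), exactly the sum wanted
    rho = np.fft.fftn(A) / cell.volume
    if np.max(np.abs(rho.imag)) > 1e-6 * max(np.max(np.abs(rho.real)), 1e-30):
        raise ValueError("synthesized map has a non-negligible imaginary part")
    return DensityGrid(rho.real, cell=cell, periodic=True, unit=unit)


def map_extrema(grid: DensityGrid):
    """(max, min, frac_position_max, frac_position_min) at grid resolution."""
    v = grid.values
    if v.size == 0:
        raise ValueError("empty grid")
    imax = np.unravel_index(np.argmax(v), v.shape)
    imin = np.unravel_index(np.argmin(v), v.shape)
    frac = lambda idx: np.array(idx, float) / np.array(v.shape)
    return float(v[imax]), float(v[imin]), frac(imax), frac(imin)


def fractal_dimension_plot(grid: DensityGrid, n_bins: int = 101):
    """Fractal-dimension curve d_f(rho0) = ln N(rho0) / ln N_total.

    Residual levels are histogrammed into ``n_bins`` equal-width bins
    symmetrized about zero; zero-count bins are omitted.  Returns
    (levels, d_f, width) where width is the span of populated levels.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    v = grid.values.ravel()
    n_total = v.size
    vmax = float(np.max(np.abs(v)))
    if vmax == 0.0:
        return np.array([0.0]), np.array([1.0]), 0.0
    edges = np.linspace(-vmax, vmax, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    with np.errstate(divide="ignore"):
        df = np.log(counts[keep]) / np.log(n_total)
    levels = centers[keep]
    width = float(levels.max() - levels.min()) if len(levels) else 0.0
    return levels, df, width
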