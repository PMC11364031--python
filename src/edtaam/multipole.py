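"""Hansen-Coppens pseudoatom model and aspherical form factors.

A pseudoatom density is

    rho(r) = rho_core(r)
           + P_val kappa^3 rho_val(kappa r)
           + sum_{l,m} P_lm kappa'^3 R_l(kappa' r) y_lm(r_hat)

with rho_core / rho_val built from the package's single-zeta Slater shells
(:mod:`edtaam.slater`), R_l the normalized Slater deformation radial function
and y_lm orthonormal *real* spherical harmonics (the package's own databank
normalization; populations are therefore expressed with respect to y_lm).

The X-ray form factor follows term by term:

    f_x(h) = f_core(s) + P_val f_val(s/kappa)
           + sum_l 4 pi i^l <j_l>(q/kappa') sum_m P_lm y_lm(R^T h_hat)

where R rotates the pseudoatom local frame into the global Cartesian frame
and q = 4 pi s.  Electron form factors are obtained with the Mott-Bethe
formula applied to the full (complex) X-ray factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import MOTT_BETHE_C
from .slater import (ATOMIC_NUMBER, VALENCE_ELECTRONS, Shell,
                     spherical_atom_shells, shells_ff, shells_density,
                     slater_fourier_bessel, slater_radial, real_sph_harm)

__all__ = ["MultipoleAtomModel", "neutral_multipole_atom", "hc_form_factor",
           "spherical_component_curve", "DEFAULT_RADIAL_N"]

#: Default Slater powers n_l of the deformation radial functions.
DEFAULT_RADIAL_N = {
    "H": {1: 1, 2: 2},
    "C": {1: 2, 2: 2, 3: 3, 4: 4},
    "N": {1: 2, 2: 2, 3: 3, 4: 4},
    "O": {1: 2, 2: 2, 3: 3, 4: 4},
    "F": {1: 2, 2: 2, 3: 3, 4: 4},
    "Fe": {1: 4, 2: 4, 3: 4, 4: 4},
}

#: Conventional maximum multipole order per element (metal: hexadecapole,
#: first-row: octupole, hydrogen: dipole).
DEFAULT_LMAX = {"H": 1, "C": 3, "N": 3, "O": 3, "F": 3, "Fe": 4}


@dataclass
class MultipoleAtomModel:
    """Hansen-Coppens parameters of one pseudoatom."""

    element: str
    core_shells: list[Shell]
    valence_shells: list[Shell]  # occupancies normalized to sum to 1
    p_val: float
    kappa: float = 1.0
    kappa_prime: float = 1.0
    #: populations keyed by (l, m), electrons; l >= 1 terms carry zero charge
    p_lm: dict[tuple[int, int], float] = field(default_factory=dict)
    #: Slater power per l for the deformation radial functions
    radial_n: dict[int, float] = field(default_factory=dict)
    #: deformation radial exponent (1/Angstrom); default 2 * valence zeta
    radial_zeta: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        for (l, m) in self.p_lm:
            if l < 1 or l > 4 or abs(m) > l:
                raise ValueError(f"invalid multipole index (l={l}, m={m})")
        if not self.radial_n:
            self.radial_n = dict(DEFAULT_RADIAL_N[self.element])
        if not self.radial_zeta:
            zv = max(sh.zeta for sh in self.valence_shells)
            self.radial_zeta = {l: 2.0 * zv for l in self.radial_n}

    @property
    def z(self) -> int:
        return ATOMIC_NUMBER[self.element]

    @property
    def p_core(self) -> float:
        return sum(sh.occ for sh in self.core_shells)

    @property
    def n_electrons(self) -> float:
        return self.p_core + self.p_val

    @property
    def charge(self) -> float:
        return self.z - self.n_electrons

    def copy(self) -> "MultipoleAtomModel":
        return replace(self, p_lm=dict(self.p_lm),
                       radial_n=dict(self.radial_n),
                       radial_zeta=dict(self.radial_zeta))

    # -- spherical pieces ---------------------------------------------------

    def f_core(self, s) -> np.ndarray:
        return shells_ff(self.core_shells, s)

    def f_val(self, s) -> np.ndarray:
        """Normalized (one-electron) valence factor, before kappa scaling."""
        return shells_ff(self.valence_shells, s)

    def density(self, rvecs: np.ndarray) -> np.ndarray:
        """Total model density (e/A^3) at Cartesian points relative to the nucleus."""
        rvecs = np.atleast_2d(rvecs)
        r = np.linalg.norm(rvecs, axis=-1)
        rho = shells_density(self.core_shells, r)
        rho = rho + self.p_val * self.kappa**3 * shells_density(
            self.valence_shells, self.kappa * r)
        if self.p_lm:
            safe = np.where(r < 1e-12, 1.0, r)
            u = rvecs / safe[:, None]
            kp = self.kappa_prime
            for l in sorted({l for (l, _) in self.p_lm}):
                Rl = kp**3 * slater_radial(int(self.radial_n[l]),
                                           self.radial_zeta[l], kp * r)
                for (ll, m), p in self.p_lm.items():
                    if ll == l and p != 0.0:
                        rho = rho + p * Rl * real_sph_harm(l, m, u)
        return rho


def neutral_multipole_atom(element: str, frozen_4s: bool = True
                           ) -> MultipoleAtomModel:
    """Spherical neutral pseudoatom (the IAM limit of the model).

    For Fe the 4s^2 electrons are by default frozen into the core and only
    the 3d shell is treated as refinable valence density.
    """
    shells = spherical_atom_shells(element)
    if element == "Fe" and frozen_4s:
        core = [sh for sh in shells if (sh.n, sh.l) != (3, 2)]
        val = [sh for sh in shells if (sh.n, sh.l) == (3, 2)]
    else:
        nv = VALENCE_ELECTRONS[element]
        core, val, acc = [], [], 0.0
        for sh in reversed(shells):
            if acc < nv - 1e-9:
                val.append(sh)
                acc += sh.occ
            else:
                core.append(sh)
        core.reverse()
        val.reverse()
    p_val = sum(sh.occ for sh in val)
    val_norm = [Shell(sh.n, sh.l, sh.occ / p_val, sh.zeta) for sh in val]
    return MultipoleAtomModel(element, core, val_norm, p_val)


def hc_form_factor(model: MultipoleAtomModel, hvec, radiation="xray",
                   rotation: np.ndarray | None = None,
                   s_min: float = 0.01) -> np.ndarray:
    """Complex form factor for Cartesian scattering vectors ``hvec``.

    ``hvec`` has shape (..., 3) with |hvec| = 1/d = 2 s (the usual d* vector
    in 1/Angstrom).  ``rotation`` is the 3x3 matrix sending local-frame to
    global coordinates; the reciprocal direction is rotated back into the
    pseudoatom frame before the angular factors are evaluated.
    """
    hvec = np.atleast_2d(np.asarray(hvec, dtype=float))
    dstar = np.linalg.norm(hvec, axis=-1)
    s = 0.5 * dstar
    fx = np.asarray(model.f_core(s)
                    + model.p_val * model.f_val(s / model.kappa),
                    dtype=complex)
    if model.p_lm:
        safe = np.where(dstar < 1e-12, 1.0, dstar)
        u = hvec / safe[:, None]
        if rotation is not None:
            u = u @ rotation  # global -> local frame (R^T on column vectors)
        kp = model.kappa_prime
        for l in sorted({l for (l, _) in model.p_lm}):
            jl = slater_fourier_bessel(l, int(model.radial_n[l]),
                                       model.radial_zeta[l], s / kp)
            ang = np.zeros(len(u))
            for (ll, m), p in model.p_lm.items():
                if ll == l and p != 0.0:
                    ang = ang + p * real_sph_harm(l, m, u)
            fx = fx + 4.0 * math.pi * (1j) ** l * jl * ang
    rad = getattr(radiation, "value", radiation)
    if rad == "xray":
        return fx
    if rad != "electron":
        raise ValueError(f"unknown radiation {radiation!r}")
    # Mott-Bethe on the full complex X-ray factor
    out = np.empty_like(fx)
    big = s >= s_min
    sb = s[big]
    out[big] = MOTT_BETHE_C * (model.z - fx[big]) / sb**2
    if np.any(~big):
        if abs(model.charge) > 1e-6:
            raise ValueError(
                "electron factor of a charged pseudoatom diverges below "
                f"s={s_min}")
        # series limit using the spherical part (deformation terms with
        # l >= 1 vanish at least as s^l and do not contribute at s -> 0,
        # l=1 contributes linearly; evaluated via small-s quadratic fit)
        for i in np.nonzero(~big)[0]:
            h1 = hvec[i] * 1.0
            n1 = np.linalg.norm(h1)
            if n1 < 1e-12:
                direc = np.array([0.0, 0.0, 1.0])
            else:
                direc = h1 / n1
            s1, s2 = s_min, 2.0 * s_min
            f1 = hc_form_factor(model, direc[None, :] * 2 * s1, "xray",
                                rotation)[0]
            f2 = hc_form_factor(model, direc[None, :] * 2 * s2, "xray",
                                rotation)[0]
            g1, g2 = model.z - f1, model.z - f2
            beta = (g2 / s2**2 - g1 / s1**2) / (s2**2 - s1**2)
            alpha = g1 / s1**2 - beta * s1**2
            out[i] = MOTT_BETHE_C * (alpha + beta * s[i] ** 2)
    return out


def spherical_component_curve(model: MultipoleAtomModel, s,
                              radiation="xray", s_min: float = 0.01
                              ) -> np.ndarray:
    """f_core + P_val f_val(kappa) on an s grid, ignoring deformation terms."""
    s = np.asarray(s, dtype=float)
    fx = model.f_core(s) + model.p_val * model.f_val(s / model.kappa)
    rad = getattr(radiation, "value", radiation)
    if rad == "xray":
        return fx
    from .formfactor import mott_bethe
    func = lambda ss: model.f_core(ss) + model.p_val * model.f_val(ss / model.kappa)
    return mott_bethe(func, model.z, s, s_min=s_min)
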