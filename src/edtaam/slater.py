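"""Slater-type radial functions, screening rules and their Fourier transforms.

The spherical building block is the normalized single-exponential density

    rho_{n,zeta}(r) = N r^(2n-2) exp(-2 zeta r),   integral rho d3r = 1,

which is the modulus-squared of a single-zeta Slater orbital with quantum
number ``n`` and exponent ``zeta``.  Atomic densities are superpositions of
such shells with the shell occupancies of the electron configuration;
exponents come from Slater's screening rules (computed, not tabulated, so the
parametrization is reproducible from the configuration alone).

Deformation (aspherical) density terms use the conventional normalized radial
function

    R_l(r) = alpha^(n+3) / (n+2)!  r^n exp(-alpha r),  integral R r^2 dr = 1,

whose order-``l`` Fourier-Bessel transform ``<j_l>(q)`` is evaluated in
closed form (with a series fallback at small ``q`` to avoid cancellation).

All lengths are Angstrom, exponents 1/Angstrom, and ``q = 4 pi s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import BOHR_ANGSTROM

__all__ = [
    "Shell",
    "slater_exponent",
    "spherical_atom_shells",
    "shells_ff",
    "shells_density",
    "slater_fourier_bessel",
    "real_sph_harm",
    "VALENCE_ELECTRONS",
    "ATOMIC_NUMBER",
]

# Ground-state configurations as (n, l, occupancy) in Slater-group order.
_CONFIG = {
    "H": [(1, 0, 1)],
    "C": [(1, 0, 2), (2, 0, 2), (2, 1, 2)],
    "N": [(1, 0, 2), (2, 0, 2), (2, 1, 3)],
    "O": [(1, 0, 2), (2, 0, 2), (2, 1, 4)],
    "F": [(1, 0, 2), (2, 0, 2), (2, 1, 5)],
    "Fe": [
        (1, 0, 2),
        (2, 0, 2), (2, 1, 6),
        (3, 0, 2), (3, 1, 6),
        (3, 2, 6),
        (4, 0, 2),
    ],
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Fe": 26}

#: Number of valence electrons of the neutral atom (outermost shells; for Fe
#: the 3d+4s block).
VALENCE_ELECTRONS = {"H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "Fe": 8}

_N_EFF = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7, 5: 4.0, 6: 4.2}


@dataclass(frozen=True)
class Shell:
    """One occupied (n, l) shell with its Slater exponent in 1/Angstrom."""

    n: int
    l: int
    occ: float
    zeta: float


def _slater_group(n: int, l: int) -> tuple[int, int]:
    # Slater groups: [1s][2s2p][3s3p][3d][4s4p][4d][4f]...
    if l <= 1:
        return (n, 0)
    return (n, l)


def slater_exponent(element: str, n: int, l: int,
                    config: list[tuple[int, int, float]] | None = None) -> float:
    """Slater's-rules orbital exponent for shell (n, l), in 1/Angstrom."""
    Z = ATOMIC_NUMBER[element]
    cfg = config if config is not None else _CONFIG[element]
    group = _slater_group(n, l)
    sigma = 0.0
    for (nn, ll, occ) in cfg:
        if occ <= 0:
            continue
        g = _slater_group(nn, ll)
        if g == group:
            n_same = occ - 1 if (nn, ll) == (n, l) else occ
            sigma += (0.30 if group == (1, 0) else 0.35) * n_same
        elif g < group:
            if l <= 1:
                sigma += (0.85 if nn == n - 1 else 1.00) * occ
            else:
                # d/f electron: everything below screens fully
                sigma += 1.00 * occ
    zeta_au = max(Z - sigma, 0.3) / _N_EFF[n]
    return zeta_au / BOHR_ANGSTROM


def spherical_atom_shells(element: str, charge: float = 0.0
                          ) -> list[Shell]:
    """Shells of an isolated (possibly ionized) atom.

    A positive ``charge`` removes electrons from the outermost shells first
    (4s before 3d for transition metals, following the usual cation rule);
    a negative charge adds electrons to the outermost open shell.
    """
    cfg = [list(t) for t in _CONFIG[element]]
    q = float(charge)
    if q > 0:
        # removal order: descending (n, then l=0 before higher l at same n)
        order = sorted(range(len(cfg)),
                       key=lambda i: (cfg[i][0], -cfg[i][1]), reverse=True)
        for i in order:
            if q <= 0:
                break
            take = min(cfg[i][2], q)
            cfg[i][2] -= take
            q -= take
    elif q < 0:
        cfg[-1][2] += -q
    shells = []
    cfg_t = [tuple(t) for t in cfg]
    for (n, l, occ) in cfg_t:
        if occ <= 0:
            continue
        shells.append(Shell(n, l, occ, slater_exponent(element, n, l, cfg_t)))
    return shells


# ---------------------------------------------------------------------------
# Fourier transforms


def _F(n: int, alpha: float, q: np.ndarray) -> np.ndarray:
    """int_0^inf r^n exp(-alpha r) exp(i q r) dr = n! / (alpha - i q)^(n+1)."""
    return math.factorial(n) / (alpha - 1j * q) ** (n + 1)


def shells_ff(shells: list[Shell], s) -> np.ndarray:
    """Spherical scattering factor (electrons) of a shell superposition.

    f(s) = sum_shells occ * f_shell(q),  q = 4 pi s; f_shell(0) = 1.
    """
    s = np.asarray(s, dtype=float)
    q = 4.0 * math.pi * s
    out = np.zeros_like(s)
    small = q < 1e-8
    qs = np.where(small, 1.0, q)
    for sh in shells:
        m = 2 * sh.n
        alpha = 2.0 * sh.zeta
        # f(q) = alpha^(2n+1)/(2n)! * Im F(2n-1)/q
        val = alpha ** (m + 1) / math.factorial(m) * np.imag(
            _F(m - 1, alpha, qs)) / qs
        out += sh.occ * np.where(small, 1.0, val)
    return out


def shells_density(shells: list[Shell], r) -> np.ndarray:
    """Radial density rho(r) (electrons / Angstrom^3) of a shell superposition."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for sh in shells:
        m = 2 * sh.n - 2
        alpha = 2.0 * sh.zeta
        N = alpha ** (m + 3) / (4.0 * math.pi * math.factorial(m + 2))
        out += sh.occ * N * r**m * np.exp(-alpha * r)
    return out


# spherical Bessel expansions:  j_l(x) = sum_k  c_sin[k]/x^k sin x + c_cos[k]/x^k cos x
_JL = {
    0: ({1: 1.0}, {}),
    1: ({2: 1.0}, {1: -1.0}),
    2: ({3: 3.0, 1: -1.0}, {2: -3.0}),
    3: ({4: 15.0, 2: -6.0}, {3: -15.0, 1: 1.0}),
    4: ({5: 105.0, 3: -45.0, 1: 1.0}, {4: -105.0, 2: 10.0}),
}


def _dfact(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def slater_fourier_bessel(l: int, n: int, alpha: float, s) -> np.ndarray:
    """<j_l>(q) = alpha^(n+3)/(n+2)! * int r^(n+2) exp(-alpha r) j_l(q r) dr.

    ``n`` is the Slater radial power of R_l(r) (so the integrand carries
    r^(n+2)); requires n >= l - 1 for convergence of every partial term.
    """
    if l not in _JL:
        raise ValueError(f"unsupported multipole order l={l}")
    m = n + 2
    if m - l - 1 < 0:
        raise ValueError(f"radial power n={n} too small for l={l}")
    s = np.asarray(s, dtype=float)
    q = 4.0 * math.pi * s
    norm = alpha ** (n + 3) / math.factorial(n + 2)
    out = np.empty_like(q)
    small = q < 0.2 * alpha
    # power series of j_l(x) = sum_k (-1)^k x^(l+2k) / (2^k k! (2l+2k+1)!!),
    # summed adaptively; converges fast for q < alpha/4
    if np.any(small):
        qq = q[small]
        g = lambda p: math.factorial(p) / alpha ** (p + 1)
        ser = np.zeros_like(qq)
        for k in range(40):
            term = ((-1) ** k * qq ** (l + 2 * k)
                    / (2.0**k * math.factorial(k) * _dfact(2 * l + 2 * k + 1))
                    * g(m + l + 2 * k))
            ser += term
            if np.max(np.abs(term)) < 1e-15 * max(np.max(np.abs(ser)), 1e-300):
                break
        out[small] = norm * ser
    big = ~small
    if np.any(big):
        qq = q[big]
        acc = np.zeros_like(qq)
        c_sin, c_cos = _JL[l]
        for k, c in c_sin.items():
            acc += c * np.imag(_F(m - k, alpha, qq)) / qq**k
        for k, c in c_cos.items():
            acc += c * np.real(_F(m - k, alpha, qq)) / qq**k
        out[big] = norm * acc
    return out


def slater_radial(l_power_n: int, alpha: float, r) -> np.ndarray:
    """Normalized deformation radial function R(r) = N r^n exp(-alpha r)."""
    n = l_power_n
    r = np.asarray(r, dtype=float)
    N = alpha ** (n + 3) / math.factorial(n + 2)
    return N * r**n * np.exp(-alpha * r)


# ---------------------------------------------------------------------------
# Real spherical harmonics (orthonormal), l <= 4


@lru_cache(maxsize=None)
def _lpmv_coeff(l: int, m: int) -> float:
    return math.sqrt((2 * l + 1) / (4 * math.pi)
                     * math.factorial(l - m) / math.factorial(l + m))


def real_sph_harm(l: int, m: int, unit_vecs: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonic y_lm on an (N, 3) array of unit vectors.

    m > 0: cosine-type, m < 0: sine-type, Condon-Shortley phase absorbed.
    """
    from scipy.special import lpmv

    v = np.atleast_2d(np.asarray(unit_vecs, dtype=float))
    z = np.clip(v[:, 2], -1.0, 1.0)
    phi = np.arctan2(v[:, 1], v[:, 0])
    am = abs(m)
    P = lpmv(am, l, z)
    c = _lpmv_coeff(l, am)
    if m == 0:
        out = c * P
    elif m > 0:
        out = math.sqrt(2.0) * c * P * np.cos(am * phi) * (-1) ** am
    else:
        out = math.sqrt(2.0) * c * P * np.sin(am * phi) * (-1) ** am
    return out
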