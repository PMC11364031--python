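"""Spherical atomic scattering factors: IAM, charged IAM and Gaussian fits.

Three families of spherical factors are available:

* tabulated neutral factors through :mod:`gemmi` — the standard analytic
  4-Gaussian X-ray parametrization and the 5-Gaussian electron
  parametrization for neutral atoms;
* Slater-model factors for neutral *and charged* atoms computed from the
  package's own single-zeta atomic densities (``xray_slater``), from which
  charged electron factors follow via the Mott-Bethe formula;
* user-fitted sums of Gaussians (:func:`fit_gaussians`), the parametric form
  required by conventional refinement engines.

``s = sin(theta)/lambda`` in 1/Angstrom throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import MOTT_BETHE_C
from .slater import ATOMIC_NUMBER, spherical_atom_shells, shells_ff

__all__ = [
    "Radiation",
    "GaussianFormFactor",
    "FormFactorCurve",
    "evaluate_gaussian_ff",
    "xray_iam",
    "electron_iam",
    "xray_slater",
    "electron_slater",
    "mott_bethe",
    "mott_bethe_curve",
    "combine_partial_charge",
    "fit_gaussians",
]


class Radiation(enum.Enum):
    ELECTRON = "electron"
    XRAY = "xray"


@dataclass(frozen=True)
class GaussianFormFactor:
    """Sum-of-Gaussians scattering curve f(s) = sum a_i exp(-b_i s^2) + c.

    For charged species the unscreened Coulomb divergence cannot be carried
    by Gaussians; following the convention of electron ion-factor tables it
    is kept analytic: a non-zero ``coulomb_q`` adds C_MB * q / s^2 on
    evaluation (electron curves only).
    """

    species_label: str
    radiation: Radiation
    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float = 0.0
    coulomb_q: float = 0.0

    def __post_init__(self):
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have the same length")

    @property
    def n_terms(self) -> int:
        return len(self.a)

    def __call__(self, s):
        return evaluate_gaussian_ff(self, s)


@dataclass(frozen=True)
class FormFactorCurve:
    """A generic (non-parametric) scattering curve with a radiation tag."""

    species_label: str
    radiation: Radiation
    func: object = field(repr=False)

    def __call__(self, s):
        return self.func(np.asarray(s, dtype=float))


def evaluate_gaussian_ff(ff: GaussianFormFactor, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    out = np.exp(-np.multiply.outer(s**2, np.asarray(ff.b))) @ np.asarray(ff.a) \
        + ff.c
    if ff.coulomb_q != 0.0:
        if np.any(s <= 0):
            raise ValueError("charged curve undefined at s = 0")
        out = out + MOTT_BETHE_C * ff.coulomb_q / s**2
    return out


def xray_iam(element: str) -> GaussianFormFactor:
    """Neutral-atom analytic X-ray factor (4 Gaussians + constant)."""
    coef = gemmi.Element(element).it92
    return GaussianFormFactor(element, Radiation.XRAY,
                              tuple(coef.a), tuple(coef.b), coef.c)


def electron_iam(element: str) -> GaussianFormFactor:
    """Neutral-atom tabulated electron factor (5 Gaussians, Angstrom units)."""
    coef = gemmi.Element(element).c4322
    return GaussianFormFactor(element, Radiation.ELECTRON,
                              tuple(coef.a), tuple(coef.b), 0.0)


def xray_slater(element: str, charge: float = 0.0) -> FormFactorCurve:
    """Slater-model spherical X-ray factor for a neutral atom or ion."""
    shells = spherical_atom_shells(element, charge)
    label = element if charge == 0 else f"{element}{charge:+g}"
    return FormFactorCurve(label, Radiation.XRAY,
                           lambda s, sh=shells: shells_ff(sh, s))


def mott_bethe(fx, Z: float, s, s_min: float = 0.01) -> np.ndarray:
    """Electron form factor f_e(s) = C (Z - f_x(s)) / s^2, in Angstrom.

    For species that are neutral at s=0 the removable singularity is handled
    by a second-order series extrapolation below ``s_min``; for ions the
    genuine C*q/s^2 divergence makes values below ``s_min`` a domain error.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    q_net = Z - float(np.asarray(fx(np.array([0.0])))[0])
    # tolerance covers the f(0) != Z residual of fitted neutral tabulations
    neutral = abs(q_net) < 0.02
    if not neutral and np.any(s < s_min):
        raise ValueError(
            f"electron factor of an ion (net charge {q_net:+.3f}) diverges "
            f"as C*q/s^2; evaluation below s={s_min} is not defined")
    out = np.empty_like(s)
    big = s >= s_min
    sb = s[big]
    out[big] = MOTT_BETHE_C * (Z - np.asarray(fx(sb))) / sb**2
    if np.any(~big):
        # g(s) = Z - f_x(s) = alpha s^2 + beta s^4 for a neutral species
        s1, s2 = s_min, 2.0 * s_min
        g1 = Z - float(np.asarray(fx(np.array([s1])))[0])
        g2 = Z - float(np.asarray(fx(np.array([s2])))[0])
        beta = (g2 / s2**2 - g1 / s1**2) / (s2**2 - s1**2)
        alpha = g1 / s1**2 - beta * s1**2
        ss = s[~big]
        out[~big] = MOTT_BETHE_C * (alpha + beta * ss**2)
    return out


def mott_bethe_curve(fx, Z: float, label: str = "",
                     s_min: float = 0.01) -> FormFactorCurve:
    return FormFactorCurve(label or getattr(fx, "species_label", "?"),
                           Radiation.ELECTRON,
                           lambda s: mott_bethe(fx, Z, s, s_min=s_min))


def electron_slater(element: str, charge: float = 0.0,
                    s_min: float = 0.01) -> FormFactorCurve:
    """Electron factor of a (possibly charged) Slater-model atom."""
    fx = xray_slater(element, charge)
    return mott_bethe_curve(fx, ATOMIC_NUMBER[element],
                            label=fx.species_label, s_min=s_min)


def combine_partial_charge(ff_neutral, ff_ion, q_fraction: float) -> FormFactorCurve:
    """Linear combination (1-q) f_neutral + q f_ion of two same-radiation curves."""
    if not 0.0 <= q_fraction <= 1.0:
        raise ValueError("q_fraction must be in [0, 1]")
    r1 = getattr(ff_neutral, "radiation", None)
    r2 = getattr(ff_ion, "radiation", None)
    if r1 is not None and r2 is not None and r1 != r2:
        raise ValueError(f"cannot mix radiation types {r1} and {r2}")
    label = (f"{getattr(ff_neutral, 'species_label', '?')}"
             f"/{getattr(ff_ion, 'species_label', '?')}:{q_fraction:g}")
    return FormFactorCurve(
        label, r1 or r2,
        lambda s: (1.0 - q_fraction) * np.asarray(ff_neutral(s))
        + q_fraction * np.asarray(ff_ion(s)))


def gaussian_set_to_json(ffs: dict, path) -> None:
    """Serialize a {label: GaussianFormFactor} set to JSON."""
    import json

    doc = {lab: dict(species_label=f.species_label,
                     radiation=f.radiation.value, a=list(f.a), b=list(f.b),
                     c=f.c, coulomb_q=f.coulomb_q)
           for lab, f in ffs.items()}
    with open(path, "w") as fh:
        json.dump({"format": "edtaam-gaussians-1", "entries": doc}, fh,
                  indent=1)


def gaussian_set_from_json(path) -> dict:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "edtaam-gaussians-1":
        raise ValueError("not an edtaam Gaussian form-factor file")
    return {lab: GaussianFormFactor(e["species_label"],
                                    Radiation(e["radiation"]),
                                    tuple(e["a"]), tuple(e["b"]), e["c"],
                                    e.get("coulomb_q", 0.0))
            for lab, e in doc["entries"].items()}


@dataclass
class GaussianFitReport:
    rms: float
    max_abs: float
    max_rel: float
    converged: bool
    n_iter: int


def fit_gaussians(s, f, n_terms: int = 4, species_label: str = "fit",
                  radiation: Radiation = Radiation.ELECTRON,
                  fit_constant: bool = False, coulomb_q: float = 0.0,
                  max_nfev: int = 20000) -> tuple[GaussianFormFactor, GaussianFitReport]:
    """Least-squares fit of a sum of ``n_terms`` Gaussians to (s, f) samples.

    Levenberg-Marquardt with a few deterministic width initializations; the
    best fit is kept.  Non-convergence is flagged in the report, never
    silently ignored.  For electron curves of ions pass the net charge as
    ``coulomb_q``: the analytic C * q / s^2 divergence is subtracted before
    fitting and restored on evaluation.
    """
    from scipy.optimize import least_squares

    s = np.asarray(s, dtype=float)
    f = np.asarray(f, dtype=float)
    if coulomb_q != 0.0:
        if np.any(s <= 0):
            raise ValueError("charged curve samples must have s > 0")
        f = f - MOTT_BETHE_C * coulomb_q / s**2
    if s.size < 2 * n_terms + 1:
        raise ValueError("need at least 2*n_terms+1 samples")

    def unpack(p):
        a = p[:n_terms]
        b = p[n_terms:2 * n_terms] ** 2  # widths kept non-negative
        c = p[-1] if fit_constant else 0.0
        return a, b, c

    def resid(p):
        a, b, c = unpack(p)
        return np.exp(-np.multiply.outer(s**2, b)) @ a + c - f

    f0 = f[np.argmin(s)]
    best = None
    for spread in (np.array([0.1, 0.5, 2.0, 8.0, 30.0]),
                   np.array([0.05, 0.3, 1.5, 6.0, 25.0]) * 2.0,
                   np.geomspace(0.08, 60.0, 5)):
        b0 = spread[:n_terms]
        p0 = np.concatenate([np.full(n_terms, f0 / n_terms), np.sqrt(b0)])
        if fit_constant:
            p0 = np.append(p0, 0.0)
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Gaussian fit failed for every initialization")
    a, b, c = unpack(best.x)
    order = np.argsort(b)
    ff = GaussianFormFactor(species_label, radiation,
                            tuple(a[order]), tuple(b[order]), float(c),
                            coulomb_q=coulomb_q)
    res = resid(best.x)
    scale = np.maximum(np.abs(f), 1e-3 * np.max(np.abs(f)))
    report = GaussianFitReport(
        rms=float(np.sqrt(np.mean(res**2))),
        max_abs=float(np.max(np.abs(res))),
        max_rel=float(np.max(np.abs(res) / scale)),
        converged=bool(best.success),
        n_iter=int(best.nfev),
    )
    return ff, report
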