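"""Kinematical least-squares refinement against F^2 and agreement statistics.

The objective is  sum_h w_h (F_obs^2 - k |F_calc|^2)^2  with the standard
small-molecule weighting scheme

    w = 1 / [ sigma^2(F_obs^2) + (a P)^2 + b P ],   P = (F_obs^2 + 2 F_calc^2)/3,

negative F_obs^2 floored at zero inside P.  Free parameters are the scale k,
non-hydrogen fractional coordinates and anisotropic U_ij (or U_iso);
hydrogens ride on their parents with fixed offsets and U_iso tied to the
parent U_eq.  Minimization is Levenberg-Marquardt with analytic derivatives;
form factors are frozen during a refinement (the .tsc convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalStructure, ReflectionSet
from .structure_factors import atom_factor_array, debye_waller

__all__ = ["RefinementConfig", "RefinementResult", "weight", "r_factors",
           "goof", "shell_r1", "ellipsoid_ratios", "rmsd_models",
           "refine_lsq", "optimize_weights", "f_and_sigma_from_f2"]

#: Riding-distance table (Angstrom), neutron-normalized X-H bond lengths.
RIDING_XH = {
    ("C", "methyl"): 1.077,
    ("C", "secondary"): 1.092,
    ("C", "aromatic"): 1.083,
    ("O", "hydroxyl"): 0.983,
    ("default", "default"): 1.083,
}


@dataclass
class RefinementConfig:
    weight_a: float = 0.0
    weight_b: float = 0.0
    optimize_weights: bool = False
    f_obs_sigma_cut: float = 4.0
    max_iterations: int = 100
    convergence_threshold: float = 1e-9
    refine_coordinates: bool = True
    refine_adps: bool = True
    extinction_refined: bool = False
    parameter_locks: frozenset = frozenset()
    n_weight_cycles: int = 3

    def __post_init__(self):
        if self.weight_a < 0 or self.weight_b < 0:
            raise ValueError("weighting scalars must be non-negative")
        if self.f_obs_sigma_cut < 0:
            raise ValueError("sigma cut must be non-negative")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    scale: float
    r1_strong: float
    r1_all: float
    wr2: float
    goof: float
    n_reflections: int
    n_strong: int
    n_params: int
    weights: tuple[float, float]
    f_calc: np.ndarray
    converged: bool
    n_iter: int
    extinction: float = 0.0
    history: list = field(default_factory=list)
    #: parameter shifts (final - initial) and esds from the LM covariance,
    #: ordered as [scale, per-site coords/U, (extinction)]
    shifts: np.ndarray | None = None
    esds: np.ndarray | None = None


def weight(f_obs2, sigma, f_calc2, a: float, b: float) -> np.ndarray:
    """SHELX-style weights; sigma must be positive."""
    f_obs2 = np.asarray(f_obs2, float)
    sigma = np.asarray(sigma, float)
    f_calc2 = np.asarray(f_calc2, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    P = (np.maximum(f_obs2, 0.0) + 2.0 * f_calc2) / 3.0
    return 1.0 / (sigma**2 + (a * P) ** 2 + b * P)


def f_and_sigma_from_f2(f2, sigma2):
    """Convert F^2, sigma(F^2) to F, sigma(F) by simple truncation.

    F = sqrt(max(F^2, 0)); sigma(F) = sigma(F^2) / (2 F) with a floor at
    sigma(F^2)^(1/2) for weak reflections.
    """
    f2 = np.asarray(f2, float)
    sigma2 = np.asarray(sigma2, float)
    f = np.sqrt(np.maximum(f2, 0.0))
    sf = np.where(f > np.sqrt(sigma2) / 2.0,
                  sigma2 / np.maximum(2.0 * f, 1e-30), np.sqrt(sigma2))
    return f, sf


def r_factors(f_obs2, sigma, f_calc2, scale: float = 1.0,
              cut: float = 4.0):
    """(R1_strong, R1_all, wR2): R1 on |F| over F_o > cut*sigma(F_o), wR2 on F^2.

    wR2 uses unit weights here; the weighted refinement statistic with the
    full scheme is reported by :func:`goof` and the refinement result.
    """
    f_obs2 = np.asarray(f_obs2, float)
    sigma = np.asarray(sigma, float)
    f_calc2 = np.asarray(f_calc2, float)
    fo, sfo = f_and_sigma_from_f2(f_obs2, sigma)
    fc = np.sqrt(np.maximum(scale * f_calc2, 0.0))
    strong = fo > cut * sfo
    def r1(mask):
        if not np.any(mask):
            return float("nan")
        return float(np.sum(np.abs(fo[mask] - fc[mask]))
                     / np.sum(fo[mask]))
    num = np.sum((f_obs2 - scale * f_calc2) ** 2)
    den = np.sum(f_obs2**2)
    wr2 = float(np.sqrt(num / den)) if den > 0 else float("nan")
    return r1(strong), r1(np.ones_like(strong, bool)), wr2


def goof(f_obs2, sigma, f_calc2, weights, n_params: int,
         scale: float = 1.0) -> float:
    f_obs2 = np.asarray(f_obs2, float)
    n = len(f_obs2)
    if n <= n_params:
        raise ValueError(f"degrees of freedom <= 0 (n={n}, p={n_params})")
    resid = f_obs2 - scale * np.asarray(f_calc2, float)
    chi2 = np.sum(np.asarray(weights, float) * resid**2)
    return float(np.sqrt(chi2 / (n - n_params)))


def shell_r1(reflections: ReflectionSet, f_calc2, scale: float,
             shell_boundaries, cut: float = 4.0):
    """Per-shell R1 with all parameters and the global scale locked.

    ``shell_boundaries`` are resolution limits in Angstrom, descending
    (e.g. [8.65, 2.0, 0.85] gives two shells).  Returns a list of dicts.
    """
    b = list(shell_boundaries)
    if b != sorted(b, reverse=True):
        raise ValueError("shell boundaries must be descending")
    f_calc2 = np.asarray(f_calc2, float)
    out = []
    for dmax, dmin in zip(b[:-1], b[1:]):
        mask = (reflections.d <= dmax) & (reflections.d > dmin)
        n_all = int(np.sum(mask))
        if n_all == 0:
            out.append(dict(d_max=dmax, d_min=dmin, n_strong=0, n_all=0,
                            r1_strong=float("nan"), r1_all=float("nan")))
            continue
        fo, sfo = f_and_sigma_from_f2(reflections.f2[mask],
                                      reflections.sigma[mask])
        r1s, r1a, _ = r_factors(reflections.f2[mask],
                                reflections.sigma[mask],
                                f_calc2[mask], scale, cut)
        out.append(dict(d_max=dmax, d_min=dmin,
                        n_strong=int(np.sum(fo > cut * sfo)), n_all=n_all,
                        r1_strong=r1s, r1_all=r1a))
    return out


def u_cartesian(structure: CrystalStructure, site) -> np.ndarray:
    """U tensor in a Cartesian frame (CIF convention conversion)."""
    N = np.diag(structure.cell.reciprocal_lengths)
    A = structure.cell.orth_matrix
    U = site.u_matrix()
    return A @ N @ U @ N @ A.T


def ellipsoid_ratios(structure: CrystalStructure):
    """Max/min RMS displacement ratio per anisotropic atom and their mean.

    Non-positive-definite tensors are flagged and excluded from the mean.
    """
    per_atom = {}
    flagged = []
    vals = []
    for site in structure.sites:
        if not site.is_aniso:
            continue
        evals = np.linalg.eigvalsh(u_cartesian(structure, site))
        if evals[0] <= 0:
            flagged.append(site.label)
            per_atom[site.label] = float("nan")
            continue
        ratio = float(np.sqrt(evals[-1] / evals[0]))
        per_atom[site.label] = ratio
        vals.append(ratio)
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_atom, mean, flagged


def rmsd_models(model_a: CrystalStructure, model_b: CrystalStructure,
                include_h: bool = False):
    """(coordinate RMSD, bond-length RMSD) in Angstrom over matched labels."""
    from .geometry import bond_list

    sel_a = {s.label: s for s in model_a.sites
             if include_h or s.element != "H"}
    sel_b = {s.label: s for s in model_b.sites
             if include_h or s.element != "H"}
    unmatched = sorted(set(sel_a) ^ set(sel_b))
    if unmatched:
        raise ValueError(f"unmatched atom labels: {unmatched}")
    labels = sorted(sel_a)
    xa = model_a.cell.orthogonalize(
        np.array([sel_a[l].frac for l in labels]))
    xb = model_b.cell.orthogonalize(
        np.array([sel_b[l].frac for l in labels]))
    coord_rmsd = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    bonds = [(a, b) for a, b, _ in bond_list(model_a)
             if a in sel_a and b in sel_a]
    if bonds:
        da, db = [], []
        pos_a = {l: x for l, x in zip(labels, xa)}
        pos_b = {l: x for l, x in zip(labels, xb)}
        for a, b in bonds:
            da.append(np.linalg.norm(pos_a[a] - pos_a[b]))
            db.append(np.linalg.norm(pos_b[a] - pos_b[b]))
        bond_rmsd = float(np.sqrt(np.mean((np.array(da) - np.array(db))**2)))
    else:
        bond_rmsd = float("nan")
    return coord_rmsd, bond_rmsd


# ---------------------------------------------------------------------------
# Riding hydrogens


def riding_map(structure: CrystalStructure):
    """parent label and U_eq multiplier for every H; offsets fixed in fractional space."""
    from .geometry import bonded_neighbours

    nb = bonded_neighbours(structure)
    riders = {}
    for site in structure.sites:
        if site.element != "H":
            continue
        parents = [l for l in nb[site.label]
                   if structure.site(l).element != "H"]
        if not parents:
            continue
        parent = parents[0]
        n_h = sum(1 for l in nb[parent]
                  if structure.site(l).element == "H")
        mult = 1.5 if n_h >= 3 else 1.2
        offset = site.frac - structure.site(parent).frac
        riders[site.label] = (parent, mult, offset.copy())
    return riders


def apply_riding(structure: CrystalStructure, riders) -> None:
    for h_label, (parent, mult, offset) in riders.items():
        h = structure.site(h_label)
        p = structure.site(parent)
        h.frac = p.frac + offset
        ueq = float(np.trace(p.u_matrix()) / 3.0)
        h.u_iso = mult * ueq
        h.u_aniso = None


# ---------------------------------------------------------------------------
# Least-squares engine


class _Parametrization:
    """Maps the free-parameter vector onto a working structure."""

    def __init__(self, structure: CrystalStructure, config: RefinementConfig):
        self.structure = structure
        self.config = config
        self.riders = riding_map(structure)
        self.free_sites = [
            s.label for s in structure.sites
            if s.element != "H" and s.label not in config.parameter_locks]
        self.slices = {}
        idx = 1  # slot 0 is the scale factor
        for lab in self.free_sites:
            site = structure.site(lab)
            ncoord = 3 if config.refine_coordinates else 0
            nu = (6 if site.is_aniso else 1) if config.refine_adps else 0
            self.slices[lab] = (idx, ncoord, nu)
            idx += ncoord + nu
        # optional single isotropic extinction scalar, last slot
        self.extinction_index = idx if config.extinction_refined else None
        if config.extinction_refined:
            idx += 1
        self.n_params = idx

    def get_vector(self, scale: float) -> np.ndarray:
        p = np.zeros(self.n_params)
        p[0] = scale
        for lab, (i, nc, nu) in self.slices.items():
            site = self.structure.site(lab)
            if nc:
                p[i:i + 3] = site.frac
            if nu == 6:
                p[i + nc:i + nc + 6] = site.u_aniso
            elif nu == 1:
                p[i + nc] = site.u_iso
        return p

    def set_vector(self, p: np.ndarray) -> None:
        for lab, (i, nc, nu) in self.slices.items():
            site = self.structure.site(lab)
            if nc:
                site.frac = p[i:i + 3].copy()
            if nu == 6:
                site.u_aniso = p[i + nc:i + nc + 6].copy()
            elif nu == 1:
                site.u_iso = float(p[i + nc])
        apply_riding(self.structure, self.riders)


def _sf_with_derivs(par: _Parametrization, hkl: np.ndarray,
                    fvals: np.ndarray, s: np.ndarray,
                    want_derivs: bool = True):
    """F(h) and dF/dparam for the current working structure."""
    st = par.structure
    sg = st.spacegroup
    x = st.frac_coords()
    occ = np.array([site.occupancy for site in st.sites])
    astar = st.cell.reciprocal_lengths
    M = len(hkl)
    F = np.zeros(M, dtype=complex)
    dF = np.zeros((M, par.n_params), dtype=complex) if want_derivs else None
    # children per free parent (riding H move and U_eq ties)
    children = {lab: [] for lab in par.free_sites}
    for h_lab, (parent, mult, _) in par.riders.items():
        if parent in children:
            children[parent].append((h_lab, mult))
    index = {site.label: j for j, site in enumerate(st.sites)}
    for o in range(sg.n_ops):
        h_op = hkl @ sg.rotations[o]
        t = sg.translations[o]
        q = h_op * astar[None, :]
        phase = np.exp(2j * math.pi * (h_op @ x.T + (hkl @ t)[:, None]))
        T = debye_waller(st, h_op, s)
        G = fvals[o] * T * phase * occ[None, :]     # (M, N)
        F += G.sum(axis=1)
        if not want_derivs:
            continue
        for lab, (i, nc, nu) in par.slices.items():
            j = index[lab]
            cols = [j] + [index[hl] for hl, _ in children[lab]]
            Gj = G[:, cols].sum(axis=1) if len(cols) > 1 else G[:, j]
            if nc:
                # riding H shift rigidly with the parent: same fractional derivative
                Gc = G[:, cols]  # (M, n_children+1)
                dph = 2j * math.pi * h_op  # (M, 3)
                for c in range(3):
                    dF[:, i + c] += (Gc * dph[:, c:c + 1]).sum(axis=1)
            if nu == 6:
                base = i + nc
                pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
                for kk, (aa, bb) in enumerate(pairs):
                    mult = 1.0 if aa == bb else 2.0
                    dT = -2.0 * math.pi**2 * mult * q[:, aa] * q[:, bb]
                    dF[:, base + kk] += G[:, j] * dT
                    # U_eq tie of riding H (diagonal components only)
                    if aa == bb and children[lab]:
                        for hl, hmult in children[lab]:
                            jh = index[hl]
                            dTh = -8.0 * math.pi**2 * s**2 * (hmult / 3.0)
                            dF[:, base + kk] += G[:, jh] * dTh
            elif nu == 1:
                dT = -8.0 * math.pi**2 * s**2
                dF[:, i + nc] += G[:, j] * dT
                for hl, hmult in children[lab]:
                    jh = index[hl]
                    dF[:, i + nc] += G[:, jh] * dT * hmult
    return F, dF


def refine_lsq(structure: CrystalStructure, reflections: ReflectionSet,
               provider, config: RefinementConfig | None = None
               ) -> RefinementResult:
    """Weighted F^2 refinement; returns refined structure and statistics."""
    from scipy.optimize import least_squares

    config = config or RefinementConfig()
    work = structure.copy()
    par = _Parametrization(work, config)
    if par.n_params >= len(reflections):
        raise ValueError(
            f"n_params={par.n_params} >= n_obs={len(reflections)}")
    hkl = reflections.hkl.astype(float)
    s = reflections.s
    fvals = atom_factor_array(work, hkl, provider)
    f_obs2 = reflections.f2
    sigma = reflections.sigma

    # initial scale from a quick F_calc
    F0, _ = _sf_with_derivs(par, hkl, fvals, s, want_derivs=False)
    fc2 = np.abs(F0) ** 2
    scale0 = float(np.sum(f_obs2 * fc2) / np.sum(fc2**2))
    p = par.get_vector(scale0)
    p_init = p.copy()

    a, b = config.weight_a, config.weight_b
    history = []
    converged = False
    n_iter_total = 0
    for cycle in range(config.n_weight_cycles):
        par.set_vector(p)
        Fc, _ = _sf_with_derivs(par, hkl, fvals, s, want_derivs=False)
        w = weight(f_obs2, sigma, p[0] * np.abs(Fc) ** 2, a, b)
        sw = np.sqrt(w)

        ext = par.extinction_index

        def _eff(pv, y):
            if ext is None:
                return y, np.ones_like(y)
            damp = 1.0 + pv[ext] * y
            return y / damp, 1.0 / damp**2

        def resid(pv):
            par.set_vector(pv)
            F, _ = _sf_with_derivs(par, hkl, fvals, s, want_derivs=False)
            eff, _ = _eff(pv, np.abs(F) ** 2)
            return sw * (f_obs2 - pv[0] * eff)

        def jac(pv):
            par.set_vector(pv)
            F, dF = _sf_with_derivs(par, hkl, fvals, s)
            y = np.abs(F) ** 2
            eff, deff_dy = _eff(pv, y)
            J = np.empty((len(hkl), par.n_params))
            dabs2 = 2.0 * np.real(np.conj(F)[:, None] * dF)
            J[:] = -sw[:, None] * pv[0] * deff_dy[:, None] * dabs2
            J[:, 0] = -sw * eff
            if ext is not None:
                J[:, ext] = sw * pv[0] * y**2 / (1.0 + pv[ext] * y) ** 2
            return J

        sol = least_squares(resid, p, jac=jac, method="lm",
                            xtol=config.convergence_threshold,
                            ftol=config.convergence_threshold,
                            max_nfev=config.max_iterations * 3)
        p = sol.x
        n_iter_total += sol.nfev
        history.append(dict(cycle=cycle, cost=float(sol.cost),
                            nfev=int(sol.nfev)))
        converged = bool(sol.success)

    # esds from the weighted normal matrix at convergence
    J = jac(p)
    r = resid(p)
    dof = max(len(hkl) - par.n_params, 1)
    try:
        cov = np.linalg.inv(J.T @ J) * (r @ r) / dof
        esds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        names = [lab for lab in par.free_sites]
        raise ValueError(
            f"singular normal matrix; check parameters of sites {names}")
    par.set_vector(p)
    Fc, _ = _sf_with_derivs(par, hkl, fvals, s, want_derivs=False)
    fc2 = np.abs(Fc) ** 2
    x_ext = float(p[par.extinction_index]) if par.extinction_index else 0.0
    if par.extinction_index is not None:
        fc2 = fc2 / (1.0 + x_ext * fc2)
    scale = float(p[0])
    w = weight(f_obs2, sigma, scale * fc2, a, b)
    r1s, r1a, wr2 = r_factors(f_obs2, sigma, fc2, scale,
                              config.f_obs_sigma_cut)
    fo, sfo = f_and_sigma_from_f2(f_obs2, sigma)
    gf = goof(f_obs2, sigma, fc2, w, par.n_params, scale)
    return RefinementResult(
        structure=work, scale=scale, r1_strong=r1s, r1_all=r1a, wr2=wr2,
        goof=gf, n_reflections=len(reflections),
        n_strong=int(np.sum(fo > config.f_obs_sigma_cut * sfo)),
        n_params=par.n_params, weights=(a, b), f_calc=Fc,
        converged=converged, n_iter=n_iter_total, history=history,
        extinction=x_ext, shifts=p - p_init, esds=esds)


def optimize_weights(f_obs2, sigma, f_calc2, scale: float, n_params: int,
                     n_intensity_bins: int = 10, n_resolution_bins: int = 5,
                     d=None, max_cycles: int = 200):
    """Optimize (a, b) so the goodness of fit is flat and close to one.

    Reflections are binned by calculated intensity (and resolution when ``d``
    is given); a Nelder-Mead search minimizes the squared deviation of every
    bin GooF from 1.  Returns (a, b, bin_table, converged).
    """
    from scipy.optimize import minimize

    f_obs2 = np.asarray(f_obs2, float)
    sigma = np.asarray(sigma, float)
    f_calc2 = np.asarray(f_calc2, float) * scale
    n = len(f_obs2)
    resid2 = (f_obs2 - f_calc2) ** 2
    order = np.argsort(f_calc2)
    bins = [order[i::n_intensity_bins] for i in range(n_intensity_bins)]
    if d is not None:
        order_d = np.argsort(np.asarray(d, float))
        bins += [order_d[i::n_resolution_bins]
                 for i in range(n_resolution_bins)]
    dof = max(n - n_params, 1)

    def bin_goofs(ab):
        a, b = abs(ab[0]), abs(ab[1])
        w = weight(f_obs2, sigma, f_calc2, a, b)
        chi = w * resid2 * (n / dof)
        return np.array([np.sqrt(np.mean(chi[idx])) for idx in bins])

    def objective(ab):
        g = bin_goofs(ab)
        return float(np.sum((g - 1.0) ** 2))

    best = None
    for start in ([0.05, 0.0], [0.15, 1.0], [0.0, 0.5]):
        sol = minimize(objective, np.asarray(start), method="Nelder-Mead",
                       options=dict(maxiter=max_cycles, xatol=1e-5,
                                    fatol=1e-10))
        if best is None or sol.fun < best.fun:
            best = sol
    a, b = abs(best.x[0]), abs(best.x[1])
    table = bin_goofs(best.x)
    return float(a), float(b), table, bool(best.success)
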