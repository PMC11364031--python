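"""Kinematical structure factors with pluggable per-atom scattering models.

F(h) = sum_ops sum_sites occ * f_site(h R_op) * T(h R_op; U_site)
       * exp(2 pi i [ (h R_op) . x_site + h . t_op ])

Aspherical form factors are evaluated at the rotated reciprocal vector
``h R_op`` so that each symmetry copy scatters with its correctly oriented
pseudoatom density; displacement factors use the same trick with the
asymmetric-unit U tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crystal import CrystalStructure, UnitCell

__all__ = ["SphericalProvider", "MultipoleProvider", "TableProvider",
           "HybridProvider", "atom_factor_array", "calc_structure_factors",
           "debye_waller", "local_axes_rotation"]


class SphericalProvider:
    """Direction-independent factors: one curve f(s) per scatterer key."""

    def __init__(self, curves: dict):
        self.curves = dict(curves)

    def factors(self, structure, hkl, hvec, s, op_index):
        n = len(structure.sites)
        out = np.empty((len(s), n), dtype=complex)
        cache = {}
        for j, site in enumerate(structure.sites):
            key = site.scatterer
            if key not in cache:
                try:
                    curve = self.curves[key]
                except KeyError:
                    raise KeyError(
                        f"no scattering curve for scatterer {key!r}") from None
                cache[key] = np.asarray(curve(s), dtype=complex)
            out[:, j] = cache[key]
        return out


class MultipoleProvider:
    """Hansen-Coppens pseudoatom factors, with per-site local frames."""

    def __init__(self, models: dict, rotations: dict | None = None,
                 radiation="electron"):
        self.models = dict(models)
        self.rotations = dict(rotations or {})
        self.radiation = radiation

    def factors(self, structure, hkl, hvec, s, op_index):
        from .multipole import hc_form_factor
        n = len(structure.sites)
        out = np.empty((len(s), n), dtype=complex)
        for j, site in enumerate(structure.sites):
            model = self.models[site.label]
            rot = self.rotations.get(site.label)
            out[:, j] = hc_form_factor(model, hvec, self.radiation, rot)
        return out


class TableProvider:
    """Per-reflection factors looked up from a FormFactorTable (.tsc)."""

    def __init__(self, table):
        self.table = table
        self._index = {tuple(h): i for i, h in enumerate(table.hkl)}
        self._col = {lab: k for k, lab in enumerate(table.atoms)}

    def factors(self, structure, hkl, hvec, s, op_index):
        rows = np.empty(len(hkl), dtype=int)
        for i, h in enumerate(np.asarray(hkl, int)):
            key = tuple(int(v) for v in h)
            if key not in self._index:
                raise KeyError(f"reflection {key} missing from form-factor table")
            rows[i] = self._index[key]
        cols = []
        for site in structure.sites:
            if site.label not in self._col:
                raise KeyError(f"atom {site.label!r} missing from form-factor table")
            cols.append(self._col[site.label])
        return self.table.values[np.ix_(rows, cols)]


class HybridProvider:
    """Route each site to a provider by its part_id (hybrid IAM/TAAM models)."""

    def __init__(self, part_providers: dict):
        self.part_providers = dict(part_providers)

    def factors(self, structure, hkl, hvec, s, op_index):
        n = len(structure.sites)
        out = np.empty((len(s), n), dtype=complex)
        done = np.zeros(n, dtype=bool)
        for part, provider in self.part_providers.items():
            cols = [j for j, site in enumerate(structure.sites)
                    if site.part_id == part]
            if not cols:
                continue
            sub = provider.factors(structure, hkl, hvec, s, op_index)
            out[:, cols] = sub[:, cols]
            done[cols] = True
        if not done.all():
            missing = [structure.sites[j].part_id for j in np.nonzero(~done)[0]]
            raise KeyError(f"no provider for part_id(s) {sorted(set(missing))}")
        return out


def debye_waller(structure: CrystalStructure, hkl_rot: np.ndarray,
                 s: np.ndarray) -> np.ndarray:
    """Anisotropic/isotropic attenuation, shape (n_refl, n_sites)."""
    astar = structure.cell.reciprocal_lengths
    q = hkl_rot * astar[None, :]  # h_i a*_i components
    n = len(structure.sites)
    out = np.empty((len(hkl_rot), n))
    for j, site in enumerate(structure.sites):
        if site.u_aniso is not None:
            u11, u22, u33, u12, u13, u23 = site.u_aniso
            expo = (u11 * q[:, 0]**2 + u22 * q[:, 1]**2 + u33 * q[:, 2]**2
                    + 2 * u12 * q[:, 0] * q[:, 1]
                    + 2 * u13 * q[:, 0] * q[:, 2]
                    + 2 * u23 * q[:, 1] * q[:, 2])
            out[:, j] = np.exp(-2.0 * math.pi**2 * expo)
        else:
            out[:, j] = np.exp(-8.0 * math.pi**2 * (site.u_iso or 0.0) * s**2)
    return out


def atom_factor_array(structure: CrystalStructure, hkl: np.ndarray,
                      provider) -> np.ndarray:
    """Form factors f_j(h R_op), shape (n_ops, n_refl, n_sites)."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    sg = structure.spacegroup
    s = 1.0 / (2.0 * np.maximum(
        np.asarray(_d(structure.cell, hkl)), 1e-12))
    out = np.empty((sg.n_ops, len(hkl), len(structure.sites)), dtype=complex)
    for o in range(sg.n_ops):
        h_op = hkl @ sg.rotations[o]
        hvec = structure.cell.dstar_vectors(h_op)
        out[o] = provider.factors(structure, h_op, hvec, s, o)
    return out


def _d(cell: UnitCell, hkl):
    from .crystal import d_spacing
    return d_spacing(cell, hkl)


def calc_structure_factors(structure: CrystalStructure, hkl,
                           provider=None, fvals: np.ndarray | None = None
                           ) -> np.ndarray:
    """Complex structure factors for integer reflections ``hkl``.

    Either a scatterer ``provider`` or a precomputed ``fvals`` array from
    :func:`atom_factor_array` must be given.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    if fvals is None:
        if provider is None:
            raise ValueError("need provider or fvals")
        fvals = atom_factor_array(structure, hkl, provider)
    sg = structure.spacegroup
    x = structure.frac_coords()
    occ = np.array([site.occupancy for site in structure.sites])
    d = np.asarray(_d(structure.cell, hkl))
    s = 1.0 / (2.0 * np.maximum(d, 1e-12))
    F = np.zeros(len(hkl), dtype=complex)
    for o in range(sg.n_ops):
        h_op = hkl @ sg.rotations[o]
        t = sg.translations[o]
        phase = np.exp(2j * math.pi * (h_op @ x.T + (hkl @ t)[:, None]))
        T = debye_waller(structure, h_op, s)
        F += np.einsum("mn,mn,mn,n->m", fvals[o], T, phase, occ)
    return F


def local_axes_rotation(structure: CrystalStructure, label: str,
                        bonds: dict[str, list[str]] | None = None
                        ) -> np.ndarray | None:
    """Deterministic local Cartesian frame for a pseudoatom.

    z points to the highest-priority bonded neighbour (largest atomic
    number, then shortest distance, then label), x is the orthogonalized
    direction to the second neighbour; returns the matrix whose columns are
    the local axes in global coordinates, or None for isolated atoms.
    """
    from .slater import ATOMIC_NUMBER
    from .geometry import bonded_neighbours

    if bonds is None:
        bonds = bonded_neighbours(structure)
    nb = bonds.get(label, [])
    if not nb:
        return None
    cart = {s.label: c for s, c in zip(structure.sites,
                                       structure.cart_coords())}
    here = cart[label]

    def prio(other: str):
        el = structure.site(other).element
        return (-ATOMIC_NUMBER.get(el, 0),
                float(np.linalg.norm(cart[other] - here)), other)

    nb = sorted(nb, key=prio)
    z = cart[nb[0]] - here
    z = z / np.linalg.norm(z)
    xref = None
    for other in nb[1:]:
        v = cart[other] - here
        v = v - (v @ z) * z
        if np.linalg.norm(v) > 1e-6:
            xref = v / np.linalg.norm(v)
            break
    if xref is None:
        # single neighbour: any perpendicular; fixed rule for determinism
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ z) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        v = trial - (trial @ z) * z
        xref = v / np.linalg.norm(v)
    y = np.cross(z, xref)
    return np.column_stack([xref, y, z])
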