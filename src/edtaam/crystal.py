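"""Crystal data model: cell, symmetry, sites, ADPs, reflection sets.

Conventions: fractional coordinates; anisotropic displacement parameters in
the CIF U_ij convention (Angstrom^2), entering the Debye-Waller factor as

    T(h) = exp(-2 pi^2 sum_ij U_ij h_i h_j a*_i a*_j),

with a*_i the reciprocal cell lengths; s = 1/(2d) = sin(theta)/lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["UnitCell", "SpaceGroup", "AtomSite", "CrystalStructure",
           "ReflectionSet", "d_spacing", "generate_hkl"]


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")

    @property
    def gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self.gemmi.volume

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix turning fractional into Cartesian coordinates."""
        return np.array(self.gemmi.orth.mat.tolist())

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self.gemmi.frac.mat.tolist())

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        r = self.gemmi.reciprocal()
        return np.array([r.a, r.b, r.c])

    @property
    def recip_matrix(self) -> np.ndarray:
        """Rows are the reciprocal basis vectors a*, b*, c* (1/Angstrom)."""
        return np.linalg.inv(self.orth_matrix)

    def dstar_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Cartesian scattering vectors d* = h a* + k b* + l c*, |d*| = 1/d."""
        return np.atleast_2d(np.asarray(hkl, float)) @ self.recip_matrix

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(frac, float)) @ self.orth_matrix.T


def d_spacing(cell: UnitCell, hkl) -> np.ndarray:
    """Resolution d (Angstrom) of reflections; (0,0,0) maps to +inf."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    dstar = np.linalg.norm(cell.dstar_vectors(hkl), axis=-1)
    with np.errstate(divide="ignore"):
        return np.where(dstar > 0, 1.0 / np.where(dstar > 0, dstar, 1.0),
                        np.inf)


class SpaceGroup:
    """Symmetry operations, backed by gemmi (symbol- or operator-defined)."""

    def __init__(self, symbol: str | None = None,
                 triplets: list[str] | None = None):
        if triplets is not None:
            ops = gemmi.GroupOps([gemmi.Op(t) for t in triplets])
            self.symbol = symbol or "?"
        else:
            sg = gemmi.SpaceGroup(symbol)
            ops = sg.operations()
            self.symbol = sg.hm
        self._ops = ops
        self.rotations = []
        self.translations = []
        for op in ops:
            self.rotations.append(np.array(op.rot, dtype=float) / op.DEN)
            self.translations.append(np.array(op.tran, dtype=float) / op.DEN)
        self.rotations = np.array(self.rotations)
        self.translations = np.array(self.translations)

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    @property
    def triplets(self) -> list[str]:
        return [op.triplet() for op in self._ops]

    def is_absent(self, hkl) -> np.ndarray:
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        return np.array([self._ops.is_systematically_absent(list(map(int, h)))
                         for h in hkl])

    @property
    def is_centrosymmetric(self) -> bool:
        return self._ops.is_centrosymmetric()

    def gops(self) -> gemmi.GroupOps:
        return self._ops


@dataclass
class AtomSite:
    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    u_iso: float | None = None
    u_aniso: np.ndarray | None = None  # (U11, U22, U33, U12, U13, U23)
    part_id: int = 0
    scatterer: str | None = None  # defaults to element symbol

    def __post_init__(self):
        self.frac = np.asarray(self.frac, dtype=float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
        if self.scatterer is None:
            self.scatterer = self.element

    @property
    def is_aniso(self) -> bool:
        return self.u_aniso is not None

    def u_matrix(self) -> np.ndarray:
        if self.u_aniso is not None:
            u11, u22, u33, u12, u13, u23 = self.u_aniso
            return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
        u = self.u_iso or 0.0
        return np.eye(3) * u

    def copy(self) -> "AtomSite":
        return AtomSite(self.label, self.element, self.frac.copy(),
                        self.occupancy, self.u_iso,
                        None if self.u_aniso is None else self.u_aniso.copy(),
                        self.part_id, self.scatterer)


@dataclass
class CrystalStructure:
    cell: UnitCell
    spacegroup: SpaceGroup
    sites: list[AtomSite]
    name: str = "structure"

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites])

    def cart_coords(self) -> np.ndarray:
        return self.cell.orthogonalize(self.frac_coords())

    def expand_symmetry(self) -> np.ndarray:
        """All symmetry copies, fractional, shape (n_ops, n_sites, 3)."""
        x = self.frac_coords()
        sg = self.spacegroup
        return np.einsum("oij,nj->oni", sg.rotations, x) + \
            sg.translations[:, None, :]

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(self.cell, self.spacegroup,
                                [s.copy() for s in self.sites], self.name)


class ReflectionSet:
    """Unique reflections with F_obs^2 and sigma(F_obs^2).

    Duplicate hkl on input are merged with inverse-variance weights (a
    warning is emitted); sigma must be strictly positive, while negative
    F_obs^2 (weak data) are allowed.
    """

    def __init__(self, hkl, f2, sigma, cell: UnitCell):
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        f2 = np.asarray(f2, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if not (len(hkl) == len(f2) == len(sigma)):
            raise ValueError("hkl, f2, sigma must have equal lengths")
        if np.any(sigma <= 0):
            raise ValueError("sigma(F^2) must be positive")
        uniq, inverse, counts = np.unique(hkl, axis=0, return_inverse=True,
                                          return_counts=True)
        if len(uniq) != len(hkl):
            import warnings
            warnings.warn("duplicate hkl merged with inverse-variance weights")
            w = 1.0 / sigma**2
            f2m = np.bincount(inverse, weights=w * f2) / \
                np.bincount(inverse, weights=w)
            sm = 1.0 / np.sqrt(np.bincount(inverse, weights=w))
            hkl, f2, sigma = uniq, f2m, sm
        self.hkl = hkl
        self.f2 = f2
        self.sigma = sigma
        self.cell = cell
        self.d = d_spacing(cell, hkl)
        self.s = 1.0 / (2.0 * self.d)

    def __len__(self) -> int:
        return len(self.hkl)

    def select(self, mask) -> "ReflectionSet":
        return ReflectionSet(self.hkl[mask], self.f2[mask],
                             self.sigma[mask], self.cell)

    @property
    def mean_i_over_sigma(self) -> float:
        return float(np.mean(self.f2 / self.sigma))


def generate_hkl(cell: UnitCell, spacegroup: SpaceGroup,
                 d_min: float, d_max: float = np.inf,
                 unique: bool = True, drop_absent: bool = True) -> np.ndarray:
    """Integer Miller indices with d_min <= d <= d_max.

    With ``unique=True`` one representative per symmetry-equivalent group
    (reciprocal-space asymmetric unit of the Laue class) is returned.
    """
    hmax = [int(np.floor(l / d_min)) for l in (cell.a, cell.b, cell.c)]
    rng = [np.arange(-m, m + 1) for m in hmax]
    H, K, L = np.meshgrid(*rng, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacing(cell, hkl)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    if unique:
        asu = gemmi.ReciprocalAsu(gemmi.SpaceGroup(spacegroup.symbol)
                                  if spacegroup.symbol != "?" else
                                  gemmi.SpaceGroup("P1"))
        keep = np.array([asu.is_in(tuple(map(int, h))) for h in hkl])
        hkl = hkl[keep]
    if drop_absent:
        hkl = hkl[~spacegroup.is_absent(hkl)]
    return hkl
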