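"""Synthetic tris-acetylacetonate iron(III) test system with known ground truth.

Everything downstream of data collection can be exercised without any
external data: an idealized FeAcAc-like molecule (Fe + three bidentate O,O
chelating acac ligands, FeC15H21O6) is packed into an orthorhombic Pbca cell
(a=15.35, b=13.56, c=16.50 A), reflections are simulated to d_min = 0.85 A
with a declared sigma(F^2) model scaled to a target mean I/sigma and thinned
to a completeness target, and ground-truth scattering is either spherical
neutral (IAM) or an aspherical multipole model with partial charges
("taam" truth: metal charge well below the formal +3, strongly negative
carbonyl O, positive carbonyl C).

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .crystal import (AtomSite, CrystalStructure, ReflectionSet, SpaceGroup,
                      UnitCell, generate_hkl)
from .multipole import MultipoleAtomModel, neutral_multipole_atom
from .structure_factors import (MultipoleProvider, SphericalProvider,
                                calc_structure_factors, local_axes_rotation)

__all__ = ["SimulationSpec", "make_structure", "make_molecule",
           "truth_multipole_models", "simulate_reflections",
           "make_benchmark_pair", "electron_iam_curves"]

FE_O = 1.99        # Fe-O coordination distance, A
C_O = 1.28         # carbonyl C-O, conjugated chelate
C_C_RING = 1.39    # carbonyl C - central C
C_C_METHYL = 1.50
C_H_METHYL = 1.077  # neutron-normalized
C_H_RING = 1.083
O_C_C3_ANGLE = 124.0  # O-C(carbonyl)-C(central) angle, degrees

#: Molecular orientation (ZYZ Euler angles, rad) and fractional offset of the
#: Fe position used to pack the rigid molecule into the Pbca cell; found once
#: by maximizing the minimum intermolecular contact with
#: :func:`optimize_placement` and frozen for reproducibility.
DEFAULT_PLACEMENT = ((1.0002, 3.4615, 5.5311), (0.3487, 0.5355, 0.3167))


@dataclass(frozen=True)
class SimulationSpec:
    cell: tuple = (15.35, 13.56, 16.50)
    spacegroup: str = "Pbca"
    d_min: float = 0.85
    d_max: float = 8.65
    completeness: float = 0.92
    mean_i_over_sigma: float = 8.4
    noise_g: float = 0.02          # sigma(F^2) = t * sqrt(F^2 + g (F^2)^2)
    noise_scale: float = 1.0       # multiplies the added noise, not sigma
    truth: str = "taam"            # "iam" | "taam"
    adp_anisotropy: float = 0.5
    perturb_xyz: float = 0.03      # A, start-model coordinate perturbation
    perturb_u: float = 0.005       # A^2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")
        if self.truth not in ("iam", "taam"):
            raise ValueError(f"unknown ground-truth model {self.truth!r}")


def _euler_zyz(a, b, c):
    def rz(t):
        return np.array([[math.cos(t), -math.sin(t), 0],
                         [math.sin(t), math.cos(t), 0], [0, 0, 1]])

    def ry(t):
        return np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0],
                         [-math.sin(t), 0, math.cos(t)]])

    return rz(a) @ ry(b) @ rz(c)


def _ligand_2d():
    """In-plane coordinates of one chelate ring; solved from bond constraints."""
    from scipy.optimize import fsolve

    p = FE_O / math.sqrt(2.0)
    o1 = np.array([p, p])

    def eqs(v):
        cx, cy, c3 = v
        c1 = np.array([cx, cy])
        e1 = np.linalg.norm(c1 - o1) - C_O
        e2 = np.linalg.norm(c1 - np.array([c3, 0.0])) - C_C_RING
        u1 = (o1 - c1) / np.linalg.norm(o1 - c1)
        u2 = (np.array([c3, 0.0]) - c1) / np.linalg.norm(
            np.array([c3, 0.0]) - c1)
        e3 = u1 @ u2 - math.cos(math.radians(O_C_C3_ANGLE))
        return [e1, e2, e3]

    cx, cy, c3 = fsolve(eqs, [2.6, 1.2, 3.3], full_output=False)
    return np.array([cx, cy]), float(c3)


def make_molecule():
    """(elements, cartesian positions, labels) of the idealized molecule, Fe at origin."""
    c1_2d, c3_2d = _ligand_2d()
    pairs = [(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
             (np.array([0, 0, 1.0]), np.array([-1.0, 0, 0])),
             (np.array([0, -1.0, 0]), np.array([0, 0, -1.0]))]
    els, pos = ["Fe"], [np.zeros(3)]
    for e1, e2 in pairs:
        u = (e1 + e2) / np.linalg.norm(e1 + e2)
        v = (e1 - e2) / np.linalg.norm(e1 - e2)
        put = lambda xy: xy[0] * u + xy[1] * v
        o1 = put((FE_O / math.sqrt(2), FE_O / math.sqrt(2)))
        o2 = put((FE_O / math.sqrt(2), -FE_O / math.sqrt(2)))
        c1 = put(c1_2d)
        c2 = put(c1_2d * np.array([1.0, -1.0]))
        c3 = put((c3_2d, 0.0))
        ring_h = c3 + C_H_RING * u
        mols = [("O", o1), ("O", o2), ("C", c1), ("C", c2), ("C", c3),
                ("H", ring_h)]
        w = np.cross(u, v)  # ligand plane normal
        for cc, oo in ((c1, o1), (c2, o2)):
            d1 = (oo - cc) / np.linalg.norm(oo - cc)
            d2 = (c3 - cc) / np.linalg.norm(c3 - cc)
            dm = -(d1 + d2)
            dm /= np.linalg.norm(dm)
            c4 = cc + C_C_METHYL * dm
            mols.append(("C", c4))
            t = (c4 - cc) / np.linalg.norm(c4 - cc)
            n1 = w.copy()
            n2 = np.cross(t, n1)
            ct, st = math.cos(math.radians(70.53)), math.sin(math.radians(70.53))
            for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3):
                hdir = t * ct + (n1 * math.cos(phi) + n2 * math.sin(phi)) * st
                mols.append(("H", c4 + C_H_METHYL * hdir))
        for el, xyz in mols:
            els.append(el)
            pos.append(xyz)
    pos = np.array(pos)
    counts = {}
    labels = []
    for el in els:
        counts[el] = counts.get(el, 0) + 1
        labels.append(f"{el}{counts[el]}")
    return els, pos, labels


def min_intermolecular_contact(structure: CrystalStructure) -> float:
    """Minimum distance between the asymmetric-unit molecule and any symmetry
    copy (minimum-image over lattice translations)."""
    frac = structure.expand_symmetry()  # (n_ops, n_sites, 3)
    ref = frac[0]
    A = structure.cell.orth_matrix
    best = np.inf
    n_ops = frac.shape[0]
    for o in range(n_ops):
        for shift in np.ndindex(3, 3, 3):
            tvec = np.array(shift) - 1
            if o == 0 and np.all(tvec == 0):
                continue
            d = ref[:, None, :] - (frac[o] + tvec)[None, :, :]
            cart = d @ A.T
            best = min(best, float(np.min(np.linalg.norm(cart, axis=-1))))
    return best


def optimize_placement(cell: UnitCell, sg: SpaceGroup, els, pos, labels,
                       seed: int = 0, n_coarse: int = 300):
    """Search rotation+translation maximizing the minimum intermolecular contact."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)

    def build(v):
        R = _euler_zyz(*v[:3])
        frac = (pos @ R.T) @ np.linalg.inv(cell.orth_matrix).T \
            + np.asarray(v[3:])[None, :]
        sites = [AtomSite(lab, el, f) for lab, el, f in zip(labels, els, frac)]
        return CrystalStructure(cell, sg, sites)

    def cost(v):
        return -min_intermolecular_contact(build(v))

    best_v, best_c = None, np.inf
    for _ in range(n_coarse):
        v = np.concatenate([rng.uniform(0, 2 * math.pi, 3),
                            rng.uniform(0, 0.5, 3)])
        c = cost(v)
        if c < best_c:
            best_v, best_c = v, c
    sol = minimize(cost, best_v, method="Nelder-Mead",
                   options=dict(maxiter=400, xatol=1e-3, fatol=1e-3))
    v = sol.x if sol.fun < best_c else best_v
    return tuple(v[:3]), tuple(v[3:]), -min(sol.fun, best_c)


def make_structure(spec: SimulationSpec | None = None) -> CrystalStructure:
    """Idealized FeAcAc-like crystal structure with anisotropic ADPs."""
    spec = spec or SimulationSpec()
    cell = UnitCell(*spec.cell)
    sg = SpaceGroup(spec.spacegroup)
    els, pos, labels = make_molecule()
    angles, shift = DEFAULT_PLACEMENT
    R = _euler_zyz(*angles)
    frac = (pos @ R.T) @ np.linalg.inv(cell.orth_matrix).T \
        + np.asarray(shift)[None, :]
    rng = np.random.default_rng(spec.seed + 7)
    base_ueq = {"Fe": 0.018, "O": 0.028, "C": 0.032, "H": 0.04}
    sites = []
    for lab, el, f in zip(labels, els, frac):
        if el == "H":
            sites.append(AtomSite(lab, el, f, u_iso=base_ueq["H"]))
            continue
        a = spec.adp_anisotropy
        u_eq = base_ueq[el]
        evals = u_eq * np.array([1.0 + a, 1.0, 1.0 - 0.6 * a])
        # deterministic random orientation per atom
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        U_cart = Q @ np.diag(evals) @ Q.T
        # CIF convention: U_cif = N^-1 A^-1 U_cart A^-T N^-1
        Ainv = np.linalg.inv(cell.orth_matrix)
        Ninv = np.diag(1.0 / cell.reciprocal_lengths)
        Ucif = Ninv @ Ainv @ U_cart @ Ainv.T @ Ninv
        u6 = np.array([Ucif[0, 0], Ucif[1, 1], Ucif[2, 2],
                       Ucif[0, 1], Ucif[0, 2], Ucif[1, 2]])
        sites.append(AtomSite(lab, el, f, u_aniso=u6))
    st = CrystalStructure(cell, sg, sites, name="FeAcAc_synthetic")
    # hybrid-model partition tags: metal part 1, organic ligand part 2
    for s in st.sites:
        s.part_id = 1 if s.element == "Fe" else 2
    # hydrogen U_iso follows the riding convention (1.2/1.5 x parent U_eq)
    from .refine import apply_riding, riding_map
    apply_riding(st, riding_map(st))
    return st


# ---------------------------------------------------------------------------
# Ground-truth scattering models

#: Hand-set aspherical ground truth ("taam"-like): valence populations give a
#: metal charge far below the formal +3 and strongly charged carbonyl
#: groups; deformation populations put lone-pair/bonding density on O and
#: the conjugated C.  Generator constants, chosen once.
TRUTH_PVAL = {"Fe": 5.6, "O": 6.30, "C_carbonyl": 3.72,
              "C_central": 4.05, "C_methyl": 4.0}
TRUTH_KAPPA = {"Fe": 1.0, "O": 0.97, "C_carbonyl": 1.01,
               "C_central": 1.0, "C_methyl": 1.0, "H": 1.15}
TRUTH_PLM = {
    "O": {(1, 0): 0.06, (2, 0): -0.10},
    "C_carbonyl": {(1, 0): 0.08, (3, 3): 0.25},
    "C_central": {(1, 0): 0.05, (3, 3): 0.20},
    "C_methyl": {(3, 3): 0.18},
    "H": {(1, 0): 0.12},
}


def _carbon_class(structure: CrystalStructure, label: str,
                  bonds: dict) -> str:
    nb_el = sorted(structure.site(l).element for l in bonds[label])
    if nb_el == ["C", "C", "O"]:
        return "C_carbonyl"
    if nb_el.count("H") >= 3:
        return "C_methyl"
    return "C_central"


def truth_multipole_models(structure: CrystalStructure):
    """(models, rotations) of the aspherical ground truth, charge-balanced."""
    from .geometry import bonded_neighbours

    bonds = bonded_neighbours(structure)
    models, rotations = {}, {}
    h_labels = []
    total = 0.0
    for site in structure.sites:
        el = site.element
        cls = el if el != "C" else _carbon_class(structure, site.label, bonds)
        model = neutral_multipole_atom(el)
        model.kappa = TRUTH_KAPPA.get(cls, TRUTH_KAPPA.get(el, 1.0))
        model.p_lm = dict(TRUTH_PLM.get(cls, TRUTH_PLM.get(el, {})))
        if el == "H":
            h_labels.append(site.label)
        else:
            model.p_val = TRUTH_PVAL[cls]
            total += model.z - model.p_core - model.p_val
        models[site.label] = model
        rotations[site.label] = local_axes_rotation(structure, site.label,
                                                    bonds)
    # neutral molecule: spread the balancing charge over the hydrogens
    h_pval = 1.0 + total / len(h_labels)
    for lab in h_labels:
        models[lab].p_val = h_pval
    return models, rotations


def electron_iam_curves(structure: CrystalStructure,
                        charged: dict | None = None):
    """Slater-family spherical electron curves per scatterer.

    ``charged`` maps element -> formal charge (e.g. {"Fe": 3, "O": -0.5});
    non-integer O charges are built as the linear combination of the neutral
    atom and the O- ion.
    """
    from .formfactor import combine_partial_charge, electron_slater

    charged = charged or {}
    curves = {}
    for el in {s.element for s in structure.sites}:
        q = charged.get(el, 0.0)
        if q == 0:
            curves[el] = electron_slater(el, 0.0)
        elif float(q).is_integer():
            curves[el] = electron_slater(el, float(q))
        else:
            frac = abs(q)
            ion = electron_slater(el, math.copysign(1.0, q))
            curves[el] = combine_partial_charge(electron_slater(el, 0.0),
                                                ion, frac)
    return curves


def truth_provider(structure: CrystalStructure, spec: SimulationSpec):
    if spec.truth == "iam":
        return SphericalProvider(electron_iam_curves(structure))
    models, rotations = truth_multipole_models(structure)
    return MultipoleProvider(models, rotations, radiation="electron")


def simulate_reflections(structure: CrystalStructure,
                         spec: SimulationSpec | None = None,
                         provider=None):
    """ReflectionSet plus a ground-truth record (noise-free F^2, scale t)."""
    spec = spec or SimulationSpec()
    if spec.d_min < 0.4:
        raise ValueError("d_min below the supported form-factor range")
    hkl = generate_hkl(structure.cell, structure.spacegroup,
                       spec.d_min, spec.d_max)
    if provider is None:
        provider = truth_provider(structure, spec)
    F = calc_structure_factors(structure, hkl, provider)
    f2 = np.abs(F) ** 2
    rng = np.random.default_rng(spec.seed)
    g = spec.noise_g
    shape = np.sqrt(np.maximum(f2, 1e-12) + g * f2**2)
    t = float(np.mean(f2 / shape)) / spec.mean_i_over_sigma
    if t <= 0:
        t = 1e-6
    sigma = t * shape
    f2_obs = f2 + rng.normal(size=len(f2)) * sigma * spec.noise_scale
    keep = np.ones(len(hkl), dtype=bool)
    n_drop = int(round((1.0 - spec.completeness) * len(hkl)))
    if n_drop > 0:
        drop = rng.choice(len(hkl), size=n_drop, replace=False)
        keep[drop] = False
    refl = ReflectionSet(hkl[keep], f2_obs[keep], sigma[keep],
                         structure.cell)
    truth = dict(hkl=hkl, f2_true=f2, sigma_scale=t, kept=keep,
                 provider=provider)
    return refl, truth


def make_benchmark_pair(spec: SimulationSpec | None = None):
    """(reflections, perturbed IAM start structure, ground-truth record).

    Data are simulated under the aspherical truth; the start model carries
    seeded coordinate and ADP perturbations so that refinement has work to
    do, mirroring the situation of refining an experimental dataset with
    different scattering-factor models.
    """
    spec = spec or SimulationSpec()
    if spec.truth != "taam":
        spec = replace(spec, truth="taam")
    truth_structure = make_structure(spec)
    refl, truth = simulate_reflections(truth_structure, spec)
    start = truth_structure.copy()
    rng = np.random.default_rng(spec.seed + 1)
    Ainv = np.linalg.inv(truth_structure.cell.orth_matrix)
    for site in start.sites:
        if site.element == "H":
            continue
        shift_cart = rng.normal(scale=spec.perturb_xyz / math.sqrt(3),
                                size=3)
        site.frac = site.frac + Ainv @ shift_cart
        if site.u_aniso is not None:
            site.u_aniso = site.u_aniso + np.concatenate([
                rng.normal(scale=spec.perturb_u, size=3),
                rng.normal(scale=spec.perturb_u / 2, size=3)])
    # keep riding geometry consistent with perturbed parents
    from .refine import riding_map, apply_riding
    apply_riding(start, riding_map(truth_structure))
    truth["structure"] = truth_structure
    return refl, start, truth
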