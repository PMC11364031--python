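"""Multipole-parameter refinement against theoretical structure factors and
atom-type databanks.

A molecule is placed static (zero ADPs) in an artificial box; target
structure factors — from an external quantum-chemistry calculation read
through a file adapter, or from a declared ground-truth multipole model —
are fitted by adjusting selected Hansen-Coppens parameters per pseudoatom.
Refined parameters can be averaged over chemically equivalent atom types
into a JSON databank that is re-applied to (other) structures, with a
spherical-neutral fallback for atom types without an entry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalStructure, UnitCell
from .multipole import MultipoleAtomModel, hc_form_factor, neutral_multipole_atom

__all__ = ["TheoreticalSFSet", "static_structure_factors",
           "refine_multipoles", "assign_atom_types",
           "build_databank", "apply_databank",
           "save_databank", "load_databank"]


@dataclass
class TheoreticalSFSet:
    hkl: np.ndarray
    f: np.ndarray                # complex X-ray structure factors
    cell: UnitCell               # the artificial box
    valence_only: bool = False

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, int))
        self.f = np.asarray(self.f, complex)
        if len(self.hkl) == 0:
            raise ValueError("empty structure-factor set")
        if len(self.hkl) != len(self.f):
            raise ValueError("hkl and f length mismatch")


def _atom_ff(model: MultipoleAtomModel, hvec, rotation,
             valence_only: bool) -> np.ndarray:
    f = hc_form_factor(model, hvec, "xray", rotation)
    if valence_only:
        s = 0.5 * np.linalg.norm(np.atleast_2d(hvec), axis=-1)
        f = f - model.f_core(s)
    return f


def static_structure_factors(models, frac_positions, cell: UnitCell, hkl,
                             rotations=None, valence_only: bool = False
                             ) -> np.ndarray:
    """X-ray structure factors of a static (ADP-free) molecule in a P1 box."""
    hkl = np.atleast_2d(np.asarray(hkl, float))
    x = np.atleast_2d(np.asarray(frac_positions, float))
    hvec = cell.dstar_vectors(hkl)
    F = np.zeros(len(hkl), dtype=complex)
    phase = np.exp(2j * math.pi * (hkl @ x.T))
    for j, model in enumerate(models):
        rot = rotations[j] if rotations is not None else None
        F += _atom_ff(model, hvec, rot, valence_only) * phase[:, j]
    return F


# ---------------------------------------------------------------------------
# Parameter refinement


def _collect_params(models: dict, flags: dict):
    """(labels, getters, setters) for the free parameters."""
    entries = []
    for label, flag in flags.items():
        model = models[label]
        if flag.get("p_val"):
            entries.append((label, "p_val", None))
        if flag.get("kappa"):
            entries.append((label, "kappa", None))
        if flag.get("kappa_prime"):
            entries.append((label, "kappa_prime", None))
        for lm in flag.get("p_lm", []):
            entries.append((label, "p_lm", tuple(lm)))
    return entries


def refine_multipoles(start_models: dict, frac_positions: dict,
                      sf: TheoreticalSFSet, refine_flags: dict,
                      rotations: dict | None = None,
                      max_nfev: int = 2000):
    """Least-squares fit of model structure factors to a target set.

    ``start_models`` maps atom label -> MultipoleAtomModel (copied, not
    mutated), ``frac_positions`` label -> fractional position in the box,
    ``refine_flags`` label -> {"p_val": bool, "kappa": bool,
    "kappa_prime": bool, "p_lm": [(l, m), ...]}.  Returns
    (refined_models, R, report).  R = sum ||F_t|-|F_m|| / sum |F_t|.
    """
    from scipy.optimize import least_squares

    labels = list(start_models)
    models = {lab: start_models[lab].copy() for lab in labels}
    entries = _collect_params(models, refine_flags)
    if not entries:
        raise ValueError("no free parameters selected")
    x = np.array([frac_positions[lab] for lab in labels])
    rots = ([rotations.get(lab) for lab in labels]
            if rotations is not None else None)

    def get_vec():
        out = []
        for lab, name, lm in entries:
            m = models[lab]
            out.append(m.p_lm.get(lm, 0.0) if name == "p_lm"
                       else getattr(m, name))
        return np.array(out)

    def set_vec(p):
        for val, (lab, name, lm) in zip(p, entries):
            m = models[lab]
            if name == "p_lm":
                m.p_lm[lm] = float(val)
            else:
                setattr(m, name, float(val))

    target = np.concatenate([sf.f.real, sf.f.imag])

    def resid(p):
        set_vec(p)
        F = static_structure_factors([models[lab] for lab in labels], x,
                                     sf.cell, sf.hkl, rots, sf.valence_only)
        return np.concatenate([F.real, F.imag]) - target

    p0 = get_vec()
    jac_cols = len(p0)
    if jac_cols >= 2 * len(sf.hkl):
        raise ValueError("more free parameters than observations")
    sol = least_squares(resid, p0, method="lm", max_nfev=max_nfev)
    # symmetry-equivalent parameters make the normal matrix rank deficient;
    # detect it at the solution and name the correlated set
    _, R_qr = np.linalg.qr(sol.jac)
    diag = np.abs(np.diag(R_qr))
    bad = diag < 1e-10 * max(diag.max(), 1e-300)
    if np.any(bad):
        names = [f"{lab}.{name}" + (f"{lm}" if lm else "")
                 for flag, (lab, name, lm) in zip(bad, entries) if flag]
        raise ValueError(
            f"rank-deficient refinement; correlated/undetermined "
            f"parameters: {names}")
    set_vec(sol.x)
    F = static_structure_factors([models[lab] for lab in labels], x,
                                 sf.cell, sf.hkl, rots, sf.valence_only)
    R = float(np.sum(np.abs(np.abs(sf.f) - np.abs(F)))
              / np.sum(np.abs(sf.f)))
    report = dict(converged=bool(sol.success), nfev=int(sol.nfev),
                  cost=float(sol.cost),
                  shifts={f"{lab}.{name}" + (f"{lm}" if lm else ""):
                          float(b - a)
                          for (lab, name, lm), a, b
                          in zip(entries, p0, sol.x)})
    return models, R, report


def assign_atom_types(structure: CrystalStructure) -> dict[str, str]:
    """Chemical-environment key per atom label (see geometry.atom_type_keys)."""
    from .geometry import atom_type_keys
    return atom_type_keys(structure)


# ---------------------------------------------------------------------------
# Databank


def build_databank(models: dict, type_keys: dict) -> dict:
    """Average multipolar parameters over atom types.

    P_val, kappa, kappa' and frame-aligned P_lm are averaged arithmetically
    per key (local frames are assumed equivalently defined across exemplars
    by the deterministic local-axes rule).
    """
    groups: dict[str, list] = {}
    for label, model in models.items():
        groups.setdefault(type_keys[label], []).append(model)
    bank = {}
    for key, group in groups.items():
        ref = group[0]
        lm_keys = sorted({lm for m in group for lm in m.p_lm})
        bank[key] = dict(
            element=ref.element,
            p_val=float(np.mean([m.p_val for m in group])),
            kappa=float(np.mean([m.kappa for m in group])),
            kappa_prime=float(np.mean([m.kappa_prime for m in group])),
            p_lm={f"{l},{m}": float(np.mean([g.p_lm.get((l, m), 0.0)
                                             for g in group]))
                  for (l, m) in lm_keys},
            n_exemplars=len(group),
        )
    return bank


def apply_databank(bank: dict, structure: CrystalStructure,
                   fallback_spherical: bool = True) -> dict:
    """Per-atom multipole models for a structure from a databank.

    Atoms with no matching type key fall back to the spherical neutral
    pseudoatom when ``fallback_spherical`` is set, else raise KeyError.
    """
    keys = assign_atom_types(structure)
    out = {}
    for site in structure.sites:
        key = keys[site.label]
        if key in bank:
            entry = bank[key]
            model = neutral_multipole_atom(entry["element"])
            model.p_val = entry["p_val"]
            model.kappa = entry["kappa"]
            model.kappa_prime = entry["kappa_prime"]
            model.p_lm = {tuple(int(v) for v in k.split(",")): p
                          for k, p in entry["p_lm"].items()}
        elif fallback_spherical:
            model = neutral_multipole_atom(site.element)
        else:
            raise KeyError(f"no databank entry for atom type {key!r} "
                           f"({site.label})")
        out[site.label] = model
    return out


def save_databank(bank: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(format="edtaam-databank-1", entries=bank), fh,
                  indent=1)


def load_databank(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "edtaam-databank-1":
        raise ValueError("not an edtaam databank file")
    return doc["entries"]
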