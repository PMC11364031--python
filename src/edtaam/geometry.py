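"""Molecular geometry helpers: bonds, atom-type keys, RMSD support."""

from __future__ import annotations

import numpy as np
import gemmi

from .crystal import CrystalStructure

__all__ = ["bonded_neighbours", "bond_list", "atom_type_keys"]

#: Bonds are declared when the interatomic distance is below the sum of
#: covalent radii times this tolerance factor.
BOND_TOLERANCE = 1.15


def _radii(structure: CrystalStructure) -> np.ndarray:
    return np.array([gemmi.Element(s.element).covalent_r
                     for s in structure.sites])


def bond_list(structure: CrystalStructure) -> list[tuple[str, str, float]]:
    """Intramolecular bonds (label_a, label_b, distance) within the asymmetric unit."""
    cart = structure.cart_coords()
    r = _radii(structure)
    diff = cart[:, None, :] - cart[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cut = (r[:, None] + r[None, :]) * BOND_TOLERANCE
    out = []
    n = len(structure.sites)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < cut[i, j]:
                out.append((structure.sites[i].label,
                            structure.sites[j].label, float(dist[i, j])))
    return out


def bonded_neighbours(structure: CrystalStructure) -> dict[str, list[str]]:
    nb: dict[str, list[str]] = {s.label: [] for s in structure.sites}
    for a, b, _ in bond_list(structure):
        nb[a].append(b)
        nb[b].append(a)
    return nb


def atom_type_keys(structure: CrystalStructure) -> dict[str, str]:
    """Chemical-environment key per atom: element, sorted first-shell
    elements and sorted second-shell signatures.

    Chemically equivalent atoms of a molecular graph (e.g. all carbonyl O of
    a tris-chelate) share a key; disconnected atoms get singleton keys with a
    warning.
    """
    import warnings

    nb = bonded_neighbours(structure)
    el = {s.label: s.element for s in structure.sites}
    first = {lab: ",".join(sorted(el[x] for x in nbs))
             for lab, nbs in nb.items()}
    keys = {}
    for s in structure.sites:
        nbs = nb[s.label]
        if not nbs:
            warnings.warn(f"atom {s.label} has no bonds; singleton atom type")
            keys[s.label] = f"{s.element}|isolated:{s.label}"
            continue
        second = sorted(f"{el[x]}({first[x]})" for x in nbs)
        keys[s.label] = f"{s.element}|{'|'.join(second)}"
    return keys
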