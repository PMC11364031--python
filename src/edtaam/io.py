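"""File I/O: small-molecule CIF, SHELX HKLF4, Gaussian cube and XYZ."""

from __future__ import annotations

import numpy as np
import gemmi

from .crystal import (AtomSite, CrystalStructure, ReflectionSet, SpaceGroup,
                      UnitCell)

__all__ = ["write_cif", "read_cif", "write_hklf4", "read_hklf4",
           "write_cube", "read_cube", "read_xyz", "write_xyz"]


# ---------------------------------------------------------------------------
# CIF

_MANDATORY = ["_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_atom_site_label", "_atom_site_fract_x"]


def write_cif(structure: CrystalStructure, path,
              reflections: ReflectionSet | None = None,
              block_name: str | None = None) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name or structure.name)
    cell = structure.cell
    for tag, val in [("a", cell.a), ("b", cell.b), ("c", cell.c)]:
        block.set_pair(f"_cell_length_{tag}", f"{val:.4f}")
    for tag, val in [("alpha", cell.alpha), ("beta", cell.beta),
                     ("gamma", cell.gamma)]:
        block.set_pair(f"_cell_angle_{tag}", f"{val:.4f}")
    block.set_pair("_space_group_name_H-M_alt",
                   gemmi.cif.quote(structure.spacegroup.symbol))
    loop = block.init_loop("_space_group_symop_", ["operation_xyz"])
    for trip in structure.spacegroup.triplets:
        loop.add_row([gemmi.cif.quote(trip)])
    loop = block.init_loop("_atom_site_", [
        "label", "type_symbol", "fract_x", "fract_y", "fract_z",
        "occupancy", "U_iso_or_equiv", "adp_type", "disorder_group"])
    for s in structure.sites:
        if s.is_aniso:
            ueq = float(np.trace(s.u_matrix()) / 3.0)
            adp = "Uani"
        else:
            ueq = s.u_iso or 0.0
            adp = "Uiso"
        loop.add_row([s.label, s.element,
                      f"{s.frac[0]:.6f}", f"{s.frac[1]:.6f}",
                      f"{s.frac[2]:.6f}", f"{s.occupancy:.4f}",
                      f"{ueq:.6f}", adp, str(s.part_id)])
    aniso = [s for s in structure.sites if s.is_aniso]
    if aniso:
        loop = block.init_loop("_atom_site_aniso_", [
            "label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"])
        for s in aniso:
            u = s.u_aniso
            loop.add_row([s.label] + [f"{v:.6f}" for v in
                                      (u[0], u[1], u[2], u[3], u[4], u[5])])
    if reflections is not None:
        loop = block.init_loop("_refln_", [
            "index_h", "index_k", "index_l",
            "F_squared_meas", "F_squared_sigma"])
        for h, f2, sg in zip(reflections.hkl, reflections.f2,
                             reflections.sigma):
            loop.add_row([str(h[0]), str(h[1]), str(h[2]),
                          f"{f2:.4f}", f"{sg:.4f}"])
    doc.write_file(str(path))


class CifParseError(ValueError):
    pass


def read_cif(path, block_name: str | None = None
             ) -> tuple[CrystalStructure, ReflectionSet | None]:
    doc = gemmi.cif.read(str(path))
    if block_name is None:
        block = doc[0]
    else:
        block = doc.find_block(block_name)
        if block is None:
            raise CifParseError(
                f"datablock {block_name!r} not found; available: "
                f"{[b.name for b in doc]}")
    missing = [t for t in _MANDATORY if not block.find_values(t)]
    if missing:
        raise CifParseError(f"missing mandatory CIF items: {missing}")
    small = gemmi.make_small_structure_from_block(block)
    g = small.cell
    cell = UnitCell(g.a, g.b, g.c, g.alpha, g.beta, g.gamma)
    triplets = [v.strip("'\" ") for v in
                (block.find_values("_space_group_symop_operation_xyz")
                 or block.find_values("_symmetry_equiv_pos_as_xyz"))]
    symbol = small.spacegroup_hm or None
    if triplets:
        sg = SpaceGroup(symbol=symbol, triplets=triplets)
    elif symbol:
        sg = SpaceGroup(symbol)
    else:
        raise CifParseError("no symmetry operations or space-group symbol")
    parts = {}
    pl = block.find_loop("_atom_site_label")
    if pl:
        labels = list(block.find_values("_atom_site_label"))
        groups = list(block.find_values("_atom_site_disorder_group") or [])
        for i, lab in enumerate(labels):
            if i < len(groups) and groups[i] not in (".", "?", ""):
                parts[lab] = int(groups[i])
    sites = []
    for gs in small.sites:
        aniso = None
        u = gs.aniso
        if u.nonzero():
            aniso = np.array([u.u11, u.u22, u.u33, u.u12, u.u13, u.u23])
        sites.append(AtomSite(
            label=gs.label, element=gs.element.name,
            frac=np.array([gs.fract.x, gs.fract.y, gs.fract.z]),
            occupancy=gs.occ if gs.occ > 0 else 1.0,
            u_iso=None if aniso is not None else gs.u_iso,
            u_aniso=aniso, part_id=parts.get(gs.label, 0)))
    structure = CrystalStructure(cell, sg, sites, name=block.name)
    refl = None
    hcol = block.find_values("_refln_index_h")
    if hcol:
        h = np.array([int(v) for v in block.find_values("_refln_index_h")])
        k = np.array([int(v) for v in block.find_values("_refln_index_k")])
        l = np.array([int(v) for v in block.find_values("_refln_index_l")])
        f2 = np.array([float(v) for v in
                       block.find_values("_refln_F_squared_meas")])
        sig = np.array([float(v) for v in
                        block.find_values("_refln_F_squared_sigma")])
        refl = ReflectionSet(np.stack([h, k, l], axis=1), f2, sig, cell)
    return structure, refl


# ---------------------------------------------------------------------------
# SHELX HKLF4

class HklParseError(ValueError):
    pass


def write_hklf4(reflections: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        for h, f2, sg in zip(reflections.hkl, reflections.f2,
                             reflections.sigma):
            fh.write(f"{h[0]:4d}{h[1]:4d}{h[2]:4d}{f2:8.2f}{sg:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hklf4(path, cell: UnitCell) -> ReflectionSet:
    hkl, f2, sigma = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                h = int(raw[0:4]); k = int(raw[4:8]); l = int(raw[8:12])
                fo2 = float(raw[12:20]); sg = float(raw[20:28])
            except ValueError as exc:
                raise HklParseError(f"line {lineno}: {exc}") from None
            if h == 0 and k == 0 and l == 0:
                break
            if sg <= 0:
                raise HklParseError(
                    f"line {lineno}: sigma(F^2) must be positive, got {sg}")
            hkl.append([h, k, l]); f2.append(fo2); sigma.append(sg)
    if not hkl:
        raise HklParseError("no reflection records")
    return ReflectionSet(np.array(hkl), np.array(f2), np.array(sigma), cell)


# ---------------------------------------------------------------------------
# Gaussian cube (molecular, non-periodic, orthogonal voxels)

_BOHR = 0.529177210544


def write_cube(path, values: np.ndarray, origin, spacing,
               atom_numbers=None, atom_positions=None,
               comment: str = "edtaam density grid") -> None:
    """Write a scalar field to Gaussian-cube format (lengths in Angstrom)."""
    values = np.asarray(values)
    origin = np.asarray(origin, float) / _BOHR
    spacing = np.asarray(spacing, float) / _BOHR
    numbers = list(atom_numbers or [])
    pos = np.asarray(atom_positions, float) / _BOHR if atom_positions is not None \
        else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write(comment + "\n")
        fh.write("scalar field written by edtaam\n")
        fh.write(f"{len(numbers):5d}{origin[0]:12.6f}{origin[1]:12.6f}"
                 f"{origin[2]:12.6f}\n")
        for ax in range(3):
            v = [0.0, 0.0, 0.0]
            v[ax] = spacing[ax]
            fh.write(f"{values.shape[ax]:5d}{v[0]:12.6f}{v[1]:12.6f}"
                     f"{v[2]:12.6f}\n")
        for z, p in zip(numbers, pos):
            fh.write(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}"
                     f"{p[2]:12.6f}\n")
        flat = values.reshape(values.shape[0] * values.shape[1],
                              values.shape[2])
        for row in flat:
            for i in range(0, len(row), 6):
                fh.write("".join(f"{v:13.5e}" for v in row[i:i + 6]) + "\n")


def read_cube(path):
    """Read a Gaussian cube; returns (values, origin_A, spacing_A, numbers, pos_A)."""
    with open(path) as fh:
        fh.readline(); fh.readline()
        parts = fh.readline().split()
        natom = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) * _BOHR
        shape, spacing = [], []
        for _ in range(3):
            parts = fh.readline().split()
            shape.append(int(parts[0]))
            vec = np.array([float(x) for x in parts[1:4]])
            spacing.append(np.linalg.norm(vec) * _BOHR)
        numbers, pos = [], []
        for _ in range(abs(natom)):
            parts = fh.readline().split()
            numbers.append(int(parts[0]))
            pos.append([float(x) for x in parts[2:5]])
        data = np.array(fh.read().split(), dtype=float)
    values = data.reshape(shape)
    return values, origin, np.array(spacing), numbers, np.array(pos) * _BOHR


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path):
    """Returns (elements, positions_A)."""
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        fh.readline()
        els, pos = [], []
        for _ in range(n):
            parts = fh.readline().split()
            els.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
    return els, np.array(pos)


def write_xyz(path, elements, positions, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, p in zip(elements, np.asarray(positions, float)):
            fh.write(f"{el} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
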