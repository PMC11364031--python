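"""Plain-text .tsc tables of per-reflection, per-atom complex form factors.

Dialect: a header with ``TITLE``, optional ``SYMM``, and ``SCATTERERS:``
(whitespace-separated atom labels), closed by ``DATA:``; then one line per
reflection: ``h k l`` followed by one ``re,im`` pair per scatterer.
Comment lines starting with ``#`` or ``!`` are tolerated anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FormFactorTable", "write_tsc", "read_tsc"]


@dataclass
class FormFactorTable:
    hkl: np.ndarray                 # (M, 3) int
    atoms: list[str]                # ordered scatterer labels
    values: np.ndarray              # (M, n_atoms) complex
    radiation: str = "electron"
    title: str = "edtaam"
    symm: str = "expanded"

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=complex))
        if self.values.shape != (len(self.hkl), len(self.atoms)):
            raise ValueError("values must have shape (n_refl, n_atoms)")


def write_tsc(table: FormFactorTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"TITLE: {table.title}\n")
        fh.write(f"SYMM: {table.symm}\n")
        fh.write(f"AD: {table.radiation}\n")
        fh.write("SCATTERERS: " + " ".join(table.atoms) + "\n")
        fh.write("DATA:\n")
        for h, row in zip(table.hkl, table.values):
            cells = " ".join(f"{v.real:.8e},{v.imag:.8e}" for v in row)
            fh.write(f"{h[0]} {h[1]} {h[2]} {cells}\n")


class TscParseError(ValueError):
    pass


def read_tsc(path) -> FormFactorTable:
    title, symm, radiation = "", "", "electron"
    atoms: list[str] = []
    hkl, rows = [], []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "!")):
                continue
            if not in_data:
                upper = line.upper()
                if upper.startswith("TITLE:"):
                    title = line.split(":", 1)[1].strip()
                elif upper.startswith("SYMM:"):
                    symm = line.split(":", 1)[1].strip()
                elif upper.startswith("AD:"):
                    radiation = line.split(":", 1)[1].strip()
                elif upper.startswith("SCATTERERS:"):
                    atoms = line.split(":", 1)[1].split()
                elif upper.startswith("DATA"):
                    if not atoms:
                        raise TscParseError(
                            f"line {lineno}: DATA before SCATTERERS header")
                    in_data = True
                continue
            parts = line.split()
            if len(parts) != 3 + len(atoms):
                raise TscParseError(
                    f"line {lineno}: expected 3 indices + {len(atoms)} "
                    f"factors, got {len(parts)} fields")
            try:
                h = [int(p) for p in parts[:3]]
                vals = []
                for p in parts[3:]:
                    re, _, im = p.partition(",")
                    vals.append(complex(float(re), float(im) if im else 0.0))
            except ValueError as exc:
                raise TscParseError(f"line {lineno}: {exc}") from None
            hkl.append(h)
            rows.append(vals)
    if not atoms:
        raise TscParseError("missing SCATTERERS header")
    if not hkl:
        raise TscParseError("no reflection records found")
    return FormFactorTable(np.array(hkl), atoms, np.array(rows),
                           radiation=radiation, title=title, symm=symm)
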