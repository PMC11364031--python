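import numpy as np
import pytest

from edtaam.crystal import (AtomSite, CrystalStructure, SpaceGroup, UnitCell,
                            d_spacing)


def naive_structure_factors(structure, hkl, curves):
    """Brute-force double loop over symmetry-expanded atoms; the independent
    oracle for the vectorized structure-factor engine."""
    out = []
    sg = structure.spacegroup
    astar = structure.cell.reciprocal_lengths
    for h in np.asarray(hkl, float):
        total = 0.0 + 0.0j
        for site in structure.sites:
            for R, t in zip(sg.rotations, sg.translations):
                x = R @ site.frac + t
                h_rot = h @ R
                d = d_spacing(structure.cell, [h])[0]
                s = 1.0 / (2.0 * d)
                f = curves[site.element](np.array([s]))[0]
                if site.is_aniso:
                    q = h_rot * astar
                    U = site.u_matrix()
                    T = np.exp(-2 * np.pi**2 * q @ U @ q)
                else:
                    T = np.exp(-8 * np.pi**2 * site.u_iso * s**2)
                total += site.occupancy * f * T * np.exp(
                    2j * np.pi * np.dot(h, x))
        out.append(total)
    return np.array(out)


@pytest.fixture(scope="session")
def p1_cell():
    return UnitCell(10.0, 10.0, 10.0)


@pytest.fixture(scope="session")
def random_p1_structure():
    """Five-atom triclinic-free P1 structure with mixed ADPs."""
    rng = np.random.default_rng(42)
    cell = UnitCell(9.0, 11.0, 8.0)
    sg = SpaceGroup("P1")
    sites = []
    for i, el in enumerate(["C", "O", "Fe", "C", "H"]):
        u_aniso = None
        u_iso = None
        if el != "H":
            d = rng.uniform(0.01, 0.03, 3)
            off = rng.uniform(-0.002, 0.002, 3)
            u_aniso = np.array([d[0], d[1], d[2], off[0], off[1], off[2]])
        else:
            u_iso = 0.03
        sites.append(AtomSite(f"{el}{i}", el, rng.uniform(0, 1, 3),
                              u_iso=u_iso, u_aniso=u_aniso))
    return CrystalStructure(cell, sg, sites)


@pytest.fixture(scope="session")
def synthetic_structure():
    from edtaam.synthetic import SimulationSpec, make_structure
    return make_structure(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def small_molecule_box():
    """The idealized molecule placed static in a 30 A cubic P1 box."""
    from edtaam.synthetic import make_molecule

    els, pos, labels = make_molecule()
    cell = UnitCell(30.0, 30.0, 30.0)
    frac = pos @ np.linalg.inv(cell.orth_matrix).T + 0.5
    sites = [AtomSite(l, e, f) for l, e, f in zip(labels, els, frac)]
    return CrystalStructure(cell, SpaceGroup("P1"), sites)
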