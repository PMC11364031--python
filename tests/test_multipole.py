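"""Hansen-Coppens pseudoatom model: limits, linearity, transforms."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
import scipy.special as sp

from edtaam.multipole import (MultipoleAtomModel, hc_form_factor,
                              neutral_multipole_atom,
                              spherical_component_curve)
from edtaam.slater import (real_sph_harm, slater_fourier_bessel,
                           slater_radial, spherical_atom_shells, shells_ff)
from edtaam.formfactor import xray_slater, electron_slater


def _hvec(s):
    h = np.zeros((len(s), 3))
    h[:, 0] = 2.0 * np.asarray(s)
    return h


def test_spherical_limit_equals_neutral_slater_atom():
    s = np.linspace(0.0, 1.5, 40)
    for el in ["H", "C", "O", "Fe"]:
        model = neutral_multipole_atom(el)
        f = hc_form_factor(model, _hvec(s), "xray")
        np.testing.assert_allclose(f.real, xray_slater(el)(s), atol=1e-12)
        np.testing.assert_allclose(f.imag, 0.0, atol=1e-12)


def test_monopole_normalization_at_zero():
    model = neutral_multipole_atom("O")
    f0 = hc_form_factor(model, np.zeros((1, 3)), "xray")[0]
    assert f0.real == pytest.approx(model.p_core + model.p_val, abs=1e-10)


def test_fe_frozen_core_partition():
    fe = neutral_multipole_atom("Fe")
    assert fe.p_core == pytest.approx(20)   # Ar core + frozen 4s^2
    assert fe.p_val == pytest.approx(6)     # 3d electrons
    assert fe.charge == pytest.approx(0)


def test_form_factor_linear_in_populations():
    rng = np.random.default_rng(1)
    h = rng.normal(size=(12, 3))
    base = neutral_multipole_atom("O")
    m1 = base.copy(); m1.p_lm = {(1, 0): 0.3}
    m2 = base.copy(); m2.p_lm = {(1, 0): 0.6}
    f0 = hc_form_factor(base, h, "xray")
    f1 = hc_form_factor(m1, h, "xray")
    f2 = hc_form_factor(m2, h, "xray")
    np.testing.assert_allclose(f2 - f0, 2.0 * (f1 - f0), rtol=1e-10)
    # linear in p_val as well
    m3 = base.copy(); m3.p_val = base.p_val + 1.0
    f3 = hc_form_factor(m3, h, "xray")
    s = 0.5 * np.linalg.norm(h, axis=1)
    np.testing.assert_allclose(f3 - f0, base.f_val(s), rtol=1e-10)


@pytest.mark.parametrize("l,n", [(1, 2), (2, 2), (3, 3), (4, 4)])
def test_fourier_bessel_transform_matches_quadrature(l, n):
    alpha = 5.1
    for s in [0.004, 0.02, 0.09, 0.35, 1.1]:
        q = 4 * math.pi * s
        oracle, _ = quad(lambda r: slater_radial(n, alpha, r)
                         * sp.spherical_jn(l, q * r) * r**2, 0, 60,
                         limit=200)
        val = slater_fourier_bessel(l, n, alpha, np.array([s]))[0]
        assert val == pytest.approx(oracle, abs=1e-10)


def test_dipole_form_factor_against_brute_force_quadrature():
    """A single l=1 deformation term must match direct evaluation of the
    defining radial-transform integral times the angular factor."""
    model = neutral_multipole_atom("O")
    model.p_lm = {(1, 0): 0.4}
    zeta = model.radial_zeta[1]
    nrad = model.radial_n[1]
    s_grid = [0.05, 0.2, 0.6, 1.0]
    direction = np.array([0.3, -0.4, 0.866])
    direction /= np.linalg.norm(direction)
    for s in s_grid:
        h = (direction * 2 * s)[None, :]
        full = hc_form_factor(model, h, "xray")[0]
        sph = hc_form_factor(neutral_multipole_atom("O"), h, "xray")[0]
        jl, _ = quad(lambda r: slater_radial(nrad, zeta, r)
                     * sp.spherical_jn(1, 4 * math.pi * s * r) * r**2,
                     0, 50, limit=200)
        expect = (4 * math.pi * 1j * jl
                  * 0.4 * real_sph_harm(1, 0, direction[None, :])[0])
        assert full - sph == pytest.approx(expect, abs=1e-6)


def test_kappa_scaling_contracts_valence_factor():
    m = neutral_multipole_atom("O")
    m_contracted = m.copy(); m_contracted.kappa = 1.2
    s = np.array([0.4])
    # contracted density (kappa>1) falls off slower in reciprocal space
    assert hc_form_factor(m_contracted, _hvec(s), "xray")[0].real > \
        hc_form_factor(m, _hvec(s), "xray")[0].real


def test_spherical_component_matches_full_factor_without_deformation():
    m = neutral_multipole_atom("C")
    m.kappa = 1.05
    m.p_val = 3.7
    s = np.linspace(0.0, 1.2, 25)
    np.testing.assert_allclose(
        spherical_component_curve(m, s, "xray"),
        hc_form_factor(m, _hvec(s), "xray").real, atol=1e-12)


def test_partially_charged_fe_curve_lies_below_iam_fe3_at_low_s():
    """A metal pseudoatom with a partial (sub-formal) positive charge
    scatters electrons less strongly than the formally charged IAM ion
    through the low-resolution range."""
    fe = neutral_multipole_atom("Fe")
    fe.p_val = 5.6   # effective charge +0.4, well below the formal +3
    s = np.linspace(0.02, 0.15, 30)
    taam_curve = spherical_component_curve(fe, s, "electron")
    iam_fe3 = electron_slater("Fe", 3.0)(s)
    assert np.all(taam_curve < iam_fe3)
    # the overestimation grows without bound toward low resolution and the
    # two curves converge toward the high-s end of the data range
    gap = iam_fe3 - taam_curve
    assert gap[0] > 10 * gap[-1]
    s_hi = np.array([0.5, 0.6])
    gap_hi = electron_slater("Fe", 3.0)(s_hi) - \
        spherical_component_curve(fe, s_hi, "electron")
    assert np.all(np.abs(gap_hi) < 0.05)


def test_model_density_integrates_to_electron_count():
    m = neutral_multipole_atom("C")
    r = np.linspace(1e-4, 12, 4000)
    rho = m.density(np.column_stack([r, np.zeros_like(r), np.zeros_like(r)]))
    total = np.trapezoid(4 * np.pi * r**2 * rho, r)
    assert total == pytest.approx(m.n_electrons, abs=1e-3)


def test_deformation_density_carries_zero_net_charge():
    m = neutral_multipole_atom("O")
    m.p_lm = {(1, 0): 0.5}
    rng = np.random.default_rng(0)
    # random spherical average: integrate density over a few shells
    r = np.linspace(1e-3, 10, 800)
    base = neutral_multipole_atom("O")
    # angular integral of y_1m over the sphere is zero; check numerically
    th = np.arccos(rng.uniform(-1, 1, 2000))
    ph = rng.uniform(0, 2 * np.pi, 2000)
    dirs = np.column_stack([np.sin(th) * np.cos(ph),
                            np.sin(th) * np.sin(ph), np.cos(th)])
    pts = dirs * 1.0
    diff = m.density(pts) - base.density(pts)
    assert abs(np.mean(diff)) < 5e-3 * np.max(np.abs(diff))


def test_invalid_multipole_index_rejected():
    with pytest.raises(ValueError):
        MultipoleAtomModel("O", spherical_atom_shells("O")[:2],
                           spherical_atom_shells("O")[2:], 6.0,
                           p_lm={(5, 0): 0.1})
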