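"""Spherical form factors: Gaussian curves, Mott-Bethe, partial charges, fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edtaam.constants import MOTT_BETHE_C
from edtaam.formfactor import (GaussianFormFactor, Radiation,
                               combine_partial_charge, electron_iam,
                               electron_slater, evaluate_gaussian_ff,
                               fit_gaussians, mott_bethe, xray_iam,
                               xray_slater)
from edtaam.slater import ATOMIC_NUMBER


def test_gaussian_ff_at_zero_is_sum_of_amplitudes():
    ff = GaussianFormFactor("X", Radiation.XRAY, (1.0, 2.0, 0.5), (1, 5, 20),
                            c=0.25)
    assert evaluate_gaussian_ff(ff, 0.0) == pytest.approx(3.75)


def test_neutral_carbon_xray_factor_equals_z_at_zero():
    assert xray_iam("C")(0.0) == pytest.approx(6.0, abs=0.02)


def test_negative_s_rejected():
    with pytest.raises(ValueError):
        evaluate_gaussian_ff(xray_iam("C"), np.array([-0.1]))


def test_mott_bethe_matches_independent_closed_form_for_hydrogen():
    # analytic ground-state H: f_x(s) = 16 / (4 + (4 pi a0 s)^2 / ... )^2
    a0 = 0.529177210544

    def fx_h_clean(s):
        q = np.asarray(s) * 4.0 * np.pi
        return 1.0 / (1.0 + (q * a0 / 2.0) ** 2) ** 2

    s = np.linspace(0.05, 1.0, 50)
    fe = mott_bethe(fx_h_clean, 1, s)
    independent = MOTT_BETHE_C * (1.0 - fx_h_clean(s)) / s**2
    np.testing.assert_allclose(fe, independent, rtol=1e-10)


def test_mott_bethe_neutral_small_s_limit_is_finite_and_continuous():
    fx = xray_iam("C")
    fe = mott_bethe(fx, 6, np.array([0.0, 0.005, 0.01, 0.02]))
    assert np.all(np.isfinite(fe))
    # series extrapolation continuous with direct evaluation at the cutoff
    assert fe[2] == pytest.approx(
        float(mott_bethe(fx, 6, np.array([0.0100001]))[0]), rel=1e-3)


def test_mott_bethe_ion_diverges_with_charge_sign():
    s = np.array([0.02, 0.05])
    fe3 = electron_slater("Fe", 3.0)(s)
    fe0 = electron_slater("Fe", 0.0)(s)
    # positive ion: strong positive divergence at small s
    assert fe3[0] > fe0[0] + 50
    assert fe3[1] > fe0[1]
    om = electron_slater("O", -1.0)(s)
    o0 = electron_slater("O", 0.0)(s)
    assert om[0] < o0[0] - 50
    with pytest.raises(ValueError):
        electron_slater("Fe", 3.0)(np.array([0.001]))


def test_mott_bethe_reproduces_tabulated_neutral_electron_factors():
    """Spherical neutral X-ray factors -> electron factors within combined
    tabulation fit error (H excluded: Z - f_x amplifies its fit error)."""
    s = np.linspace(0.05, 1.2, 120)
    for el in ["C", "O", "Fe"]:
        fe = mott_bethe(xray_iam(el), ATOMIC_NUMBER[el], s)
        tab = electron_iam(el)(s)
        assert np.max(np.abs(fe - tab) / np.abs(tab)) < 0.05


def test_charged_ordering_reverses_toward_high_s():
    s_low, s_high = 0.05, 2.0
    fe3 = electron_slater("Fe", 3.0)
    fe0 = electron_slater("Fe", 0.0)
    gap_low = fe3(np.array([s_low]))[0] - fe0(np.array([s_low]))[0]
    gap_high = fe3(np.array([s_high]))[0] - fe0(np.array([s_high]))[0]
    assert gap_low > 10.0
    assert abs(gap_high) < 0.2 * gap_low


@given(st.floats(0.0, 1.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_partial_charge_combination_is_convex(q):
    s = np.linspace(0.02, 1.0, 7)
    neutral = electron_slater("O", 0.0)
    ion = electron_slater("O", -1.0)
    mix = combine_partial_charge(neutral, ion, q)
    np.testing.assert_allclose(
        mix(s), (1 - q) * neutral(s) + q * ion(s), rtol=1e-12)


def test_partial_charge_half_is_arithmetic_mean():
    s = np.linspace(0.02, 1.2, 9)
    mix = combine_partial_charge(electron_slater("O", 0.0),
                                 electron_slater("O", -1.0), 0.5)
    mean = 0.5 * (electron_slater("O", 0.0)(s) + electron_slater("O", -1.0)(s))
    np.testing.assert_allclose(mix(s), mean, rtol=1e-12)


def test_partial_charge_rejects_mixed_radiation():
    with pytest.raises(ValueError):
        combine_partial_charge(xray_slater("O"), electron_slater("O", -1.0),
                               0.5)


def test_gaussian_fit_recovers_exact_gaussian_model():
    truth = GaussianFormFactor("toy", Radiation.ELECTRON,
                               (2.0, 1.0, 0.5, 0.2), (0.3, 2.0, 8.0, 30.0))
    s = np.linspace(0.0, 1.2, 60)
    ff, rep = fit_gaussians(s, truth(s))
    assert rep.rms < 1e-8
    np.testing.assert_allclose(ff(s), truth(s), atol=1e-7)


def test_gaussian_fit_of_partial_charge_curve_within_one_percent():
    """O^0.5- electron curve: the screened part is fitted by 4 Gaussians to
    1% of the curve scale, the C*q/s^2 divergence kept analytic."""
    mix = combine_partial_charge(electron_slater("O", 0.0),
                                 electron_slater("O", -1.0), 0.5)
    s = np.linspace(0.0578, 1.2, 150)   # refinement range, d <= 8.65 A
    ff, rep = fit_gaussians(s, mix(s), coulomb_q=-0.5)
    assert rep.converged
    scale = np.max(np.abs(mix(s)))
    assert rep.max_abs < 0.01 * scale
    # dense-grid oracle: evaluate the linear combination directly
    s_dense = np.linspace(0.06, 1.19, 500)
    assert np.max(np.abs(ff(s_dense) - mix(s_dense))) < 0.01 * scale


def test_gaussian_fit_invariant_under_duplicated_samples():
    truth = electron_slater("C", 0.0)
    s = np.linspace(0.02, 1.2, 40)
    ff1, _ = fit_gaussians(s, truth(s))
    s2 = np.concatenate([s, s])
    ff2, _ = fit_gaussians(s2, truth(s2))
    grid = np.linspace(0.05, 1.1, 30)
    np.testing.assert_allclose(ff1(grid), ff2(grid), atol=2e-4)


def test_gaussian_set_json_round_trip(tmp_path):
    from edtaam.formfactor import (fit_gaussians, gaussian_set_from_json,
                                   gaussian_set_to_json)
    s = np.linspace(0.06, 1.2, 60)
    ff1, _ = fit_gaussians(s, electron_slater("C")(s), species_label="C")
    ff2, _ = fit_gaussians(s, electron_slater("O", -1.0)(s),
                           species_label="O1-", coulomb_q=-1.0)
    path = tmp_path / "set.json"
    gaussian_set_to_json({"C": ff1, "O1-": ff2}, path)
    back = gaussian_set_from_json(path)
    grid = np.linspace(0.06, 1.1, 20)
    np.testing.assert_allclose(back["C"](grid), ff1(grid), rtol=1e-12)
    np.testing.assert_allclose(back["O1-"](grid), ff2(grid), rtol=1e-12)
    assert back["O1-"].coulomb_q == -1.0


def test_refit_of_tabulated_electron_curve_tracks_tabulation():
    """4-Gaussian refit of the neutral O electron factor stays within the
    fit residual it reports on the sample grid."""
    tab = electron_iam("O")
    s = np.linspace(0.0, 1.2, 100)
    ff, rep = fit_gaussians(s, tab(s))
    assert np.max(np.abs(ff(s) - tab(s))) <= rep.max_abs + 1e-12
    assert rep.max_rel < 0.01
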