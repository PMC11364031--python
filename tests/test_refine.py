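"""Weighting scheme, agreement statistics and the least-squares engine."""

import numpy as np
import pytest

from edtaam.crystal import AtomSite, CrystalStructure, ReflectionSet, SpaceGroup
from edtaam.formfactor import electron_slater
from edtaam.refine import (RefinementConfig, apply_riding, ellipsoid_ratios,
                           goof, optimize_weights, r_factors, refine_lsq,
                           riding_map, rmsd_models, shell_r1, weight)
from edtaam.structure_factors import SphericalProvider
from edtaam.synthetic import (SimulationSpec, make_structure,
                              simulate_reflections, electron_iam_curves)


# --------------------------------------------------------------------------
# weighting scheme


def test_weight_reduces_to_inverse_variance():
    w = weight([4.0], [2.0], [4.0], 0.0, 0.0)
    assert w[0] == pytest.approx(0.25)


def test_weight_hand_computed_example():
    # F_obs^2 = F_calc^2 = 3, sigma = 1, a = 1, b = 0 -> P = 3, w = 1/10
    assert weight([3.0], [1.0], [3.0], 1.0, 0.0)[0] == pytest.approx(0.1)


def test_weight_with_reported_taam_parameters():
    """The optimized (a, b) pair of the custom-TAAM electron refinement,
    applied to one synthetic reflection, against direct hand evaluation."""
    a, b = 0.1483, 5.0209
    f_obs2, sigma, f_calc2 = 140.0, 9.0, 150.0
    P = (f_obs2 + 2 * f_calc2) / 3.0
    expected = 1.0 / (sigma**2 + (a * P) ** 2 + b * P)
    assert weight([f_obs2], [sigma], [f_calc2], a, b)[0] == \
        pytest.approx(expected, rel=1e-14)


def test_weight_floors_negative_intensity_in_p():
    w = weight([-5.0], [1.0], [3.0], 0.5, 1.0)
    P = 2.0  # (0 + 2*3)/3
    assert w[0] == pytest.approx(1.0 / (1.0 + 1.0 + 2.0))


def test_weight_rejects_bad_sigma():
    with pytest.raises(ValueError):
        weight([1.0], [-1.0], [1.0], 0.0, 0.0)


# --------------------------------------------------------------------------
# statistics


def test_r1_zero_for_perfect_fit():
    f2 = np.array([10.0, 40.0, 90.0])
    r1s, r1a, wr2 = r_factors(f2, np.full(3, 0.1), f2, 1.0)
    assert r1s == pytest.approx(0.0, abs=1e-14)
    assert wr2 == pytest.approx(0.0, abs=1e-14)


def test_r1_uniform_ten_percent_amplitude_error():
    fo = np.array([2.0, 3.0, 5.0])
    fc = 1.1 * fo
    r1s, r1a, _ = r_factors(fo**2, np.full(3, 1e-3) * fo**2, fc**2, 1.0)
    assert r1a == pytest.approx(0.1, rel=1e-10)


def test_r1_matches_naive_loop_on_random_data():
    rng = np.random.default_rng(3)
    f2 = rng.uniform(1, 100, 100)
    sig = rng.uniform(0.5, 3.0, 100)
    fc2 = f2 * rng.uniform(0.8, 1.2, 100)
    k = 1.07
    r1s, r1a, wr2 = r_factors(f2, sig, fc2, k, cut=4.0)
    fo = np.sqrt(np.maximum(f2, 0))
    sfo = np.where(fo > np.sqrt(sig) / 2, sig / (2 * fo), np.sqrt(sig))
    fc = np.sqrt(k * fc2)
    mask = fo > 4 * sfo
    r1_naive = sum(abs(a - b) for a, b, m in zip(fo, fc, mask) if m) / \
        sum(a for a, m in zip(fo, mask) if m)
    assert r1s == pytest.approx(r1_naive, abs=1e-12)


def test_goof_perfect_and_algebraic_cases():
    f2 = np.array([4.0, 9.0, 16.0, 25.0])
    w = 1.0 / np.ones(4)
    assert goof(f2, np.ones(4), f2, w, 1) == pytest.approx(0.0)
    # residuals == sigma with w = 1/sigma^2 -> GooF = sqrt(n/(n-p))
    sig = np.array([1.0, 2.0, 0.5, 3.0])
    fc2 = f2 - sig
    g = goof(f2, sig, fc2, 1.0 / sig**2, 1)
    assert g == pytest.approx(np.sqrt(4.0 / 3.0), rel=1e-12)
    with pytest.raises(ValueError):
        goof(f2, sig, fc2, w, 4)


def test_goof_matches_brute_force_sum():
    rng = np.random.default_rng(0)
    f2 = rng.uniform(5, 50, 60)
    sig = rng.uniform(0.5, 2, 60)
    fc2 = f2 + rng.normal(size=60)
    w = 1.0 / sig**2
    expected = np.sqrt(sum(wi * (a - b) ** 2 for wi, a, b
                           in zip(w, f2, fc2)) / (60 - 10))
    assert goof(f2, sig, fc2, w, 10) == pytest.approx(expected, rel=1e-12)


def test_shell_r1_single_shell_equals_global(p1_cell):
    rng = np.random.default_rng(1)
    hkl = np.array([(h, k, l) for h in range(1, 5) for k in range(3)
                    for l in range(3)])
    f2 = rng.uniform(10, 100, len(hkl))
    rs = ReflectionSet(hkl, f2, np.sqrt(f2) * 0.1, p1_cell)
    fc2 = f2 * rng.uniform(0.9, 1.1, len(rs))
    r1s, r1a, _ = r_factors(rs.f2, rs.sigma, fc2, 1.0)
    shells = shell_r1(rs, fc2, 1.0, [np.max(rs.d) + 1, np.min(rs.d) - 0.01])
    assert shells[0]["r1_strong"] == pytest.approx(r1s, abs=1e-12)
    # two shells agree with filter-then-r_factors oracle
    mid = float(np.median(rs.d))
    two = shell_r1(rs, fc2, 1.0, [np.max(rs.d) + 1, mid, np.min(rs.d) - 0.01])
    m = rs.d > mid
    oracle = r_factors(rs.f2[m], rs.sigma[m], fc2[m], 1.0)[0]
    assert two[0]["r1_strong"] == pytest.approx(oracle, abs=1e-12)
    assert two[0]["n_all"] + two[1]["n_all"] == len(rs)


def test_shell_r1_empty_shell_sentinel(p1_cell):
    rs = ReflectionSet([(1, 0, 0)], [10.0], [1.0], p1_cell)
    shells = shell_r1(rs, np.array([10.0]), 1.0, [30.0, 20.0, 5.0])
    assert shells[0]["n_all"] == 0 and np.isnan(shells[0]["r1_strong"])


def test_ellipsoid_ratios_isotropic_and_diagonal(p1_cell):
    sites = [
        AtomSite("A", "C", [0, 0, 0], u_aniso=[0.02, 0.02, 0.02, 0, 0, 0]),
        AtomSite("B", "C", [0.5, 0, 0], u_aniso=[0.04, 0.01, 0.01, 0, 0, 0]),
        AtomSite("BAD", "C", [0, 0.5, 0], u_aniso=[-0.01, 0.01, 0.01, 0, 0, 0]),
    ]
    st = CrystalStructure(p1_cell, SpaceGroup("P1"), sites)
    per_atom, mean, flagged = ellipsoid_ratios(st)
    assert per_atom["A"] == pytest.approx(1.0)
    assert per_atom["B"] == pytest.approx(2.0)
    assert flagged == ["BAD"]
    assert mean == pytest.approx(1.5)


def test_ellipsoid_ratio_matches_eigenvalue_oracle(random_p1_structure):
    from edtaam.refine import u_cartesian
    per_atom, _, flagged = ellipsoid_ratios(random_p1_structure)
    assert not flagged
    for site in random_p1_structure.sites:
        if not site.is_aniso:
            continue
        ev = np.linalg.eigvalsh(u_cartesian(random_p1_structure, site))
        assert per_atom[site.label] == pytest.approx(
            np.sqrt(ev[-1] / ev[0]))


def test_rmsd_identity_and_uniform_shift(synthetic_structure):
    st = synthetic_structure
    c, b = rmsd_models(st, st)
    assert c == pytest.approx(0.0, abs=1e-14)
    shifted = st.copy()
    for site in shifted.sites:
        site.frac = site.frac + np.array([0.1 / st.cell.a, 0, 0])
    c, b = rmsd_models(st, shifted)
    assert c == pytest.approx(0.1, rel=1e-10)
    assert b == pytest.approx(0.0, abs=1e-10)
    bad = st.copy()
    bad.sites[0].label = "XX"
    with pytest.raises(ValueError, match="unmatched"):
        rmsd_models(st, bad)


# --------------------------------------------------------------------------
# least-squares engine (reduced resolution keeps these fast)


@pytest.fixture(scope="module")
def noise_free_setup():
    spec = SimulationSpec(truth="iam", completeness=1.0, d_min=1.2, seed=5)
    st = make_structure(spec)
    refl, truth = simulate_reflections(st, spec)
    shape = np.sqrt(np.maximum(truth["f2_true"], 1e-12)
                    + spec.noise_g * truth["f2_true"] ** 2)
    exact = ReflectionSet(truth["hkl"], truth["f2_true"],
                          truth["sigma_scale"] * shape, st.cell)
    provider = SphericalProvider(electron_iam_curves(st))
    return st, exact, provider


def test_refinement_of_true_model_gives_zero_r1(noise_free_setup):
    st, refl, provider = noise_free_setup
    res = refine_lsq(st, refl, provider,
                     RefinementConfig(n_weight_cycles=1))
    assert res.r1_all < 1e-6
    assert res.scale == pytest.approx(1.0, abs=1e-8)
    assert res.converged


def test_refinement_recovers_perturbed_coordinates(noise_free_setup):
    st, refl, provider = noise_free_setup
    pert = st.copy()
    rng = np.random.default_rng(2)
    for site in pert.sites:
        if site.element != "H":
            site.frac = site.frac + rng.normal(scale=2e-3, size=3)
    apply_riding(pert, riding_map(st))
    res = refine_lsq(pert, refl, provider,
                     RefinementConfig(n_weight_cycles=1))
    A = st.cell.orth_matrix
    for site in st.sites:
        if site.element == "H":
            continue
        diff = (res.structure.site(site.label).frac - site.frac) @ A.T
        assert np.linalg.norm(diff) < 1e-4


def test_riding_hydrogens_keep_fixed_distances(noise_free_setup):
    st, refl, provider = noise_free_setup
    riders = riding_map(st)
    pert = st.copy()
    rng = np.random.default_rng(9)
    for site in pert.sites:
        if site.element != "H":
            site.frac = site.frac + rng.normal(scale=1.5e-3, size=3)
    apply_riding(pert, riders)
    res = refine_lsq(pert, refl, provider,
                     RefinementConfig(n_weight_cycles=1))
    A = st.cell.orth_matrix
    for h_label, (parent, mult, offset) in riders.items():
        d0 = np.linalg.norm(offset @ A.T)
        h = res.structure.site(h_label)
        p = res.structure.site(parent)
        d = np.linalg.norm((h.frac - p.frac) @ A.T)
        assert d == pytest.approx(d0, abs=1e-6)
        # U_iso tie
        ueq = np.trace(p.u_matrix()) / 3.0
        assert h.u_iso == pytest.approx(mult * ueq, rel=1e-10)


def test_analytic_jacobian_matches_finite_differences(p1_cell):
    from edtaam.refine import _Parametrization, _sf_with_derivs
    rng = np.random.default_rng(4)
    sites = [AtomSite("C1", "C", [0.1, 0.2, 0.3],
                      u_aniso=[0.02, 0.03, 0.025, 0.002, -0.001, 0.003]),
             AtomSite("O1", "O", [0.4, 0.1, 0.7], u_iso=0.02)]
    st = CrystalStructure(p1_cell, SpaceGroup("P1"), sites)
    cfg = RefinementConfig()
    par = _Parametrization(st, cfg)
    hkl = rng.integers(-3, 4, (10, 3)).astype(float)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    from edtaam.structure_factors import atom_factor_array, SphericalProvider
    prov = SphericalProvider({el: electron_slater(el) for el in ["C", "O"]})
    fv = atom_factor_array(st, hkl, prov)
    from edtaam.crystal import d_spacing
    s = 1.0 / (2.0 * d_spacing(st.cell, hkl))
    p0 = par.get_vector(1.0)
    F0, dF = _sf_with_derivs(par, hkl, fv, s)
    eps = 1e-7
    for i in range(1, par.n_params):
        p = p0.copy()
        p[i] += eps
        par.set_vector(p)
        Fp, _ = _sf_with_derivs(par, hkl, fv, s, want_derivs=False)
        p[i] -= 2 * eps
        par.set_vector(p)
        Fm, _ = _sf_with_derivs(par, hkl, fv, s, want_derivs=False)
        num = (Fp - Fm) / (2 * eps)
        np.testing.assert_allclose(dF[:, i], num, rtol=2e-5, atol=1e-6)


def test_refinement_errors_on_underdetermined_problem(p1_cell):
    st = CrystalStructure(p1_cell, SpaceGroup("P1"),
                          [AtomSite("C1", "C", [0.1, 0.2, 0.3], u_iso=0.02)])
    rs = ReflectionSet([(1, 0, 0), (0, 1, 0)], [1.0, 2.0], [0.1, 0.1],
                       p1_cell)
    prov = SphericalProvider({"C": electron_slater("C")})
    with pytest.raises(ValueError, match="n_params"):
        refine_lsq(st, rs, prov)


def test_esds_bracket_truth_on_noisy_data():
    """With a correctly matched model, refined coordinate deviations from
    ground truth are consistent with the reported esds."""
    from edtaam.synthetic import make_benchmark_pair, truth_multipole_models
    from edtaam.structure_factors import MultipoleProvider

    spec = SimulationSpec(seed=15, d_min=1.3)
    refl, start, truth = make_benchmark_pair(spec)
    st = truth["structure"]
    models, rots = truth_multipole_models(st)
    provider = MultipoleProvider(models, rots, "electron")
    res = refine_lsq(start, refl, provider,
                     RefinementConfig(weight_a=0.0, weight_b=0.0,
                                      n_weight_cycles=2))
    from edtaam.refine import _Parametrization
    par = _Parametrization(res.structure, RefinementConfig())
    z = []
    for lab, (i, nc, nu) in par.slices.items():
        true_frac = st.site(lab).frac
        got_frac = res.structure.site(lab).frac
        for c in range(3):
            z.append(abs(got_frac[c] - true_frac[c]) / res.esds[i + c])
    z = np.array(z)
    assert np.median(z) < 2.0            # esds are the right scale
    assert np.mean(z < 4.0) > 0.9        # and bracket the truth


def test_extinction_scalar_recovered(noise_free_setup):
    """Data damped by a single isotropic extinction factor are fit exactly
    when the scalar is refined, and the injected value is recovered."""
    st, refl, provider = noise_free_setup
    x_true = 2e-4
    f2_ext = refl.f2 / (1.0 + x_true * refl.f2)
    damped = ReflectionSet(refl.hkl, f2_ext, refl.sigma, st.cell)
    res = refine_lsq(st, damped, provider,
                     RefinementConfig(n_weight_cycles=1,
                                      extinction_refined=True))
    assert res.extinction == pytest.approx(x_true, rel=1e-3)
    assert res.r1_all < 1e-6
    # without the extinction parameter the same data fit worse
    res0 = refine_lsq(st, damped, provider,
                      RefinementConfig(n_weight_cycles=1))
    assert res0.r1_all > res.r1_all


# --------------------------------------------------------------------------
# weight optimization


def test_optimize_weights_near_zero_for_exact_sigmas():
    rng = np.random.default_rng(12)
    n = 2000
    fc2 = rng.uniform(10, 1000, n)
    sig = 0.1 * fc2**0.75
    fo2 = fc2 + rng.normal(size=n) * sig
    a, b, table, ok = optimize_weights(fo2, sig, fc2, 1.0, 50)
    assert ok
    assert a < 0.02
    assert abs(b) < 2.0
    assert np.max(table) / max(np.min(table), 1e-9) < 1.6


def test_optimize_weights_recovers_injected_p_inflation():
    rng = np.random.default_rng(13)
    n = 4000
    fc2 = rng.uniform(10, 1000, n)
    sig = 0.05 * fc2**0.6
    a_true = 0.12
    total = np.sqrt(sig**2 + (a_true * fc2) ** 2)
    fo2 = fc2 + rng.normal(size=n) * total
    a, b, table, ok = optimize_weights(fo2, sig, fc2, 1.0, 50)
    assert a == pytest.approx(a_true, abs=0.03)
    assert np.max(table) / np.min(table) < 1.5
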