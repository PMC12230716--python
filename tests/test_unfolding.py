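"""Equilibrium populations, irreversible kinetics, m-value prediction and the
global fitting engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cdspectra as cd
from cdspectra.unfolding import R_KCAL, T0_K, _solve_oligomer_fu


# ---------------------------------------------------------------------------
# Populations


def test_monomer_half_unfolded_at_tm_any_dcp():
    for dcp in (0.0, 2.3):
        pops = cd.populations_thermal(349.75, 86.8, 349.75, dcp)
        assert pops["unfolded"][0] == pytest.approx(0.5, abs=1e-12)


def test_three_state_reduces_to_two_state_when_second_transition_off():
    T = np.linspace(300.0, 360.0, 25)
    # second transition pushed far above the range: K2 ~ 0 throughout
    p3 = cd.populations_thermal(T, 80.0, 340.0, n_states=3, dH2=200.0, Tm2_K=500.0)
    p2 = cd.populations_thermal(T, 80.0, 340.0)
    np.testing.assert_allclose(p3["native"], p2["native"], atol=1e-6)
    np.testing.assert_allclose(p3["intermediate"] + p3["unfolded"],
                               p2["unfolded"], atol=1e-6)


def test_dimer_bisection_matches_dense_grid_scan():
    Ct, n, K = 1e-5, 2, 1.0  # T = Tm so K = 1
    fu = _solve_oligomer_fu(K, n, Ct)
    # independent oracle: dense scan of the mass-action residual
    grid = np.linspace(1e-9, 1 - 1e-9, 1_000_000)
    resid = np.abs(n * Ct ** (n - 1) * grid**n / (1 - grid) - K)
    fu_scan = grid[np.argmin(resid)]
    assert fu == pytest.approx(fu_scan, abs=2e-6)
    # mass-action equation satisfied to 1e-10 relative
    assert n * Ct ** (n - 1) * fu**n / (1 - fu) == pytest.approx(K, rel=1e-9)


def test_oligomer_population_depends_on_concentration():
    pops_lo = cd.populations_thermal(349.75, 86.8, 349.75, oligomer_n=2, Ct=1e-6)
    pops_hi = cd.populations_thermal(349.75, 86.8, 349.75, oligomer_n=2, Ct=1e-3)
    assert pops_lo["unfolded"][0] > pops_hi["unfolded"][0]  # dilution unfolds


def test_chemical_midpoint_and_boltzmann_ratio():
    pops = cd.populations_chemical(3.9, 3.9, 4.0)
    assert pops["unfolded"][0] == pytest.approx(0.5, abs=1e-12)
    # 1 M past D50_2: p_U/p_I equals the direct Boltzmann factor
    T = 293.15
    p3 = cd.populations_chemical(
        4.9, 2.5, 2.0, T, n_states=3, D50_2=3.9, m_2=4.0
    )
    K2 = np.exp(4.0 * (4.9 - 3.9) / (R_KCAL * T))
    assert p3["unfolded"][0] / p3["intermediate"][0] == pytest.approx(K2, rel=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    dH=st.floats(5.0, 200.0),
    Tm=st.floats(300.0, 370.0),
    dH2=st.floats(5.0, 200.0),
    Tm2=st.floats(300.0, 370.0),
    T=st.floats(274.0, 380.0),
)
def test_three_state_fractions_sum_to_one(dH, Tm, dH2, Tm2, T):
    pops = cd.populations_thermal(T, dH, Tm, n_states=3, dH2=dH2, Tm2_K=Tm2)
    total = sum(p[0] for p in pops.values())
    assert total == pytest.approx(1.0, abs=1e-9)
    assert all(0.0 <= p[0] <= 1.0 for p in pops.values())


def test_unfolded_fraction_monotone_in_temperature():
    T = np.linspace(280.0, 380.0, 200)
    fu = cd.populations_thermal(T, 86.8, 349.75, 0.0)["unfolded"]
    assert np.all(np.diff(fu) > 0)
    # with ΔCp > 0 the stability curve turns over: cold denaturation raises
    # fU again at low temperature, so monotonicity holds only above the
    # temperature of maximal stability
    fu_cp = cd.populations_thermal(T, 86.8, 349.75, 2.3)["unfolded"]
    above = T >= T[np.argmin(fu_cp)]
    assert np.all(np.diff(fu_cp[above]) > 0)


def test_signal_model_limits():
    x = np.linspace(20.0, 90.0, 10)
    frozen = {"native": np.ones_like(x), "unfolded": np.zeros_like(x)}
    y = cd.signal_model(x, frozen, {"native": (2.0, 0.5), "unfolded": (9.0, 0.0)})
    np.testing.assert_allclose(y, 2.0 + 0.5 * x)
    pops = cd.populations_thermal(x + T0_K, 86.8, 349.75)
    flat = cd.signal_model(x, pops, {"native": (7.0, 0.0), "unfolded": (7.0, 0.0)})
    np.testing.assert_allclose(flat, 7.0)
    with pytest.raises(cd.UnfoldingError, match="unknown state"):
        cd.signal_model(x, pops, {"martian": (0.0, 0.0)})


# ---------------------------------------------------------------------------
# Irreversible (Lumry-Eyring)


def test_rate_constant_is_one_at_tf():
    assert cd.rate_constant(358.15, 50.0, 358.15) == pytest.approx(1.0)


def test_infinite_scan_rate_leaves_native():
    T = np.arange(300.0, 380.0, 1.0)
    res = cd.simulate_irreversible(T, 50.0, 358.15, scan_rate=1e9)
    assert res["final"][-1] < 1e-6


def test_constant_rate_matches_closed_form():
    # Ea = 0: k == 1 everywhere, x_F(T) = 1 - exp(-(T - T0)/v)
    T = np.arange(300.0, 320.0 + 1e-9, 0.5)
    v = 2.0
    res = cd.simulate_irreversible(T, 0.0, 358.15, scan_rate=v)
    expected = 1.0 - np.exp(-(T - T[0]) / v)
    np.testing.assert_allclose(res["final"], expected, atol=1e-8)


def test_lumry_eyring_cross_checked_against_scipy_integrator():
    from scipy.integrate import solve_ivp

    Ea, Tf, v, dH, Tm = 50.0, 353.15, 1.0, 86.8, 349.75
    T = np.arange(310.0, 370.0 + 1e-9, 1.0)
    res = cd.simulate_irreversible(T, Ea, Tf, v, scheme="N<=>U->F", dH=dH, Tm_K=Tm)

    def rhs(t, y):
        k = np.exp(-(Ea / R_KCAL) * (1 / t - 1 / Tf))
        K = np.exp(-(dH * (1 - t / Tm)) / (R_KCAL * t))
        return (k / v) * (1 - y[0]) * K / (1 + K)

    sol = solve_ivp(rhs, (T[0], T[-1]), [0.0], t_eval=T, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(res["final"], sol.y[0], atol=1e-6)


def test_irreversible_input_validation():
    with pytest.raises(cd.UnfoldingError):
        cd.simulate_irreversible(np.array([300.0, 299.0]), 50.0, 358.15, 1.0)
    with pytest.raises(cd.UnfoldingError):
        cd.simulate_irreversible(np.array([300.0, 301.0]), 50.0, 358.15, -1.0)


# ---------------------------------------------------------------------------
# m-value prediction


def test_m_value_prediction_for_364_residues():
    res = cd.predict_m_value(364)
    assert res["dASA"] == pytest.approx(-907 + 93 * 364)
    assert res["dASA"] == pytest.approx(32945.0)
    assert round(res["m"], 1) == 4.5


def test_m_value_short_chain_warns_but_returns():
    with pytest.warns(UserWarning, match="negative"):
        res = cd.predict_m_value(5)
    assert res["dASA"] < 0
    # intercept of the m(dASA) correlation in kcal/mol/M
    assert (0.13 * 0.0 + 243.0) / 1000.0 == pytest.approx(0.243)


# ---------------------------------------------------------------------------
# Global fitting


def _thermal_curves(seed, noise, wavelengths=(190, 200, 210, 220, 230)):
    truth = cd.SyntheticTruth(kind="thermal-2s", noise_sd=noise, seed=seed)
    s = cd.gen_unfolding_dataset(truth)
    return [
        cd.Curve(s.param_values, s.signal_at(w), f"wl{w}") for w in wavelengths
    ], s


def test_noiseless_fit_recovers_exactly():
    curves, _ = _thermal_curves(0, 0.0)
    res = cd.global_fit(curves, cd.ModelSpec(kind="thermal", dCp=2.3))
    assert res.success
    assert res.residual_norm <= 1e-6
    assert res.estimates["Tm"] == pytest.approx(76.6, abs=1e-4)
    assert res.estimates["dH"] == pytest.approx(86.8, rel=1e-4)


def test_thermal_recovery_over_50_replicates():
    tm_err, dh_rel = [], []
    for seed in range(50):
        curves, _ = _thermal_curves(100 + seed, 0.02)
        res = cd.global_fit(curves, cd.ModelSpec(kind="thermal", dCp=2.3))
        tm_err.append(abs(res.estimates["Tm"] - 76.6))
        dh_rel.append(abs(res.estimates["dH"] - 86.8) / 86.8)
    assert np.median(tm_err) <= 0.3
    assert np.median(dh_rel) <= 0.05


def test_chemical_three_state_recovery_over_50_replicates():
    d1_err, d2_err, m2_rel = [], [], []
    model = cd.ModelSpec(kind="chemical", n_states=3)
    for seed in range(50):
        truth = cd.SyntheticTruth(kind="chemical-3s", noise_sd=0.02, seed=500 + seed)
        s = cd.gen_unfolding_dataset(truth)
        curves = [
            cd.Curve(s.param_values, s.signal_at(w), f"wl{w}")
            for w in (195, 205, 215, 222, 230)
        ]
        res = cd.global_fit(curves, model)
        d1_err.append(abs(res.estimates["D50_1"] - 2.5))
        d2_err.append(abs(res.estimates["D50_2"] - 3.9))
        m2_rel.append(abs(res.estimates["m_2"] - 4.0) / 4.0)
    assert np.median(d1_err) <= 0.2
    assert np.median(d2_err) <= 0.2
    assert np.median(m2_rel) <= 0.15


def test_svd_level_fit_agrees_with_wavelength_fit():
    curves, s = _thermal_curves(7, 0.02)
    model = cd.ModelSpec(kind="thermal", dCp=2.3)
    res_wl = cd.global_fit(curves, model)
    d = cd.rotate_to_first_spectrum(cd.decompose(s, "svd"), 2)
    coeff_curves = [
        cd.Curve(s.param_values, d.coefficients[i], f"c{i}") for i in range(2)
    ]
    res_svd = cd.global_fit(coeff_curves, model)
    joint = 2 * np.hypot(res_wl.std_errors["Tm"], res_svd.std_errors["Tm"])
    assert abs(res_wl.estimates["Tm"] - res_svd.estimates["Tm"]) <= joint


def test_std_errors_shrink_with_replicated_curves():
    rng = np.random.default_rng(42)
    x = np.arange(24.0, 85.1, 2.5)
    pops = cd.populations_thermal(x + T0_K, 86.8, 349.75, 2.3)
    clean = cd.signal_model(x, pops, {"native": (-20.0, 0.0), "unfolded": (-2.0, 0.0)})
    model = cd.ModelSpec(kind="thermal", dCp=2.3)

    def fit_n(n):
        curves = [
            cd.Curve(x, clean + rng.normal(0, 0.4, x.size), f"r{i}")
            for i in range(n)
        ]
        return cd.global_fit(curves, model).std_errors["Tm"]

    se1 = np.median([fit_n(1) for _ in range(8)])
    se4 = np.median([fit_n(4) for _ in range(8)])
    assert se4 == pytest.approx(se1 / 2.0, rel=0.5)
    assert se4 < se1


def test_shared_versus_local_parameters():
    curves, _ = _thermal_curves(3, 0.01)
    res = cd.global_fit(
        curves, cd.ModelSpec(kind="thermal", dCp=2.3), shared={"dH": "local"}
    )
    assert "Tm" in res.estimates
    assert all(f"dH_c{i}" in res.estimates for i in range(len(curves)))
    assert res.shared_map["dH"] == "local" and res.shared_map["Tm"] == "global"


def test_unreliable_parameter_flagging():
    res = cd.FitResult(
        estimates={"m_1": 1.0, "m_2": 4.0},
        std_errors={"m_1": 0.8, "m_2": 0.1},
        shared_map={}, fitted={}, residuals={}, residual_norm=0.0, success=True,
    )
    assert res.flagged_unreliable() == ["m_1"]
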