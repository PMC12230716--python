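"""Data model, CSV I/O, unit conversion and preprocessing."""

import io
import math

import numpy as np
import pytest

import cdspectra as cd
from cdspectra.spectra import KAPPA, _unit_factor


# ---------------------------------------------------------------------------
# CSV I/O


def test_matrix_layout_parses_numeric_headers_as_parameters(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text("wl,25,85\n220,-10,-3\n221,-11,-4\n222,-12,-5\n")
    s = cd.load_spectra_csv(p)
    assert s.n_spectra == 2
    assert s.unit == "millidegrees"
    np.testing.assert_allclose(s.param_values, [25.0, 85.0])
    np.testing.assert_allclose(s.values[:, 1], [-3, -4, -5])


def test_long_layout_equivalent_to_matrix(tmp_path):
    m = tmp_path / "m.csv"
    m.write_text("wl,25,85\n220,-10,-3\n221,-11,-4\n222,-12,-5\n")
    l = tmp_path / "l.csv"
    rows = ["wavelength,value,id,param"]
    for wl, va, vb in [(220, -10, -3), (221, -11, -4), (222, -12, -5)]:
        rows.append(f"{wl},{va},hot,25")
        rows.append(f"{wl},{vb},cold,85")
    l.write_text("\n".join(rows) + "\n")
    sm = cd.load_spectra_csv(m)
    sl = cd.load_spectra_csv(l, layout="long")
    np.testing.assert_allclose(sl.wavelengths, sm.wavelengths)
    np.testing.assert_allclose(sl.values, sm.values)
    np.testing.assert_allclose(sl.param_values, sm.param_values)


def test_unit_comment_and_ht_columns(tmp_path):
    p = tmp_path / "u.csv"
    p.write_text(
        "# unit: molar_ellipticity\nwl,s1,s1_HT\n220,-10,300\n221,-11,310\n"
    )
    s = cd.load_spectra_csv(p)
    assert s.unit == "molar_ellipticity"
    assert s.ht_voltage is not None
    np.testing.assert_allclose(s.ht_voltage[:, 0], [300, 310])


@pytest.mark.parametrize(
    "body,match",
    [
        ("wl,a\n220,-10\n220,-11\n", "duplicate"),
        ("wl,a\n2x0,-10\n221,-11\n", "non-numeric wavelength"),
        ("wl,a\n220,-10\n221,-11,9\n", "ragged"),
    ],
)
def test_malformed_files_rejected(tmp_path, body, match):
    p = tmp_path / "bad.csv"
    p.write_text(body)
    with pytest.raises(cd.SpectraError, match=match):
        cd.load_spectra_csv(p)


def test_save_load_roundtrip(tmp_path, small_set):
    path = tmp_path / "out.csv"
    cd.save_spectra_csv(small_set, path)
    back = cd.load_spectra_csv(path)
    assert back.unit == small_set.unit
    np.testing.assert_allclose(back.wavelengths, small_set.wavelengths)
    np.testing.assert_allclose(back.values, small_set.values)
    np.testing.assert_allclose(back.param_values, small_set.param_values)


# ---------------------------------------------------------------------------
# Unit conversion


def test_kappa_from_formula():
    assert KAPPA == 1000.0 * math.log(10.0) * (180.0 / math.pi) / 4.0
    assert KAPPA == pytest.approx(32982.0, abs=0.2)


def test_conversion_chain_anchored_on_millidegrees():
    info = cd.SampleInfo(path_length_cm=1.0, concentration_molar=1.0,
                         n_chromophores=2)
    wl = np.array([222.0])
    s = cd.SpectraSet(wl, np.array([[KAPPA]]), "millidegrees")
    assert cd.convert_units(s, info, "delta_absorbance").values[0, 0] == pytest.approx(1.0)
    assert cd.convert_units(s, info, "molar_extinction").values[0, 0] == pytest.approx(1.0)
    assert cd.convert_units(s, info, "molar_ellipticity").values[0, 0] == pytest.approx(KAPPA / 10.0)
    assert cd.convert_units(s, info, "mean_unit_molar_extinction").values[0, 0] == pytest.approx(0.5)


def test_zero_signal_is_zero_in_every_unit(sample_info):
    s = cd.SpectraSet(np.array([210.0, 220.0]), np.zeros((2, 1)))
    for unit in cd.UNITS:
        assert np.all(cd.convert_units(s, sample_info, unit).values == 0)


def test_round_trip_through_any_unit_pair(sample_info, small_set):
    for u1 in cd.UNITS:
        for u2 in cd.UNITS:
            a = cd.convert_units(small_set, sample_info, u1)
            b = cd.convert_units(a, sample_info, u2)
            back = cd.convert_units(b, sample_info, "millidegrees")
            np.testing.assert_allclose(back.values, small_set.values, rtol=1e-10)


def test_missing_sample_fields_named_in_error(small_set):
    info = cd.SampleInfo(path_length_cm=1.0)
    with pytest.raises(cd.SpectraError, match="concentration_molar"):
        cd.convert_units(small_set, info, "molar_extinction")
    with pytest.raises(cd.SpectraError, match="n_chromophores"):
        cd.convert_units(
            small_set,
            cd.SampleInfo(path_length_cm=1.0, concentration_molar=1e-5),
            "mean_unit_molar_ellipticity",
        )


def test_mg_ml_concentration_converted_at_construction():
    info = cd.SampleInfo(path_length_cm=1.0, concentration_mg_ml=1.43,
                         molecular_weight=14300.0)
    assert info.concentration_molar == pytest.approx(1e-4)


# ---------------------------------------------------------------------------
# Baseline subtraction and zeroing


def test_self_subtraction_gives_zero(small_set):
    out = cd.baseline_subtract(small_set, small_set)
    np.testing.assert_allclose(out.values, 0.0)


def test_single_baseline_applied_to_all_columns(small_set):
    base = cd.SpectraSet(small_set.wavelengths, small_set.values[:, :1])
    out = cd.baseline_subtract(small_set, base)
    np.testing.assert_allclose(out.values[:, 0], 0.0)
    np.testing.assert_allclose(
        out.values[:, 1], small_set.values[:, 1] - small_set.values[:, 0]
    )


def test_offset_grid_interpolates_linear_spectrum_exactly():
    # a linear spectrum is reproduced exactly by linear interpolation
    wl_s = np.arange(200.0, 240.1, 1.0)
    wl_b = wl_s[1:-1] + 0.5
    sample = cd.SpectraSet(wl_s, (2.0 * wl_s - 100.0)[:, None])
    baseline = cd.SpectraSet(wl_b, (0.5 * wl_b + 3.0)[:, None])
    out = cd.baseline_subtract(sample, baseline)
    expected = (2.0 * out.wavelengths - 100.0) - (0.5 * out.wavelengths + 3.0)
    np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)


def test_baseline_errors(small_set):
    other_unit = small_set.copy()
    other_unit.unit = "delta_absorbance"
    with pytest.raises(cd.SpectraError, match="unit"):
        cd.baseline_subtract(small_set, other_unit)
    far = cd.SpectraSet(np.array([300.0, 310.0]), np.zeros((2, 1)))
    with pytest.raises(cd.SpectraError, match="overlap"):
        cd.baseline_subtract(small_set, far)


def test_zero_by_window_constant_window_and_idempotence():
    wl = np.arange(290.0, 301.0, 1.0)
    s = cd.SpectraSet(wl, np.full((wl.size, 1), 5.0))
    out = cd.zero_by_window(s, 296.0, 300.0)
    np.testing.assert_allclose(out.values, 0.0)
    # inclusive window on a 1-nm grid uses exactly 5 points
    ramp = cd.SpectraSet(wl, wl[:, None].astype(float))
    z = cd.zero_by_window(ramp, 296.0, 300.0)
    assert z.values[0, 0] == pytest.approx(290.0 - np.mean([296, 297, 298, 299, 300]))
    # offset invariance and idempotence
    shifted = cd.SpectraSet(wl, ramp.values + 7.3)
    np.testing.assert_allclose(
        cd.zero_by_window(shifted, 296, 300).values, z.values, atol=1e-12
    )
    np.testing.assert_allclose(
        cd.zero_by_window(z, 296, 300).values, z.values, atol=1e-12
    )
    with pytest.raises(cd.SpectraError):
        cd.zero_by_window(s, 100.0, 120.0)


# ---------------------------------------------------------------------------
# Smoothing


def test_savgol_reproduces_polynomial_exactly():
    wl = np.arange(200.0, 240.1, 1.0)
    poly = 0.01 * wl**3 - 2 * wl + 5
    s = cd.SpectraSet(wl, poly[:, None])
    out = cd.smooth(s, window=9, polyorder=3)
    np.testing.assert_allclose(out.values[:, 0], poly, rtol=1e-9)


def test_window3_order2_is_identity():
    rng = np.random.default_rng(0)
    wl = np.arange(200.0, 230.0, 1.0)
    s = cd.SpectraSet(wl, rng.normal(size=(wl.size, 2)))
    out = cd.smooth(s, window=3, polyorder=2)
    np.testing.assert_allclose(out.values, s.values, atol=1e-10)


def test_smoothing_reduces_noise_variance():
    rng = np.random.default_rng(1)
    wl = np.arange(190.0, 260.0, 0.5)
    noise = rng.normal(size=(wl.size, 1))
    s = cd.SpectraSet(wl, noise)
    out = cd.smooth(s, window=9, polyorder=3)
    assert out.values.var() < s.values.var()


def test_smooth_parameter_validation(small_set):
    with pytest.raises(cd.SpectraError, match="odd"):
        cd.smooth(small_set, window=4)
    with pytest.raises(cd.SpectraError, match="polyorder"):
        cd.smooth(small_set, window=3, polyorder=3)


# ---------------------------------------------------------------------------
# Averaging, trimming, scaling


def test_average_replicates_groups_and_params():
    wl = np.array([220.0, 221.0])
    vals = np.column_stack([np.full(2, v) for v in (1.0, 1.0, 1.0, 4.0, -4.0)])
    s = cd.SpectraSet(
        wl, vals, names=list("abcde"),
        param_values=np.array([0.0, 0.0, 0.0, 1.0, 1.0]),
    )
    out = cd.average_replicates(
        s, {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2"}
    )
    assert out.n_spectra == 2
    np.testing.assert_allclose(out.values[:, 0], 1.0)  # 3 identical replicates
    np.testing.assert_allclose(out.values[:, 1], 0.0)  # mean of +v and -v
    np.testing.assert_allclose(out.param_values, [0.0, 1.0])


def test_average_rejects_mixed_parameters():
    wl = np.array([220.0, 221.0])
    s = cd.SpectraSet(wl, np.ones((2, 2)), names=["a", "b"],
                      param_values=np.array([0.0, 1.0]))
    with pytest.raises(cd.SpectraError, match="parameter"):
        cd.average_replicates(s, {"a": "g", "b": "g"})


def test_trim_manual_inclusive(small_set):
    out = cd.trim_wavelengths(small_set, lo=210.0, hi=230.0)
    np.testing.assert_allclose(out.wavelengths, [210.0, 220.0, 230.0])
    with pytest.raises(cd.SpectraError, match="removed"):
        cd.trim_wavelengths(small_set, lo=500.0, hi=600.0)


def test_trim_ht_threshold_cuts_at_known_crossing():
    wl = np.arange(180.0, 261.0, 1.0)
    # HT rising monotonically toward low wavelength, crossing 600 V at 190 nm
    ht = 600.0 + (190.0 - wl) * 5.0
    s = cd.SpectraSet(wl, np.zeros((wl.size, 2)),
                      ht_voltage=np.column_stack([ht, ht]))
    out = cd.trim_wavelengths(s, ht_threshold=600.0)
    assert out.wavelengths.min() == 190.0
    assert out.wavelengths.max() == 260.0
    # everywhere below threshold: unchanged
    ok = cd.SpectraSet(wl, np.zeros((wl.size, 1)),
                       ht_voltage=np.full((wl.size, 1), 100.0))
    assert cd.trim_wavelengths(ok, ht_threshold=600.0).n_wavelengths == wl.size
    with pytest.raises(cd.SpectraError, match="HT"):
        cd.trim_wavelengths(cd.SpectraSet(wl, np.zeros((wl.size, 1))),
                            ht_threshold=600.0)


def test_scale_selected_columns(small_set):
    out = cd.scale(small_set, 2.0, columns=["b"])
    np.testing.assert_allclose(out.values[:, 1], 2 * small_set.values[:, 1])
    np.testing.assert_allclose(out.values[:, 0], small_set.values[:, 0])


# ---------------------------------------------------------------------------
# Structural invariants


def test_preprocessing_is_linear_per_spectrum(small_set):
    a, b = 2.5, -1.2
    combo = small_set.copy()
    combo.values = a * small_set.values + b * small_set.values[:, ::-1]
    for op in (
        lambda s: cd.smooth(s, 3, 2),
        lambda s: cd.zero_by_window(s, 200, 240),
    ):
        lhs = op(combo).values
        rhs = a * op(small_set).values + b * op(
            cd.SpectraSet(small_set.wavelengths, small_set.values[:, ::-1])
        ).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_average_and_baseline_commute(small_set):
    base = cd.SpectraSet(small_set.wavelengths,
                         np.linspace(-1, 1, small_set.n_wavelengths)[:, None])
    groups = {"a": "g1", "b": "g1", "c": "g2"}
    s2 = small_set.copy()
    s2.param_values = None
    path1 = cd.baseline_subtract(cd.average_replicates(s2, groups), base)
    path2 = cd.average_replicates(cd.baseline_subtract(s2, base), groups)
    np.testing.assert_allclose(path1.values, path2.values, atol=1e-12)


def test_logbook_appends_one_line_per_operation(tmp_path):
    log = cd.Logbook(tmp_path / "log.txt")
    log.record("smooth", window=9, polyorder=3)
    log.record("trim_wavelengths", lo=176, hi=300)
    lines = (tmp_path / "log.txt").read_text().splitlines()
    assert len(lines) == 2
    assert "window=9" in lines[0] and "lo=176" in lines[1]
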