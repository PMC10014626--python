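"""Slice-wise HU calibration: insert measurement, fits, extrapolation."""

import numpy as np
import pytest

from femfall import (DensityVolume, apply_calibration, calibrate_volume,
                     extrapolate_missing, fit_slicewise, measure_inserts)
from femfall.calibration import InsertSeries, SliceCalibration, slice_mean_hu
from femfall.phantom import InsertLayout

DENSITIES = np.array([0.0, 50.0, 100.0, 200.0, 400.0, 800.0])


def _layout(nz, valid=None):
    centers = np.stack([np.linspace(10, 90, 6), np.full(6, 15.0)], axis=1)
    v = np.ones(nz, bool) if valid is None else valid
    return InsertLayout(centers_xy=centers, radius=7.0, valid=v,
                        densities=DENSITIES.copy())


def _volume_with_inserts(nz, hu_of_insert, background=0.0):
    """(100 x 30 x nz) HU volume with six discs per slice at known values."""
    vol = np.full((100, 30, nz), background)
    lay = _layout(nz)
    xs = np.arange(100)[:, None]
    ys = np.arange(30)[None, :]
    for k, (cx, cy) in enumerate(lay.centers_xy):
        disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= 7.0 ** 2
        for z in range(nz):
            vol[disc, z] = hu_of_insert(k, z)
    return DensityVolume(vol, spacing=1.0, unit="HU"), lay


def test_constant_inserts_measured_exactly():
    v, lay = _volume_with_inserts(9, lambda k, z: 10.0 * (k + 1))
    series = measure_inserts(v, lay, window=5)
    expected = np.tile(10.0 * (np.arange(6) + 1), (9, 1))
    np.testing.assert_allclose(series.hu, expected, atol=1e-12)


def test_moving_average_window_arithmetic():
    # insert HU rises 1, 2, ..., nz along the scan: the centred five-slice
    # average of [1..5] at the middle slice is 3, shrinking at the ends
    v, lay = _volume_with_inserts(5, lambda k, z: float(z + 1))
    series = measure_inserts(v, lay, window=5)
    assert series.hu[2, 0] == pytest.approx(3.0)
    assert series.hu[0, 0] == pytest.approx(1.0)   # window shrinks to 1
    assert series.hu[1, 0] == pytest.approx(2.0)   # shrinks to 3


def test_insert_recovery_on_noiseless_phantom(noiseless_case):
    series = measure_inserts(noiseless_case.hu_volume,
                             noiseless_case.insert_layout, window=5)
    a = noiseless_case.hu_law[:, 0][:, None]
    b = noiseless_case.hu_law[:, 1][:, None]
    law_hu = a * DENSITIES[None, :] + b
    # the measurement equals the five-slice moving average of the true law
    nz = len(law_hu)
    expected = np.empty_like(law_hu)
    for z in range(nz):
        reach = min(2, z, nz - 1 - z)
        expected[z] = law_hu[z - reach: z + reach + 1].mean(axis=0)
    assert np.abs(series.hu - expected).max() < 1e-9
    # and stays within a few HU of the unaveraged law (slow modulation)
    assert np.abs(series.hu - law_hu).max() < 2.0


def test_disc_outside_image_errors():
    v, lay = _volume_with_inserts(5, lambda k, z: 1.0)
    lay.centers_xy[0] = (-50.0, -50.0)
    with pytest.raises(ValueError):
        measure_inserts(v, lay)


def test_fit_exact_line_recovered():
    # density = 0.8 * HU + 10  =>  HU = (density - 10) / 0.8
    hu = (DENSITIES - 10.0) / 0.8
    series = InsertSeries(hu=np.tile(hu, (4, 1)), valid=np.ones(4, bool),
                          densities=DENSITIES)
    cal = fit_slicewise(series)
    np.testing.assert_allclose(cal.slope, 0.8, atol=1e-9)
    np.testing.assert_allclose(cal.intercept, 10.0, atol=1e-9)


def test_fit_matches_normal_equations_oracle(rng):
    hu = (DENSITIES - 10.0) / 0.8
    hu_pert = hu + rng.normal(0, 3.0, size=6)
    series = InsertSeries(hu=hu_pert[None, :], valid=np.ones(1, bool),
                          densities=DENSITIES)
    cal = fit_slicewise(series)
    # brute-force normal equations
    X = np.column_stack([hu_pert, np.ones(6)])
    beta = np.linalg.solve(X.T @ X, X.T @ DENSITIES)
    assert cal.slope[0] == pytest.approx(beta[0], abs=1e-9)
    assert cal.intercept[0] == pytest.approx(beta[1], abs=1e-9)


def test_all_invalid_slices_error():
    series = InsertSeries(hu=np.full((3, 6), np.nan), valid=np.zeros(3, bool),
                          densities=DENSITIES)
    with pytest.raises(ValueError):
        fit_slicewise(series)


def test_extrapolation_exact_linear_dependence():
    """When insert HU is an exact linear function of the slice mean, the
    extrapolated slices reproduce the fitted slopes to 1e-6."""
    nz = 12
    mean_profile = np.linspace(40.0, 80.0, nz)  # slice-mean surrogate

    def hu_fn(k, z):
        return (k + 1) * 0.5 * mean_profile[z] + 5.0 * k

    v, lay = _volume_with_inserts(nz, hu_fn, background=0.0)
    valid = np.ones(nz, bool)
    valid[8:] = False
    lay.valid = valid
    series = measure_inserts(v, lay, window=1)  # window 1: no smearing
    cal = fit_slicewise(series)
    mean_hu = slice_mean_hu(v)
    full = extrapolate_missing(cal, series, mean_hu)
    assert full.covers_all()
    assert np.all(full.provenance[8:] == "extrapolated")
    assert np.all(full.provenance[:8] == "fitted")
    # oracle: fit the hidden slices directly from the constructed values
    for z in range(8, nz):
        hu_true = np.array([hu_fn(k, z) for k in range(6)])
        m, b = np.polyfit(hu_true, DENSITIES, 1)
        assert full.slope[z] == pytest.approx(m, rel=1e-6)
        assert full.intercept[z] == pytest.approx(b, rel=1e-4, abs=1e-6)


def test_extrapolation_noop_and_minimum_slices():
    v, lay = _volume_with_inserts(5, lambda k, z: 10.0 * (k + 1))
    series = measure_inserts(v, lay)
    cal = fit_slicewise(series)
    same = extrapolate_missing(cal, series, slice_mean_hu(v))
    assert same is cal
    lay2 = _layout(5, valid=np.array([True, True, False, False, False]))
    v2, _ = _volume_with_inserts(5, lambda k, z: 10.0 * (k + 1))
    series2 = measure_inserts(v2, lay2)
    cal2 = fit_slicewise(series2)
    with pytest.raises(ValueError):
        extrapolate_missing(cal2, series2, slice_mean_hu(v2))


def test_apply_identity_and_unit():
    v = DensityVolume(np.arange(24, dtype=float).reshape(2, 3, 4),
                      spacing=1.0, unit="HU")
    cal = SliceCalibration(slope=np.ones(4), intercept=np.zeros(4),
                           provenance=np.full(4, "fitted", object))
    out = apply_calibration(v, cal)
    np.testing.assert_array_equal(out.values, v.values)
    assert out.unit == "mg/cm3"
    # negative HU maps below zero and is NOT clamped here
    v2 = v.copy(values=v.values - 100.0)
    out2 = apply_calibration(v2, cal)
    assert out2.values.min() < 0


def test_end_to_end_noiseless_recovery(noiseless_case):
    bmd, cal = calibrate_volume(noiseless_case.hu_volume,
                                noiseless_case.insert_layout)
    inside = noiseless_case.mask.values > 0
    err = bmd.values[inside] - noiseless_case.truth_bmd.values[inside]
    assert np.sqrt((err ** 2).mean()) < 2.0


def test_shift_invariance_of_moving_average(noiseless_case):
    """Adding a constant HU offset shifts intercepts only."""
    series = measure_inserts(noiseless_case.hu_volume,
                             noiseless_case.insert_layout)
    cal = fit_slicewise(series)
    shifted = InsertSeries(hu=series.hu + 100.0, valid=series.valid,
                           densities=series.densities)
    cal2 = fit_slicewise(shifted)
    np.testing.assert_allclose(cal2.slope, cal.slope, rtol=1e-9)
    np.testing.assert_allclose(cal2.intercept, cal.intercept - 100.0 * cal.slope,
                               atol=1e-6)
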