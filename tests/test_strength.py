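"""Strength extraction, BMC corrections, damage maps, agreement statistics."""

import numpy as np
import pytest

from femfall import (MaterialLaw, agreement, average_damage_maps, block_mesh,
                     collective_correction, criterion_displacement, damage_map,
                     individual_correction, mesh_bmc, strength_from_history)
from femfall.solver import MaterialState, SolutionHistory
from femfall.volume import DensityVolume


def _history(u, f):
    return SolutionHistory(displacement=np.asarray(u, float),
                           reaction=np.asarray(f, float),
                           state=MaterialState.zeros(1), converged=True)


# --- criterion and interpolation ------------------------------------------

def test_criterion_displacement_is_four_percent(small_model):
    import copy
    m = copy.copy(small_model)
    m.head_gt_distance = 100.0
    assert criterion_displacement(m) == pytest.approx(4.0)
    m.head_gt_distance = 80.0
    assert criterion_displacement(m) == pytest.approx(3.2)
    m.head_gt_distance = 0.0
    with pytest.raises(ValueError):
        criterion_displacement(m)


def test_strength_interpolation():
    lin = _history([0, 1, 2, 3], [0, 100, 200, 300])  # F = 100 u
    assert strength_from_history(lin, 1.5) == pytest.approx(150.0)
    plateau = _history([0, 1, 2, 3], [0, 500, 510, 510])
    assert strength_from_history(plateau, 3.0) == pytest.approx(510.0)
    with pytest.raises(ValueError):
        strength_from_history(lin, 5.0)  # no extrapolation


# --- BMC and corrections ---------------------------------------------------

def test_mesh_bmc_arithmetic_and_linearity(law):
    mesh = block_mesh((10, 1, 1), element_size=3.0, bmd=500.0, law=law)
    # 10 elements x 27 mm3 x 500 mg/cm3 = 0.135 g
    assert mesh_bmc(mesh) == pytest.approx(0.135)
    assert mesh_bmc(mesh.scale_density(1.3)) == pytest.approx(0.135 * 1.3)


def test_collective_correction_identity_and_proportional():
    ref = np.array([20.0, 25.0, 30.0, 35.0])
    c = collective_correction(ref, ref)
    assert c.slope == pytest.approx(1.0)
    assert c.intercept == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(c.collective, 1.0, atol=1e-9)
    c2 = collective_correction(2.0 * ref, ref)
    np.testing.assert_allclose(c2.collective, 2.0, atol=1e-9)
    np.testing.assert_allclose(c2.individual, 2.0, atol=1e-9)


def test_collective_correction_matches_ols_oracle(rng):
    test = rng.uniform(15, 40, size=12)
    ref = 1.1 * test + 3.0 + rng.normal(0, 1.0, size=12)
    c = collective_correction(ref, test)
    X = np.column_stack([test, np.ones(12)])
    beta = np.linalg.solve(X.T @ X, X.T @ ref)
    assert c.slope == pytest.approx(beta[0], abs=1e-9)
    assert c.intercept == pytest.approx(beta[1], abs=1e-9)
    np.testing.assert_allclose(c.collective, (beta[0] * test + beta[1]) / test,
                               atol=1e-9)


def test_individual_correction_ratio():
    assert individual_correction(20.0, 16.0) == pytest.approx(1.25)
    assert individual_correction(7.0, 7.0) == 1.0
    with pytest.raises(ValueError):
        individual_correction(20.0, 0.0)


def test_individual_correction_matches_bmc_exactly(law):
    mesh = block_mesh((4, 2, 2), element_size=3.0, bmd=420.0, law=law)
    target = 0.9 * mesh_bmc(mesh)
    f = individual_correction(target, mesh_bmc(mesh))
    corrected = mesh.scale_density(f)
    assert abs(mesh_bmc(corrected) - target) < 1e-9


# --- damage maps -----------------------------------------------------------

def test_damage_map_grid_and_bounds(small_model, law):
    from femfall import run_analysis
    u = criterion_displacement(small_model)
    hist = run_analysis(small_model, law, u, n_increments=6)
    dmap = damage_map(hist, small_model)
    assert np.allclose(dmap.spacing, 3.0)
    assert dmap.values.min() >= 0.0
    assert dmap.values.max() <= law.damage_max + 1e-12


def test_damage_map_zero_for_elastic_run(small_model, law):
    from femfall import run_analysis
    hist = run_analysis(small_model, law, 0.05, n_increments=1)  # tiny load
    dmap = damage_map(hist, small_model)
    assert np.all(dmap.values == 0.0)


def test_average_damage_maps_identity_and_disjoint():
    mask = np.zeros((12, 12, 12), np.uint8)
    mask[3:9, 3:9, 3:9] = 1
    mvol = DensityVolume(mask, spacing=3.0, unit="label")
    d1 = np.zeros((12, 12, 12))
    d1[4:6, 4:6, 4:6] = 0.8
    d2 = np.zeros_like(d1)
    d2[6:8, 6:8, 6:8] = 0.4
    m1 = DensityVolume(d1, spacing=3.0, unit="dimensionless")
    m2 = DensityVolume(d2, spacing=3.0, unit="dimensionless")
    same, used = average_damage_maps([m1, m1], [mvol, mvol], mvol)
    assert used == 2
    np.testing.assert_allclose(same.values, d1, atol=1e-6)
    mean, _ = average_damage_maps([m1, m2], [mvol, mvol], mvol)
    assert mean.values[4, 4, 4] == pytest.approx(0.4, abs=1e-6)
    assert mean.values[6, 6, 6] == pytest.approx(0.2, abs=1e-6)


# --- agreement statistics --------------------------------------------------

def test_agreement_perfect():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) * 1000
    s = agreement(x, x, bootstrap_reps=200, seed=0)
    assert s.r2 == pytest.approx(1.0)
    assert s.ccc == pytest.approx(1.0)
    assert s.see == pytest.approx(0.0, abs=1e-9)
    assert s.mae == pytest.approx(0.0, abs=1e-9)


def test_agreement_constant_shift_closed_form():
    """y = x + c keeps r2 = 1 but penalises CCC:
    CCC = 2 s2 / (2 s2 + c^2) with s2 the common variance."""
    x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    c = 15.0
    s = agreement(x, x + c, bootstrap_reps=200, seed=0)
    s2 = x.var(ddof=1)
    assert s.r2 == pytest.approx(1.0)
    assert s.mae == pytest.approx(c)
    assert s.ccc == pytest.approx(2 * s2 / (2 * s2 + c ** 2), abs=1e-12)


def test_agreement_five_pair_hand_oracle():
    """All statistics against direct formula evaluation on a 5-pair list."""
    x = np.array([2100.0, 2900.0, 3300.0, 4100.0, 5000.0])
    y = np.array([2400.0, 2700.0, 3600.0, 4000.0, 5300.0])
    s = agreement(x, y, bootstrap_reps=200, seed=1)
    n = 5
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    slope = sxy / sx ** 2
    intercept = y.mean() - slope * x.mean()
    pred = slope * x + intercept
    see = np.sqrt(((y - pred) ** 2).sum() / (n - 2))
    r2 = (sxy / (sx * sy)) ** 2
    ccc = 2 * sxy / (sx ** 2 + sy ** 2 + (x.mean() - y.mean()) ** 2)
    assert s.slope == pytest.approx(slope, abs=1e-9)
    assert s.intercept == pytest.approx(intercept, abs=1e-6)
    assert s.r2 == pytest.approx(r2, abs=1e-12)
    assert s.see == pytest.approx(see, abs=1e-9)
    assert s.cv_see == pytest.approx(see / y.mean(), abs=1e-12)
    assert s.mae == pytest.approx(np.abs(x - y).mean(), abs=1e-12)
    assert s.ccc == pytest.approx(ccc, abs=1e-12)


def test_bootstrap_reproducible_and_brackets_estimate():
    rng = np.random.default_rng(3)
    x = rng.uniform(2000, 5000, 20)
    y = 0.9 * x + rng.normal(0, 150, 20)
    a = agreement(x, y, bootstrap_reps=500, seed=42)
    b = agreement(x, y, bootstrap_reps=500, seed=42)
    assert a.r2_ci == b.r2_ci and a.ccc_ci == b.ccc_ci
    assert a.r2_ci[0] <= a.r2 <= a.r2_ci[1]
    assert a.slope_ci[0] <= a.slope <= a.slope_ci[1]


def test_agreement_input_validation():
    with pytest.raises(ValueError):
        agreement([1, 2], [1, 2], bootstrap_reps=200)
    with pytest.raises(ValueError):
        agreement([1, 2, 3], [1, 2, 3], bootstrap_reps=10)
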