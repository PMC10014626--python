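"""Coordinate-system recovery, surface distances and ROI volumes."""

from dataclasses import replace

import numpy as np
import pytest

from femfall import (DensityVolume, ROI_LABELS, detect_lt_peak, fit_head_sphere,
                     generate_phantom, implicit_axes, roi_volumes,
                     surface_distances)
from femfall.morphometry import _sphere_fit_points
from femfall.phantom import DegradationSpec, SurfaceMesh, degrade_to_reconstruction


# --- sphere fit ------------------------------------------------------------

def test_sphere_fit_voxelized_sphere():
    r, c = 24.0, np.array([30.0, 31.0, 32.0])
    grid = np.arange(64)
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r ** 2
    vol = DensityVolume(inside.astype(np.uint8), spacing=1.0, unit="label")
    center, radius, rms = fit_head_sphere(vol)
    assert np.abs(center - c).max() < 0.5
    assert abs(radius - r) < 0.5


def test_sphere_fit_exact_point_cloud(rng):
    c = np.array([5.0, -3.0, 11.0])
    r = 17.0
    d = rng.normal(size=(500, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    center, radius, rms = _sphere_fit_points(c + r * d)
    np.testing.assert_allclose(center, c, atol=1e-9)
    assert radius == pytest.approx(r, abs=1e-9)
    assert rms < 1e-9


def test_sphere_fit_degenerate_inputs():
    flat = np.zeros((100, 3))
    flat[:, :2] = np.random.default_rng(0).normal(size=(100, 2))
    with pytest.raises(ValueError):
        _sphere_fit_points(flat)
    empty = DensityVolume(np.zeros((5, 5, 5), np.uint8), spacing=1.0, unit="label")
    with pytest.raises(ValueError):
        fit_head_sphere(empty)


# --- LT peak ---------------------------------------------------------------

def test_lt_peak_matches_construction(noiseless_case):
    cs_true = noiseless_case.truth_cs
    peak = detect_lt_peak(noiseless_case.mask,
                          (np.zeros(3), np.array([0.0, 0.0, 1.0])))
    assert np.linalg.norm(peak - cs_true.lt_peak) < 2.0


def test_lt_peak_equivariant_under_rigid_motion(noiseless_case):
    """Rotating the volume by 90 degrees about z rotates the detected peak."""
    mask = noiseless_case.mask
    rotated = DensityVolume(np.rot90(mask.values, k=1, axes=(0, 1)).copy(),
                            mask.spacing, mask.origin, "label")
    def map_world(p):
        # np.rot90 on axes (0,1): new[i, j] = old[j, ny-1-i], so the old
        # index (a, b) lands at new index (ny-1-b, a)
        i = (p - mask.origin) / mask.spacing
        ny = mask.shape[1]
        return np.array([(ny - 1) - i[1], i[0], i[2]]) * mask.spacing + mask.origin

    axis_point = np.zeros(3)
    p0 = detect_lt_peak(mask, (axis_point, np.array([0.0, 0.0, 1.0])))
    p1 = detect_lt_peak(rotated, (map_world(axis_point),
                                  np.array([0.0, 0.0, 1.0])))
    assert np.linalg.norm(p1 - map_world(p0)) < 1e-6


def test_lt_peak_requires_protrusion():
    # plain cylinder: no LT boss anywhere
    grid = np.arange(50)
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    cyl = ((X - 25) ** 2 + (Y - 25) ** 2 <= 20 ** 2)
    vol = DensityVolume(cyl.astype(np.uint8), spacing=1.0, unit="label")
    with pytest.raises(ValueError):
        detect_lt_peak(vol, (np.array([25.0, 25.0, 0.0]),
                             np.array([0.0, 0.0, 1.0])),
                       medial_hint=np.array([1.0, 0.0, 0.0]))


# --- implicit axes ---------------------------------------------------------

def test_implicit_axes_recovers_angle(noiseless_case, small_spec):
    cs = implicit_axes(noiseless_case.mask)
    assert cs.neck_shaft_angle_deg() == pytest.approx(
        small_spec.neck_shaft_angle, abs=2.0)
    assert cs.axis_gap_mm < 0.5


def test_implicit_axes_head_consistent_with_sphere_fit(noiseless_case):
    cs = implicit_axes(noiseless_case.mask)
    head_region = noiseless_case.mask.values == ROI_LABELS["head"]
    center, radius, _ = fit_head_sphere(noiseless_case.mask, head_region)
    assert np.linalg.norm(cs.head_center - center) < 1.0


def test_angle_recovery_correlates_across_cohort(small_spec):
    """Configured vs recovered neck-shaft angles over a cohort of varied
    phantoms: r^2 > 0.95 (coarser grid keeps this cheap)."""
    angles = np.linspace(112.0, 142.0, 10)
    recovered = []
    for i, a in enumerate(angles):
        spec = replace(small_spec, neck_shaft_angle=float(a), noise_sd=0.0,
                       voxel_spacing=2.0, seed=100 + i)
        cs = implicit_axes(generate_phantom(spec).mask)
        recovered.append(cs.neck_shaft_angle_deg())
    r = np.corrcoef(angles, recovered)[0, 1]
    assert r ** 2 > 0.95


# --- surface distances -----------------------------------------------------

def _sphere_mask(r, n=40, spacing=1.0):
    g = (np.arange(n) - n / 2) * spacing
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    inside = X ** 2 + Y ** 2 + Z ** 2 <= r ** 2
    return DensityVolume(inside.astype(np.uint8), spacing=spacing,
                         origin=(-n / 2 * spacing,) * 3, unit="label")


def test_surface_distance_self_is_zero():
    from skimage import measure
    mask = _sphere_mask(12.0)
    verts, faces, _, _ = measure.marching_cubes(
        (mask.values > 0).astype(float), 0.5, spacing=tuple(mask.spacing))
    mesh = SurfaceMesh(verts + mask.origin, faces)
    rep = surface_distances(mesh, mask)
    assert rep.mean_mm < 0.05


def test_surface_distance_concentric_spheres():
    inner = _sphere_mask(10.0)
    outer = _sphere_mask(11.0)
    from skimage import measure
    verts, faces, _, _ = measure.marching_cubes(
        (outer.values > 0).astype(float), 0.5, spacing=tuple(outer.spacing))
    mesh = SurfaceMesh(verts + outer.origin, faces)
    rep = surface_distances(mesh, inner)
    assert rep.mean_mm == pytest.approx(1.0, abs=0.35)  # voxelisation error


def test_surface_distance_detects_misregistration():
    mask = _sphere_mask(10.0)
    from skimage import measure
    verts, faces, _, _ = measure.marching_cubes(
        (mask.values > 0).astype(float), 0.5, spacing=tuple(mask.spacing))
    mesh = SurfaceMesh(verts + mask.origin + np.array([5.0, 0, 0]), faces)
    rep = surface_distances(mesh, mask)
    assert 2.0 < rep.mean_mm < 5.5  # mean offset approaches the 5 mm shift


def test_surface_distance_per_roi_on_phantom(noiseless_case):
    d = DegradationSpec(bmd_offset=-64.0, smoothing_fwhm=3.0,
                        volume_scale=0.95, surface_noise_amplitude=1.0, seed=2)
    _, mesh = degrade_to_reconstruction(noiseless_case, d)
    rep = surface_distances(mesh, noiseless_case.mask, ROI_LABELS)
    assert rep.mean_mm < 3.0               # shrunk+noisy surface stays close
    assert (rep.per_roi["max_mm"] >= rep.per_roi["mean_mm"] - 1e-12).all()
    assert np.all(rep.node_distances >= 0)


# --- ROI volumes -----------------------------------------------------------

def test_roi_volume_arithmetic():
    arr = np.zeros((20, 20, 20), np.uint8)
    arr[:10, :10, :10] = 1  # 1000 voxels at 1 mm = 1 cm3
    vol = DensityVolume(arr, spacing=1.0, unit="label")
    out = roi_volumes(vol, {"cube": 1})
    assert out["cube"] == pytest.approx(1.0)


def test_roi_volume_tracks_degradation_scale(noiseless_case):
    d = DegradationSpec(bmd_offset=0.0, smoothing_fwhm=0.0, volume_scale=0.9,
                        surface_noise_amplitude=0.0)
    vol, _ = degrade_to_reconstruction(noiseless_case, d)
    deg_mask = DensityVolume((vol.values > 0).astype(np.uint8), vol.spacing,
                             vol.origin, "label")
    v_deg = roi_volumes(deg_mask, {"bone": 1})["bone"]
    truth_mask = DensityVolume((noiseless_case.mask.values > 0).astype(np.uint8),
                               vol.spacing, vol.origin, "label")
    v_truth = roi_volumes(truth_mask, {"bone": 1})["bone"]
    assert v_deg / v_truth == pytest.approx(0.9, abs=0.02)


def test_empty_roi_warns():
    vol = DensityVolume(np.ones((4, 4, 4), np.uint8), spacing=1.0, unit="label")
    with pytest.warns(UserWarning):
        out = roi_volumes(vol, {"missing": 9})
    assert out["missing"] == 0.0
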