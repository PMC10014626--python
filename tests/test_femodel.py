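"""Side-fall pose, distal cut, BMD mapping and mesh construction."""

import numpy as np
import pytest

from femfall import (DensityVolume, build_sidefall_model, distal_cut,
                     equivalent_sphere_radius, implicit_axes,
                     map_bmd_to_elements, sidefall_transform)
from femfall.geometry import RigidTransform


def test_sidefall_pose_angles(noiseless_case):
    cs = noiseless_case.truth_cs
    T = sidefall_transform(cs)
    posed = cs.transformed(T)
    elevation = np.degrees(np.arcsin(abs(posed.shaft_axis_dir[2])))
    assert elevation == pytest.approx(10.0, abs=0.1)
    normal = np.cross(posed.shaft_axis_dir, posed.neck_axis_dir)
    normal /= np.linalg.norm(normal)
    assert abs(np.degrees(np.arcsin(abs(normal[2])))) < 0.1
    # head medial-superior of the intersection
    rel = posed.head_center - posed.axes_intersection
    assert rel[2] > 0


def test_sidefall_transform_is_rigid(noiseless_case, rng):
    T = sidefall_transform(noiseless_case.truth_cs)
    pts = rng.normal(scale=60, size=(30, 3))
    d0 = np.linalg.norm(pts[1:] - pts[:-1], axis=1)
    d1 = np.linalg.norm(np.diff(T.apply(pts), axis=0), axis=1)
    np.testing.assert_allclose(d0, d1, atol=1e-9)


def test_sidefall_pose_idempotent(noiseless_case):
    cs = noiseless_case.truth_cs
    posed = cs.transformed(sidefall_transform(cs))
    T2 = sidefall_transform(posed)
    assert T2.rotation_angle_deg() < 0.01
    assert np.abs(T2.translation).max() < 0.01


def test_distal_cut_geometry(noiseless_case):
    cs = noiseless_case.truth_cs
    cut = distal_cut(noiseless_case.mask, cs)
    pts = cut.index_to_world(np.argwhere(cut.values > 0))
    t = (pts - cs.lt_peak) @ cs.shaft_axis_dir
    # nothing more distal than one head radius below the LT peak (within a voxel)
    assert t.min() >= -cs.head_radius - 1.5
    assert cut.values.sum() < (noiseless_case.mask.values > 0).sum()


def test_distal_cut_noop_when_plane_below_bone(noiseless_case):
    import copy
    cs = noiseless_case.truth_cs
    cs2 = copy.deepcopy(cs)
    cs2.lt_peak = cs.lt_peak - 500.0 * cs.shaft_axis_dir  # plane below everything
    cut = distal_cut(noiseless_case.mask, cs2)
    assert cut.values.sum() == (noiseless_case.mask.values > 0).sum()


def test_distal_cut_cannot_remove_everything(noiseless_case):
    import copy
    cs2 = copy.deepcopy(noiseless_case.truth_cs)
    cs2.lt_peak = cs2.lt_peak + 500.0 * cs2.shaft_axis_dir
    with pytest.raises(ValueError):
        distal_cut(noiseless_case.mask, cs2)


def test_equivalent_sphere_radius_value():
    # independent computation: r = (3 V / 4 pi)^(1/3) with V = 27 mm^3
    expected = (3.0 * 27.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    assert expected == pytest.approx(1.861, abs=5e-4)
    assert equivalent_sphere_radius(3.0) == pytest.approx(expected, rel=1e-12)


def test_bmd_mapping_uniform_volume():
    vol = DensityVolume(np.full((40, 40, 40), 400.0), spacing=1.0, unit="mg/cm3")
    centers = np.array([[20.0, 20.0, 20.0], [10.0, 15.0, 25.0]])
    out = map_bmd_to_elements(vol, centers, transform=None, element_size=3.0)
    np.testing.assert_allclose(out, 400.0, atol=1e-9)


def test_bmd_mapping_matches_bruteforce_oracle(rng):
    vol = DensityVolume(rng.uniform(0, 1000, size=(30, 30, 30)), spacing=1.0,
                        unit="mg/cm3")
    mask = DensityVolume((rng.uniform(size=(30, 30, 30)) > 0.4).astype(np.uint8),
                         spacing=1.0, unit="label")
    centers = rng.uniform(8, 22, size=(5, 3))
    out = map_bmd_to_elements(vol, centers, transform=None, element_size=3.0)
    out_m = map_bmd_to_elements(vol, centers, transform=None, element_size=3.0,
                                mask=mask)
    r = equivalent_sphere_radius(3.0)
    coords = np.argwhere(np.ones(vol.shape)) * 1.0  # voxel centres, world==index
    for c, got, got_m in zip(centers, out, out_m):
        inside = np.linalg.norm(coords - c, axis=1) <= r
        assert got == pytest.approx(vol.values.ravel()[inside].mean(), abs=1e-6)
        sel = inside & (mask.values.ravel() > 0)
        assert got_m == pytest.approx(vol.values.ravel()[sel].mean(), abs=1e-6)


def test_mesh_structure_and_node_sets(small_model):
    mesh = small_model
    assert mesh.n_nodes > mesh.n_elements          # voxel-mesh topology
    for name in ("distal_fixed", "gt_cap_base", "head_cap_top"):
        assert len(mesh.node_sets[name]) > 0, name
    assert mesh.driving_node == mesh.n_nodes - 1
    assert mesh.driving_node not in np.concatenate(list(mesh.node_sets.values()))
    assert np.all((mesh.bvtv >= 0) & (mesh.bvtv <= 1))
    assert mesh.head_gt_distance > 0


def test_caps_touch_bone_and_bone_untagged(small_model):
    mesh = small_model
    bone_nodes = set(np.unique(mesh.elements[mesh.is_bone]))
    cap_elems = mesh.elements[~mesh.is_bone]
    shared = [len(bone_nodes.intersection(e)) >= 4 for e in cap_elems]
    assert any(shared)                              # at least one shared face
    assert np.all(mesh.bvtv[~mesh.is_bone] == 0.0)
    # embedding never overwrites bone cells
    cells_bone = {tuple(c) for c in mesh.element_index[mesh.is_bone]}
    cells_cap = {tuple(c) for c in mesh.element_index[~mesh.is_bone]}
    assert not cells_bone & cells_cap


def test_cap_layer_validation(noiseless_case, law):
    cs = implicit_axes(noiseless_case.mask)
    with pytest.raises(ValueError):
        build_sidefall_model(noiseless_case.truth_bmd, noiseless_case.mask,
                             cs, law, cap_layers=6)


def test_mesh_mass_conservation(noiseless_case, law, small_model):
    """Element BMD x element volume matches the image BMC inside the model's
    cut region (the same posed-frame transverse plane the builder uses)."""
    from femfall import implicit_axes, mesh_bmc
    case = noiseless_case
    cs = implicit_axes(case.mask)
    T = sidefall_transform(cs)
    csp = cs.transformed(T)
    cut_x = (csp.lt_peak - csp.head_radius * csp.shaft_axis_dir)[0]
    idx = np.argwhere(case.mask.values > 0)
    posed = T.apply(case.mask.index_to_world(idx))
    keep = idx[posed[:, 0] >= cut_x]
    img_bmc = (case.truth_bmd.values[tuple(keep.T)].sum()
               * case.truth_bmd.voxel_volume_mm3 / 1e6)
    model_bmc = mesh_bmc(small_model)
    assert abs(model_bmc - img_bmc) / img_bmc < 0.03


def test_mesh_text_exports(tmp_path, small_model):
    inp = tmp_path / "model.inp"
    vtk = tmp_path / "model.vtk"
    small_model.write_inp(inp)
    small_model.write_vtk(vtk)
    text = inp.read_text()
    assert "*NODE" in text and "C3D8" in text and "NSET=distal_fixed" in text
    vtext = vtk.read_text()
    assert f"POINTS {small_model.n_nodes}" in vtext
    assert "CELL_TYPES" in vtext
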