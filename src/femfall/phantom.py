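"""Synthetic paired proximal-femur phantoms with known ground truth.

The generator builds a constructive-solid-geometry femur — head sphere, neck
frustum, shaft cylinder, and two ellipsoidal bosses for the greater and
lesser trochanter — voxelised with 3x3x3 supersampling so surface voxels
carry partial-volume densities.  A cortical shell of configurable thickness
surrounds the trabecular interior.  Six calibration-insert cylinders run
parallel to the slice axis below the femur, and the per-slice HU law varies
sinusoidally along the scan to emulate tube-current modulation.

A degradation operator turns the ground-truth density volume into a
"reconstruction-like" counterpart: smoother density, a systematic negative
BMD offset, a slightly smaller bone volume and a perturbed surface mesh —
the summary discrepancies reported for shape/density model reconstructions,
not their mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .morphometry import ImplicitCoordinateSystem
from .volume import DensityVolume

__all__ = [
    "PhantomSpec", "PhantomCase", "DegradationSpec", "InsertLayout", "SurfaceMesh",
    "CohortCase", "generate_phantom", "degrade_to_reconstruction", "make_cohort",
    "ROI_LABELS",
]

ROI_LABELS = {
    "head": 1,
    "neck": 2,
    "greater_trochanter": 3,
    "lesser_trochanter": 4,
    "shaft_remnant": 5,
}

_INSERT_RADIUS_MM = 7.0


@dataclass(frozen=True)
class PhantomSpec:
    """Constructive parameters of one phantom femur (lengths in mm, densities
    in mg/cm3, noise in HU)."""

    head_radius: float = 27.0
    neck_radius: float = 16.0
    neck_length: float = 40.0
    neck_shaft_angle: float = 125.0
    shaft_radius: float = 23.0
    shaft_length: float = 110.0
    cortical_thickness: float = 3.0
    trabecular_bmd: float = 250.0
    cortical_bmd: float = 900.0
    voxel_spacing: float = 1.5
    insert_densities: tuple = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        lengths = (self.head_radius, self.neck_radius, self.neck_length,
                   self.shaft_radius, self.shaft_length, self.cortical_thickness,
                   self.voxel_spacing)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if not 90.0 < self.neck_shaft_angle < 180.0:
            raise ValueError("neck_shaft_angle must be in (90, 180) degrees")
        if not self.cortical_bmd > self.trabecular_bmd >= 0:
            raise ValueError("need cortical_bmd > trabecular_bmd >= 0")
        dens = np.asarray(self.insert_densities, float)
        if dens.shape != (6,) or np.any(np.diff(dens) <= 0):
            raise ValueError("insert_densities must be 6 strictly increasing values")


@dataclass(frozen=True)
class DegradationSpec:
    """Summary degradation applied to the truth volume to emulate a
    reconstruction-like image."""

    bmd_offset: float = -64.0       # mg/cm3; negative = underestimation
    smoothing_fwhm: float = 4.0     # mm
    volume_scale: float = 0.93      # fraction of truth bone volume
    surface_noise_amplitude: float = 1.0  # mm
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.volume_scale <= 1.0:
            raise ValueError("volume_scale must be in (0, 1]")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")


@dataclass
class InsertLayout:
    """In-plane insert centres (mm, fixed over slices), radius, and per-slice
    visibility flags."""

    centers_xy: np.ndarray          # (6, 2) world mm
    radius: float
    valid: np.ndarray               # (n_slices,) bool
    densities: np.ndarray = None    # (6,) reference densities mg/cm3


@dataclass
class SurfaceMesh:
    vertices: np.ndarray            # (n, 3) world mm
    faces: np.ndarray               # (m, 3) int
    metadata: dict = field(default_factory=dict)

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def write(self, path):
        self.to_trimesh().export(str(path))


@dataclass
class PhantomCase:
    hu_volume: DensityVolume
    truth_bmd: DensityVolume
    mask: DensityVolume             # ROI label volume (uint8)
    truth_cs: ImplicitCoordinateSystem
    insert_layout: InsertLayout
    hu_law: np.ndarray              # (n_slices, 2): HU = a * BMD + b
    spec: PhantomSpec
    case_id: str = "case"


# ---------------------------------------------------------------------------
# constructive geometry

class _FemurGeometry:
    """Primitive signed distances and labels for one spec (world mm)."""

    def __init__(self, spec: PhantomSpec):
        s = spec
        self.spec = s
        alpha = np.radians(180.0 - s.neck_shaft_angle)
        self.shaft_dir = np.array([0.0, 0.0, 1.0])        # proximal
        self.junction = np.array([0.0, 0.0, s.shaft_length])
        self.neck_dir = np.array([np.sin(alpha), 0.0, np.cos(alpha)])
        self.head_center = self.junction + (s.neck_length + 0.8 * s.head_radius) * self.neck_dir
        # greater trochanter: lateral boss near the shaft top
        self.gt_center = np.array([-0.5 * s.shaft_radius, 0.0, s.shaft_length + 2.0])
        self.gt_semi = np.array([0.9, 0.65, 1.2]) * s.shaft_radius
        # lesser trochanter: medial-posterior boss below the neck base
        phi = np.radians(-25.0)
        self.lt_dirm = np.array([np.cos(phi), np.sin(phi), 0.0])
        self.lt_center = 0.8 * s.shaft_radius * self.lt_dirm + np.array(
            [0.0, 0.0, s.shaft_length - 1.2 * s.head_radius])
        self.lt_semi = np.array([0.65 * s.shaft_radius, 0.45 * s.shaft_radius,
                                 0.7 * s.shaft_radius])
        # neck frustum flares from 1.25 r_neck at the shaft to r_neck at the head
        self.neck_r0 = 1.25 * s.neck_radius
        self.neck_r1 = s.neck_radius
        self.neck_t0 = -0.3 * s.shaft_radius
        self.neck_t1 = s.neck_length + 0.4 * s.head_radius

    # each _sdf_* takes meshgrid arrays X, Y (2D) and scalar z, returns 2D sdf
    def _sdf_head(self, X, Y, z):
        c = self.head_center
        return np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (z - c[2]) ** 2) - self.spec.head_radius

    def _sdf_shaft(self, X, Y, z):
        dxy = np.sqrt(X ** 2 + Y ** 2) - self.spec.shaft_radius
        dz = max(-z, z - self.spec.shaft_length)
        return np.maximum(dxy, dz)

    def _sdf_neck(self, X, Y, z):
        J, d = self.junction, self.neck_dir
        px, py, pz = X - J[0], Y - J[1], z - J[2]
        t = px * d[0] + py * d[1] + pz * d[2]
        rx, ry, rz = px - t * d[0], py - t * d[1], pz - t * d[2]
        rho = np.sqrt(rx ** 2 + ry ** 2 + rz ** 2)
        frac = np.clip((t - 0.0) / max(self.spec.neck_length, 1e-9), 0.0, 1.0)
        radius = self.neck_r0 + (self.neck_r1 - self.neck_r0) * frac
        return np.maximum(rho - radius, np.maximum(self.neck_t0 - t, t - self.neck_t1))

    @staticmethod
    def _sdf_ellipsoid(X, Y, z, center, semi):
        k = np.sqrt(((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2
                    + ((z - center[2]) / semi[2]) ** 2)
        return (k - 1.0) * semi.min()

    def sdf_and_label(self, X, Y, z):
        """Union signed distance and ROI label (0 outside) at one z plane."""
        d_head = self._sdf_head(X, Y, z)
        d_neck = self._sdf_neck(X, Y, z)
        d_shaft = self._sdf_shaft(X, Y, z)
        d_gt = self._sdf_ellipsoid(X, Y, z, self.gt_center, self.gt_semi)
        d_lt = self._sdf_ellipsoid(X, Y, z, self.lt_center, self.lt_semi)
        sdf = np.minimum.reduce([d_head, d_neck, d_shaft, d_gt, d_lt])
        label = np.zeros(X.shape, np.uint8)
        inside = sdf < 0
        label[inside] = ROI_LABELS["shaft_remnant"]
        label[inside & (d_lt < 0)] = ROI_LABELS["lesser_trochanter"]
        label[inside & (d_gt < 0)] = ROI_LABELS["greater_trochanter"]
        label[inside & (d_neck < 0)] = ROI_LABELS["neck"]
        label[inside & (d_head < 0)] = ROI_LABELS["head"]
        return sdf, label

    def bounds(self):
        lo = np.minimum.reduce([
            self.head_center - self.spec.head_radius,
            np.array([-self.spec.shaft_radius, -self.spec.shaft_radius, 0.0]),
            self.gt_center - self.gt_semi,
            self.lt_center - self.lt_semi,
        ])
        hi = np.maximum.reduce([
            self.head_center + self.spec.head_radius,
            np.array([self.spec.shaft_radius, self.spec.shaft_radius, self.spec.shaft_length]),
            self.gt_center + self.gt_semi,
            self.lt_center + self.lt_semi,
        ])
        return lo, hi


def _hu_law(z_mm: np.ndarray) -> np.ndarray:
    """Smooth per-slice linear HU = a(z) * BMD + b(z); emulates tube-current
    modulation along the scan."""
    a = 1.25 * (1.0 + 0.05 * np.sin(2 * np.pi * z_mm / 60.0))
    b = -5.0 + 10.0 * np.sin(2 * np.pi * z_mm / 90.0 + 1.0)
    return np.stack([a, b], axis=1)


def generate_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Voxelise the constructive femur plus calibration inserts.

    Partial-volume densities come from 3x3x3 supersampling of each voxel; a
    voxel belongs to the bone mask when at least half its subsamples fall
    inside the union geometry, and its ROI label is the majority label of
    those subsamples.
    """
    geo = _FemurGeometry(spec)
    h = spec.voxel_spacing
    lo, hi = geo.bounds()
    margin = 6.0
    # insert row below the femur, spanning every slice
    y_ins = lo[1] - 2.0 * _INSERT_RADIUS_MM - 8.0
    pitch = 2.0 * _INSERT_RADIUS_MM + 4.0  # disjoint discs regardless of size
    x_centers = lo[0] + _INSERT_RADIUS_MM + pitch * np.arange(6)
    insert_xy = np.stack([x_centers, np.full(6, y_ins)], axis=1)

    grid_lo = np.array([min(lo[0], x_centers[0] - _INSERT_RADIUS_MM) - margin,
                        y_ins - _INSERT_RADIUS_MM - margin,
                        lo[2] - margin])
    grid_hi = np.array([max(hi[0], x_centers[-1] + _INSERT_RADIUS_MM) + margin,
                        hi[1] + margin, hi[2] + margin])
    shape = np.ceil((grid_hi - grid_lo) / h).astype(int)
    if np.any(shape > 512):
        raise ValueError("spec produces a femur larger than the supported grid")
    origin = grid_lo
    nx, ny, nz = (int(n) for n in shape)

    xs = origin[0] + h * np.arange(nx)
    ys = origin[1] + h * np.arange(ny)
    zs = origin[2] + h * np.arange(nz)
    sub = (np.arange(3) - 1.0) / 3.0 * h  # subsample offsets within a voxel
    Xs = xs[:, None] + np.zeros((1, ny))
    Ys = ys[None, :] + np.zeros((nx, 1))

    dens = np.asarray(spec.insert_densities, float)
    bmd = np.zeros((nx, ny, nz))
    occ = np.zeros((nx, ny, nz))
    votes = np.zeros((nx, ny, nz, 6), np.uint16)  # label histogram, 0..5

    insert_density_plane = np.zeros((nx, ny))
    insert_mask_plane = np.zeros((nx, ny), bool)
    for k, (cx, cy) in enumerate(insert_xy):
        sel = np.zeros((nx, ny), float)
        for du in sub:
            for dv in sub:
                sel += ((Xs + du - cx) ** 2 + (Ys + dv - cy) ** 2
                        <= _INSERT_RADIUS_MM ** 2)
        frac = sel / 9.0
        insert_density_plane += frac * dens[k]
        insert_mask_plane |= frac > 0.5

    for iz in range(nz):
        acc_bmd = np.zeros((nx, ny))
        acc_occ = np.zeros((nx, ny))
        acc_votes = np.zeros((nx, ny, 6), np.uint16)
        for dw in sub:
            z = zs[iz] + dw
            for du in sub:
                for dv in sub:
                    sdf, label = geo.sdf_and_label(Xs + du, Ys + dv, z)
                    inside = sdf < 0
                    cortical = inside & (sdf > -spec.cortical_thickness)
                    rho = np.where(cortical, spec.cortical_bmd,
                                   np.where(inside, spec.trabecular_bmd, 0.0))
                    acc_bmd += rho
                    acc_occ += inside
                    for lab in range(1, 6):
                        acc_votes[:, :, lab] += (label == lab)
        bmd[:, :, iz] = acc_bmd / 27.0 + insert_density_plane
        occ[:, :, iz] = acc_occ / 27.0
        votes[:, :, iz, :] = acc_votes

    mask = np.zeros((nx, ny, nz), np.uint8)
    in_bone = occ >= 0.5
    mask[in_bone] = np.argmax(votes[in_bone][:, 1:], axis=1) + 1

    hu_law = _hu_law(zs)
    hu = bmd * hu_law[None, None, :, 0] + hu_law[None, None, :, 1]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = in_bone | insert_mask_plane[:, :, None]
        hu[noisy] += rng.normal(0.0, spec.noise_sd, int(noisy.sum()))

    spacing = np.full(3, h)
    truth_bmd = DensityVolume(bmd, spacing, origin, unit="mg/cm3")
    hu_volume = DensityVolume(hu, spacing, origin, unit="HU")
    mask_vol = DensityVolume(mask, spacing, origin, unit="label")

    lt_peak = _lt_peak_from_labels(mask_vol)
    neck_dir = geo.neck_dir / np.linalg.norm(geo.neck_dir)
    cs = ImplicitCoordinateSystem(
        head_center=geo.head_center, head_radius=spec.head_radius,
        neck_axis_dir=neck_dir, neck_axis_point=geo.head_center,
        shaft_axis_dir=geo.shaft_dir, shaft_axis_point=np.array([0.0, 0.0, 0.0]),
        axes_intersection=geo.junction,
        distal_point=np.array([0.0, 0.0, 0.0]), lt_peak=lt_peak)

    layout = InsertLayout(centers_xy=insert_xy, radius=_INSERT_RADIUS_MM,
                          valid=np.ones(nz, bool), densities=dens.copy())
    return PhantomCase(hu_volume=hu_volume, truth_bmd=truth_bmd, mask=mask_vol,
                       truth_cs=cs, insert_layout=layout, hu_law=hu_law,
                       spec=spec, case_id=case_id)


def _lt_peak_from_labels(mask: DensityVolume) -> np.ndarray:
    """Surface voxel of the LT label farthest from the shaft (z) axis."""
    lab = mask.values == ROI_LABELS["lesser_trochanter"]
    if not lab.any():
        raise ValueError("phantom has no lesser-trochanter label")
    eroded = ndimage.binary_erosion(mask.values > 0)
    surf = lab & ~eroded
    if not surf.any():
        surf = lab
    idx = np.argwhere(surf)
    pts = mask.index_to_world(idx)
    r = np.hypot(pts[:, 0], pts[:, 1])
    return pts[int(np.argmax(r))]


# ---------------------------------------------------------------------------
# degradation

def degrade_to_reconstruction(case: PhantomCase, d: DegradationSpec):
    """Emulate a reconstruction-like image: shrink the bone isotropically by
    volume_scale, smooth the density field, shift the mean BMD by bmd_offset,
    and return the degraded density volume plus a surface mesh whose vertices
    carry correlated noise of the requested amplitude.

    Returns ``(DensityVolume in mg/cm3, SurfaceMesh)``.  The degraded volume is
    already in density units — reconstructions have no HU stage.
    """
    mask0 = case.mask.values > 0
    bone_bmd = np.where(mask0, case.truth_bmd.values, 0.0)
    mean_truth = float(bone_bmd[mask0].mean())
    h = case.truth_bmd.spacing

    lin = d.volume_scale ** (1.0 / 3.0)
    if d.volume_scale < 1.0:
        centroid_idx = np.argwhere(mask0).mean(axis=0)
        coords = np.meshgrid(*[np.arange(n) for n in mask0.shape], indexing="ij")
        sample = [centroid_idx[i] + (coords[i] - centroid_idx[i]) / lin for i in range(3)]
        occ = ndimage.map_coordinates(mask0.astype(float), sample, order=1)
        bmd = ndimage.map_coordinates(bone_bmd, sample, order=1)
        new_mask = occ >= 0.5
    else:
        occ = mask0.astype(float)
        bmd = bone_bmd.copy()
        new_mask = mask0.copy()
    if not new_mask.any():
        raise ValueError("degradation emptied the bone mask")

    if d.smoothing_fwhm > 0:
        sigma = d.smoothing_fwhm / 2.3548 / h
        bmd = ndimage.gaussian_filter(bmd, sigma)

    out = np.where(new_mask, bmd, 0.0)
    mean_cur = float(out[new_mask].mean())
    out[new_mask] += (mean_truth + d.bmd_offset) - mean_cur
    np.clip(out, 0.0, None, out=out)

    verts, faces, normals, _ = measure.marching_cubes(
        occ.astype(float), 0.5, spacing=tuple(h))
    verts = verts + case.truth_bmd.origin
    if d.surface_noise_amplitude > 0:
        rng = np.random.default_rng(d.seed)
        noise = rng.normal(0.0, d.surface_noise_amplitude, len(verts))
        noise = _smooth_vertex_field(noise, faces, rounds=3)
        # re-normalise so the applied amplitude matches the request
        sd = noise.std()
        if sd > 0:
            noise *= d.surface_noise_amplitude / sd
        verts = verts + noise[:, None] * normals

    mesh = SurfaceMesh(verts, faces.astype(np.int64),
                       metadata={"case_id": case.case_id,
                                 "correspondence": "marching-cubes vertex order",
                                 "degradation": d})
    vol = DensityVolume(out, case.truth_bmd.spacing.copy(),
                        case.truth_bmd.origin.copy(), unit="mg/cm3")
    return vol, mesh


def _smooth_vertex_field(field: np.ndarray, faces: np.ndarray, rounds: int = 3):
    """Average a per-vertex scalar over mesh neighbours a few times."""
    n = len(field)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2],
                        faces[:, 1], faces[:, 2], faces[:, 0]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0],
                        faces[:, 0], faces[:, 1], faces[:, 2]])
    out = field.astype(float).copy()
    for _ in range(rounds):
        acc = np.bincount(i, weights=out[j], minlength=n)
        cnt = np.bincount(i, minlength=n)
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), out)
    return out


# ---------------------------------------------------------------------------
# cohorts

_PERTURBED_FIELDS = ("head_radius", "neck_radius", "neck_length", "shaft_radius",
                     "shaft_length", "trabecular_bmd", "cortical_bmd")


@dataclass
class CohortCase:
    case_id: str
    spec: PhantomSpec
    case: PhantomCase
    degraded_bmd: DensityVolume
    degraded_mesh: SurfaceMesh


def make_cohort(n: int, base: PhantomSpec, variability: float = 0.06,
                seed: int = 0, degradation: DegradationSpec | None = None):
    """Generate ``n`` paired cases with log-normal size/density perturbations.

    ``variability`` is the fractional SD applied multiplicatively to lengths
    and densities; the neck-shaft angle is perturbed additively with SD
    ``variability * 40`` degrees, clipped to (100, 160).  Per-case seeds derive
    deterministically from ``seed``.
    """
    if n < 2:
        raise ValueError("cohorts need n >= 2 (regression stages)")
    rng = np.random.default_rng(seed)
    degradation = degradation or DegradationSpec()
    cohort = []
    for i in range(n):
        changes = {}
        for name in _PERTURBED_FIELDS:
            changes[name] = getattr(base, name) * float(
                np.exp(variability * rng.standard_normal()))
        if changes["cortical_bmd"] <= changes["trabecular_bmd"]:
            changes["cortical_bmd"] = changes["trabecular_bmd"] * 1.5
        angle = base.neck_shaft_angle + variability * 40.0 * rng.standard_normal()
        changes["neck_shaft_angle"] = float(np.clip(angle, 100.0, 160.0))
        changes["seed"] = int(rng.integers(0, 2 ** 31 - 1))
        spec_i = replace(base, **changes)
        case = generate_phantom(spec_i, case_id=f"case{i:03d}")
        deg_seed = int(rng.integers(0, 2 ** 31 - 1))
        deg = replace(degradation, seed=deg_seed)
        dv, mesh = degrade_to_reconstruction(case, deg)
        cohort.append(CohortCase(case_id=case.case_id, spec=spec_i, case=case,
                                 degraded_bmd=dv, degraded_mesh=mesh))
    return cohort


def cohort_manifest(cohort) -> pd.DataFrame:
    rows = []
    for cc in cohort:
        row = {"case_id": cc.case_id, "seed": cc.spec.seed}
        for name in _PERTURBED_FIELDS + ("neck_shaft_angle", "cortical_thickness",
                                         "voxel_spacing", "noise_sd"):
            row[name] = getattr(cc.spec, name)
        rows.append(row)
    return pd.DataFrame(rows)


def truth_bone_bmc(case: PhantomCase) -> float:
    """Volume integral of the truth density over the femur (grams).

    Integrates every voxel outside the insert columns, so partial-volume
    surface voxels contribute their fractional mass.
    """
    v = case.truth_bmd
    xs = v.axis_coords(0)[:, None]
    ys = v.axis_coords(1)[None, :]
    in_insert = np.zeros((v.shape[0], v.shape[1]), bool)
    for cx, cy in case.insert_layout.centers_xy:
        in_insert |= (xs - cx) ** 2 + (ys - cy) ** 2 <= (case.insert_layout.radius + 2.0) ** 2
    total = float(v.values[~in_insert, :].sum())
    return total * v.voxel_volume_mm3 / 1e6  # mg/cm3 * mm3 -> g


def reference_bmc(spec: PhantomSpec, spacing: float = 0.75) -> float:
    """Fine-grid quadrature of the constructive density field (grams).

    Independent of the production voxelisation: re-evaluates the geometry at a
    finer spacing so it can serve as a conservation oracle.
    """
    fine = replace(spec, voxel_spacing=spacing, noise_sd=0.0)
    return truth_bone_bmc(generate_phantom(fine))
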