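"""Implicit coordinate system of the proximal femur and geometric agreement.

The coordinate system consists of a neck axis and a shaft axis, estimated
iteratively until they (nearly) intersect, plus the femoral head sphere and
the lesser-trochanter (LT) peak.  Everything operates on label or binary
masks in the package's world convention (0-based indices, world = origin +
index * spacing, mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .geometry import closest_points_between_lines
from .volume import DensityVolume

__all__ = [
    "ImplicitCoordinateSystem", "SurfaceDistanceReport",
    "fit_head_sphere", "detect_lt_peak", "implicit_axes",
    "surface_distances", "roi_volumes",
]


@dataclass
class ImplicitCoordinateSystem:
    """Neck axis, shaft axis, head sphere, axes intersection and LT peak.

    Axis directions are unit vectors; ``shaft_axis_dir`` points proximally
    (distal cut -> femoral head side) and ``neck_axis_dir`` points from the
    axes intersection toward the head.
    """

    head_center: np.ndarray
    head_radius: float
    neck_axis_dir: np.ndarray
    neck_axis_point: np.ndarray
    shaft_axis_dir: np.ndarray
    shaft_axis_point: np.ndarray
    axes_intersection: np.ndarray
    distal_point: np.ndarray
    lt_peak: np.ndarray
    axis_gap_mm: float = 0.0
    head_fit_rms: float = 0.0

    def __post_init__(self):
        for name in ("head_center", "neck_axis_dir", "neck_axis_point",
                     "shaft_axis_dir", "shaft_axis_point", "axes_intersection",
                     "distal_point", "lt_peak"):
            setattr(self, name, np.asarray(getattr(self, name), float).reshape(3))
        for name in ("neck_axis_dir", "shaft_axis_dir"):
            v = getattr(self, name)
            setattr(self, name, v / np.linalg.norm(v))
        if self.head_radius <= 0:
            raise ValueError("head_radius must be positive")

    def neck_shaft_angle_deg(self) -> float:
        """Clinical neck-shaft angle: 180 deg minus the angle between the neck
        direction and the proximal shaft direction."""
        c = float(np.clip(self.neck_axis_dir @ self.shaft_axis_dir, -1, 1))
        return 180.0 - np.degrees(np.arccos(c))

    def transformed(self, transform) -> "ImplicitCoordinateSystem":
        t = transform
        return ImplicitCoordinateSystem(
            head_center=t.apply(self.head_center), head_radius=self.head_radius,
            neck_axis_dir=t.apply_vector(self.neck_axis_dir),
            neck_axis_point=t.apply(self.neck_axis_point),
            shaft_axis_dir=t.apply_vector(self.shaft_axis_dir),
            shaft_axis_point=t.apply(self.shaft_axis_point),
            axes_intersection=t.apply(self.axes_intersection),
            distal_point=t.apply(self.distal_point), lt_peak=t.apply(self.lt_peak),
            axis_gap_mm=self.axis_gap_mm, head_fit_rms=self.head_fit_rms)

    def to_json(self, path=None) -> str:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
             for k, v in self.__dict__.items()}
        payload = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class SurfaceDistanceReport:
    node_distances: np.ndarray           # per mesh node, mm, unsigned
    node_roi: np.ndarray                 # ROI label of nearest bone voxel
    per_roi: pd.DataFrame = field(default=None)  # mean/max per ROI
    mean_mm: float = 0.0
    max_mm: float = 0.0


# ---------------------------------------------------------------------------
# helpers

def _mask_array(mask) -> tuple[np.ndarray, DensityVolume]:
    if isinstance(mask, DensityVolume):
        return mask.values > 0, mask
    raise TypeError("mask must be a DensityVolume label/binary volume")


def _surface_points(mask: DensityVolume) -> np.ndarray:
    """World coordinates of boundary voxels (6-connectivity)."""
    binary = mask.values > 0
    surf = binary & ~ndimage.binary_erosion(binary)
    return mask.index_to_world(np.argwhere(surf))


def fit_head_sphere(mask: DensityVolume, seed_region=None):
    """Algebraic least-squares sphere fit to head-surface voxels.

    ``seed_region``: boolean array selecting the head voxels; if None the whole
    mask surface is used (sensible only when the mask IS the head).  Returns
    ``(center, radius, rms_residual)``.
    """
    binary = mask.values > 0
    if seed_region is not None:
        binary = binary & np.asarray(seed_region, bool)
    if not binary.any():
        raise ValueError("empty head region")
    region = DensityVolume(binary.astype(np.uint8), mask.spacing, mask.origin, "label")
    pts = _surface_points(region)
    return _sphere_fit_points(pts)


def _sphere_fit_points(pts: np.ndarray, trim_rounds: int = 3):
    """Sphere through a point cloud: linear algebraic fit with residual
    trimming to shed non-spherical contamination (neck surface)."""
    pts = np.asarray(pts, float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for a sphere fit")
    keep = np.ones(len(pts), bool)
    center, radius = None, None
    for _ in range(trim_rounds + 1):
        p = pts[keep]
        A = np.column_stack([2 * p, np.ones(len(p))])
        b = (p ** 2).sum(axis=1)
        sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < 4:
            raise ValueError("degenerate (coplanar) surface points")
        center = sol[:3]
        radius = np.sqrt(sol[3] + center @ center)
        resid = np.abs(np.linalg.norm(pts - center, axis=1) - radius)
        rms = float(np.sqrt((resid[keep] ** 2).mean()))
        new_keep = resid <= max(2.0 * rms, 1e-9)
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    resid = np.abs(np.linalg.norm(pts[keep] - center, axis=1) - radius)
    return center, float(radius), float(np.sqrt((resid ** 2).mean()))


def detect_lt_peak(mask: DensityVolume, shaft_axis_guess, medial_hint=None,
                   band_fraction: float = 0.55, min_protrusion: float = 1.05):
    """Surface point of maximal medial protrusion relative to the shaft axis.

    ``shaft_axis_guess``: (point, unit direction pointing proximally).
    ``medial_hint``: direction (world) toward the medial side; if None it is
    estimated from the centroid of the most proximal fifth of the mask (the
    head side, which lies medial of the shaft).
    """
    point, direction = shaft_axis_guess
    point = np.asarray(point, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)

    surf = _surface_points(mask)
    t = (surf - point) @ direction
    t_lo, t_hi = t.min(), t.max()

    if medial_hint is None:
        all_pts = mask.index_to_world(np.argwhere(mask.values > 0))
        t_all = (all_pts - point) @ direction
        prox = all_pts[t_all >= t_lo + 0.8 * (t_hi - t_lo)]
        if len(prox) == 0:
            raise ValueError("cannot estimate medial direction")
        medial_hint = prox.mean(axis=0) - point
    medial = np.asarray(medial_hint, float)
    medial = medial - (medial @ direction) * direction
    norm = np.linalg.norm(medial)
    if norm < 1e-9:
        raise ValueError("medial hint parallel to shaft axis")
    medial /= norm

    radial_vec = (surf - point) - np.outer(t, direction)
    r = np.linalg.norm(radial_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosm = (radial_vec @ medial) / np.where(r > 0, r, 1.0)
    # exclude a rim near the distal cut face (its corners protrude radially
    # when the axis guess is tilted) plus the proximal head/neck zone
    rim = max(6.0, 0.12 * (t_hi - t_lo))
    band = (t >= t_lo + rim) & (t <= t_lo + band_fraction * (t_hi - t_lo)) & (cosm > 0.3)
    if not band.any():
        raise ValueError("no medial surface points in the distal band")
    # local shaft radius for comparison: medial-side radius near the distal end
    ref_band = (t >= t_lo + rim) & (t <= t_lo + 0.25 * (t_hi - t_lo)) & (cosm > 0.3)
    r_ref = np.median(r[ref_band]) if ref_band.any() else np.median(r[band])
    peak_idx = np.argmax(np.where(band, r, -np.inf))
    if r[peak_idx] < min_protrusion * r_ref:
        raise ValueError("no lesser-trochanter protrusion found")
    return surf[peak_idx]


def _principal_axis(pts: np.ndarray):
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    w, v = np.linalg.eigh(cov)
    return c, v[:, np.argmax(w)]


def _band_axis(pts: np.ndarray, point, direction, t_lo, t_hi, n_slabs: int = 8,
               trim: bool = True):
    """Axis through thin cross-section centroids in the band [t_lo, t_hi].

    Thin planar sections of a (possibly obliquely sliced) cylinder are
    ellipses centred on the cylinder axis, so a line through their centroids
    recovers the axis even from a tilted initial direction.
    """
    t = (pts - point) @ direction
    sel = (t >= t_lo) & (t <= t_hi)
    if sel.sum() < 20:
        raise ValueError("shaft band too small for an axis estimate")
    band, tb = pts[sel], t[sel]
    edges = np.linspace(t_lo, t_hi, n_slabs + 1)
    centroids = []
    for a, b in zip(edges[:-1], edges[1:]):
        slab = band[(tb >= a) & (tb < b)]
        if len(slab) < 5:
            continue
        if trim:
            # robust to trochanter bosses protruding into the band: drop
            # voxels far from the current axis line before the centroid.
            # (Only safe once the direction estimate is already close, as
            # the trim otherwise anchors the fit to the incoming line.)
            radial = slab - point - np.outer((slab - point) @ direction,
                                             direction)
            r = np.linalg.norm(radial, axis=1)
            keep = r <= 1.3 * np.median(r)
            if keep.sum() >= 5:
                slab = slab[keep]
        centroids.append(slab.mean(axis=0))
    if len(centroids) < 3:
        raise ValueError("too few shaft cross-sections")
    centroids = np.asarray(centroids)
    c = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - c, full_matrices=False)
    axis = vt[0] if vt[0] @ direction > 0 else -vt[0]
    return c, axis


def _neck_axis(pts_all, head_center, head_radius, shaft_point, shaft_dir,
               init_toward, n_iter: int = 6):
    """Neck direction (pointing toward the head) from trimmed cross-section
    centroids along the head-centre -> shaft-axis corridor."""
    dirj = -np.asarray(init_toward, float)  # head -> junction
    dirj /= np.linalg.norm(dirj)
    dirj0 = dirj.copy()
    for _ in range(n_iter):
        q_neck, _, _ = closest_points_between_lines(head_center, dirj,
                                                    shaft_point, shaft_dir)
        s_star = (q_neck - head_center) @ dirj
        if s_star <= head_radius:
            # refinement wandered: restart from the initial corridor direction
            if abs(dirj @ dirj0) > 0.999:
                raise ValueError(
                    "neck corridor degenerate: head sits on the shaft axis")
            dirj = dirj0.copy()
            continue
        stations = np.linspace(1.05 * head_radius,
                               max(1.3 * head_radius, 0.78 * s_star), 6)
        axial = (pts_all - head_center) @ dirj
        r_trim = None
        centroids = []
        for s in stations:
            slab = np.abs(axial - s) <= 1.5
            if slab.sum() < 10:
                continue
            p = pts_all[slab]
            radial = p - head_center - np.outer((p - head_center) @ dirj, dirj)
            rn = np.linalg.norm(radial, axis=1)
            if r_trim is None:
                r_trim = max(1.7 * float(np.median(rn)), 8.0)
            keep = rn <= r_trim
            if keep.sum() >= 10:
                centroids.append(p[keep].mean(axis=0))
        if len(centroids) < 3:
            raise ValueError("could not sample neck cross-sections")
        rel = np.asarray(centroids) - head_center
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        new_dirj = vt[0] if vt[0] @ rel.mean(axis=0) > 0 else -vt[0]
        done = new_dirj @ dirj > np.cos(np.radians(0.05))
        dirj = new_dirj
        if done:
            break
    return -dirj  # point from the junction toward the head


def implicit_axes(mask: DensityVolume, gap_tol: float = 0.5,
                  max_iter: int = 50, distal_direction=None) -> ImplicitCoordinateSystem:
    """Estimate the full implicit coordinate system from a binary mask.

    Iterates: (a) shaft axis from the inertia of a distal shaft band,
    (b) neck axis from the head centre through neck cross-section centroids,
    (c) re-anchoring both axes at the midpoint of their common perpendicular —
    until the inter-axis distance falls below ``gap_tol`` (mm).
    """
    binary = mask.values > 0
    if not binary.any():
        raise ValueError("empty mask")
    pts_all = mask.index_to_world(np.argwhere(binary))

    # initial shaft direction: principal axis of the whole mask
    c_all, main_axis = _principal_axis(pts_all)
    if distal_direction is None:
        # proximal end = the end whose terminal surface fits a sphere best
        # (the femoral head); the distal end is a cut cylinder.
        surf0 = _surface_points(mask)
        t = (surf0 - c_all) @ main_axis
        rms = []
        for sel in (t <= t.min() + 0.25 * np.ptp(t), t >= t.max() - 0.25 * np.ptp(t)):
            try:
                _, rad, e = _sphere_fit_points(surf0[sel], trim_rounds=0)
                rms.append(e / max(rad, 1e-9))
            except ValueError:
                rms.append(np.inf)
        proximal_dir = -main_axis if rms[0] < rms[1] else main_axis
    else:
        proximal_dir = -np.asarray(distal_direction, float)
        proximal_dir /= np.linalg.norm(proximal_dir)
        if proximal_dir @ main_axis < 0:
            main_axis = -main_axis

    t_all = (pts_all - c_all) @ proximal_dir
    t_min, t_max = t_all.min(), t_all.max()
    span = t_max - t_min

    # head sphere from the surface of the proximal 30%
    surf = _surface_points(mask)
    t_surf = (surf - c_all) @ proximal_dir
    head_pts = surf[t_surf >= t_min + 0.72 * span]
    head_center, head_radius, head_rms = _sphere_fit_points(head_pts)

    # initial shaft axis: iterate the centroid-line fit over a distal band.
    # The band starts well above the distal cut so that oblique slabs taken
    # along a still-tilted direction are not clipped by the cut face.
    shaft_point, shaft_dir = c_all, proximal_dir
    for _ in range(5):
        t_pts = (pts_all - shaft_point) @ shaft_dir
        t0, sp = float(t_pts.min()), float(np.ptp(t_pts))
        lo = t0 + 0.12 * sp
        new_point, new_dir = _band_axis(pts_all, shaft_point, shaft_dir, lo,
                                        lo + max(25.0, 0.18 * sp), trim=False)
        done = abs(new_dir @ shaft_dir) > np.cos(np.radians(0.05))
        shaft_point, shaft_dir = new_point, new_dir
        if done:
            break

    lt_peak = None
    gap = np.inf
    neck_dir = None
    intersection = None
    prev_m = None
    converged = False
    for iteration in range(max_iter):
        lt_peak = detect_lt_peak(mask, (shaft_point, shaft_dir),
                                 medial_hint=head_center - shaft_point)
        # re-anchor the band at a height defined by the LT and the head
        # radius (just below the future distal cut), clear of the LT boss
        t_pts = (pts_all - shaft_point) @ shaft_dir
        t_lt = (lt_peak - shaft_point) @ shaft_dir
        hi = t_lt - head_radius + 2.0
        lo = max(float(t_pts.min()) + 3.0, hi - 16.0)
        if hi - lo < 8.0:
            hi = lo + 8.0
        shaft_point, shaft_dir = _band_axis(pts_all, shaft_point, shaft_dir,
                                            lo, hi)

        # neck axis: line from the head centre through trimmed neck
        # cross-section centroids, iterated to a fixed direction
        neck_dir = _neck_axis(pts_all, head_center, head_radius,
                              shaft_point, shaft_dir,
                              init_toward=head_center - c_all)

        q_shaft, q_neck, gap = closest_points_between_lines(
            shaft_point, shaft_dir, head_center, neck_dir)
        intersection = 0.5 * (q_shaft + q_neck)
        moved = np.inf if prev_m is None else float(
            np.linalg.norm(intersection - prev_m))
        prev_m = intersection
        if gap < gap_tol or moved < 0.2:
            converged = True
            break
        shaft_point = intersection
    if not converged:
        raise RuntimeError(f"implicit axes did not converge: final gap {gap:.2f} mm")

    # three-point reduction: both axes are re-anchored through the midpoint
    # of their common perpendicular, so the final neck and shaft axes
    # genuinely intersect (head centre, intersection, distal point)
    neck_dir = head_center - intersection
    neck_dir /= np.linalg.norm(neck_dir)
    shaft_point = intersection

    if lt_peak is None:
        raise ValueError("lesser trochanter not found")

    distal_pts = pts_all[t_all <= t_min + 2.0]
    distal_point = distal_pts.mean(axis=0)

    return ImplicitCoordinateSystem(
        head_center=head_center, head_radius=head_radius,
        neck_axis_dir=neck_dir, neck_axis_point=head_center,
        shaft_axis_dir=shaft_dir, shaft_axis_point=intersection,
        axes_intersection=intersection, distal_point=distal_point,
        lt_peak=lt_peak, axis_gap_mm=float(gap), head_fit_rms=head_rms)


def _project_point_on_line(p, a, d):
    d = d / np.linalg.norm(d)
    return a + ((p - a) @ d) * d


# ---------------------------------------------------------------------------
# surface distances and volumes

def surface_distances(mesh, mask: DensityVolume, roi_labels=None) -> SurfaceDistanceReport:
    """Unsigned distance from every mesh node to the mask's iso-surface.

    The mask surface is extracted by marching cubes at 0.5; nearest-point
    queries use a KD-tree over the surface vertices.  Per-ROI aggregation uses
    the ROI label of the bone voxel nearest each mesh node.
    """
    verts, faces, _, _ = measure.marching_cubes(
        (mask.values > 0).astype(float), 0.5, spacing=tuple(mask.spacing))
    verts = verts + mask.origin
    tree = cKDTree(verts)
    nodes = np.asarray(mesh.vertices if hasattr(mesh, "vertices") else mesh, float)
    dist, _ = tree.query(nodes)

    labels = mask.values
    bone_idx = np.argwhere(labels > 0)
    bone_tree = cKDTree(mask.index_to_world(bone_idx))
    _, nearest = bone_tree.query(nodes)
    node_roi = labels[tuple(bone_idx[nearest].T)]

    rows = []
    label_map = roi_labels or {}
    names = {v: k for k, v in label_map.items()}
    for lab in np.unique(node_roi):
        sel = node_roi == lab
        rows.append({"roi": names.get(lab, str(lab)), "label": int(lab),
                     "mean_mm": float(dist[sel].mean()),
                     "max_mm": float(dist[sel].max()),
                     "n_nodes": int(sel.sum())})
    per_roi = pd.DataFrame(rows)
    return SurfaceDistanceReport(node_distances=dist, node_roi=node_roi,
                                 per_roi=per_roi, mean_mm=float(dist.mean()),
                                 max_mm=float(dist.max()))


def roi_volumes(mask: DensityVolume, roi_labels: dict) -> dict:
    """Per-ROI volume in cm3 (voxel counts x voxel volume)."""
    out = {}
    vv = mask.voxel_volume_mm3 / 1000.0
    for name, lab in roi_labels.items():
        n = int(np.sum(mask.values == lab))
        if n == 0:
            warnings.warn(f"ROI '{name}' is empty")
        out[name] = n * vv
    return out
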