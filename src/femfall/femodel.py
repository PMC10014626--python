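"""Side-fall voxel FE model construction.

Pipeline: pose the femur in the fall-on-the-greater-trochanter configuration
(shaft 10 degrees above horizontal, neck-shaft plane vertical), cut the shaft
one head radius distal to the lesser trochanter, convert 3 mm voxels into
8-node hexahedral elements, map BMD to elements by equivalent-volume
spherical averaging in the source image, and add planar embedding caps at
the greater-trochanter and femoral-head contact zones with the node sets and
the head driving node used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .material import MaterialLaw
from .morphometry import ImplicitCoordinateSystem
from .volume import DensityVolume

__all__ = [
    "FEMesh", "sidefall_transform", "distal_cut", "map_bmd_to_elements",
    "build_sidefall_model", "equivalent_sphere_radius",
]

SIDEFALL_SHAFT_ANGLE_DEG = 10.0


@dataclass
class FEMesh:
    """Voxel-derived hexahedral mesh in the posed (lab) frame, mm.

    ``nodes`` excludes the driving node, which is appended last and carries
    index ``driving_node``; it is tied vertically to the ``head_cap_top`` set.
    """

    nodes: np.ndarray                 # (n_nodes, 3) incl. driving node
    elements: np.ndarray              # (n_elem, 8) C3D8 connectivity
    bvtv: np.ndarray                  # per element, 0 for embedding
    bmd: np.ndarray                   # per element mg/cm3 (pre-conversion record)
    is_bone: np.ndarray               # bool per element
    node_sets: dict                   # {distal_fixed, gt_cap_base, head_cap_top}
    driving_node: int
    head_gt_distance: float           # mm
    element_size: float               # mm
    grid_origin: np.ndarray           # world of grid cell (0,0,0) corner
    element_index: np.ndarray         # (n_elem, 3) integer cell indices
    grid_shape: tuple
    embedding_modulus_gpa: float = 2.5

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def element_centers(self) -> np.ndarray:
        return self.grid_origin + (self.element_index + 0.5) * self.element_size

    def element_volume_mm3(self) -> float:
        return float(self.element_size ** 3)

    def scale_density(self, factor: float) -> "FEMesh":
        """Return a copy with all bone densities scaled by ``factor``."""
        import copy
        out = copy.copy(self)
        out.bmd = np.where(self.is_bone, self.bmd * factor, self.bmd)
        return out

    def with_bvtv_from(self, law: MaterialLaw) -> "FEMesh":
        import copy
        out = copy.copy(self)
        out.bvtv = np.where(self.is_bone, law.bmd_to_bvtv(out.bmd), 0.0)
        return out

    # --- text export -------------------------------------------------------
    def write_inp(self, path):
        """Abaqus-style text export (nodes, C3D8 elements, node sets)."""
        with open(path, "w") as fh:
            fh.write("*NODE\n")
            for i, p in enumerate(self.nodes, start=1):
                fh.write(f"{i}, {p[0]:.4f}, {p[1]:.4f}, {p[2]:.4f}\n")
            fh.write("*ELEMENT, TYPE=C3D8\n")
            for e, conn in enumerate(self.elements, start=1):
                fh.write(str(e) + ", " + ", ".join(str(c + 1) for c in conn) + "\n")
            for name, ids in self.node_sets.items():
                fh.write(f"*NSET, NSET={name}\n")
                for chunk in np.array_split(np.asarray(ids) + 1,
                                            max(1, len(ids) // 12)):
                    fh.write(", ".join(map(str, chunk)) + "\n")

    def write_vtk(self, path, cell_data: dict | None = None):
        """Legacy-VTK unstructured-grid text export."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nfemfall mesh\nASCII\n"
                     "DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {self.n_nodes} float\n")
            np.savetxt(fh, self.nodes, fmt="%.4f")
            m = self.n_elements
            fh.write(f"CELLS {m} {9 * m}\n")
            np.savetxt(fh, np.column_stack([np.full(m, 8), self.elements]), fmt="%d")
            fh.write(f"CELL_TYPES {m}\n")
            np.savetxt(fh, np.full(m, 12), fmt="%d")  # VTK_HEXAHEDRON
            data = {"bmd": self.bmd, "bvtv": self.bvtv,
                    "is_bone": self.is_bone.astype(int)}
            data.update(cell_data or {})
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float), fmt="%.5f")


def equivalent_sphere_radius(element_size: float) -> float:
    """Radius of the sphere with the volume of a cubic element."""
    return (3.0 * element_size ** 3 / (4.0 * np.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# pose

def sidefall_transform(cs: ImplicitCoordinateSystem,
                       internal_rotation_deg: float = 0.0) -> RigidTransform:
    """Rigid transform to the side-fall pose.

    After the transform the proximal shaft direction makes 10 degrees with
    the horizontal plane (z = const), the neck-shaft plane contains the
    vertical, and the head lies medial-superior (+x, +z) of the shaft.  The
    axes intersection maps to the origin.  ``internal_rotation_deg`` rotates
    about the shaft axis beforehand (anteversion compensation; phantoms are
    built without anteversion so the default is 0).
    """
    s = cs.shaft_axis_dir.copy()
    n = cs.neck_axis_dir.copy()
    if internal_rotation_deg != 0.0:
        n = _rotate_about(n, s, np.radians(internal_rotation_deg))
    m = np.cross(s, n)
    nrm = np.linalg.norm(m)
    if nrm < 1e-9:
        raise ValueError("neck and shaft axes are parallel")
    m /= nrm
    u3 = np.cross(s, m)
    src = np.column_stack([s, m, u3])

    a = np.radians(SIDEFALL_SHAFT_ANGLE_DEG)
    t1 = np.array([np.cos(a), 0.0, np.sin(a)])     # proximal shaft, 10 deg up
    t2 = np.array([0.0, -1.0, 0.0])                # plane normal horizontal
    t3 = np.cross(t1, t2)                          # = (sin a, 0, -cos a)
    dst = np.column_stack([t1, t2, t3])

    R = dst @ src.T
    # ensure the head ends up superior; flip the in-plane normal if not
    if (R @ n)[2] < 0:
        dst = np.column_stack([t1, -t2, -t3])
        R = dst @ src.T
    t = -R @ cs.axes_intersection
    return RigidTransform(R, t)


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))


# ---------------------------------------------------------------------------
# cut and BMD mapping

def distal_cut(mask: DensityVolume, cs: ImplicitCoordinateSystem) -> DensityVolume:
    """Remove voxels more than one head radius distal (along the shaft axis)
    of the LT peak."""
    idx = np.argwhere(mask.values > 0)
    if len(idx) == 0:
        raise ValueError("empty mask")
    pts = mask.index_to_world(idx)
    t = (pts - cs.lt_peak) @ cs.shaft_axis_dir
    keep = t >= -cs.head_radius
    if not keep.any():
        raise ValueError("distal cut removed the entire bone")
    out = mask.values.copy()
    drop = idx[~keep]
    out[tuple(drop.T)] = 0
    # the cut must not disconnect or remove the shaft anchor region
    remaining = out > 0
    labels, n = ndimage.label(remaining, ndimage.generate_binary_structure(3, 1))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        if np.sort(counts)[-2] > 0.02 * counts.max():
            raise ValueError("distal cut disconnected the bone")
        remaining = labels == 1 + int(np.argmax(counts))
    return DensityVolume(remaining.astype(mask.values.dtype), mask.spacing,
                         mask.origin, unit="label")


def map_bmd_to_elements(bmd: DensityVolume, element_centers: np.ndarray,
                        transform: RigidTransform | None = None,
                        element_size: float = 3.0,
                        mask: DensityVolume | None = None) -> np.ndarray:
    """Average BMD over an equivalent-volume sphere per element.

    ``element_centers`` are in the posed frame; ``transform`` is the pose
    (source -> posed), so centers are pulled back through its inverse.  The
    average enumerates the source voxels whose centres fall inside the
    sphere of radius (3 V_e / 4 pi)^(1/3).  When ``mask`` is given, only
    in-mask (bone) voxels contribute: surface elements then carry bone-like
    density instead of a bone/background mixture, which keeps the total
    mineral content of the element model within ~1% of the image.
    """
    r = equivalent_sphere_radius(element_size)
    centers = np.asarray(element_centers, float)
    if transform is not None:
        centers = transform.inverse().apply(centers)
    vals = np.asarray(bmd.values, float)
    sp, orig = bmd.spacing, bmd.origin
    shape = np.array(vals.shape)
    in_mask = None if mask is None else (mask.values > 0)
    out = np.zeros(len(centers))
    reach = np.ceil(r / sp).astype(int)
    for k, c in enumerate(centers):
        ic = (c - orig) / sp
        lo = np.maximum(0, np.floor(ic - reach).astype(int))
        hi = np.minimum(shape, np.ceil(ic + reach).astype(int) + 1)
        if np.any(lo >= hi):
            continue
        ix, iy, iz = (np.arange(lo[d], hi[d]) for d in range(3))
        dx = (orig[0] + ix * sp[0] - c[0])[:, None, None]
        dy = (orig[1] + iy * sp[1] - c[1])[None, :, None]
        dz = (orig[2] + iz * sp[2] - c[2])[None, None, :]
        inside = dx ** 2 + dy ** 2 + dz ** 2 <= r ** 2
        if in_mask is not None:
            inside &= in_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if inside.any():
            block = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            out[k] = block[inside].mean()
    return out


# ---------------------------------------------------------------------------
# full model

_CORNER = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])


def build_sidefall_model(bmd: DensityVolume, mask: DensityVolume,
                         cs: ImplicitCoordinateSystem, law: MaterialLaw,
                         element_size: float = 3.0, cap_layers: int = 4,
                         internal_rotation_deg: float = 0.0,
                         embedding_modulus_gpa: float = 2.5) -> FEMesh:
    """Build the complete side-fall FE model from a calibrated density volume,
    its bone mask and the implicit coordinate system.

    The distal cut is applied in the posed frame along a vertical (transverse)
    plane one head radius distal of the LT peak measured along the shaft axis,
    which keeps the fully-constrained distal face flat and grid-aligned.
    """
    if not 3 <= cap_layers <= 4:
        raise ValueError("embedding depth is three to four voxel layers")
    T = sidefall_transform(cs, internal_rotation_deg)
    cs_posed = cs.transformed(T)

    # posed bounding box of the mask
    idx = np.argwhere(mask.values > 0)
    pts = T.apply(mask.index_to_world(idx))
    cut_point = cs_posed.lt_peak - cs_posed.head_radius * cs_posed.shaft_axis_dir
    keep = pts[:, 0] >= cut_point[0]
    if not keep.any():
        raise ValueError("distal cut removed the entire bone")
    pts = pts[keep]

    h = float(element_size)
    lo = pts.min(axis=0) - h
    lo[2] -= cap_layers * h            # room for the GT cap below
    hi = pts.max(axis=0) + h
    hi[2] += cap_layers * h            # room for the head cap above
    shape = np.ceil((hi - lo) / h).astype(int)
    origin = lo

    # bone occupancy: pull element centers back into the source frame and
    # sample the mask occupancy trilinearly
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cell_idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centers = origin + (cell_idx + 0.5) * h
    back = T.inverse().apply(centers)
    occ = ndimage.map_coordinates((mask.values > 0).astype(float),
                                  ((back - mask.origin) / mask.spacing).T,
                                  order=1, mode="constant")
    bone = (occ >= 0.5) & (centers[:, 0] >= cut_point[0])
    if not bone.any():
        raise ValueError("no bone elements on the grid")

    bone_grid = np.zeros(tuple(shape), bool)
    bone_grid[tuple(cell_idx[bone].T)] = True
    labels, n = ndimage.label(bone_grid, ndimage.generate_binary_structure(3, 1))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        if np.sort(counts)[-2] > 0.02 * counts.max():
            raise ValueError("bone disconnected after cut")
        bone_grid = labels == 1 + int(np.argmax(counts))

    # embedding caps: boxes over the bone footprint in the terminal z layers
    occ_z = np.where(bone_grid.any(axis=(0, 1)))[0]
    zmin_b, zmax_b = occ_z.min(), occ_z.max()
    cap_grid = np.zeros_like(bone_grid)
    for zr, znew in ((range(zmin_b, min(zmin_b + cap_layers, zmax_b)),
                      range(max(0, zmin_b - 0), zmin_b + cap_layers)),
                     (range(max(zmax_b - cap_layers + 1, zmin_b), zmax_b + 1),
                      range(zmax_b - cap_layers + 1, min(zmax_b + 1, bone_grid.shape[2])))):
        footprint = bone_grid[:, :, list(zr)].any(axis=2)
        footprint = ndimage.binary_dilation(footprint, iterations=1)
        xs, ys = np.where(footprint)
        box = np.zeros_like(footprint)
        box[xs.min():xs.max() + 1, ys.min():ys.max() + 1] = True
        for z in znew:
            cap_grid[:, :, z] |= box
    cap_grid &= ~bone_grid

    solid = bone_grid | cap_grid
    cells = np.argwhere(solid)
    is_bone = bone_grid[tuple(cells.T)]

    # shared-node mesh
    corner_ids = cells[:, None, :] + _CORNER[None, :, :]
    flat = np.ravel_multi_index(corner_ids.reshape(-1, 3).T,
                                tuple(np.asarray(shape) + 1))
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8)
    node_ijk = np.column_stack(np.unravel_index(uniq, tuple(np.asarray(shape) + 1)))
    nodes = origin + node_ijk * h

    # BMD mapping (bone elements only)
    bone_centers = origin + (cells[is_bone] + 0.5) * h
    ebmd = np.zeros(len(cells))
    ebmd[is_bone] = np.clip(
        map_bmd_to_elements(bmd, bone_centers, T, element_size=h, mask=mask),
        0.0, None)
    bvtv = np.where(is_bone, law.bmd_to_bvtv(ebmd), 0.0)

    # node sets
    xmin = nodes[:, 0].min()
    distal_fixed = np.where(nodes[:, 0] <= xmin + 0.5 * h)[0]
    zmin_n, zmax_n = nodes[:, 2].min(), nodes[:, 2].max()
    cap_node_ids = np.unique(elements[~is_bone])
    gt_cap_base = cap_node_ids[nodes[cap_node_ids, 2] <= zmin_n + 0.25 * h]
    head_cap_top = cap_node_ids[nodes[cap_node_ids, 2] >= zmax_n - 0.25 * h]
    if len(gt_cap_base) == 0 or len(head_cap_top) == 0:
        raise ValueError("embedding caps have no boundary faces")

    # driving node at the posed head centre
    head_center = cs_posed.head_center
    nodes = np.vstack([nodes, head_center])
    driving_node = len(nodes) - 1

    # GT endpoint: the lowest (impact-side, most lateral in the fall pose)
    # bone element centre
    bone_c = origin + (cells[is_bone] + 0.5) * h
    gt_point = bone_c[np.argmin(bone_c[:, 2])]
    head_gt_distance = float(np.linalg.norm(head_center - gt_point))

    return FEMesh(nodes=nodes, elements=elements, bvtv=bvtv, bmd=ebmd,
                  is_bone=is_bone,
                  node_sets={"distal_fixed": distal_fixed,
                             "gt_cap_base": gt_cap_base,
                             "head_cap_top": head_cap_top},
                  driving_node=driving_node,
                  head_gt_distance=head_gt_distance, element_size=h,
                  grid_origin=origin, element_index=cells,
                  grid_shape=tuple(shape),
                  embedding_modulus_gpa=embedding_modulus_gpa)
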