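"""BMD/BMC agreement between paired density volumes.

Per-ROI mean density and mineral content, voxel-voxel density correlation in
the overlap, and cohort mean absolute-difference maps on a 3 mm template
grid (mean-pooled downsampling, mask-driven non-rigid mapping to a template
femur, common-height crop, voxel-wise averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registration import apply_deformation, nonrigid_register
from .volume import DensityVolume, mean_pool_downsample

__all__ = ["roi_density", "voxel_correlation", "difference_map",
           "joint_histogram"]


def roi_density(bmd: DensityVolume, mask: DensityVolume,
                roi_labels: dict) -> pd.DataFrame:
    """Mean BMD (mg/cm3) and BMC (g) per ROI.

    BMC is the volume integral of density over the ROI; an empty ROI is an
    error (a silent zero would poison downstream regressions).
    """
    if bmd.unit != "mg/cm3":
        raise ValueError("roi_density expects a calibrated density volume")
    vv = bmd.voxel_volume_mm3
    rows = []
    for name, lab in roi_labels.items():
        sel = mask.values == lab
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI '{name}' is empty")
        mean_bmd = float(bmd.values[sel].mean())
        bmc = float(bmd.values[sel].sum()) * vv / 1e6  # mg/cm3*mm3 -> g
        rows.append({"roi": name, "label": lab, "n_voxels": n,
                     "volume_cm3": n * vv / 1000.0,
                     "mean_bmd": mean_bmd, "bmc_g": bmc})
    return pd.DataFrame(rows)


def voxel_correlation(a: DensityVolume, b: DensityVolume,
                      overlap_mask: np.ndarray,
                      roi_labels: dict | None = None,
                      roi_volume: DensityVolume | None = None) -> pd.DataFrame:
    """Squared Pearson correlation of paired voxel densities in the overlap.

    ``overlap_mask``: boolean array of voxels labelled bone in BOTH images.
    With ``roi_labels``/``roi_volume`` the correlation is also reported per
    region.
    """
    if a.shape != b.shape:
        raise ValueError("paired volumes must share a grid (register first)")
    ov = np.asarray(overlap_mask, bool)
    if not ov.any():
        raise ValueError("empty overlap")

    def r2(sel):
        x, y = a.values[sel], b.values[sel]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1] ** 2)

    rows = [{"roi": "overlap", "label": 0, "n_voxels": int(ov.sum()),
             "r2": r2(ov)}]
    if roi_labels is not None and roi_volume is not None:
        for name, lab in roi_labels.items():
            sel = ov & (roi_volume.values == lab)
            if sel.any():
                rows.append({"roi": name, "label": lab,
                             "n_voxels": int(sel.sum()), "r2": r2(sel)})
    return pd.DataFrame(rows)


def difference_map(pairs, template_mask: DensityVolume,
                   grid_spacing_mm: float = 3.0) -> tuple[DensityVolume, int]:
    """Mean |BMD_a - BMD_b| over a cohort, on the template's 3 mm grid.

    ``pairs``: iterable of (a, b, mask) triples on a common per-case grid,
    already rigidly aligned within each pair.  Each case is mean-pool
    downsampled to ``grid_spacing_mm``, mapped non-rigidly (mask-driven) onto
    the template, cropped to the common shaft height, and the absolute
    differences are averaged voxel-wise.  Returns (map, n_pairs_used).
    """
    template3 = mean_pool_downsample(template_mask, grid_spacing_mm)
    template3.values = (template3.values >= 0.5).astype(np.uint8)
    accum = np.zeros(template3.shape)
    count = np.zeros(template3.shape, int)
    used = 0
    for item in pairs:
        a, b, mask = item
        try:
            a3 = mean_pool_downsample(a, grid_spacing_mm)
            b3 = mean_pool_downsample(b, grid_spacing_mm)
            m3 = mean_pool_downsample(mask, grid_spacing_mm)
            m3.values = (m3.values >= 0.5).astype(np.uint8)
            diff = a3.copy(values=np.abs(a3.values - b3.values))
            field = nonrigid_register(template3, m3)
            warped_diff = apply_deformation(diff, field, order=1)
            warped_mask = apply_deformation(m3, field, order=1)
            inside = warped_mask.values >= 0.5
        except RuntimeError as exc:
            warnings.warn(f"pair skipped (registration failure): {exc}")
            continue
        accum[inside] += warped_diff.values[inside]
        count[inside] += 1
        used += 1
    if used == 0:
        raise ValueError("no pair could be registered")
    # common-height crop along the shaft: voxels seen by every used pair
    common = count == used
    out = np.where(common, accum / np.maximum(count, 1), 0.0)
    return DensityVolume(out, template3.spacing, template3.origin,
                         unit="mg/cm3"), used


def joint_histogram(a: DensityVolume, b: DensityVolume, overlap_mask,
                    bins: int = 64) -> pd.DataFrame:
    """2D histogram counts of paired densities (exportable as CSV)."""
    ov = np.asarray(overlap_mask, bool)
    h, xe, ye = np.histogram2d(a.values[ov], b.values[ov], bins=bins)
    rec = [(xe[i], ye[j], h[i, j]) for i in range(bins) for j in range(bins)
           if h[i, j] > 0]
    return pd.DataFrame(rec, columns=["a_edge", "b_edge", "count"])
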