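"""Slice-wise HU -> BMD calibration from the six-insert phantom.

Tube-current modulation makes the HU of a given density drift along the
scan, so each slice gets its own linear map.  Insert HU values are averaged
over an in-plane disc and smoothed with a five-slice centred moving average;
slices where the calibration phantom is not visible get their insert HU
extrapolated from the per-insert linear relation between insert HU and the
slice-mean HU (a surrogate for the mass in the slice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import DensityVolume

__all__ = ["InsertSeries", "SliceCalibration", "measure_inserts",
           "fit_slicewise", "extrapolate_missing", "apply_calibration",
           "calibrate_volume", "slice_mean_hu"]

_SAMPLING_DISC_FRACTION = 0.6  # of the insert radius; avoids partial-volume rims


@dataclass
class InsertSeries:
    """Per-slice mean HU for each insert (NaN where invalid)."""

    hu: np.ndarray                 # (n_slices, 6)
    valid: np.ndarray              # (n_slices,) bool
    densities: np.ndarray          # (6,) mg/cm3, strictly increasing

    def __post_init__(self):
        self.hu = np.asarray(self.hu, float)
        self.valid = np.asarray(self.valid, bool)
        self.densities = np.asarray(self.densities, float)
        if self.densities.shape != (6,) or np.any(np.diff(self.densities) <= 0):
            raise ValueError("need 6 strictly increasing insert densities")
        if self.hu.shape != (len(self.valid), 6):
            raise ValueError("hu must be (n_slices, 6)")


@dataclass
class SliceCalibration:
    """Per-slice linear map density = slope * HU + intercept."""

    slope: np.ndarray              # (n_slices,) (mg/cm3)/HU
    intercept: np.ndarray          # (n_slices,) mg/cm3
    provenance: np.ndarray         # (n_slices,) {"fitted", "extrapolated", "missing"}

    def covers_all(self) -> bool:
        return bool(np.all(self.provenance != "missing"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slice": np.arange(len(self.slope)),
                             "slope": self.slope, "intercept": self.intercept,
                             "provenance": self.provenance})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def measure_inserts(v: DensityVolume, layout, window: int = 5) -> InsertSeries:
    """Mean insert HU per slice, then a centred moving average over slices.

    ``layout`` is an InsertLayout (centres, radius, per-slice validity).  The
    in-plane sampling disc has 60% of the insert radius.  The moving-average
    window shrinks symmetrically at the volume ends.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    if v.unit not in ("HU", "dimensionless"):
        raise ValueError("measure_inserts expects an HU volume")
    nz = v.shape[2]
    valid = np.asarray(layout.valid, bool)
    if len(valid) != nz:
        raise ValueError("layout validity length must match slice count")
    r = layout.radius * _SAMPLING_DISC_FRACTION
    xs = v.axis_coords(0)[:, None]
    ys = v.axis_coords(1)[None, :]
    raw = np.full((nz, 6), np.nan)
    for k, (cx, cy) in enumerate(np.asarray(layout.centers_xy, float)):
        disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
        if not disc.any():
            raise ValueError(f"insert {k} sampling disc lies outside the image")
        raw[:, k] = v.values[disc, :].mean(axis=0)
    raw[~valid] = np.nan

    half = window // 2
    smooth = np.full_like(raw, np.nan)
    vi = np.where(valid)[0]
    for pos, z in enumerate(vi):
        # shrink the window symmetrically near the ends of the valid run
        reach = min(half, pos, len(vi) - 1 - pos)
        sel = vi[pos - reach: pos + reach + 1]
        smooth[z] = raw[sel].mean(axis=0)
    dens = getattr(layout, "densities", None)
    if dens is None:
        raise ValueError("layout must carry insert reference densities")
    return InsertSeries(hu=smooth, valid=valid, densities=np.asarray(dens, float))


def fit_slicewise(series: InsertSeries) -> SliceCalibration:
    """Ordinary least squares density = slope * HU + intercept per valid slice."""
    nz = len(series.valid)
    slope = np.full(nz, np.nan)
    intercept = np.full(nz, np.nan)
    prov = np.full(nz, "missing", dtype=object)
    if not series.valid.any():
        raise ValueError("no valid slices: nothing to fit")
    for z in np.where(series.valid)[0]:
        hu = series.hu[z]
        good = np.isfinite(hu)
        if np.unique(hu[good]).size < 2:
            continue
        p = np.polyfit(hu[good], series.densities[good], 1)
        slope[z], intercept[z] = p[0], p[1]
        prov[z] = "fitted"
    if not np.any(prov == "fitted"):
        raise ValueError("no slice had two distinct insert values to fit")
    return SliceCalibration(slope=slope, intercept=intercept, provenance=prov)


def slice_mean_hu(v: DensityVolume) -> np.ndarray:
    """Average HU of each slice (mass surrogate for extrapolation)."""
    return v.values.mean(axis=(0, 1))


def extrapolate_missing(cal: SliceCalibration, series: InsertSeries,
                        mean_hu: np.ndarray) -> SliceCalibration:
    """Fill invalid slices via the insert-HU ~ slice-mean-HU relation.

    For each insert a simple linear regression of its HU on the slice mean is
    fitted over the valid slices and used to predict the insert HU on the
    invalid ones, which are then fitted like ordinary slices and flagged
    ``extrapolated``.
    """
    mean_hu = np.asarray(mean_hu, float)
    fitted = cal.provenance == "fitted"
    missing = ~series.valid
    if not missing.any():
        return cal
    if fitted.sum() < 3:
        raise ValueError("need at least 3 valid slices to extrapolate")
    slope = cal.slope.copy()
    intercept = cal.intercept.copy()
    prov = cal.provenance.copy()
    pred_hu = np.empty((missing.sum(), 6))
    for k in range(6):
        p = np.polyfit(mean_hu[fitted], series.hu[fitted, k], 1)
        pred_hu[:, k] = np.polyval(p, mean_hu[missing])
    for row, z in zip(pred_hu, np.where(missing)[0]):
        q = np.polyfit(row, series.densities, 1)
        slope[z], intercept[z] = q[0], q[1]
        prov[z] = "extrapolated"
    return SliceCalibration(slope=slope, intercept=intercept, provenance=prov)


def apply_calibration(v: DensityVolume, cal: SliceCalibration) -> DensityVolume:
    """Slice-wise linear HU -> mg/cm3 map.  Values are not clamped here;
    negative densities are clipped only when material properties are mapped."""
    if not cal.covers_all():
        raise ValueError("calibration does not cover every slice")
    bmd = v.values * cal.slope[None, None, :] + cal.intercept[None, None, :]
    return DensityVolume(bmd, v.spacing.copy(), v.origin.copy(), unit="mg/cm3")


def calibrate_volume(v: DensityVolume, layout, densities=None,
                     window: int = 5) -> tuple[DensityVolume, SliceCalibration]:
    """End-to-end convenience: measure, fit, extrapolate if needed, apply."""
    if densities is not None and not hasattr(layout, "densities"):
        layout = _LayoutWithDensities(layout, np.asarray(densities, float))
    series = measure_inserts(v, layout, window=window)
    cal = fit_slicewise(series)
    if not cal.covers_all():
        cal = extrapolate_missing(cal, series, slice_mean_hu(v))
    return apply_calibration(v, cal), cal


class _LayoutWithDensities:
    def __init__(self, layout, densities):
        self.centers_xy = layout.centers_xy
        self.radius = layout.radius
        self.valid = layout.valid
        self.densities = densities
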