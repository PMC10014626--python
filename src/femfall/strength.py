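"""Femoral strength extraction, BMC corrections, damage maps and agreement
statistics.

Strength is the reaction force at the head driving node when its vertical
displacement reaches 4% of the head-centre-to-greater-trochanter distance.
Two density corrections link reconstruction-based models to their reference
counterparts: a collective correction from the cohort BMC regression and an
individual correction from the per-case BMC ratio.  Agreement between paired
strength sets is summarised by the regression line, r^2, SEE, MAE, their
coefficients of variation, Lin's concordance correlation coefficient, and
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .femodel import FEMesh
from .registration import apply_deformation, nonrigid_register
from .solver import SolutionHistory
from .volume import DensityVolume

__all__ = [
    "CorrectionFactors", "AgreementStats", "criterion_displacement",
    "strength_from_history", "mesh_bmc", "collective_correction",
    "individual_correction", "damage_map", "average_damage_maps", "agreement",
]

STRENGTH_DISPLACEMENT_FRACTION = 0.04


@dataclass
class CorrectionFactors:
    slope: float                    # m of BMC_ref ~ m * BMC_test + b
    intercept: float                # b, grams
    collective: np.ndarray          # per-case f_collective
    individual: np.ndarray          # per-case f_individual

    def __post_init__(self):
        if np.any(self.collective <= 0) or np.any(self.individual <= 0):
            raise ValueError("correction factors must be positive")


@dataclass
class AgreementStats:
    r2: float
    r2_ci: tuple
    slope: float
    slope_ci: tuple
    intercept: float
    intercept_ci: tuple
    see: float
    cv_see: float
    mae: float
    cv_mae: float
    ccc: float
    ccc_ci: tuple
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": self.n, "r2": self.r2,
            "r2_lo": self.r2_ci[0], "r2_hi": self.r2_ci[1],
            "slope": self.slope, "slope_lo": self.slope_ci[0],
            "slope_hi": self.slope_ci[1], "intercept": self.intercept,
            "intercept_lo": self.intercept_ci[0],
            "intercept_hi": self.intercept_ci[1],
            "see": self.see, "cv_see": self.cv_see,
            "mae": self.mae, "cv_mae": self.cv_mae,
            "ccc": self.ccc, "ccc_lo": self.ccc_ci[0],
            "ccc_hi": self.ccc_ci[1]}])


# ---------------------------------------------------------------------------
# strength

def criterion_displacement(mesh: FEMesh) -> float:
    """4% of the head-centre-to-GT distance, mm."""
    if mesh.head_gt_distance <= 0:
        raise ValueError("head-GT distance must be positive")
    return STRENGTH_DISPLACEMENT_FRACTION * mesh.head_gt_distance


def strength_from_history(history: SolutionHistory, u_star: float) -> float:
    """Reaction force (N) linearly interpolated at displacement ``u_star``."""
    u = history.displacement
    if u_star > u[-1] + 1e-9:
        raise ValueError("history does not reach the criterion displacement")
    return float(np.interp(u_star, u, history.reaction))


def mesh_bmc(mesh: FEMesh) -> float:
    """Volume integral of element BMD over bone elements, grams."""
    v = mesh.element_volume_mm3()
    return float(mesh.bmd[mesh.is_bone].sum()) * v / 1e6


# ---------------------------------------------------------------------------
# BMC corrections

def collective_correction(bmc_ref, bmc_test) -> CorrectionFactors:
    """Cohort-level correction from the OLS regression of reference BMC on
    test (reconstruction-based) BMC; f_i = (m b_i + c) / b_i."""
    ref = np.asarray(bmc_ref, float)
    test = np.asarray(bmc_test, float)
    if len(ref) != len(test) or len(ref) < 3:
        raise ValueError("need >= 3 paired BMC values")
    if np.any(test <= 0):
        raise ValueError("test BMC must be positive")
    m, b = np.polyfit(test, ref, 1)
    collective = (m * test + b) / test
    individual = ref / test
    return CorrectionFactors(slope=float(m), intercept=float(b),
                             collective=collective, individual=individual)


def individual_correction(bmc_ref: float, bmc_test: float) -> float:
    """Per-case BMC ratio; scaling the mesh densities by it matches the
    reference BMC exactly."""
    if bmc_test <= 0:
        raise ValueError("test BMC must be positive")
    return float(bmc_ref) / float(bmc_test)


# ---------------------------------------------------------------------------
# damage maps

def damage_map(history: SolutionHistory, mesh: FEMesh) -> DensityVolume:
    """Per-element damage at the strength point written into the 3 mm grid."""
    arr = np.zeros(mesh.grid_shape)
    dmg_gp = history.state.damage.reshape(-1, 8).mean(axis=1)
    bone_cells = mesh.element_index[mesh.is_bone]
    arr[tuple(bone_cells.T)] = dmg_gp
    return DensityVolume(arr, np.full(3, mesh.element_size),
                         mesh.grid_origin + 0.5 * mesh.element_size,
                         unit="dimensionless")


def average_damage_maps(maps, masks, template_mask: DensityVolume):
    """Warp damage maps onto the template (mask-driven non-rigid) and average
    voxel-wise.  Returns (mean map, n_used)."""
    template = template_mask.copy(
        values=(template_mask.values > 0).astype(np.uint8))
    accum = np.zeros(template.shape)
    used = 0
    for dmap, mask in zip(maps, masks):
        try:
            fieldd = nonrigid_register(template, mask)
            warped = apply_deformation(dmap, fieldd, order=1)
        except RuntimeError as exc:
            warnings.warn(f"damage map skipped: {exc}")
            continue
        accum += np.clip(warped.values, 0.0, 1.0)
        used += 1
    if used == 0:
        raise ValueError("no damage map could be registered")
    return DensityVolume(accum / used, template.spacing, template.origin,
                         unit="dimensionless"), used


# ---------------------------------------------------------------------------
# agreement statistics

def _ccc(x, y):
    """Lin's concordance correlation coefficient (sample moments, ddof=1)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    return 2 * sxy / (x.var(ddof=1) + y.var(ddof=1) + (x.mean() - y.mean()) ** 2)


def agreement(x, y, bootstrap_reps: int = 2000, seed: int = 0) -> AgreementStats:
    """Agreement of predictor ``x`` with reference ``y``.

    OLS y = slope*x + intercept; r^2; SEE with the n-2 denominator and its CV
    relative to mean(y); MAE of the paired values and its CV; Lin's CCC; and
    95% percentile-bootstrap confidence intervals over resampled pairs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need >= 3 paired values")
    if bootstrap_reps < 100:
        raise ValueError("bootstrap needs >= 100 replicates for CIs")

    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    see = float(np.sqrt(((y - pred) ** 2).sum() / (n - 2)))
    mae = float(np.abs(x - y).mean())
    mean_y = float(y.mean())

    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, 4))
    for i in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            boot[i] = np.nan
            continue
        rb = stats.linregress(xb, yb)
        boot[i] = (rb.rvalue ** 2, rb.slope, rb.intercept, _ccc(xb, yb))
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)

    return AgreementStats(
        r2=float(res.rvalue ** 2), r2_ci=(float(lo[0]), float(hi[0])),
        slope=float(res.slope), slope_ci=(float(lo[1]), float(hi[1])),
        intercept=float(res.intercept),
        intercept_ci=(float(lo[2]), float(hi[2])),
        see=see, cv_see=see / mean_y, mae=mae, cv_mae=mae / mean_y,
        ccc=float(_ccc(x, y)), ccc_ci=(float(lo[3]), float(hi[3])), n=n)
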