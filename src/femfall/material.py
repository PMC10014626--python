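"""Constitutive law for voxel bone: BV/TV-scaled elasticity, quadric yield,
and plastic-strain-driven isotropic damage.

The elastic modulus and the tensile/compressive yield stresses scale with
bone volume fraction (BV/TV) through a two-branch power law that meets with
value continuity at BV/TV = 0.5.  The upper branch is calibrated to two
anchor states: pore-less bone (BV/TV = 1: E = 24 GPa, sigma_t = 199 MPa,
sigma_c = 264 MPa) and typical cortical bone (BV/TV = 0.907: E = 15.9 GPa).
Yield strains are constant in BV/TV by construction (sigma/E fixed at
0.83% tension, 1.1% compression), so the yield stresses inherit the modulus
scaling.

Yield is the isotropic form of a generalized quadric criterion,

    f(sigma) = sqrt(sigma : F4 : sigma) + chi * tr(sigma) - 1,

with the quadratic form split into deviatoric and hydrostatic parts and a
single interaction parameter; it is calibrated so uniaxial tension yields at
sigma_t(BV/TV) and uniaxial compression at -sigma_c(BV/TV).

Damage is isotropic, driven by cumulative plastic strain kappa:
D = D_max * (1 - exp(-k_d * kappa)), reducing every component of the elastic
stiffness alike; nominal stress = (1 - D) * effective stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MaterialLaw", "MaterialState", "VOIGT_TENSOR_WEIGHT"]

# Voigt order (s11, s22, s33, s12, s13, s23); weights turning a Voigt stress
# dot product into the tensor double contraction
VOIGT_TENSOR_WEIGHT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
_M_HYD = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


@dataclass
class MaterialLaw:
    """BMD -> BV/TV -> stiffness/yield/damage material description.

    Stresses in MPa, moduli in GPa at the interface (converted where needed),
    densities in mg/cm3.
    """

    E0: float = 24.0                  # GPa at BV/TV = 1
    sigma_t0: float = 199.0           # MPa at BV/TV = 1
    sigma_c0: float = 264.0           # MPa at BV/TV = 1
    poisson: float = 0.3
    breakpoint: float = 0.5           # BV/TV branch junction
    exponent_low: float = 1.88        # trabecular-branch power
    anchor_bvtv: float = 0.907        # cortical anchor used to set the upper power
    anchor_modulus: float = 15.9      # GPa at anchor_bvtv
    rho_ref: float = 1100.0 / 0.907   # mg/cm3 mapping to BV/TV = 1
    interaction: float = 0.0          # hydrostatic share of the quadric form
    damage_rate: float = 2.0          # k_d
    damage_max: float = 0.9           # D_max < 1

    exponent_high: float = field(init=False)
    _coeff_low: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.damage_max < 1:
            raise ValueError("damage_max must be in (0, 1)")
        if self.sigma_c0 <= self.sigma_t0:
            raise ValueError("compressive yield must exceed tensile yield")
        self.exponent_high = float(
            np.log(self.anchor_modulus / self.E0) / np.log(self.anchor_bvtv))
        e_break = self.E0 * self.breakpoint ** self.exponent_high
        self._coeff_low = e_break / self.breakpoint ** self.exponent_low

    # --- scalar laws -------------------------------------------------------
    def bmd_to_bvtv(self, bmd):
        """Linear BMD (mg/cm3) -> BV/TV, clamped to [0, 1]."""
        return np.clip(np.asarray(bmd, float) / self.rho_ref, 0.0, 1.0)

    def stiffness_of(self, bvtv):
        """Elastic modulus in GPa for BV/TV in [0, 1] (two power branches)."""
        v = np.asarray(bvtv, float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("BV/TV must lie in [0, 1]")
        upper = self.E0 * np.power(v, self.exponent_high, where=v > 0,
                                   out=np.zeros_like(v))
        lower = self._coeff_low * np.power(v, self.exponent_low, where=v > 0,
                                           out=np.zeros_like(v))
        return np.where(v >= self.breakpoint, upper, lower)[()]

    @property
    def yield_strain_tension(self) -> float:
        return self.sigma_t0 / (self.E0 * 1000.0)

    @property
    def yield_strain_compression(self) -> float:
        return self.sigma_c0 / (self.E0 * 1000.0)

    def yield_stresses_of(self, bvtv):
        """(tensile, compressive) yield stresses in MPa; constant yield
        strains make them proportional to the modulus."""
        e_mpa = np.asarray(self.stiffness_of(bvtv)) * 1000.0
        return (self.yield_strain_tension * e_mpa)[()], \
               (self.yield_strain_compression * e_mpa)[()]

    def damage_of(self, kappa):
        """Saturating damage D(kappa) = D_max (1 - exp(-k_d kappa))."""
        k = np.asarray(kappa, float)
        if np.any(k < 0):
            raise ValueError("cumulative plastic strain must be >= 0")
        return (self.damage_max * (1.0 - np.exp(-self.damage_rate * k)))[()]

    # --- quadric yield criterion ------------------------------------------
    def yield_coefficients(self, bvtv):
        """(quadratic 6x6 matrix A, linear chi) of the criterion at BV/TV.

        f(s) = sqrt(s^T A s) + chi * tr(s) - 1 on Voigt stresses, with the
        doubled shear metric baked into A so gradients are conjugate to
        engineering plastic strain.
        """
        st, sc = self.yield_stresses_of(bvtv)
        st, sc = float(st), float(sc)
        if st <= 0 or sc <= 0:
            raise ValueError("yield undefined at zero BV/TV")
        q = 0.5 * (1.0 / st + 1.0 / sc)
        chi = 0.5 * (1.0 / st - 1.0 / sc)
        f_hyd = self.interaction * q * q
        f_dev = 1.5 * (q * q - f_hyd)  # (2/3) f_dev + f_hyd = q^2 at uniaxial
        dg = np.diag(VOIGT_TENSOR_WEIGHT)
        mm = np.outer(_M_HYD, _M_HYD)
        A = f_dev * (dg - mm / 3.0) + f_hyd * mm
        return A, chi

    def yield_function(self, stress, bvtv):
        """Evaluate f(sigma); < 0 elastic, = 0 on the yield surface.

        ``stress``: Voigt 6-vector (or array (..., 6)) in MPa.
        """
        s = np.asarray(stress, float)
        A, chi = self.yield_coefficients(bvtv)
        quad = np.einsum("...i,ij,...j->...", s, A, s)
        tr = s[..., :3].sum(axis=-1)
        return (np.sqrt(np.maximum(quad, 0.0)) + chi * tr - 1.0)[()]

    # --- elasticity --------------------------------------------------------
    def elastic_matrix(self, modulus_gpa) -> np.ndarray:
        """Isotropic stiffness (MPa) in Voigt notation with engineering shear."""
        e = np.asarray(modulus_gpa, float) * 1000.0
        nu = self.poisson
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        C = np.zeros(np.shape(e) + (6, 6))
        for i in range(3):
            for j in range(3):
                C[..., i, j] = lam
            C[..., i, i] = lam + 2 * mu
        for i in range(3, 6):
            C[..., i, i] = mu
        return C


@dataclass
class MaterialState:
    """Per-integration-point history: plastic strain (engineering Voigt),
    cumulative plastic strain kappa, damage D."""

    plastic_strain: np.ndarray
    kappa: np.ndarray
    damage: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "MaterialState":
        return cls(np.zeros((n, 6)), np.zeros(n), np.zeros(n))

    def copy(self) -> "MaterialState":
        return MaterialState(self.plastic_strain.copy(), self.kappa.copy(),
                             self.damage.copy())
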