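"""Two-layer skin optical-property model.

The skin is modelled as a melanin-bearing epidermis of finite thickness on
top of a semi-infinite blood-bearing dermis.  Physiological parameters map
to per-wavelength absorption and scattering coefficients:

* reduced scattering, shared by both layers:
  mu_s'(lambda) = alpha * (lambda/600 nm)^(-beta)
* epidermal absorption (melanin power law):
  mu_a_epi(lambda) = f_mel * 39.0 mm^-1 * (lambda/550 nm)^(-3)
* blood absorption: mu_a_blood = s*mu_a_oxy + (1-s)*mu_a_red
* dermal absorption with vessel-packaging correction:
  mu_a_derm = f_blood * c_VD * mu_a_blood,
  c_VD = (1 - exp(-D*mu_a_blood)) / (D*mu_a_blood)

All lengths are millimetres; coefficients are mm^-1.  The Henyey-Greenstein
anisotropy is fixed at g = 0.8 for all wavelengths, so the unreduced
scattering coefficient used by the photon-transport engine is
mu_s = mu_s'/(1-g) = 5*mu_s'.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np

from .chromophores import ChromophoreSet
from .spectra import CANONICAL_GRID, Spectrum, WavelengthGrid

__all__ = [
    "TissueParams", "LayerOptics", "reduced_scattering", "epidermis_absorption",
    "blood_absorption", "vessel_packaging_factor", "dermis_absorption",
    "layer_optics", "ANISOTROPY", "MELANIN_K", "T_EPI_RANGE", "MUSP_RANGE",
]

ANISOTROPY = 0.8
MELANIN_K = 39.0  # mm^-1, epidermal absorption scale at 550 nm for f_mel = 1
MELANIN_GAMMA = -3.0
MELANIN_LAMBDA0 = 550.0
SCATTER_LAMBDA0 = 600.0

T_EPI_RANGE = (0.0025, 0.49)  # mm
MUSP_RANGE = (1.0, 90.5)  # mm^-1, valid reduced-scattering range over the grid
S_FIT_RANGE = (-0.2, 1.2)  # SO2 fraction range allowed during fitting


@dataclass
class TissueParams:
    """Physiological parameters of the two-layer skin model.

    Attributes
    ----------
    t_epi : epidermis thickness, mm
    f_mel : melanin tissue fraction of the epidermis (dimensionless)
    f_blood : blood tissue fraction of the dermis (dimensionless)
    s : blood oxygen saturation fraction; the fitting range extends to
        [-0.2, 1.2] because estimates are deliberately not clipped
    d_vessel : mean vessel diameter D, mm
    alpha : reduced scattering coefficient at 600 nm, mm^-1
    beta : scattering power (dimensionless)
    """

    t_epi: float
    f_mel: float
    f_blood: float
    s: float
    d_vessel: float
    alpha: float
    beta: float

    def validate(self) -> "TissueParams":
        if not (T_EPI_RANGE[0] <= self.t_epi <= T_EPI_RANGE[1]):
            raise ValueError(f"t_epi={self.t_epi} mm outside {T_EPI_RANGE}")
        if not (0.0 <= self.f_mel <= 1.0):
            raise ValueError(f"f_mel={self.f_mel} outside [0, 1]")
        if not (0.0 <= self.f_blood <= 1.0):
            raise ValueError(f"f_blood={self.f_blood} outside [0, 1]")
        if not (S_FIT_RANGE[0] <= self.s <= S_FIT_RANGE[1]):
            raise ValueError(f"s={self.s} outside {S_FIT_RANGE}")
        if self.d_vessel <= 0:
            raise ValueError("vessel diameter D must be > 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        lam = CANONICAL_GRID.lambdas
        musp = self.alpha * (lam / SCATTER_LAMBDA0) ** (-self.beta)
        if musp.min() < MUSP_RANGE[0] - 1e-9 or musp.max() > MUSP_RANGE[1] + 1e-9:
            raise ValueError(
                f"mu_s' spans [{musp.min():.3g}, {musp.max():.3g}] mm^-1, "
                f"outside the validated range {MUSP_RANGE}"
            )
        return self

    # flat key-value serialization (config records)
    def to_record(self) -> dict:
        return {
            "t_epi_mm": self.t_epi, "f_mel": self.f_mel, "f_blood": self.f_blood,
            "so2": self.s, "d_vessel_mm": self.d_vessel,
            "alpha": self.alpha, "beta": self.beta,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "TissueParams":
        return cls(t_epi=rec["t_epi_mm"], f_mel=rec["f_mel"], f_blood=rec["f_blood"],
                   s=rec["so2"], d_vessel=rec["d_vessel_mm"],
                   alpha=rec["alpha"], beta=rec["beta"])

    def as_array(self) -> np.ndarray:
        return np.array([self.t_epi, self.f_mel, self.f_blood, self.s,
                         self.d_vessel, self.alpha, self.beta])

    @classmethod
    def from_array(cls, a) -> "TissueParams":
        return cls(*map(float, a))


@dataclass
class LayerOptics:
    """Per-wavelength optical coefficients of the two layers."""

    mu_a_epi: Spectrum
    mu_a_derm: Spectrum
    mu_s_prime: Spectrum  # shared by both layers
    g: float = ANISOTROPY
    t_epi: float = 0.1  # mm

    @property
    def mu_s(self) -> Spectrum:
        """Unreduced scattering coefficient mu_s'/(1-g)."""
        return Spectrum(self.mu_s_prime.values / (1.0 - self.g))


def reduced_scattering(alpha: float, beta: float,
                       grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """mu_s'(lambda) = alpha * (lambda/600)^(-beta), mm^-1."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    lam = grid.lambdas
    return Spectrum(alpha * (lam / SCATTER_LAMBDA0) ** (-beta), grid)


def epidermis_absorption(f_mel: float,
                         grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """Melanin power-law epidermal absorption, mm^-1."""
    if f_mel < 0:
        raise ValueError("f_mel must be >= 0")
    lam = grid.lambdas
    return Spectrum(f_mel * MELANIN_K * (lam / MELANIN_LAMBDA0) ** MELANIN_GAMMA, grid)


def blood_absorption(s: float, chromophores: ChromophoreSet) -> Spectrum:
    """Affine mix of oxygenated and reduced whole-blood absorption."""
    oxy, red = chromophores.mu_a_oxy, chromophores.mu_a_red
    return Spectrum(s * oxy.values + (1.0 - s) * red.values, oxy.grid)


def vessel_packaging_factor(d_vessel: float, mu_a_blood: Spectrum) -> Spectrum:
    """Vessel packaging correction c_VD = (1 - exp(-D*mu_a)) / (D*mu_a).

    Blood confined to discrete vessels absorbs less than a homogeneous
    distribution of the same amount of hemoglobin; the factor lies in
    (0, 1] and tends to 1 as D -> 0.  A series expansion is used where
    D*mu_a < 1e-6 to avoid cancellation.
    """
    if d_vessel <= 0:
        raise ValueError("vessel diameter D must be > 0")
    x = d_vessel * mu_a_blood.values
    small = x < 1e-6
    out = np.empty_like(x)
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs * xs / 6.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return Spectrum(out, mu_a_blood.grid)


def dermis_absorption(params: TissueParams, chromophores: ChromophoreSet) -> Spectrum:
    """mu_a_derm = f_blood * c_VD * mu_a_blood, mm^-1."""
    mu_b = blood_absorption(params.s, chromophores)
    c_vd = vessel_packaging_factor(params.d_vessel, mu_b)
    return Spectrum(params.f_blood * c_vd.values * mu_b.values, mu_b.grid)


def layer_optics(params: TissueParams, chromophores: ChromophoreSet) -> LayerOptics:
    """Assemble the full per-wavelength layer coefficients."""
    return LayerOptics(
        mu_a_epi=epidermis_absorption(params.f_mel),
        mu_a_derm=dermis_absorption(params, chromophores),
        mu_s_prime=reduced_scattering(params.alpha, params.beta),
        g=ANISOTROPY,
        t_epi=params.t_epi,
    )
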