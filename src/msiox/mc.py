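"""White Monte Carlo photon transport in a two-layer slab and the 4-D
reflectance look-up table (LUT) queried by the forward model.

The simulation is *white*: photons propagate with zero absorption and the
per-photon pathlength in each layer is recorded for every photon exiting
the top surface.  Absorption is applied afterwards analytically with
Beer-Lambert's law, so a single scattering simulation serves an entire
grid of absorption values.

Geometry and conventions
------------------------
* z axis points downward into the tissue; the surface is z = 0.
* Pencil-beam launch at the origin, direction +z.
* Epidermis occupies 0 <= z < t_epi, the dermis z >= t_epi (semi-infinite).
* Both layers share mu_s and the Henyey-Greenstein anisotropy g, and the
  same refractive index (1.4 by default), so only the air/tissue surface
  refracts; unpolarized Fresnel reflection is applied there.
* All photons exiting the top surface are collected regardless of exit
  position and angle (spatially integrated reflectance).
* Photons are terminated once their total pathlength exceeds ``max_path``
  (default 400 mm); the terminated fraction is recorded in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit
from scipy.interpolate import RegularGridInterpolator

from .spectra import Spectrum

__all__ = [
    "PhotonRecords", "ReflectanceLUT", "LutAxisSpec", "run_white_mc",
    "apply_absorption", "absorption_grid", "build_lut", "interpolate_T",
    "sample_hg_cosines",
]

N_TISSUE_DEFAULT = 1.4
MAX_PATH_DEFAULT = 400.0  # mm


@njit(cache=True, fastmath=True)
def _hg_cosines(g, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        u = np.random.random()
        if abs(g) < 1e-12:
            out[i] = 2.0 * u - 1.0
        else:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
            out[i] = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return out


def sample_hg_cosines(g: float, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` Henyey-Greenstein scattering-angle cosines."""
    return _hg_cosines(float(g), int(n), int(seed))


@njit(cache=True, fastmath=True)
def _fresnel_reflectance(cos_i, n_rel):
    """Unpolarized Fresnel reflectance for internal incidence.

    ``n_rel`` is n_inside/n_outside (> 1 for tissue/air); ``cos_i`` is the
    cosine of the internal incidence angle.
    """
    if n_rel == 1.0:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    # note: going from index n_rel to 1
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _white_mc_kernel(t_epi, mu_s, g, n_photons, n_rel, max_path, seed):
    np.random.seed(seed)
    path_epi = np.empty(n_photons)
    path_derm = np.empty(n_photons)
    detected = np.zeros(n_photons, dtype=np.bool_)
    n_capped = 0

    # specular reflection of the normally incident beam at launch
    w0 = 1.0 - ((n_rel - 1.0) / (n_rel + 1.0)) ** 2

    for i in range(n_photons):
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        pe = 0.0  # pathlength in epidermis
        pd = 0.0  # pathlength in dermis
        total = 0.0
        alive = True
        while alive:
            step = -np.log(np.random.random()) / mu_s
            remaining = step
            while remaining > 0.0:
                # distance to the top surface along the current direction
                if uz < 0.0:
                    d_surf = -z / uz
                else:
                    d_surf = 1.0e30
                d_move = remaining if remaining < d_surf else d_surf
                z_new = z + uz * d_move
                # partition the segment between the two layers
                if uz == 0.0:
                    if z < t_epi:
                        pe += d_move
                    else:
                        pd += d_move
                else:
                    z_lo = z if z < z_new else z_new
                    z_hi = z_new if z_new > z else z
                    dz = z_hi - z_lo
                    if dz > 0.0:
                        over = z_hi - t_epi
                        if over < 0.0:
                            over = 0.0
                        if over > dz:
                            over = dz
                        frac_derm = over / dz
                    else:
                        frac_derm = 0.0 if z < t_epi else 1.0
                    pe += d_move * (1.0 - frac_derm)
                    pd += d_move * frac_derm
                total += d_move
                z = z_new
                if d_move == d_surf and remaining >= d_surf:
                    # photon reached the surface: escape or internal reflection
                    z = 0.0
                    r = _fresnel_reflectance(-uz, n_rel)
                    if np.random.random() >= r:
                        path_epi[i] = pe
                        path_derm[i] = pd
                        detected[i] = True
                        alive = False
                        remaining = 0.0
                    else:
                        uz = -uz
                        remaining -= d_move
                else:
                    remaining -= d_move
            if not alive:
                break
            if total > max_path:
                n_capped += 1
                break
            # Henyey-Greenstein scatter
            u = np.random.random()
            if abs(g) < 1e-12:
                cost = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
            sint = np.sqrt(1.0 - cost * cost)
            phi = 2.0 * np.pi * np.random.random()
            cosp = np.cos(phi)
            sinp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                uz_n = -sint * cosp * den + uz * cost
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux, uy, uz = ux_n / norm, uy_n / norm, uz_n / norm
    return path_epi, path_derm, detected, n_capped, w0


@dataclass
class PhotonRecords:
    """Per-photon layer pathlengths and weights for detected photons."""

    path_epi: np.ndarray  # mm
    path_derm: np.ndarray  # mm
    weight: np.ndarray  # dimensionless, in (0, 1]
    n_launched: int
    n_capped: int  # photons terminated at the pathlength cap
    meta: dict = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return self.path_epi.size

    @property
    def detected_fraction(self) -> float:
        """Total detected weight per launched photon (reflectance at mu_a=0)."""
        return float(self.weight.sum() / self.n_launched)

    @property
    def capped_fraction(self) -> float:
        return self.n_capped / self.n_launched


def run_white_mc(t_epi: float, mu_s: float, g: float = 0.8, n_photons: int = 100_000,
                 seed: int = 0, n_tissue: float = N_TISSUE_DEFAULT,
                 max_path: float = MAX_PATH_DEFAULT) -> PhotonRecords:
    """Run a white (zero absorption) MC simulation of the two-layer slab.

    Parameters
    ----------
    t_epi
        Epidermis thickness, mm.
    mu_s
        Unreduced scattering coefficient, mm^-1 (identical in both layers;
        mu_s = mu_s'/(1-g) = 5*mu_s' at g = 0.8).
    n_tissue
        Tissue refractive index relative to air (1.0 gives a matched,
        Fresnel-free boundary).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if mu_s <= 0:
        raise ValueError("mu_s must be > 0")
    if t_epi < 0:
        raise ValueError("t_epi must be >= 0")
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie in (-1, 1)")
    pe, pd, det, n_capped, w0 = _white_mc_kernel(
        float(t_epi), float(mu_s), float(g), int(n_photons),
        float(n_tissue), float(max_path), int(seed))
    pe, pd = pe[det], pd[det]
    return PhotonRecords(
        path_epi=pe, path_derm=pd, weight=np.full(pe.size, w0),
        n_launched=int(n_photons), n_capped=int(n_capped),
        meta={"t_epi": t_epi, "mu_s": mu_s, "g": g, "seed": seed,
              "n_tissue": n_tissue, "max_path": max_path})


def apply_absorption(records: PhotonRecords, mu_a_epi: float, mu_a_derm: float) -> float:
    """Post-hoc Beer-Lambert absorption -> detected reflectance T."""
    if mu_a_epi < 0 or mu_a_derm < 0:
        raise ValueError("absorption coefficients must be >= 0")
    att = np.exp(-mu_a_epi * records.path_epi - mu_a_derm * records.path_derm)
    return float(np.sum(records.weight * att) / records.n_launched)


def absorption_grid(records: PhotonRecords, mu_a_epi_axis: np.ndarray,
                    mu_a_derm_axis: np.ndarray) -> np.ndarray:
    """Beer-Lambert reflectance on a full (mu_a_epi, mu_a_derm) grid.

    Factorizes exp(-a*pe - d*pd) into two per-photon attenuation matrices
    and contracts them with a matrix product.
    """
    a = np.exp(-np.outer(np.asarray(mu_a_epi_axis, float), records.path_epi))
    d = np.exp(-np.outer(np.asarray(mu_a_derm_axis, float), records.path_derm))
    return (a * records.weight) @ d.T / records.n_launched


@dataclass
class LutAxisSpec:
    """Axis node layout of the reflectance LUT (all strictly increasing)."""

    t_epi: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.0025, 0.49, 9))
    mu_s_prime: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 90.5, 9))
    mu_a: np.ndarray = field(
        default_factory=lambda: np.concatenate(([0.0], np.geomspace(1e-4, 100.0, 24))))

    @classmethod
    def compact(cls) -> "LutAxisSpec":
        """Reduced axes bracketing the default tissue-parameter sampling
        ranges (t_epi in [0.025, 0.3] mm, mu_s' <= alpha_max*(400/600)^-beta_max
        ~= 16.5 mm^-1), for desk-scale LUT builds."""
        return cls(
            t_epi=np.geomspace(0.02, 0.35, 7),
            mu_s_prime=np.geomspace(0.9, 17.0, 7),
            mu_a=np.concatenate(([0.0], np.geomspace(1e-4, 50.0, 20))),
        )

    def validate(self) -> "LutAxisSpec":
        for name in ("t_epi", "mu_s_prime", "mu_a"):
            ax = np.asarray(getattr(self, name), float)
            if np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            setattr(self, name, ax)
        if self.t_epi[0] < 0 or self.mu_s_prime[0] <= 0 or self.mu_a[0] < 0:
            raise ValueError("axis nodes outside the validated ranges")
        return self


@dataclass
class ReflectanceLUT:
    """4-D table of MC-simulated reflectance T(t_epi, mu_s'_600, mu_a_epi, mu_a_derm).

    Interpolation is multilinear in transformed coordinates: log(t_epi),
    log(mu_s') and log(mu_a + a0) on each absorption axis, where a0 is the
    smallest positive absorption node (this maps the exact-zero node onto a
    finite coordinate).
    """

    t_epi_axis: np.ndarray
    mu_s_prime_axis: np.ndarray
    mu_a_epi_axis: np.ndarray
    mu_a_derm_axis: np.ndarray
    values: np.ndarray  # shape (n_t, n_s, n_ae, n_ad)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._interp = None
        expected = (self.t_epi_axis.size, self.mu_s_prime_axis.size,
                    self.mu_a_epi_axis.size, self.mu_a_derm_axis.size)
        if self.values.shape != expected:
            raise ValueError(f"LUT values shape {self.values.shape} != {expected}")

    def _offsets(self):
        ae = self.mu_a_epi_axis
        ad = self.mu_a_derm_axis
        a0e = ae[ae > 0].min() if np.any(ae > 0) else 1.0
        a0d = ad[ad > 0].min() if np.any(ad > 0) else 1.0
        return a0e, a0d

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            a0e, a0d = self._offsets()
            self._interp = RegularGridInterpolator(
                (np.log(self.t_epi_axis), np.log(self.mu_s_prime_axis),
                 np.log(self.mu_a_epi_axis + a0e), np.log(self.mu_a_derm_axis + a0d)),
                self.values, method="linear", bounds_error=True)
        return self._interp

    # --- persistence -----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f["t_epi_axis"] = self.t_epi_axis
            f["mu_s_prime_axis"] = self.mu_s_prime_axis
            f["mu_a_epi_axis"] = self.mu_a_epi_axis
            f["mu_a_derm_axis"] = self.mu_a_derm_axis
            f["values"] = self.values
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "ReflectanceLUT":
        with h5py.File(path, "r") as f:
            return cls(
                t_epi_axis=f["t_epi_axis"][:],
                mu_s_prime_axis=f["mu_s_prime_axis"][:],
                mu_a_epi_axis=f["mu_a_epi_axis"][:],
                mu_a_derm_axis=f["mu_a_derm_axis"][:],
                values=f["values"][:],
                meta=dict(f.attrs))


def build_lut(axis_spec: LutAxisSpec | None = None, n_photons_per_node: int = 100_000,
              seed: int = 0, g: float = 0.8, n_tissue: float = N_TISSUE_DEFAULT,
              max_path: float = MAX_PATH_DEFAULT, progress: bool = False) -> ReflectanceLUT:
    """Build the 4-D reflectance LUT.

    One white MC simulation is run per (t_epi, mu_s') node; the two
    absorption axes are filled analytically by Beer-Lambert attenuation of
    the recorded pathlengths.
    """
    spec = (axis_spec or LutAxisSpec()).validate()
    n_t, n_s = spec.t_epi.size, spec.mu_s_prime.size
    values = np.empty((n_t, n_s, spec.mu_a.size, spec.mu_a.size))
    capped = np.empty((n_t, n_s))
    for i, t_epi in enumerate(spec.t_epi):
        for j, musp in enumerate(spec.mu_s_prime):
            mu_s = musp / (1.0 - g)
            node_seed = (int(seed) + 7919 * i + 104729 * j) % (2**31 - 1)
            rec = run_white_mc(t_epi, mu_s, g=g, n_photons=n_photons_per_node,
                               seed=node_seed, n_tissue=n_tissue, max_path=max_path)
            values[i, j] = absorption_grid(rec, spec.mu_a, spec.mu_a)
            capped[i, j] = rec.capped_fraction
            if progress:
                print(f"LUT node t_epi={t_epi:.4f} mm, mu_s'={musp:.2f} 1/mm: "
                      f"R0={values[i, j, 0, 0]:.4f}, capped={capped[i, j]:.4f}")
    return ReflectanceLUT(
        t_epi_axis=spec.t_epi, mu_s_prime_axis=spec.mu_s_prime,
        mu_a_epi_axis=spec.mu_a.copy(), mu_a_derm_axis=spec.mu_a.copy(),
        values=values,
        meta={"n_photons_per_node": n_photons_per_node, "g": g,
              "n_tissue": n_tissue, "max_path": max_path, "seed": seed,
              "max_capped_fraction": float(capped.max())})


def interpolate_T(lut: ReflectanceLUT, t_epi: float, mu_s_prime: Spectrum | np.ndarray,
                  mu_a_epi: Spectrum | np.ndarray, mu_a_derm: Spectrum | np.ndarray,
                  clip: bool = False) -> Spectrum:
    """Interpolate tissue reflectance T(lambda) from the LUT.

    The scattering axis of the LUT is scalar, so each wavelength is queried
    independently with its own mu_s'(lambda).  With ``clip=True`` queries
    are clamped to the LUT hull instead of raising (used by the inverse
    fitter whose box bounds cannot exactly express the hull).
    """
    musp = mu_s_prime.values if isinstance(mu_s_prime, Spectrum) else np.asarray(mu_s_prime, float)
    ae = mu_a_epi.values if isinstance(mu_a_epi, Spectrum) else np.asarray(mu_a_epi, float)
    ad = mu_a_derm.values if isinstance(mu_a_derm, Spectrum) else np.asarray(mu_a_derm, float)
    a0e, a0d = lut._offsets()
    pts = np.empty((musp.size, 4))
    pts[:, 0] = np.log(max(t_epi, 1e-300))
    pts[:, 1] = np.log(np.maximum(musp, 1e-300))
    pts[:, 2] = np.log(np.maximum(ae, 0.0) + a0e)
    pts[:, 3] = np.log(np.maximum(ad, 0.0) + a0d)
    axes = (np.log(lut.t_epi_axis), np.log(lut.mu_s_prime_axis),
            np.log(lut.mu_a_epi_axis + a0e), np.log(lut.mu_a_derm_axis + a0d))
    if clip:
        for k in range(4):
            pts[:, k] = np.clip(pts[:, k], axes[k][0], axes[k][-1])
    else:
        names = ("t_epi", "mu_s_prime", "mu_a_epi", "mu_a_derm")
        for k in range(4):
            if pts[:, k].min() < axes[k][0] - 1e-12 or pts[:, k].max() > axes[k][-1] + 1e-12:
                raise ValueError(f"query outside LUT hull on axis {names[k]!r}")
        for k in range(4):
            pts[:, k] = np.clip(pts[:, k], axes[k][0], axes[k][-1])
    vals = lut._interpolator()(pts)
    if isinstance(mu_s_prime, Spectrum):
        return Spectrum(vals)
    return vals
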