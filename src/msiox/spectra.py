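"""Canonical wavelength grid, spectrum container and resampling utilities.

All spectral quantities in the package live on a single canonical grid:
integer wavelengths 400..700 nm inclusive, 1 nm spacing (301 samples).
Raw tabulations (chromophore tables, spectrometer sweeps, lamp spectra)
are brought onto this grid by :func:`resample_to_grid`, which applies a
1 nm boxcar anti-aliasing filter before linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID_NM",
    "N_WAVELENGTHS",
    "WavelengthGrid",
    "Spectrum",
    "resample_to_grid",
    "grid_index",
]

#: Canonical wavelength grid in nanometres (400, 401, ..., 700).
GRID_NM = np.arange(400, 701, dtype=float)
N_WAVELENGTHS = GRID_NM.size  # 301


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive integer wavelength grid, 400..700 nm in 1 nm steps."""

    lambdas: np.ndarray = field(default_factory=lambda: GRID_NM.copy())

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("wavelength grid must be a 1-D vector")
        d = np.diff(lam)
        if not np.all(d > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "lambdas", lam)

    def __len__(self) -> int:
        return self.lambdas.size


# Shared default grid instance.
CANONICAL_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """Per-wavelength values on the canonical grid.

    Units depend on context: mm^-1 for absorption/scattering coefficients,
    dimensionless for transmission/reflectance, relative irradiance for
    lamp emission.
    """

    values: np.ndarray
    grid: WavelengthGrid = field(default_factory=lambda: CANONICAL_GRID)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"spectrum has {v.shape} values for a grid of length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        self.values = v

    @property
    def lambdas(self) -> np.ndarray:
        return self.grid.lambdas

    def at(self, wavelength_nm: float) -> float:
        """Value at an on-grid wavelength."""
        return float(self.values[grid_index(wavelength_nm, self.grid)])

    # light-weight arithmetic; results share the grid
    def __mul__(self, other):
        o = other.values if isinstance(other, Spectrum) else other
        return Spectrum(self.values * o, self.grid)

    __rmul__ = __mul__

    def __add__(self, other):
        o = other.values if isinstance(other, Spectrum) else other
        return Spectrum(self.values + o, self.grid)

    def copy(self) -> "Spectrum":
        return Spectrum(self.values.copy(), self.grid)


def grid_index(wavelength_nm: float, grid: WavelengthGrid = CANONICAL_GRID) -> int:
    lam = grid.lambdas
    i = int(np.argmin(np.abs(lam - wavelength_nm)))
    if abs(lam[i] - wavelength_nm) > 1e-9:
        raise ValueError(f"{wavelength_nm} nm is not on the grid")
    return i


def _boxcar_1nm(wl: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Moving average over a 1 nm wide window centred on each sample.

    The average is taken over the tabulated samples falling inside
    [wl - 0.5, wl + 0.5] nm; data already sampled at >= 1 nm spacing pass
    through unchanged.  Windows shrink at the ends of the tabulated range
    (no extrapolation).
    """
    if wl.size < 2:
        return val.copy()
    half = 0.5 + 1e-9  # inclusive window edges
    cum = np.concatenate(([0.0], np.cumsum(val)))
    lo = np.searchsorted(wl, wl - half, side="left")
    hi = np.searchsorted(wl, wl + half, side="right")
    width = hi - lo
    # data sampled at >= 1 nm spacing passes through bit-exactly
    return np.where(width == 1, val, (cum[hi] - cum[lo]) / width)


def resample_to_grid(raw, grid: WavelengthGrid = CANONICAL_GRID) -> Spectrum:
    """Smooth a raw (wavelength, value) tabulation and resample onto the grid.

    The tabulation is smoothed with a 1 nm wide moving-average filter (to
    avoid aliasing of sub-nanometre structure) and linearly interpolated
    onto the canonical 1 nm grid.

    Parameters
    ----------
    raw
        Sequence of (wavelength_nm, value) pairs or a (N, 2) array with
        strictly increasing wavelengths covering [400, 700] nm.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("raw tabulation must be an (N, 2) array of (wavelength, value)")
    wl, val = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(wl) > 0):
        raise ValueError("raw wavelengths must be strictly increasing")
    lam = grid.lambdas
    if wl[0] > lam[0] or wl[-1] < lam[-1]:
        raise ValueError(
            f"raw tabulation [{wl[0]}, {wl[-1]}] nm does not cover the "
            f"grid [{lam[0]}, {lam[-1]}] nm"
        )
    smoothed = _boxcar_1nm(wl, val)
    return Spectrum(np.interp(lam, wl, smoothed), grid)
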