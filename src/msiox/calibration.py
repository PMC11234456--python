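"""Estimation of the per-band sensor spectral response from an LCTF sweep,
and fitting of the detector-noise and lamp-variation models.

The calibration sweep steps a narrowband (~7 nm FWHM) tunable filter from
400 to 700 nm; at each setting m the camera records band intensities
I[n, m] while a calibrated spectrometer records the reflected irradiance
R_m(lambda).  The forward model is linear in the unknown response,

    IC[n, m] = sum_lambda r_n(lambda) R_m(lambda),

but because the passband is several nm wide the response cannot be read off
directly; it is recovered per band by nonlinear least squares on the
residual vector

    chi = [ I[n, m]/<I>_{n,m} - IC[n, m]  (for every m),
            0.2 * Delta_r(lambda_i)       (for every interior pair) ],

where Delta_r is an amplitude-normalized first difference,
Delta_r_i = (r_{i+1} - r_i) / (0.5 r_i + 0.5 r_{i+1} + <r>_lambda).
The grand-mean normalization of the measured intensities makes the solution
insensitive to overall lamp intensity, exposure and gain; the smoothness
penalty suppresses noise-driven high-frequency structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import least_squares

from .camera import N_BANDS, NoiseModel, SensorResponse
from .spectra import CANONICAL_GRID, Spectrum

__all__ = [
    "CalibrationDataset", "CalibrationResult", "penalty_vector",
    "estimate_response", "fit_noise_model", "fit_lamp_variation", "fit_lamp_q",
]

SMOOTHNESS_WEIGHT = 0.2


@dataclass
class CalibrationDataset:
    """LCTF sweep data: band intensities and reference spectra, dark-subtracted.

    ``I`` has shape (16, M); ``R`` has shape (M, 301) with row m the reference
    spectrum (already resampled to the canonical grid) for LCTF setting m;
    ``settings`` are the LCTF center wavelengths in nm.
    """

    I: np.ndarray
    R: np.ndarray
    settings: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.settings = np.asarray(self.settings, dtype=float)
        m = self.settings.size
        if self.I.shape != (N_BANDS, m):
            raise ValueError(f"I must have shape ({N_BANDS}, {m})")
        if self.R.shape != (m, len(CANONICAL_GRID)):
            raise ValueError(f"R must have shape ({m}, {len(CANONICAL_GRID)})")
        if np.any(self.I < 0) or np.any(self.R < 0):
            raise ValueError("intensities and reference spectra must be >= 0")

    @property
    def grand_mean(self) -> float:
        """<I[n, m]> over all bands and settings (held fixed during fitting)."""
        return float(self.I.mean())

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f["I"] = self.I
            f["R"] = self.R
            f["settings"] = self.settings
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "CalibrationDataset":
        with h5py.File(path, "r") as f:
            return cls(I=f["I"][:], R=f["R"][:], settings=f["settings"][:],
                       meta=dict(f.attrs))


@dataclass
class CalibrationResult:
    r_star: SensorResponse
    residual_norm: float
    solver_report: list  # per band: dict(nfev, status, success)


def _smoothness_terms(r: np.ndarray, weight: float = SMOOTHNESS_WEIGHT):
    """weight * Delta_r for interior wavelength pairs, plus Jacobian parts."""
    mean_r = r.mean()
    num = r[1:] - r[:-1]
    den = 0.5 * r[:-1] + 0.5 * r[1:] + mean_r
    ok = den > 1e-300
    delta = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    return weight * delta, num, den, ok, mean_r


def penalty_vector(r_n: np.ndarray | Spectrum, dataset: CalibrationDataset,
                   band: int,
                   smoothness_weight: float = SMOOTHNESS_WEIGHT) -> np.ndarray:
    """Residual vector for band ``band``: intensity residuals for all M
    settings followed by the 0.2-weighted smoothness terms."""
    r = r_n.values if isinstance(r_n, Spectrum) else np.asarray(r_n, float)
    y = dataset.I[band] / dataset.grand_mean
    resid_I = y - dataset.R @ r
    smooth, *_ = _smoothness_terms(r, smoothness_weight)
    return np.concatenate([resid_I, smooth])


def _penalty_jacobian(r: np.ndarray, dataset: CalibrationDataset,
                      smoothness_weight: float = SMOOTHNESS_WEIGHT) -> np.ndarray:
    n = r.size
    _, num, den, ok, _ = _smoothness_terms(r, smoothness_weight)
    j_smooth = np.zeros((n - 1, n))
    idx = np.arange(n - 1)
    inv_den = np.where(ok, 1.0 / np.where(ok, den, 1.0), 0.0)
    # band part: d(num)/dr
    j_smooth[idx, idx] -= inv_den
    j_smooth[idx, idx + 1] += inv_den
    # denominator part: local amplitudes plus the global mean (dense rank-1)
    common = np.where(ok, num * inv_den ** 2, 0.0)
    j_smooth[idx, idx] -= common * 0.5
    j_smooth[idx, idx + 1] -= common * 0.5
    j_smooth -= np.outer(common, np.full(n, 1.0 / n))
    return np.vstack([-dataset.R, smoothness_weight * j_smooth])


def _ridge_init(dataset: CalibrationDataset, band: int, ridge: float) -> np.ndarray:
    """Linear warm start: ridge-regularized inversion of the (linear) forward
    model, clipped at zero; flat fallback if degenerate."""
    R = dataset.R
    y = dataset.I[band] / dataset.grand_mean
    n = R.shape[1]
    try:
        sol = np.linalg.solve(R.T @ R + ridge * np.eye(n), R.T @ y)
    except np.linalg.LinAlgError:
        sol = np.full(n, y.mean() / max(R.sum(axis=1).mean(), 1e-12))
    sol = np.clip(sol, 0.0, None)
    if not np.any(sol > 0):
        sol = np.full(n, 1e-3)
    return sol


def estimate_response(dataset: CalibrationDataset, init: np.ndarray | None = None,
                      xtol: float = 1e-8, max_nfev: int = 400,
                      ridge: float = 1e-4,
                      smoothness_weight: float = SMOOTHNESS_WEIGHT) -> CalibrationResult:
    """Estimate all 16 band responses by bounded nonlinear least squares.

    Bands are solved independently; the grand-mean intensity normalization
    is computed once from the dataset and held fixed.  Non-convergence is
    reported per band in ``solver_report`` with the best iterate retained.
    """
    n_lambda = len(CANONICAL_GRID)
    r_star = np.empty((N_BANDS, n_lambda))
    report = []
    total = 0.0
    for band in range(N_BANDS):
        x0 = init[band] if init is not None else _ridge_init(dataset, band, ridge)
        x0 = np.clip(np.asarray(x0, float), 0.0, None)
        sol = least_squares(
            penalty_vector, x0,
            jac=lambda r, *a, w=smoothness_weight, d=dataset: _penalty_jacobian(r, d, w),
            args=(dataset, band, smoothness_weight), bounds=(0.0, np.inf),
            method="trf", xtol=xtol, ftol=xtol, gtol=None, max_nfev=max_nfev)
        r_star[band] = sol.x
        total += float(sol.cost)
        report.append({"band": band, "nfev": int(sol.nfev),
                       "status": int(sol.status), "success": bool(sol.success)})
    return CalibrationResult(
        r_star=SensorResponse(r_star, meta={"source": "estimate_response"}),
        residual_norm=float(np.sqrt(2.0 * total)),
        solver_report=report)


def fit_noise_model(white_stack: np.ndarray, I_max: float = 1.0) -> NoiseModel:
    """Fit per-band noise coefficients from repeated white measurements.

    ``white_stack`` has shape (n_levels, n_repeats, 16): repeated band
    intensities over time at several lamp intensity levels.  For each level
    the relative temporal variance var(I)/mean(I)^2 estimates var(eps); a
    per-band linear regression of that variance on mean intensity yields
    the intercept a_n and slope 1/b_n.
    """
    stack = np.asarray(white_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[2] != N_BANDS:
        raise ValueError("white_stack must have shape (n_levels, n_repeats, 16)")
    n_levels, n_repeats = stack.shape[:2]
    if n_levels < 2:
        raise ValueError("need >= 2 intensity levels to separate a_n from 1/b_n")
    if n_repeats < 30:
        raise ValueError("need >= 30 repeats per level for stable variances")
    mean_I = stack.mean(axis=1)  # (levels, bands)
    var_eps = stack.var(axis=1, ddof=1) / mean_I ** 2
    a = np.empty(N_BANDS)
    inv_b = np.empty(N_BANDS)
    for n in range(N_BANDS):
        design = np.column_stack([np.ones(n_levels), mean_I[:, n]])
        coef, *_ = np.linalg.lstsq(design, var_eps[:, n], rcond=None)
        a[n], inv_b[n] = coef
    a = np.clip(a, 0.0, None)
    inv_b = np.clip(inv_b, 0.0, None)
    b = np.where(inv_b > 0, 1.0 / np.where(inv_b > 0, inv_b, 1.0), np.inf)
    return NoiseModel(a=a, b=b, I_max=I_max)


def fit_lamp_variation(L_series, L_angles):
    """Derive the stable lamp spectrum and its deviation envelopes.

    Parameters
    ----------
    L_series
        Sequence of (time_minutes, Spectrum) covering the warm-up; must
        include t = 0 and t = 60 min.
    L_angles
        Mapping {angle_deg: Spectrum}; must include 0 and 22 deg.

    Returns
    -------
    (L, delta_t_max, delta_theta_max)
        Stable spectrum L = L(t=60 min, 0 deg) and the maximal fractional
        deviations delta_t_max = L(0)/L(60) - 1,
        delta_theta_max = L(22 deg)/L(0 deg) - 1.
    """
    times = {t: s for t, s in L_series}
    if 0 not in times or 60 not in times:
        raise ValueError("L_series must include t=0 and t=60 min spectra")
    if 0 not in L_angles or 22 not in L_angles:
        raise ValueError("L_angles must include 0 and 22 deg spectra")
    L = times[60]
    delta_t_max = Spectrum(times[0].values / L.values - 1.0)
    delta_theta_max = Spectrum(L_angles[22].values / L_angles[0].values - 1.0)
    return L, delta_t_max, delta_theta_max


def fit_lamp_q(L_obs: Spectrum, L: Spectrum, delta_max: Spectrum) -> float:
    """Least-squares scale factor q such that L_obs ~= L*(1 + q*delta_max)."""
    d = delta_max.values
    y = L_obs.values / L.values - 1.0
    denom = float(d @ d)
    if denom == 0:
        return 0.0
    return float(d @ y / denom)
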