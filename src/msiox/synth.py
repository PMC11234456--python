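"""Synthetic MSI spectra, training sets and test fixtures.

A single synthetic, fully-normalized MSI spectrum is produced by a six-step
procedure that chains the tissue and hardware models:

1. draw tissue parameters and compute the MC reflectance T(lambda) from the
   LUT (the *amount* of melanin, f_mel*t_epi, is randomized and divided by
   the drawn epidermis thickness to give f_mel);
2. perturb the lamp spectrum with q_t, q_theta ~ U[0, 1];
3. draw a mean detected intensity R_I ~ N(I_max/2, 0.2*I_max), truncated to
   (0.05*I_max, I_max];
4. scale the noiseless band intensities to mean R_I;
5. draw per-band noise factors eps_n with variance a_n + I[n]/b_n;
6. apply the noise.

A synthetic *white* spectrum is generated the same way with T = 1 and
independent q's, R_I and noise (white calibration happens at a different
time and angle than the measurement), and the final training input is the
doubly normalized N[n] = (I_T/I_W) / <I_T/I_W>_n with band mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .camera import (MSISpectrum, N_BANDS, NoiseModel, OpticsAndLamp,
                     SensorResponse, default_noise_model, default_optics,
                     default_sensor_response, model_intensity,
                     model_intensity_ann, normalize, sample_noise)
from .chromophores import ChromophoreSet, load_chromophores
from .mc import LutAxisSpec, ReflectanceLUT, build_lut, interpolate_T
from .spectra import CANONICAL_GRID, GRID_NM, Spectrum
from .tissue import (MUSP_RANGE, TissueParams, dermis_absorption,
                     epidermis_absorption, reduced_scattering)
from .calibration import CalibrationDataset

__all__ = [
    "ForwardModels", "ParamDistribution", "TrainingSet", "sample_params",
    "tissue_reflectance", "synthesize_spectrum", "make_split",
    "generate_training_set", "generate_lctf_fixture", "PhantomScene",
    "occlusion_release_so2", "generate_phantom_movie", "build_default_lut",
]


@dataclass
class ForwardModels:
    """The component models needed to synthesize an MSI spectrum."""

    lut: ReflectanceLUT
    response: SensorResponse
    optics: OpticsAndLamp
    noise: NoiseModel
    chromophores: ChromophoreSet

    @classmethod
    def default(cls, lut: ReflectanceLUT) -> "ForwardModels":
        return cls(lut=lut, response=default_sensor_response(),
                   optics=default_optics(), noise=default_noise_model(),
                   chromophores=load_chromophores())


def build_default_lut(n_photons_per_node: int = 20_000, seed: int = 0,
                      **kwargs) -> ReflectanceLUT:
    """Desk-scale LUT covering the default parameter-sampling ranges."""
    return build_lut(LutAxisSpec.compact(), n_photons_per_node=n_photons_per_node,
                     seed=seed, **kwargs)


@dataclass
class ParamDistribution:
    """Sampling laws for the tissue parameters.

    Each range is (low, high); ``log=True`` ranges are log-uniform.  The
    melanin *amount* (f_mel * t_epi, mm) is sampled and divided by the
    sampled epidermis thickness.  (alpha, beta) pairs are rejection-sampled
    so that mu_s'(lambda) stays inside the validated scattering range over
    the whole grid.
    """

    t_epi: tuple = (0.025, 0.3)  # mm, log-uniform
    mel_amount: tuple = (2.5e-5, 0.01)  # mm, log-uniform
    f_blood: tuple = (0.001, 0.1)  # log-uniform
    s: tuple = (0.0, 1.0)  # uniform
    d_vessel: tuple = (0.005, 0.3)  # mm, log-uniform
    alpha: tuple = (1.0, 6.0)  # mm^-1, log-uniform
    beta: tuple = (0.5, 2.5)  # uniform

    def _draw(self, rng, rng_tuple, log: bool, size=None):
        lo, hi = rng_tuple
        if log:
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
        return rng.uniform(lo, hi, size)

    def sample_one(self, rng: np.random.Generator) -> TissueParams:
        t_epi = float(self._draw(rng, self.t_epi, log=True))
        amount = float(self._draw(rng, self.mel_amount, log=True))
        f_mel = min(amount / t_epi, 1.0)
        while True:
            alpha = float(self._draw(rng, self.alpha, log=True))
            beta = float(self._draw(rng, self.beta, log=False))
            musp_lo = alpha * (GRID_NM[-1] / 600.0) ** (-beta)
            musp_hi = alpha * (GRID_NM[0] / 600.0) ** (-beta)
            if MUSP_RANGE[0] <= musp_lo and musp_hi <= MUSP_RANGE[1]:
                break
        return TissueParams(
            t_epi=t_epi, f_mel=f_mel,
            f_blood=float(self._draw(rng, self.f_blood, log=True)),
            s=float(self._draw(rng, self.s, log=False)),
            d_vessel=float(self._draw(rng, self.d_vessel, log=True)),
            alpha=alpha, beta=beta).validate()


def sample_params(dist: ParamDistribution, n: int, seed: int) -> list[TissueParams]:
    """Draw ``n`` reproducible tissue parameter sets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [dist.sample_one(rng) for _ in range(n)]


def tissue_reflectance(params: TissueParams, models: ForwardModels,
                       clip: bool = False) -> Spectrum:
    """T(lambda) for a parameter set, interpolated from the LUT."""
    musp = reduced_scattering(params.alpha, params.beta)
    mu_a_epi = epidermis_absorption(params.f_mel)
    mu_a_derm = dermis_absorption(params, models.chromophores)
    return interpolate_T(models.lut, params.t_epi, musp, mu_a_epi, mu_a_derm,
                         clip=clip)


def _draw_mean_intensity(rng: np.random.Generator, noise: NoiseModel) -> float:
    """Step 3: R_I ~ N(I_max/2, 0.2*I_max), truncated to (0.05*I_max, I_max]."""
    while True:
        r_i = rng.normal(0.5 * noise.I_max, 0.2 * noise.I_max)
        if 0.05 * noise.I_max < r_i <= noise.I_max:
            return r_i


def _noisy_pass(T: Spectrum, models: ForwardModels, rng: np.random.Generator,
                add_noise: bool, q_override=None) -> np.ndarray:
    q_t, q_theta = (rng.uniform(0.0, 1.0, 2) if q_override is None else q_override)
    noiseless = model_intensity_ann(models.response, models.optics, T,
                                    q_t, q_theta, np.zeros(N_BANDS))
    if not add_noise:
        return noiseless.values
    r_i = _draw_mean_intensity(rng, models.noise)
    scaled = r_i * noiseless.values / noiseless.values.mean()
    eps = sample_noise(models.noise, np.clip(scaled, 0, models.noise.I_max), rng)
    return scaled * (1.0 + eps)


def synthesize_spectrum(params: TissueParams, models: ForwardModels,
                        seed_or_rng, add_noise: bool = True,
                        shared_q: bool = False, clip: bool = False):
    """Synthesize one fully-normalized MSI spectrum.

    Returns ``(MSISpectrum, so2_percent)``.  With ``add_noise=False`` and
    ``shared_q=True`` the tissue and white passes see identical hardware
    states and the result reduces to the plain normalized forward model.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    T = tissue_reflectance(params, models, clip=clip)
    q = rng.uniform(0.0, 1.0, 2) if shared_q else None
    tissue = _noisy_pass(T, models, rng, add_noise, q_override=q)
    white = _noisy_pass(Spectrum(np.ones(len(CANONICAL_GRID))), models, rng,
                        add_noise, q_override=q)
    ratio = tissue / white
    n_ann = MSISpectrum(ratio / ratio.mean(), state="fully_normalized")
    return n_ann, 100.0 * params.s


def make_split(n: int, seed: int, fractions=(0.70, 0.15, 0.15)) -> dict:
    """Shuffled train/val/test index split at the stated proportions."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {"train": np.sort(perm[:n_train]),
            "val": np.sort(perm[n_train:n_train + n_val]),
            "test": np.sort(perm[n_train + n_val:])}


@dataclass
class TrainingSet:
    """Synthetic spectra X (n, 16), SO2 targets y (%), parameters and split."""

    X: np.ndarray
    y: np.ndarray
    params: np.ndarray  # (n, 7) rows: t_epi, f_mel, f_blood, s, D, alpha, beta
    split: dict

    def subset(self, which: str):
        idx = self.split[which]
        return self.X[idx], self.y[idx]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f["X"] = self.X
            f["y"] = self.y
            f["params"] = self.params
            for k, v in self.split.items():
                f[f"split/{k}"] = v

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with h5py.File(path, "r") as f:
            return cls(X=f["X"][:], y=f["y"][:], params=f["params"][:],
                       split={k: f[f"split/{k}"][:] for k in f["split"]})


def generate_training_set(dist: ParamDistribution, models: ForwardModels,
                          n: int = 50_000, seed: int = 0,
                          add_noise: bool = True) -> TrainingSet:
    """Generate ``n`` synthetic (spectrum, SO2) pairs with a 70/15/15 split."""
    rng = np.random.default_rng(seed)
    plist = sample_params(dist, n, seed=int(rng.integers(2**31 - 1)))
    X = np.empty((n, N_BANDS))
    y = np.empty(n)
    p_arr = np.empty((n, 7))
    for i, p in enumerate(plist):
        spec, so2 = synthesize_spectrum(p, models, rng, add_noise=add_noise)
        X[i] = spec.values
        y[i] = so2
        p_arr[i] = p.as_array()
    return TrainingSet(X=X, y=y, params=p_arr,
                       split=make_split(n, seed=int(rng.integers(2**31 - 1))))


# ---------------------------------------------------------------------------
# Calibration fixtures
# ---------------------------------------------------------------------------

def generate_lctf_fixture(true_response: SensorResponse, optics: OpticsAndLamp,
                          fwhm: float = 7.0, noise_level: float = 0.0,
                          seed: int = 0, gain: float = 1000.0) -> CalibrationDataset:
    """Synthetic LCTF calibration sweep, 400..700 nm in 1 nm steps.

    Each reference spectrum R_m is the lamp seen through a Gaussian LCTF
    passband of the stated FWHM, as recorded by the calibrated spectrometer
    (which does not look through the camera-side optics, so F is *not*
    applied to R_m; any camera-side filtering is part of the effective
    response being calibrated).  Band intensities follow the linear sweep
    model with optional relative Gaussian noise.  The dataset emulates
    dark-subtracted, ROI-averaged acquisition.
    """
    rng = np.random.default_rng(seed)
    lam = GRID_NM
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = lam.copy()
    base = optics.L.values
    R = np.empty((centers.size, lam.size))
    for m, c in enumerate(centers):
        R[m] = base * np.exp(-0.5 * ((lam - c) / sigma) ** 2)
    I = gain * (true_response.r @ R.T)
    if noise_level > 0:
        I = I * (1.0 + noise_level * rng.standard_normal(I.shape))
    I = np.clip(I, 0.0, None)
    return CalibrationDataset(I=I, R=R, settings=centers,
                              meta={"fwhm_nm": fwhm, "noise_level": noise_level,
                                    "seed": seed, "gain": gain})


def generate_white_stack(models: ForwardModels, levels, n_repeats: int = 200,
                         seed: int = 0) -> np.ndarray:
    """Repeated white measurements at several mean intensity levels,
    shaped (n_levels, n_repeats, 16), for noise-model fitting."""
    rng = np.random.default_rng(seed)
    white = model_intensity(models.response, models.optics,
                            Spectrum(np.ones(len(CANONICAL_GRID))))
    # normalize by the brightest band so no level saturates the ADC
    shape = white.values / white.values.max()
    out = np.empty((len(levels), n_repeats, N_BANDS))
    for i, level in enumerate(levels):
        base = level * shape
        for t in range(n_repeats):
            eps = sample_noise(models.noise, np.clip(base, 0, models.noise.I_max), rng)
            out[i, t] = base * (1.0 + eps)
    return out


# ---------------------------------------------------------------------------
# Phantom hypercube movies
# ---------------------------------------------------------------------------

@dataclass
class PhantomScene:
    """Per-pixel SO2 over time on a fixed tissue-parameter background.

    ``so2_frames`` has shape (n_frames, H, W) with SO2 as a fraction; all
    other tissue parameters are taken from ``base_params``.
    """

    so2_frames: np.ndarray
    base_params: TissueParams | None = None
    dark_offset: float = 0.02

    def __post_init__(self) -> None:
        self.so2_frames = np.asarray(self.so2_frames, dtype=float)
        if self.so2_frames.ndim != 3:
            raise ValueError("so2_frames must have shape (n_frames, H, W)")
        if self.base_params is None:
            # geometric mid-range background tissue
            self.base_params = TissueParams(
                t_epi=0.0866, f_mel=0.0058, f_blood=0.01, s=0.6,
                d_vessel=0.0387, alpha=2.449, beta=1.5)

    @classmethod
    def uniform(cls, so2: float, n_frames: int, shape=(16, 16), **kw) -> "PhantomScene":
        return cls(np.full((n_frames, *shape), so2), **kw)


def occlusion_release_so2(n_frames: int = 100, baseline: float = 0.60,
                          floor: float = 0.0, peak: float = 0.85) -> np.ndarray:
    """SO2 trajectory of an occlusion-release provocation (fractions).

    Mirrors the standard 1 min baseline / 5 min occlusion / 4 min release
    protocol: baseline for the first tenth of the frames, exponential
    desaturation that plateaus at ~0 for the remainder of the occlusion
    (superficial blood desaturates completely under a prolonged arterial
    occlusion), a rapid reperfusion overshoot to the peak, and a slow
    recovery toward baseline.
    """
    n_base = max(int(0.10 * n_frames), 1)
    n_occl = int(0.60 * n_frames)
    n_rise = max(int(0.04 * n_frames), 1)
    s = np.empty(n_frames)
    s[:n_base] = baseline
    occl = np.arange(n_occl - n_base, dtype=float)
    s[n_base:n_occl] = floor + (baseline - floor) * np.exp(-occl / (0.08 * n_frames))
    rise_end = n_occl + n_rise
    s[n_occl:rise_end] = np.linspace(s[n_occl - 1], peak, n_rise)
    rec = np.arange(n_frames - rise_end, dtype=float)
    s[rise_end:] = baseline + (peak - baseline) * np.exp(-rec / (0.30 * n_frames))
    return s


def _mosaicize(cube: np.ndarray) -> np.ndarray:
    """(16, H, W) hypercube -> (4H, 4W) mosaic frame (row-major band order)."""
    n_b, h, w = cube.shape
    frame = np.empty((4 * h, 4 * w))
    for b in range(n_b):
        frame[b // 4::4, b % 4::4] = cube[b]
    return frame


def generate_phantom_movie(scene: PhantomScene, models: ForwardModels, seed: int = 0,
                           so2_quant: float = 1e-3):
    """Render a phantom scene into raw mosaic frames plus white/dark data.

    Returns a dict with ``frames`` (list of (4H, 4W) arrays), ``white``
    (one mosaic frame), ``dark`` (one mosaic frame) and ``meta``.  Band
    intensities per pixel come from the forward model with lamp variation
    drawn per frame, detector noise per pixel/band, and a constant dark
    offset added.  SO2 values are quantized to ``so2_quant`` so the
    spectral forward model runs once per distinct level.
    """
    rng = np.random.default_rng(seed)
    n_frames, h, w = scene.so2_frames.shape
    noise = models.noise
    frames = []
    cache: dict[float, np.ndarray] = {}

    def band_values(s: float, q_t: float, q_theta: float) -> np.ndarray:
        T = cache.get(s)
        if T is None:
            p = replace(scene.base_params, s=s)
            T = tissue_reflectance(p, models, clip=True).values
            cache[s] = T
        out = model_intensity_ann(models.response, models.optics, Spectrum(T),
                                  q_t, q_theta, np.zeros(N_BANDS))
        return out.values

    for f in range(n_frames):
        q_t, q_theta = rng.uniform(0.0, 1.0, 2)
        s_q = np.round(scene.so2_frames[f] / so2_quant) * so2_quant
        cube = np.empty((N_BANDS, h, w))
        for s in np.unique(s_q):
            vals = band_values(float(s), q_t, q_theta)
            vals = 0.5 * noise.I_max * vals / vals.mean()
            cube[:, s_q == s] = vals[:, None]
        eps = rng.normal(0.0, np.sqrt(noise.variance(
            np.clip(cube, 0, noise.I_max).transpose(1, 2, 0))))
        cube = cube * (1.0 + np.maximum(eps, -0.999).transpose(2, 0, 1))
        frames.append(_mosaicize(cube) + scene.dark_offset)

    # white recording: T = 1, its own hardware state
    q_t, q_theta = rng.uniform(0.0, 1.0, 2)
    wvals = model_intensity_ann(models.response, models.optics,
                                Spectrum(np.ones(len(CANONICAL_GRID))),
                                q_t, q_theta, np.zeros(N_BANDS)).values
    wvals = 0.7 * noise.I_max * wvals / wvals.mean()
    wcube = np.broadcast_to(wvals[:, None, None], (N_BANDS, h, w)).copy()
    eps = rng.normal(0.0, np.sqrt(noise.variance(
        np.clip(wcube, 0, noise.I_max).transpose(1, 2, 0))))
    wcube = wcube * (1.0 + np.maximum(eps, -0.999).transpose(2, 0, 1))
    white = _mosaicize(wcube) + scene.dark_offset

    dark = np.full((4 * h, 4 * w), scene.dark_offset)
    return {"frames": frames, "white": white, "dark": dark,
            "meta": {"seed": seed, "n_frames": n_frames, "shape": (h, w),
                     "dark_offset": scene.dark_offset,
                     "so2_frames": scene.so2_frames}}
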