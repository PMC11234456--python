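"""Hypercube preprocessing, ROI extraction and per-pixel SO2 mapping.

Raw snapshot frames carry a recurring 4x4 band mosaic: a (4H, 4W) frame
becomes a (16, H, W) hypercube.  Preprocessing runs the four standard
steps in order:

1. subtract the nearest-in-time dark frame (ambient light / offset);
2. demosaic each band by bilinear interpolation on its own sparse lattice;
3. white-normalize with a white-reference cube processed through steps 1-2;
4. intensity-normalize each hypercube pixel by its 16-band mean.

The result has a per-pixel band mean of exactly 1 wherever the white cube
is valid, matching the normalization the estimators were trained on.

Conventions: 0-based indices, band axis first, row-major; ROI rectangles
are half-open [r0, r1) x [c0, c1); band b of the mosaic sits at row offset
b // 4 and column offset b % 4 inside each 4x4 tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .camera import MSISpectrum, N_BANDS
from .estimators import AnnModel

__all__ = [
    "RawFrame", "Hypercube", "So2Map", "demosaic", "preprocess",
    "roi_average", "so2_map", "temporal_average", "nearest_dark",
    "write_frame_tiff", "read_frame_tiff", "write_hypercube_tiff",
    "read_hypercube_tiff", "write_so2_tiff",
]


@dataclass
class RawFrame:
    """Single mosaic-patterned sensor frame."""

    pixels: np.ndarray
    exposure_ms: float = 20.0
    timestamp: float = 0.0
    kind: str = "measurement"  # measurement | white | dark

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.shape[0] % 4 or p.shape[1] % 4:
            raise ValueError("frame dimensions must be divisible by 4")
        if self.kind not in ("measurement", "white", "dark"):
            raise ValueError(f"unknown frame kind {self.kind!r}")
        self.pixels = p


@dataclass
class Hypercube:
    """(16, H, W) band stack with a normalization state."""

    values: np.ndarray
    state: str = "raw"  # raw | dark_corrected | white_normalized | fully_normalized
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != N_BANDS:
            raise ValueError("hypercube must have shape (16, H, W)")
        self.values = v
        if self.mask is None:
            self.mask = np.ones(v.shape[1:], dtype=bool)


@dataclass
class So2Map:
    """Per-pixel SO2 in percent (unclipped) with a validity mask."""

    values: np.ndarray
    mask: np.ndarray


def nearest_dark(frames: list[RawFrame], timestamp: float) -> RawFrame:
    """Dark frame nearest in time; ties broken toward the earlier frame."""
    darks = [f for f in frames if f.kind == "dark"]
    if not darks:
        raise ValueError("no dark frames available")
    return min(darks, key=lambda f: (abs(f.timestamp - timestamp), f.timestamp))


def demosaic(frame: RawFrame) -> Hypercube:
    """Interpolate each band's sparse mosaic samples to the hypercube grid.

    Band b is sampled at mosaic sites (4i + b//4, 4j + b%4); each band is
    bilinearly interpolated on its own lattice to the common tile-center
    positions (4i + 1.5, 4j + 1.5), with linear extrapolation at the
    borders so affine images are reproduced exactly everywhere.
    """
    p = frame.pixels
    h, w = p.shape[0] // 4, p.shape[1] // 4
    cube = np.empty((N_BANDS, h, w))
    ii, jj = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    for b in range(N_BANDS):
        dr, dc = b // 4, b % 4
        lattice = p[dr::4, dc::4]
        interp = RegularGridInterpolator(
            (np.arange(h, dtype=float), np.arange(w, dtype=float)), lattice,
            method="linear", bounds_error=False, fill_value=None)
        # tile centre (4i+1.5) in this band's lattice index coordinates
        u = ii + (1.5 - dr) / 4.0
        v = jj + (1.5 - dc) / 4.0
        cube[b] = interp(np.stack([u.ravel(), v.ravel()], axis=1)).reshape(h, w)
    return Hypercube(cube, state="raw")


def _dark_corrected_cube(frame: RawFrame, dark: RawFrame) -> Hypercube:
    sub = np.clip(frame.pixels - dark.pixels, 0.0, None)
    cube = demosaic(RawFrame(sub, frame.exposure_ms, frame.timestamp, frame.kind))
    cube.state = "dark_corrected"
    return cube


def preprocess(measurement: RawFrame, darks: list[RawFrame] | RawFrame,
               white: RawFrame, dark_for_white: RawFrame | None = None) -> Hypercube:
    """Run preprocessing steps 1-4 on a measurement frame.

    ``darks`` may be a single dark frame or a list searched nearest-in-time.
    The white frame is processed through steps 1-2 itself (using
    ``dark_for_white``, or the same nearest dark).  Pixels whose white
    spectrum contains a non-positive band are masked out.
    """
    if isinstance(darks, RawFrame):
        dark = darks
    else:
        dark = nearest_dark(darks, measurement.timestamp)
    dark_w = dark_for_white if dark_for_white is not None else dark
    meas = _dark_corrected_cube(measurement, dark)
    wcube = _dark_corrected_cube(white, dark_w)

    valid = np.all(wcube.values > 0, axis=0)
    ratio = np.where(wcube.values > 0, meas.values / np.where(
        wcube.values > 0, wcube.values, 1.0), 0.0)
    band_mean = ratio.mean(axis=0)
    valid &= band_mean > 0
    out = np.where(band_mean > 0, ratio / np.where(band_mean > 0, band_mean, 1.0), 0.0)
    return Hypercube(out, state="fully_normalized", mask=valid)


def roi_average(cube: Hypercube, roi: tuple[int, int, int, int]) -> MSISpectrum:
    """Spatial mean spectrum of a half-open [r0, r1) x [c0, c1) ROI,
    re-normalized to band mean 1."""
    r0, c0, r1, c1 = roi
    h, w = cube.values.shape[1:]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} outside image {h}x{w}")
    spec = cube.values[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return MSISpectrum(spec / spec.mean(), state="fully_normalized")


def so2_map(cube: Hypercube, model: AnnModel) -> So2Map:
    """Vectorized ANN prediction over all masked pixels of a normalized cube."""
    if cube.state != "fully_normalized":
        raise ValueError("so2_map requires a fully_normalized hypercube")
    h, w = cube.values.shape[1:]
    flat = cube.values.reshape(N_BANDS, -1).T
    out = np.full(h * w, np.nan)
    m = cube.mask.ravel()
    out[m] = model.predict(flat[m])
    return So2Map(values=out.reshape(h, w), mask=cube.mask.copy())


def temporal_average(frames: list[RawFrame], window: int = 8) -> RawFrame:
    """Elementwise mean of the first ``window`` frames (on-the-fly averaging
    of consecutive snapshots reduces temporal noise ~window-fold)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(frames) < window:
        raise ValueError("not enough frames for the requested window")
    sel = frames[:window]
    pix = np.mean([f.pixels for f in sel], axis=0)
    return RawFrame(pix, exposure_ms=sel[0].exposure_ms,
                    timestamp=float(np.mean([f.timestamp for f in sel])),
                    kind=sel[0].kind)


# ---------------------------------------------------------------------------
# TIFF interchange
# ---------------------------------------------------------------------------

def write_frame_tiff(path, frame: RawFrame) -> None:
    """Store a mosaic frame as 16-bit grayscale TIFF (intensities are
    scaled by 65535, i.e. I_max = 1.0 maps to full scale)."""
    import tifffile

    data = np.clip(frame.pixels, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535.0 + 0.5).astype(np.uint16),
                     metadata={"exposure_ms": frame.exposure_ms,
                               "timestamp": frame.timestamp,
                               "kind": frame.kind})


def read_frame_tiff(path, kind: str = "measurement",
                    timestamp: float = 0.0) -> RawFrame:
    import tifffile

    data = tifffile.imread(path).astype(float) / 65535.0
    return RawFrame(data, timestamp=timestamp, kind=kind)


def write_hypercube_tiff(path, cube: Hypercube) -> None:
    """One 32-bit float page per band (16 pages)."""
    import tifffile

    tifffile.imwrite(path, cube.values.astype(np.float32),
                     metadata={"state": cube.state})


def read_hypercube_tiff(path, state: str = "raw") -> Hypercube:
    import tifffile

    return Hypercube(tifffile.imread(path).astype(float), state=state)


def write_so2_tiff(path, so2: So2Map) -> None:
    """32-bit float SO2 map in percent; masked pixels are NaN."""
    import tifffile

    out = np.where(so2.mask, so2.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, out)
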