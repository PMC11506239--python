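"""Mask-restricted spatial smoothing, temporal filtering and normalization.

All operations take and return :class:`~fpetbold.series.FrameSeries`; voxels
outside the brain mask are left at 0.  The high-pass is a discrete-cosine
basis projection (removes periods longer than the cutoff, keeps the mean);
the low-pass is a zero-phase 4th-order Butterworth.  Default order in the
pipeline is smooth -> normalize -> filter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .phantom import RegionAtlas
from .series import FrameSeries

__all__ = [
    "smooth_gaussian",
    "highpass",
    "lowpass",
    "cerebellum_normalize",
    "wholebrain_normalize",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(series: FrameSeries, fwhm_mm) -> FrameSeries:
    """Frame-wise 3D Gaussian smoothing, mask-normalized.

    ``fwhm_mm`` is the kernel full width at half maximum per axis in mm (a
    scalar applies to all three axes).  Mask normalization divides the
    smoothed masked data by the smoothed mask so that constants are
    preserved inside the brain and no intensity bleeds in from background.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm <= 0):
        raise ValueError("FWHM must be positive")
    sigma_vox = fwhm * _FWHM_TO_SIGMA / np.asarray(series.voxel_size)
    mask = series.brain_mask
    smooth_mask = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.zeros_like(series.data)
    for t in range(series.n_frames):
        frame = np.where(mask, series.data[..., t], 0.0)
        sm = ndimage.gaussian_filter(frame, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            normed = np.where(smooth_mask > 1e-12, sm / smooth_mask, 0.0)
        out[..., t] = np.where(mask, normed, 0.0)
    return series.with_data(out)


def dct_basis(n_frames: int, frame_duration: float, cutoff_period: float
              ) -> np.ndarray:
    """Low-frequency DCT-II regressors with period > ``cutoff_period`` s."""
    total = n_frames * frame_duration
    n_basis = int(np.floor(2.0 * total / cutoff_period))
    k = np.arange(1, max(n_basis, 0) + 1)
    n = np.arange(n_frames)
    # column k has period 2*total/k
    return np.cos(np.pi * np.outer(n + 0.5, k) / n_frames)


def highpass(series: FrameSeries, cutoff_period: float = 256.0) -> FrameSeries:
    """Remove slow components (period > cutoff) by DCT-basis regression.

    The temporal mean is retained, so a constant series passes unchanged.
    Idempotent: applying the filter twice equals applying it once.
    """
    if series.n_frames < 4:
        raise ValueError("need at least 4 frames to high-pass filter")
    basis = dct_basis(series.n_frames, series.timing.frame_duration, cutoff_period)
    mask = series.brain_mask
    y = series.data[mask]  # (voxels, frames)
    mean = y.mean(axis=1, keepdims=True)
    if basis.shape[1] > 0:
        q, _ = np.linalg.qr(basis - basis.mean(axis=0, keepdims=True))
        resid = (y - mean) - ((y - mean) @ q) @ q.T
    else:
        resid = y - mean
    out = np.zeros_like(series.data)
    out[mask] = resid + mean
    return series.with_data(out)


def lowpass(series: FrameSeries, cutoff_period: float = 300.0) -> FrameSeries:
    """Zero-phase Butterworth low-pass attenuating periods below the cutoff.

    The default 300-s cutoff is half the 10-min task-block duration, chosen
    to suppress frame-to-frame noise while leaving the slow uptake ramp and
    block-scale task response intact.
    """
    if series.n_frames < 16:
        raise ValueError("too few frames to low-pass filter")
    fs = 1.0 / series.timing.frame_duration
    wn = (1.0 / cutoff_period) / (fs / 2.0)
    if not 0 < wn < 1:
        raise ValueError(
            f"cutoff period {cutoff_period}s not resolvable at {fs} Hz sampling"
        )
    b, a = signal.butter(4, wn)
    mask = series.brain_mask
    out = np.zeros_like(series.data)
    out[mask] = signal.filtfilt(b, a, series.data[mask], axis=-1)
    return series.with_data(out)


def cerebellum_normalize(series: FrameSeries, atlas: RegionAtlas) -> FrameSeries:
    """Divide every frame by that frame's cerebellum mean (reference-region
    intensity normalization); the cerebellar TAC becomes identically 1."""
    ref = atlas.mask("cerebellum") & series.brain_mask
    if not ref.any():
        raise ValueError("cerebellum region is empty")
    ref_course = series.data[ref].mean(axis=0)
    if np.any(ref_course == 0):
        raise ValueError("zero cerebellum mean in at least one frame")
    out = np.zeros_like(series.data)
    out[series.brain_mask] = series.data[series.brain_mask] / ref_course
    return series.with_data(out)


def wholebrain_normalize(series: FrameSeries) -> FrameSeries:
    """Divide every frame by its in-mask mean, yielding the relative
    (time-activity) uptake map; the global uptake course divides out and
    only regional deviations remain."""
    mask = series.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    mean_course = series.data[mask].mean(axis=0)
    if np.any(mean_course == 0):
        raise ValueError("zero in-mask mean in at least one frame")
    out = np.zeros_like(series.data)
    out[mask] = series.data[mask] / mean_course
    return series.with_data(out)
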