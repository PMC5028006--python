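"""Movie preprocessing: ΔF/F, smoothing, high-pass, trim, SNR masking.

The stages run in a fixed order mirroring the acquisition pipeline:

1. per-pixel baseline normalisation (ΔF/F over the sequence mean),
2. temporal moving average (default 4 frames),
3. spatial moving average (default 8×8 pixels, mask-aware),
4. zero-phase high-pass filter (default 0.5 Hz, 2nd-order Butterworth),
5. trim of the initial segment (default 10 s).

:func:`preprocess_movie` applies the full chain and stamps the output
with a hash of the applied configuration.  Individual stages are exposed
for testing and reuse; when a mask is supplied, spatial smoothing
renormalises its window over included pixels only, so excluded pixels
never leak into downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import Mask, VoltageMovie
from .utils import config_hash

__all__ = [
    "PreprocessConfig",
    "baseline_normalize",
    "smooth_temporal",
    "smooth_spatial",
    "highpass",
    "trim_initial",
    "build_mask",
    "preprocess_movie",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (defaults match 50 Hz data)."""

    temporal_window: int = 4      # frames
    spatial_kernel: int = 8       # pixels (square averaging filter)
    highpass_hz: float = 0.5
    trim_s: float = 10.0
    snr_fraction: float = 0.5

    def to_dict(self) -> dict:
        return {
            "temporal_window": self.temporal_window,
            "spatial_kernel": self.spatial_kernel,
            "highpass_hz": self.highpass_hz,
            "trim_s": self.trim_s,
            "snr_fraction": self.snr_fraction,
        }


def baseline_normalize(movie: VoltageMovie) -> VoltageMovie:
    """ΔF/F: per pixel, (value − baseline) / baseline with the temporal mean as baseline.

    Pixels whose baseline is exactly zero are degenerate (no fluorescence);
    their output is set to zero and a warning is emitted.
    """
    if movie.n_frames < 2:
        raise ValueError("baseline normalisation needs at least 2 frames")
    baseline = movie.data.mean(axis=0, keepdims=True)
    zero = baseline == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} pixel(s) have zero baseline; output set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, baseline)
    out = (movie.data - baseline) / safe
    out[np.broadcast_to(zero, out.shape)] = 0.0
    return movie.copy_with(out, baseline_normalized=True)


def smooth_temporal(movie: VoltageMovie, window: int = 4) -> VoltageMovie:
    """Centred moving average along time with renormalised edge windows."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > movie.n_frames:
        raise ValueError(f"window {window} exceeds movie length {movie.n_frames}")
    if window == 1:
        return movie.copy_with(movie.data.copy())
    kern = np.ones(window)
    num = ndimage.convolve1d(movie.data, kern, axis=0, mode="constant", cval=0.0)
    den = ndimage.convolve1d(
        np.ones(movie.n_frames), kern, mode="constant", cval=0.0
    )[:, None, None]
    return movie.copy_with(num / den, temporal_window=window)


def smooth_spatial(
    movie: VoltageMovie, kernel: int = 8, mask: Mask | None = None
) -> VoltageMovie:
    """Per-frame square moving average with renormalised partial windows.

    With a mask, the average runs over included pixels only (excluded
    pixels carry zero weight) and excluded pixels are zeroed in the
    output, so no information crosses the mask boundary.
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    h, w = movie.frame_shape
    if kernel > h or kernel > w:
        raise ValueError(f"kernel {kernel} larger than frame {h}x{w}")
    if mask is not None and mask.shape != (h, w):
        raise ValueError("mask shape does not match movie frames")
    weights = np.ones((h, w)) if mask is None else mask.include.astype(float)
    kern = np.ones(kernel)

    def box2d(a: np.ndarray) -> np.ndarray:
        a = ndimage.convolve1d(a, kern, axis=-2, mode="constant", cval=0.0)
        return ndimage.convolve1d(a, kern, axis=-1, mode="constant", cval=0.0)

    num = box2d(movie.data * weights)
    den = box2d(weights)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if mask is not None:
        out *= mask.include
    return movie.copy_with(out, spatial_kernel=kernel)


def highpass(movie: VoltageMovie, cutoff_hz: float = 0.5, order: int = 2) -> VoltageMovie:
    """Zero-phase Butterworth high-pass along time (forward–backward).

    Zero-phase filtering avoids shifting event onsets, which the cascade
    timing downstream depends on.
    """
    nyquist = movie.frame_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=movie.frame_rate, output="sos")
    out = signal.sosfiltfilt(sos, movie.data, axis=0)
    return movie.copy_with(np.ascontiguousarray(out), highpass_hz=cutoff_hz)


def trim_initial(movie: VoltageMovie, duration_s: float = 10.0) -> VoltageMovie:
    """Drop the first ``round(duration_s × frame_rate)`` frames."""
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    n_drop = int(round(duration_s * movie.frame_rate))
    if n_drop >= movie.n_frames:
        raise ValueError(
            f"trim of {duration_s} s removes all {movie.n_frames} frames"
        )
    return movie.copy_with(movie.data[n_drop:].copy(), trimmed_s=duration_s)


def build_mask(
    mean_intensity: np.ndarray,
    manual_mask: Mask | None = None,
    snr_fraction: float = 0.5,
) -> Mask:
    """SNR mask: keep pixels whose mean intensity reaches a fraction of the maximum.

    The maximum is taken over the manual mask when one is given (the
    field of view), else over the whole frame; the result is intersected
    with the manual mask.
    """
    intensity = np.asarray(mean_intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("mean_intensity must be 2-D")
    if not np.all(np.isfinite(intensity)) or np.any(intensity < 0):
        raise ValueError("mean_intensity must be finite and non-negative")
    if not 0.0 <= snr_fraction <= 1.0:
        raise ValueError("snr_fraction must be in [0, 1]")
    if manual_mask is not None:
        if manual_mask.shape != intensity.shape:
            raise ValueError("manual mask shape mismatch")
        fov = manual_mask.include
    else:
        fov = np.ones_like(intensity, dtype=bool)
    peak = intensity[fov].max()
    include = fov & (intensity >= snr_fraction * peak)
    if not include.any():
        raise ValueError(
            f"SNR criterion at fraction {snr_fraction} excludes every pixel "
            f"(peak intensity {peak:g})"
        )
    provenance = "combined" if manual_mask is not None else "snr"
    return Mask(include, provenance=provenance)


def preprocess_movie(
    movie: VoltageMovie,
    mask: Mask | None = None,
    config: PreprocessConfig | None = None,
) -> VoltageMovie:
    """Full preprocessing chain in fixed order; output carries the config hash.

    Order: ΔF/F → temporal smooth → spatial smooth → high-pass → trim.
    """
    cfg = config or PreprocessConfig()
    out = baseline_normalize(movie)
    out = smooth_temporal(out, cfg.temporal_window)
    out = smooth_spatial(out, cfg.spatial_kernel, mask=mask)
    out = highpass(out, cfg.highpass_hz)
    if cfg.trim_s > 0:
        out = trim_initial(out, cfg.trim_s)
    out.meta["preprocess_hash"] = config_hash(cfg.to_dict())
    return out
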