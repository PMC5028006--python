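"""Canonical dynamical-regime samples used for validation.

Three cascade-size samples span the regimes the κ statistic is designed
to discriminate:

* :func:`critical_size_sample` — one long sparse-drive simulation at
  branching parameter 1.0; sizes close to a power law with exponent −1.5
  (κ ≈ 1).
* :func:`supercritical_size_sample` — branching parameter 1.4, pooled
  over many short independent sequences.  Sustained supercritical drive
  on a finite lattice enters an endemic phase in which all activity
  merges into a single component, so the anesthetized-like regime of
  abundant large-but-finite cascades is emulated as short bursts, each
  detected independently and pooled (cascade detection per sequence with
  pooled size distributions, as for real image sequences).  κ > 1.
* :func:`noise_size_sample` — spectrum-matched pixel-wise independent
  noise pushed through the full preprocessing and point-process
  pipeline; spatial smoothing imposes a characteristic cascade scale
  with a deficient large-size tail, κ < 1.

The parameter values here are frozen study conditions; change them only
by deliberate redesign, not per analysis.
"""

from __future__ import annotations

import warnings

import numpy as np

from .cascades import detect_cascades, sizes_of
from .pointprocess import to_point_process
from .preprocess import preprocess_movie
from .synthetic import (
    NoiseSpec,
    SimulationConfig,
    generate_noise_movie,
    one_over_f_spectrum,
    simulate_branching_cascades,
)
from .utils import spawn_seeds

__all__ = [
    "critical_size_sample",
    "supercritical_size_sample",
    "noise_size_sample",
]


def critical_size_sample(
    seed: int = 0,
    grid: int = 64,
    n_frames: int = 6000,
    drive_rate: float = 7e-4,
) -> np.ndarray:
    """Cascade sizes from one critical (branching = 1.0) simulation.

    The defaults yield well over 10^4 cascades with the active-pixel
    rate near 1% of pixels per frame.
    """
    cfg = SimulationConfig(
        grid_height=grid,
        grid_width=grid,
        n_frames=n_frames,
        branching_param=1.0,
        drive_rate=drive_rate,
        seed=seed,
    )
    pp, _, _ = simulate_branching_cascades(cfg)
    return sizes_of(detect_cascades(pp)).sizes


def supercritical_size_sample(
    seed: int = 0,
    grid: int = 64,
    n_windows: int = 200,
    window_frames: int = 40,
    drive_rate: float = 2e-4,
    branching_param: float = 1.4,
) -> np.ndarray:
    """Pooled cascade sizes from short supercritical burst sequences.

    Each sequence starts from an empty lattice; cascades are detected
    per sequence and the size samples pooled, mirroring per-sequence
    detection with pooled distributions on real data.
    """
    seeds = spawn_seeds(seed, n_windows)
    sizes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in seeds:
            cfg = SimulationConfig(
                grid_height=grid,
                grid_width=grid,
                n_frames=window_frames,
                branching_param=branching_param,
                drive_rate=drive_rate,
                seed=s,
            )
            pp, _, _ = simulate_branching_cascades(cfg)
            sizes.append(sizes_of(detect_cascades(pp)).sizes)
    return np.concatenate(sizes)


def noise_size_sample(
    seed: int = 0,
    grid: int = 64,
    n_frames: int = 2500,
    frame_rate: float = 50.0,
    spectrum_exponent: float = 1.0,
    threshold_sd: float = 1.0,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Cascade sizes of the full-pipeline noise control.

    A 1/f-spectrum pixel-wise independent noise movie, scaled to 5%
    fractional fluctuations around a unit fluorescence baseline, is
    preprocessed (ΔF/F, 4-frame and 8×8 smoothing, 0.5 Hz high-pass,
    10 s trim) and converted to +1 S.D. crossing events before cascade
    detection.
    """
    spec = NoiseSpec(
        n_frames=n_frames,
        frame_rate=frame_rate,
        seed=seed,
        template_spectrum=one_over_f_spectrum(n_frames, frame_rate, spectrum_exponent),
    )
    movie = generate_noise_movie(spec, grid, grid)
    sd = movie.data.std()
    scale = noise_sd / sd if sd > 0 else 0.0
    movie = movie.copy_with(movie.data * scale + 1.0)
    pre = preprocess_movie(movie)
    pp = to_point_process(pre, threshold_sd=threshold_sd)
    return sizes_of(detect_cascades(pp)).sizes
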