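"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators are provided:

* :func:`simulate_branching_cascades` — a branching process on a pixel
  lattice.  Each spontaneous seed event starts a cascade; every active
  pixel independently attempts to activate each of its 4 von-Neumann
  neighbours in the next frame with probability ``branching_param / 4``,
  so the expected offspring count per active pixel equals the branching
  parameter σ.  σ = 1 is critical (cascade sizes near a power law with
  exponent −1.5), σ > 1 supercritical (excess large cascades), σ < 1
  subcritical.
* :func:`generate_noise_movie` — pixel-wise independent noise whose
  per-pixel expected one-sided power spectrum equals a prescribed
  template (inverse FFT of the template amplitude with i.i.d. uniform
  random phases).  This is the control dataset: it matches single-pixel
  temporal statistics while destroying all interactions between pixels.
* :func:`render_voltage_movie` — turns a binary event movie into a
  continuous fluorescence movie by convolving each event with a temporal
  response kernel and adding scaled noise, so the full preprocessing +
  thresholding chain can be exercised end to end.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Mask, PointProcessMovie, VoltageMovie
from .utils import UnionFind

__all__ = [
    "SimulationConfig",
    "NoiseSpec",
    "simulate_branching_cascades",
    "simulate_burst_sequence",
    "generate_noise_movie",
    "one_over_f_spectrum",
    "exponential_kernel",
    "render_voltage_movie",
]

#: fraction of the grid simultaneously active above which a frame counts
#: as saturated (interference then distorts the branching statistics)
SATURATION_FRACTION = 0.5


@dataclass
class SimulationConfig:
    """Parameters of the lattice branching process.

    Parameters
    ----------
    grid_height, grid_width : int
        Lattice dimensions in pixels (>= 1).
    n_frames : int
        Number of frames to simulate (>= 1).
    frame_rate : float
        Nominal acquisition rate in Hz (metadata for downstream stages).
    branching_param : float
        Expected number of next-frame activations caused by one active
        pixel (sigma >= 0); 1 is critical.
    drive_rate : float
        Probability per pixel per frame of a spontaneous seed event.
        The default keeps activity sparse (about 1% of pixels active per
        frame at criticality on a 64x64 grid).
    seed : int
        RNG seed; identical seeds give bit-identical simulations.
    """

    grid_height: int
    grid_width: int
    n_frames: int
    frame_rate: float = 50.0
    branching_param: float = 1.0
    drive_rate: float = 7e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_height < 1 or self.grid_width < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.branching_param < 0:
            raise ValueError("branching_param must be >= 0")
        if not 0.0 <= self.drive_rate <= 1.0:
            raise ValueError("drive_rate must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


# spatial adjacency used for both spreading and ground-truth merging
_NEIGHBOUR_SHIFTS = ((1, 0), (-1, 0), (0, 1), (0, -1))
# spatio-temporal offsets (dt=0 spatial handled separately; dt=1 below)
_DT1_SHIFTS = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1))


def _shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D array by (dy, dx), zero-filling exposed borders."""
    out = np.zeros_like(a)
    h, w = a.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = a[ys_src, xs_src]
    return out


def _collect_pairs(a: np.ndarray, b: np.ndarray, bucket: list) -> None:
    """Record label pairs where two labelled arrays overlap with different ids."""
    both = (a > 0) & (b > 0) & (a != b)
    if both.any():
        pairs = np.stack([a[both], b[both]], axis=1)
        bucket.append(np.unique(pairs, axis=0))


def simulate_branching_cascades(
    config: SimulationConfig,
) -> tuple[PointProcessMovie, np.ndarray, dict]:
    """Simulate lattice branching cascades with ground-truth labels.

    Returns
    -------
    pp : PointProcessMovie
        Binary event movie (T, H, W).
    labels : ndarray of int32, same shape
        Ground-truth cascade id per event (0 = no event).  Labels are
        connected components under the same spatio-temporal adjacency
        the cascade detector uses: two cascades whose events touch
        (|dt| <= 1 and same pixel or 4-neighbours) are merged into one
        label, and each such merge is counted as a collision.
    meta : dict
        ``n_cascades``, ``n_events``, ``collisions``, ``saturated``,
        ``max_active_fraction``, ``active_fraction`` (mean), ``seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w, t_total = cfg.grid_height, cfg.grid_width, cfg.n_frames
    p_child = min(cfg.branching_param / 4.0, 1.0)

    events = np.zeros((t_total, h, w), dtype=bool)
    labels = np.zeros((t_total, h, w), dtype=np.int64)
    uf = UnionFind(0)
    next_id = 1
    pair_bucket: list = []
    max_active = 0.0

    prev_lab = np.zeros((h, w), dtype=np.int64)
    for t in range(t_total):
        new_lab = np.zeros((h, w), dtype=np.int64)
        prev_active = prev_lab > 0
        if p_child > 0 and prev_active.any():
            for dy, dx in _NEIGHBOUR_SHIFTS:
                attempt = prev_active & (rng.random((h, w)) < p_child)
                child = _shift2d(np.where(attempt, prev_lab, 0), dy, dx)
                free = (child > 0) & (new_lab == 0)
                new_lab[free] = child[free]
        seeds = rng.random((h, w)) < cfg.drive_rate
        seed_new = seeds & (new_lab == 0)
        n_new = int(seed_new.sum())
        if n_new:
            new_lab[seed_new] = np.arange(next_id, next_id + n_new)
            uf.grow(n_new)
            next_id += n_new
        # spatio-temporal adjacency between distinct lineages -> merge later
        _collect_pairs(new_lab, _shift2d(new_lab, 0, 1), pair_bucket)
        _collect_pairs(new_lab, _shift2d(new_lab, 1, 0), pair_bucket)
        for dy, dx in _DT1_SHIFTS:
            _collect_pairs(new_lab, _shift2d(prev_lab, dy, dx), pair_bucket)
        labels[t] = new_lab
        events[t] = new_lab > 0
        max_active = max(max_active, events[t].mean())
        prev_lab = new_lab

    collisions = 0
    if pair_bucket:
        for a, b in np.unique(np.concatenate(pair_bucket, axis=0), axis=0):
            if uf.union(int(a), int(b)):
                collisions += 1
    roots = uf.roots()
    # compress merged ids to consecutive 1..n
    used = np.unique(roots[1:]) if next_id > 1 else np.array([], dtype=np.int64)
    remap = np.zeros(next_id, dtype=np.int64)
    remap[used] = np.arange(1, len(used) + 1)
    labels = remap[roots[labels]]
    n_cascades = len(used)

    saturated = max_active >= SATURATION_FRACTION
    if saturated:
        warnings.warn(
            f"activity saturated the grid (max active fraction {max_active:.2f})",
            RuntimeWarning,
            stacklevel=2,
        )
    meta = {
        "n_cascades": int(n_cascades),
        "n_events": int(events.sum()),
        "collisions": int(collisions),
        "saturated": bool(saturated),
        "max_active_fraction": float(max_active),
        "active_fraction": float(events.mean()),
        "branching_param": cfg.branching_param,
        "drive_rate": cfg.drive_rate,
        "seed": cfg.seed,
    }
    pp = PointProcessMovie(
        events,
        cfg.frame_rate,
        mask=Mask.full(h, w),
        meta=dict(meta),
    )
    return pp, labels.astype(np.int32), meta


def simulate_burst_sequence(
    config: SimulationConfig, n_segments: int
) -> PointProcessMovie:
    """Concatenation of independent burst segments into one event movie.

    Each segment is a fresh simulation (``config.n_frames`` frames,
    starting from an empty lattice) with its own seed spawned from
    ``config.seed``.  In the supercritical regime this emulates bursty,
    slow-wave-like dynamics — large cascades that terminate — instead of
    the endemic phase a continuously driven supercritical lattice
    enters, in which all activity merges into a single component.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    from .utils import spawn_seeds

    seeds = spawn_seeds(config.seed, n_segments)
    chunks = []
    for s in seeds:
        seg_cfg = SimulationConfig(
            grid_height=config.grid_height,
            grid_width=config.grid_width,
            n_frames=config.n_frames,
            frame_rate=config.frame_rate,
            branching_param=config.branching_param,
            drive_rate=config.drive_rate,
            seed=s,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pp, _, _ = simulate_branching_cascades(seg_cfg)
        chunks.append(pp.events)
    events = np.concatenate(chunks, axis=0)
    return PointProcessMovie(
        events,
        config.frame_rate,
        mask=Mask.full(config.grid_height, config.grid_width),
        meta={"n_segments": n_segments, "segment_frames": config.n_frames},
    )


@dataclass
class NoiseSpec:
    """Template for spectrum-matched pixel-wise noise.

    Parameters
    ----------
    template_spectrum : ndarray, optional
        One-sided power values on the rfft frequency grid of ``n_frames``
        samples (length ``n_frames // 2 + 1``, all >= 0).  Exactly one of
        ``template_spectrum`` and ``reference_trace`` must be given.
    reference_trace : ndarray, optional
        A 1-D trace from which the template spectrum is measured as the
        periodogram, mimicking noise matched to recorded data.
    n_frames : int
    frame_rate : float
    seed : int
    """

    n_frames: int
    frame_rate: float = 50.0
    seed: int = 0
    template_spectrum: np.ndarray | None = None
    reference_trace: np.ndarray | None = None
    _spectrum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if (self.template_spectrum is None) == (self.reference_trace is None):
            raise ValueError("give exactly one of template_spectrum or reference_trace")
        n_bins = self.n_frames // 2 + 1
        if self.reference_trace is not None:
            trace = np.asarray(self.reference_trace, dtype=float)
            if trace.ndim != 1 or len(trace) != self.n_frames:
                raise ValueError("reference_trace must be 1-D of length n_frames")
            spec = np.abs(np.fft.rfft(trace)) ** 2 / self.n_frames
        else:
            spec = np.asarray(self.template_spectrum, dtype=float)
            if spec.ndim != 1 or len(spec) != n_bins:
                raise ValueError(
                    f"template_spectrum must have length n_frames//2+1 = {n_bins}"
                )
        if np.any(spec < 0):
            raise ValueError("spectrum values must be >= 0")
        self._spectrum = spec

    @property
    def spectrum(self) -> np.ndarray:
        return self._spectrum


def generate_noise_movie(spec: NoiseSpec, grid_height: int, grid_width: int) -> VoltageMovie:
    """Pixel-wise independent noise with a prescribed expected power spectrum.

    Each pixel's trace is synthesised by inverse rFFT of the template
    amplitude with independent uniform random phases, so its expected
    one-sided periodogram equals the template exactly; distinct pixels
    use independent phases and are mutually independent.
    """
    if grid_height < 1 or grid_width < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(spec.seed)
    t_total = spec.n_frames
    n_bins = t_total // 2 + 1
    amp = np.sqrt(spec.spectrum * t_total)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(grid_height, grid_width, n_bins))
    coeff = amp * np.exp(1j * phases)
    # DC and (for even T) Nyquist bins must be real for a real signal
    coeff[..., 0] = amp[0]
    if t_total % 2 == 0:
        coeff[..., -1] = amp[-1] * np.sign(np.cos(phases[..., -1]))
    traces = np.fft.irfft(coeff, n=t_total, axis=-1)
    data = np.moveaxis(traces, -1, 0).astype(np.float64)
    return VoltageMovie(
        data,
        spec.frame_rate,
        meta={"source": "spectrum_matched_noise", "seed": spec.seed},
    )


def one_over_f_spectrum(
    n_frames: int, frame_rate: float, exponent: float = 1.0, power_at_1hz: float = 1.0
) -> np.ndarray:
    """One-sided 1/f^exponent power template on the rfft grid (DC set to 0)."""
    freqs = np.fft.rfftfreq(n_frames, d=1.0 / frame_rate)
    spec = np.zeros_like(freqs)
    nz = freqs > 0
    spec[nz] = power_at_1hz / freqs[nz] ** exponent
    return spec


def exponential_kernel(tau_s: float, frame_rate: float, n_taus: float = 5.0) -> np.ndarray:
    """Causal exponentially decaying response kernel, peak value 1."""
    n = max(int(round(n_taus * tau_s * frame_rate)), 1)
    t = np.arange(n) / frame_rate
    return np.exp(-t / tau_s)


def render_voltage_movie(
    events: PointProcessMovie,
    kernel: np.ndarray,
    noise: VoltageMovie | None = None,
    noise_amplitude: float = 0.0,
    baseline: float = 1.0,
) -> VoltageMovie:
    """Render events into a fluorescence movie: kernel convolution + noise.

    Each event at (t, y, x) contributes ``kernel`` to that pixel's trace
    starting at frame t (causal temporal convolution); the scaled noise
    movie and a constant baseline are added so the result behaves like a
    raw fluorescence movie (positive baseline with fractional deviations).
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size < 1:
        raise ValueError("kernel must be a non-empty 1-D array")
    if not np.all(np.isfinite(kernel)):
        raise ValueError("kernel must be finite")
    if noise is not None and noise.data.shape != events.events.shape:
        raise ValueError(
            f"noise shape {noise.data.shape} does not match events {events.events.shape}"
        )
    t_total = events.n_frames
    from scipy.signal import fftconvolve

    sig = fftconvolve(
        events.events.astype(np.float64), kernel[:, None, None], axes=0
    )[:t_total]
    if noise is not None and noise_amplitude != 0.0:
        sig = sig + noise_amplitude * noise.data
    sig = sig + baseline
    return VoltageMovie(
        sig,
        events.frame_rate,
        meta={"source": "rendered", "kernel_len": int(kernel.size)},
    )
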