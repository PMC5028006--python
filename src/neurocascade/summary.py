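"""Metric time courses, correlation summaries and distribution plots.

This module assembles per-window values of the pipeline's metrics
(κ, H_state, H_trans, mean H_reg, mean κ_reg, total IT) into a tidy
time course, reports Pearson correlations of each metric against a
covariate (typically time), and renders cascade-size distribution plots
with the −1.5 power-law reference overlaid.

It also provides two fixed-seed simulation suites:

* :func:`simulate_recovery_suite` — windows whose branching parameter
  steps from supercritical (1.4) to critical (1.0), emulating recovery
  from anesthesia; each window is rendered into a fluorescence movie
  (event kernel + spectrum-shaped noise) and pushed through the full
  preprocessing → point-process → metrics pipeline.
* :func:`simulate_noise_suite` — matched windows of pure spectrum-shaped
  noise, the control in which every metric-vs-time relationship should
  be null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cascades import CascadeSizeSample, detect_cascades, kappa, regional_kappa, sizes_of
from .core import PointProcessMovie
from .pointprocess import to_point_process
from .preprocess import PreprocessConfig, preprocess_movie
from .regional import regional_analysis
from .states import (
    cluster_states,
    downsample_spatial,
    state_visitation_entropy,
    transition_entropy,
)
from .synthetic import (
    NoiseSpec,
    SimulationConfig,
    exponential_kernel,
    generate_noise_movie,
    one_over_f_spectrum,
    render_voltage_movie,
    simulate_burst_sequence,
)
from .utils import spawn_seeds

__all__ = [
    "correlate",
    "analyze_window",
    "SuiteConfig",
    "simulate_recovery_suite",
    "simulate_noise_suite",
    "metric_correlations",
    "distribution_plots",
]

METRICS = ["kappa", "h_state", "h_trans", "h_reg_mean", "kappa_reg_mean", "it_total"]


def correlate(metric, covariate) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between two paired series."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def analyze_window(
    pp: PointProcessMovie,
    k: int = 10,
    region_size: int = 8,
    n_shuffles: int = 20,
    seed: int = 0,
    downsample_factor: int = 2,
) -> dict:
    """All per-window metrics from one point-process window.

    Returns κ (cortex-wide cascades), H_state and H_trans (k-means with
    ``k`` states on factor-2 downsampled frames), mean H_reg, mean κ_reg
    and total IT from the regional analysis.  κ values are NaN when a
    window lacks two distinct cascade sizes.
    """
    out: dict = {}
    cascades = detect_cascades(pp)
    sizes = sizes_of(cascades)
    try:
        out["kappa"] = kappa(sizes)
    except ValueError:
        out["kappa"] = np.nan
    out["n_cascades"] = len(cascades)
    out["n_events"] = pp.n_events

    ds = downsample_spatial(pp, downsample_factor)
    seq = cluster_states(ds, k=k, seed=seed)
    out["h_state"] = state_visitation_entropy(seq)
    out["h_trans"] = transition_entropy(seq)

    reg = regional_analysis(
        pp, region_size=region_size, n_shuffles=n_shuffles, seed=seed + 1
    )
    out["h_reg_mean"] = float(np.mean(reg["h_reg"]))
    out["it_total"] = float(np.sum(reg["it"]))
    kreg = regional_kappa(pp, reg["grid"])
    kvals = np.array([v["kappa"] for v in kreg.values()], dtype=float)
    out["kappa_reg_mean"] = float(np.nanmean(kvals)) if np.isfinite(kvals).any() else np.nan
    return out


@dataclass
class SuiteConfig:
    """Study conditions for the simulated recovery / noise suites.

    Windows emulate successive image sequences during recovery from
    anesthesia: the branching parameter steps from ``branching_start``
    (supercritical, anesthetized-like) to ``branching_stop`` (critical,
    awake-like).  Events are rendered with a causal exponential response
    kernel plus 1/f-spectrum noise and analysed through the full
    preprocessing + point-process pipeline.
    """

    n_windows: int = 20
    branching_start: float = 1.4
    branching_stop: float = 1.0
    grid: int = 32
    segments_per_window: int = 25
    segment_frames: int = 50
    frame_rate: float = 50.0
    drive_rate: float = 2e-4
    kernel_tau_s: float = 0.1
    noise_amplitude: float = 0.3
    noise_exponent: float = 1.0
    threshold_sd: float = 1.0
    k: int = 10
    region_size: int = 8
    n_shuffles: int = 20
    # spatial kernel scaled to the small synthetic field of view
    # (8 px on a 320x240 recording corresponds to ~2 px on 32x32)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(spatial_kernel=2, trim_s=2.0)
    )

    @property
    def frames_per_window(self) -> int:
        return self.segments_per_window * self.segment_frames


def _render_and_analyze(
    events_pp: PointProcessMovie | None,
    cfg: SuiteConfig,
    noise_seed: int,
    analysis_seed: int,
) -> dict:
    """Render (events + noise) or pure noise, preprocess, convert, analyse."""
    spec = NoiseSpec(
        n_frames=cfg.frames_per_window,
        frame_rate=cfg.frame_rate,
        seed=noise_seed,
        template_spectrum=one_over_f_spectrum(
            cfg.frames_per_window, cfg.frame_rate, cfg.noise_exponent
        ),
    )
    noise = generate_noise_movie(spec, cfg.grid, cfg.grid)
    noise_sd = noise.data.std()
    if noise_sd > 0:
        noise = noise.copy_with(noise.data / noise_sd)
    if events_pp is None:
        empty = PointProcessMovie(
            np.zeros((cfg.frames_per_window, cfg.grid, cfg.grid), dtype=bool),
            cfg.frame_rate,
        )
        movie = render_voltage_movie(
            empty,
            exponential_kernel(cfg.kernel_tau_s, cfg.frame_rate),
            noise=noise,
            noise_amplitude=1.0,
        )
    else:
        movie = render_voltage_movie(
            events_pp,
            exponential_kernel(cfg.kernel_tau_s, cfg.frame_rate),
            noise=noise,
            noise_amplitude=cfg.noise_amplitude,
        )
    pre = preprocess_movie(movie, config=cfg.preprocess)
    pp = to_point_process(pre, threshold_sd=cfg.threshold_sd)
    return analyze_window(
        pp,
        k=cfg.k,
        region_size=cfg.region_size,
        n_shuffles=cfg.n_shuffles,
        seed=analysis_seed,
    )


def _assemble(rows: list[dict], cfg: SuiteConfig, condition: str) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["condition"] = condition
    df["time_min"] = df["window"] * cfg.frames_per_window / cfg.frame_rate / 60.0
    return df


def simulate_recovery_suite(cfg: SuiteConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-window metric time course of the simulated recovery experiment."""
    cfg = cfg or SuiteConfig()
    branching = np.linspace(cfg.branching_start, cfg.branching_stop, cfg.n_windows)
    seeds = spawn_seeds(seed, 3 * cfg.n_windows)
    rows = []
    for w, b in enumerate(branching):
        sim_seed, noise_seed, an_seed = seeds[3 * w : 3 * w + 3]
        sim_cfg = SimulationConfig(
            grid_height=cfg.grid,
            grid_width=cfg.grid,
            n_frames=cfg.segment_frames,
            frame_rate=cfg.frame_rate,
            branching_param=float(b),
            drive_rate=cfg.drive_rate,
            seed=sim_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            events = simulate_burst_sequence(sim_cfg, cfg.segments_per_window)
            row = _render_and_analyze(events, cfg, noise_seed, an_seed)
        row["window"] = w
        row["branching_param"] = float(b)
        rows.append(row)
    return _assemble(rows, cfg, "recovery")


def simulate_noise_suite(cfg: SuiteConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Matched pure-noise windows: the control with no pixel interactions."""
    cfg = cfg or SuiteConfig()
    seeds = spawn_seeds(seed + 1, 2 * cfg.n_windows)
    rows = []
    for w in range(cfg.n_windows):
        noise_seed, an_seed = seeds[2 * w : 2 * w + 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = _render_and_analyze(None, cfg, noise_seed, an_seed)
        row["window"] = w
        row["branching_param"] = np.nan
        rows.append(row)
    return _assemble(rows, cfg, "noise")


def metric_correlations(df: pd.DataFrame, covariate: str = "window") -> pd.DataFrame:
    """Pearson r and p of each metric against a covariate column."""
    rows = []
    for metric in METRICS:
        if metric not in df:
            continue
        try:
            r, p = correlate(df[metric], df[covariate])
        except ValueError:
            r, p = np.nan, np.nan
        rows.append({"metric": metric, "covariate": covariate, "r": r, "p": p})
    return pd.DataFrame(rows)


def distribution_plots(
    samples: list[CascadeSizeSample],
    out_dir,
    labels: list[str] | None = None,
    exponent: float = -1.5,
    stem: str = "cascade_sizes",
) -> list[Path]:
    """Log-log cascade-size probability and cumulative plots with reference.

    One probability-density panel (logarithmic binning) and one CDF
    panel; the truncated power-law reference with the given exponent is
    overlaid on both.  Returns the written file paths (empty list, with
    a warning, if no non-empty sample remains).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .cascades import ReferenceCDF

    samples = [s for s in samples if len(s)]
    if not samples:
        warnings.warn("no non-empty cascade-size samples; nothing plotted", stacklevel=2)
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = labels or [s.provenance for s in samples]

    fig, (ax_pdf, ax_cdf) = plt.subplots(1, 2, figsize=(9, 4))
    z_lo = min(int(s.sizes.min()) for s in samples)
    z_hi = max(int(s.sizes.max()) for s in samples)
    for s, lab in zip(samples, labels):
        edges = np.unique(np.round(np.logspace(0, np.log10(s.sizes.max() + 1), 30)))
        widths = np.diff(edges)
        hist, _ = np.histogram(s.sizes, bins=edges)
        dens = hist / hist.sum() / widths
        centers = np.sqrt(edges[:-1] * edges[1:])
        keep = dens > 0
        ax_pdf.loglog(centers[keep], dens[keep], "o-", ms=3, label=lab)
        zs = np.sort(s.sizes)
        ax_cdf.semilogx(zs, np.arange(1, len(zs) + 1) / len(zs), label=lab)
    zz = np.logspace(np.log10(z_lo), np.log10(max(z_hi, z_lo + 1)), 100)
    norm = zz[0] ** exponent
    ax_pdf.loglog(zz, zz**exponent / norm * 0.5, "k--", label=f"z^{exponent}")
    if z_hi > z_lo:
        ref = ReferenceCDF(z_lo, z_hi, exponent)
        ax_cdf.semilogx(zz, ref(zz), "k--", label="reference")
    ax_pdf.set_xlabel("cascade size z")
    ax_pdf.set_ylabel("P(z)")
    ax_cdf.set_xlabel("cascade size z")
    ax_cdf.set_ylabel("CDF")
    ax_cdf.legend(fontsize=7)
    ax_pdf.legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / f"{stem}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]
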