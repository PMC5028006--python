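"""Synthetic-data generators: branching cascades, matched-spectrum noise, rendering."""

import numpy as np
import pytest

from neurocascade.cascades import detect_cascades, label_cascades, sizes_of
from neurocascade.core import PointProcessMovie, VoltageMovie
from neurocascade.pointprocess import to_point_process
from neurocascade.synthetic import (
    NoiseSpec,
    SimulationConfig,
    exponential_kernel,
    generate_noise_movie,
    one_over_f_spectrum,
    render_voltage_movie,
    simulate_branching_cascades,
    simulate_burst_sequence,
)

from oracles import labels_to_partition


def sim(seed=0, **kw):
    defaults = dict(
        grid_height=24, grid_width=24, n_frames=400, branching_param=1.0,
        drive_rate=7e-4, seed=seed,
    )
    defaults.update(kw)
    return simulate_branching_cascades(SimulationConfig(**defaults))


class TestBranchingSimulator:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(0, 8, 10)
        with pytest.raises(ValueError):
            SimulationConfig(8, 8, 0)
        with pytest.raises(ValueError):
            SimulationConfig(8, 8, 10, branching_param=-0.5)
        with pytest.raises(ValueError):
            SimulationConfig(8, 8, 10, drive_rate=1.5)

    def test_deterministic_given_seed(self):
        pp1, lab1, meta1 = sim(seed=7)
        pp2, lab2, meta2 = sim(seed=7)
        assert np.array_equal(pp1.events, pp2.events)
        assert np.array_equal(lab1, lab2)
        assert meta1 == meta2
        pp3, _, _ = sim(seed=8)
        assert not np.array_equal(pp1.events, pp3.events)

    def test_zero_branching_gives_singleton_cascades(self):
        # at sparse drive and this seed no two seeds land adjacent, so
        # every cascade is a lone seed event that dies immediately
        pp, labels, meta = sim(seed=3, branching_param=0.0, drive_rate=2e-4)
        assert meta["collisions"] == 0
        sizes = np.bincount(labels.ravel())[1:]
        assert meta["n_cascades"] > 10
        assert np.all(sizes[sizes > 0] == 1)

    def test_labels_cover_exactly_the_events(self):
        pp, labels, meta = sim(seed=5)
        assert np.array_equal(labels > 0, pp.events)
        assert labels.max() == meta["n_cascades"]

    def test_ground_truth_matches_detector_partition(self):
        """Ground-truth labels are connected components under the detector's
        own adjacency, so detection reproduces the partition exactly."""
        pp, labels, meta = sim(seed=11)
        det_labels, n = label_cascades(pp)
        assert n == meta["n_cascades"]
        assert labels_to_partition(labels) == labels_to_partition(det_labels)

    def test_median_cascade_size_nondecreasing_in_branching(self):
        medians = []
        for b in (0.6, 0.8, 1.0, 1.2, 1.4):
            cfg = SimulationConfig(32, 32, 40, branching_param=b,
                                   drive_rate=2e-4, seed=0)
            pp = simulate_burst_sequence(cfg, 40)
            sizes = sizes_of(detect_cascades(pp)).sizes
            medians.append(np.median(sizes))
        assert all(a <= b for a, b in zip(medians, medians[1:]))

    def test_saturation_flagged_not_fatal(self):
        with pytest.warns(RuntimeWarning, match="saturated"):
            pp, _, meta = sim(seed=1, branching_param=2.5, drive_rate=1e-2,
                              n_frames=60)
        assert meta["saturated"]
        assert meta["max_active_fraction"] >= 0.5

    def test_burst_sequence_concatenates_segments(self):
        cfg = SimulationConfig(16, 16, 30, branching_param=1.0, seed=2)
        pp = simulate_burst_sequence(cfg, 4)
        assert pp.n_frames == 120
        assert pp.meta["n_segments"] == 4


class TestNoiseGenerator:
    def test_zero_spectrum_gives_zero_movie(self):
        spec = NoiseSpec(n_frames=64, template_spectrum=np.zeros(33), seed=0)
        movie = generate_noise_movie(spec, 4, 4)
        assert np.all(movie.data == 0)

    def test_negative_power_rejected(self):
        bad = np.ones(33)
        bad[5] = -1.0
        with pytest.raises(ValueError, match=">= 0"):
            NoiseSpec(n_frames=64, template_spectrum=bad)

    def test_seed_contract(self):
        spec = lambda s: NoiseSpec(
            n_frames=128, template_spectrum=np.ones(65), seed=s
        )
        a = generate_noise_movie(spec(1), 3, 3)
        b = generate_noise_movie(spec(1), 3, 3)
        c = generate_noise_movie(spec(2), 3, 3)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_white_template_flat_periodogram_and_independent_pixels(self):
        """Monte-Carlo check of the synthesis: flat expected spectrum and
        zero cross-correlation between pixels."""
        n = 10_000
        template = np.ones(n // 2 + 1)
        movie = generate_noise_movie(
            NoiseSpec(n_frames=n, template_spectrum=template, seed=4), 4, 4
        )
        traces = movie.data.reshape(n, -1).T
        psd = np.abs(np.fft.rfft(traces, axis=1)) ** 2 / n
        mean_psd = psd.mean(axis=0)[1:-1]  # DC/Nyquist are phase-constrained
        assert abs(mean_psd.mean() - 1.0) < 0.05
        corr = np.corrcoef(traces)
        off_diag = corr[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off_diag).max() < 0.05

    def test_spectrum_converges_to_shaped_template(self):
        n = 8192
        template = one_over_f_spectrum(n, 50.0, exponent=1.0)
        movie = generate_noise_movie(
            NoiseSpec(n_frames=n, template_spectrum=template, seed=5), 8, 8
        )
        traces = movie.data.reshape(n, -1).T
        psd = (np.abs(np.fft.rfft(traces, axis=1)) ** 2 / n).mean(axis=0)
        sel = slice(1, n // 2)  # skip DC and Nyquist
        ratio = psd[sel] / template[sel]
        # expected ratio 1 at every bin; averaged over 64 pixels
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_reference_trace_spectrum_measured(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(size=256)
        spec = NoiseSpec(n_frames=256, reference_trace=trace, seed=0)
        expected = np.abs(np.fft.rfft(trace)) ** 2 / 256
        assert np.allclose(spec.spectrum, expected)


class TestRendering:
    def test_no_events_returns_noise_plus_baseline(self):
        noise = VoltageMovie(np.random.default_rng(0).normal(size=(20, 4, 4)), 50.0)
        empty = PointProcessMovie(np.zeros((20, 4, 4), dtype=bool), 50.0)
        out = render_voltage_movie(empty, [1.0], noise=noise, noise_amplitude=1.0,
                                   baseline=0.0)
        assert np.allclose(out.data, noise.data)

    def test_single_event_traces_kernel(self):
        events = np.zeros((10, 3, 3), dtype=bool)
        events[2, 1, 1] = True
        kernel = np.array([1.0, 0.5, 0.25])
        out = render_voltage_movie(
            PointProcessMovie(events, 50.0), kernel, baseline=0.0
        )
        trace = out.data[:, 1, 1]
        assert np.allclose(trace[2:5], kernel, atol=1e-12)
        assert np.allclose(out.data[:, 0, 0], 0.0, atol=1e-12)

    def test_dim_mismatch_rejected(self):
        noise = VoltageMovie(np.zeros((20, 4, 4)) + 1.0, 50.0)
        events = PointProcessMovie(np.zeros((10, 4, 4), dtype=bool), 50.0)
        with pytest.raises(ValueError, match="does not match"):
            render_voltage_movie(events, [1.0], noise=noise, noise_amplitude=1.0)

    def test_noiseless_identity_rendering_recovers_events(self):
        """Unit kernel, no noise: thresholding recovers the planted events."""
        rng = np.random.default_rng(6)
        events = np.zeros((300, 6, 6), dtype=bool)
        for _ in range(40):  # isolated events, no two on adjacent frames
            t = int(rng.integers(1, 299))
            y, x = int(rng.integers(6)), int(rng.integers(6))
            if not events[max(t - 1, 0) : t + 2, y, x].any():
                events[t, y, x] = True
        pp_in = PointProcessMovie(events, 50.0)
        movie = render_voltage_movie(pp_in, [1.0], baseline=0.5)
        recovered = to_point_process(movie, threshold_sd=1.0)
        assert np.array_equal(recovered.events, events)

    def test_event_recovery_under_noise(self):
        """Causal decaying kernel plus moderate noise: most planted event
        onsets are recovered within one frame at the right pixel."""
        rng = np.random.default_rng(7)
        t_total, h, w = 1000, 8, 8
        events = np.zeros((t_total, h, w), dtype=bool)
        planted = []
        for _ in range(120):
            t = int(rng.integers(5, t_total - 5))
            y, x = int(rng.integers(h)), int(rng.integers(w))
            if not events[t - 3 : t + 4, y, x].any():
                events[t, y, x] = True
                planted.append((t, y, x))
        noise = VoltageMovie(rng.normal(size=(t_total, h, w)) * 0.2, 50.0)
        movie = render_voltage_movie(
            PointProcessMovie(events, 50.0),
            exponential_kernel(0.1, 50.0),
            noise=noise,
            noise_amplitude=1.0,
        )
        recovered = to_point_process(movie, threshold_sd=1.0)
        hits = sum(
            recovered.events[max(t - 1, 0) : t + 2, y, x].any()
            for t, y, x in planted
        )
        assert hits / len(planted) > 0.85
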