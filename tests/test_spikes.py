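"""Multiunit extraction: filtering, robust detection, clustering, selection."""

import numpy as np
import pytest
from scipy.stats import norm

from gednet.spikes import (WaveformSet, bandpass_spike_filter, binary_train,
                           detect_and_align, estimate_noise_sd, sort_multiunits,
                           window_length)

FS = 30_000.0


def _waveform_template(fs=FS, hump=0.35, trough_w=0.12, hump_t=0.45, hump_w=0.25):
    """Negative trough with an after-hump, the canonical extracellular shape."""
    n = window_length(fs)
    t = (np.arange(n) - int(round(0.7e-3 * fs))) / fs * 1e3  # ms around trough
    trough = -np.exp(-0.5 * (t / trough_w) ** 2)
    after = hump * np.exp(-0.5 * ((t - hump_t) / hump_w) ** 2)
    return trough + after


def _plant_spikes(rng, rate_n=100, amp=8.0, fs=FS, dur=10.0):
    x = rng.standard_normal(int(dur * fs))
    tmpl = _waveform_template(fs)
    n_w = tmpl.size
    times = np.sort(rng.choice(np.arange(n_w, x.size - 2 * n_w, 2 * n_w),
                               size=rate_n, replace=False))
    for t in times:
        x[t:t + n_w] += amp * tmpl
    return x, times + int(round(0.7e-3 * fs))  # trough positions


class TestFilter:
    def test_passband_tone_preserved_zero_lag(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        y = bandpass_spike_filter(x, FS)
        core = slice(5000, 25000)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (core.stop - core.start - 1)
        assert lag == 0
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_attenuated_20db(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_spike_filter(x, FS)
        assert np.abs(y[5000:25000]).max() < 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_spike_filter(np.zeros(40000), FS), 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_spike_filter(np.zeros(1000), 10_000.0)


class TestNoiseSD:
    def test_gaussian_calibration(self, rng):
        x = rng.standard_normal(200_000)
        assert estimate_noise_sd(x) == pytest.approx(1.0, rel=0.02)

    def test_constant_series_zero(self):
        assert estimate_noise_sd(np.full(100, 2.5)) == 0.0

    def test_robust_to_large_outliers(self, rng):
        x = rng.standard_normal(100_000)
        x[::100] = 100.0                 # 1% huge artifacts
        assert estimate_noise_sd(x) == pytest.approx(1.0, rel=0.05)


class TestDetection:
    def test_planted_spikes_found_and_trough_aligned(self, rng):
        x, troughs = _plant_spikes(rng)
        ws = detect_and_align(x, FS)
        align = ws.align_index
        assert np.all(ws.waveforms.argmin(axis=1) == align)
        # every planted trough is detected; extras are bounded by the
        # Gaussian 4-SD noise crossing rate
        d = np.abs(ws.event_times[:, None] - troughs[None, :]).min(axis=0)
        assert np.sum(d <= 2) >= 98
        expected_false = norm.cdf(-4.0) * x.size
        assert ws.n_events <= 100 + 3 * expected_false + 5

    def test_noise_false_event_rate_bounded_by_gaussian_tail(self, rng):
        x = rng.standard_normal(int(20 * FS))
        ws = detect_and_align(x, FS)
        # upcrossing rate of a -4 SD level, corrected for the window lockout
        p = norm.cdf(-4.0)
        upper = 3 * p * x.size
        assert ws.n_events <= upper

    def test_all_positive_signal_no_events(self):
        x = np.abs(np.random.default_rng(1).standard_normal(int(FS))) + 0.1
        assert detect_and_align(x, FS).n_events == 0


class TestSorting:
    def test_two_shapes_recovered(self, rng):
        x = rng.standard_normal(int(20 * FS)) * 0.5
        t_a = _waveform_template(FS, hump=0.6, trough_w=0.10, hump_t=0.35,
                                 hump_w=0.15)
        t_b = 1.5 * _waveform_template(FS, hump=0.55, trough_w=0.20,
                                       hump_t=0.50, hump_w=0.35)
        n_w = t_a.size
        slots = np.arange(n_w, x.size - 2 * n_w, 2 * n_w)
        rng.shuffle(slots)
        truth = {}
        for i, t in enumerate(slots[:300]):
            tmpl = t_a if i % 2 == 0 else t_b
            x[t:t + n_w] += 9.0 * tmpl
            truth[t] = i % 2
        ws = detect_and_align(x, FS)
        out = sort_multiunits(ws, seed=0)
        units = out.accepted_units()
        assert len(units) == 2
        # label agreement with planted identities
        planted = []
        for et in out.event_times:
            cand = [t for t in truth if abs(et - t - ws.align_index) <= 3]
            planted.append(truth[cand[0]] if cand else -1)
        planted = np.asarray(planted)
        ok = planted >= 0
        labels = out.cluster_labels[ok]
        planted = planted[ok]
        agree = max(np.mean((labels == units[0]) == (planted == 0)),
                    np.mean((labels == units[0]) == (planted == 1)))
        assert agree >= 0.95

    def test_jittered_duplicates_fused_to_one_unit(self, rng):
        x = rng.standard_normal(int(15 * FS)) * 0.5
        tmpl = _waveform_template(FS)
        n_w = tmpl.size
        for t in np.arange(n_w, x.size - 2 * n_w, 2 * n_w):
            x[t:t + n_w] += 8.0 * tmpl * rng.uniform(0.95, 1.05)
        ws = detect_and_align(x, FS)
        out = sort_multiunits(ws, fuse_corr=0.95, seed=0)
        assert len(out.accepted_units()) == 1

    def test_positive_going_cluster_rejected(self, rng):
        x = rng.standard_normal(int(10 * FS)) * 0.5
        tmpl = -_waveform_template(FS)   # inverted: positive hump before, no after-hump
        n_w = tmpl.size
        for t in np.arange(n_w, x.size - 2 * n_w, 2 * n_w):
            x[t:t + n_w] += 8.0 * tmpl
        ws = detect_and_align(x, FS)
        if ws.n_events:
            out = sort_multiunits(ws, seed=0)
            assert len(out.accepted_units()) == 0

    def test_deterministic_given_seed(self, rng):
        x, _ = _plant_spikes(rng, rate_n=80)
        ws = detect_and_align(x, FS)
        a = sort_multiunits(ws, seed=5)
        b = sort_multiunits(ws, seed=5)
        assert np.array_equal(a.cluster_labels, b.cluster_labels)

    def test_independent_electrodes_give_uncorrelated_trains(self, rng):
        trains = []
        for _ in range(2):
            x, _ = _plant_spikes(rng, rate_n=120)
            ws = detect_and_align(x, FS)
            out = sort_multiunits(ws, seed=0)
            u = out.accepted_units()[0]
            trains.append(binary_train(out, u, 10_000, 1000.0))
        r = np.corrcoef(trains[0], trains[1])[0, 1]
        assert abs(r) < 0.05
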