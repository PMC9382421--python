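"""Background subtraction, dF/F0 transient detection, and amplitude synchrony."""

import numpy as np
import pandas as pd
import pytest

from neuroquant.calcium import (
    RoiRejectedError,
    amplitude_correlation,
    amplitude_profiles,
    analyze_trace,
    detect_transients,
    subtract_background,
    transient_stats,
)
from neuroquant.core import FluorescenceTrace, Transient
from neuroquant.simulate import CaSimParams, simulate_fluorescence

FS = 15.3


def _trace(raw, bg=None, roi="ROI1"):
    raw = np.asarray(raw, dtype=float)
    bg = np.zeros_like(raw) if bg is None else np.asarray(bg, dtype=float)
    return FluorescenceTrace(roi, raw, bg, FS)


class TestSubtractBackground:
    def test_constant_offset(self, rng):
        bg = rng.normal(50.0, 0.0, 200)
        corrected, sd = subtract_background(_trace(bg + 100.0, bg))
        np.testing.assert_allclose(corrected, 100.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_noise_sd_of_difference(self, rng):
        n = 20_000
        raw = 100.0 + rng.normal(0.0, 2.0, n)
        bg = rng.normal(0.0, 2.0, n)
        _, sd = subtract_background(_trace(raw, bg))
        assert abs(sd - np.sqrt(2.0) * 2.0) / (np.sqrt(2.0) * 2.0) < 0.25

    def test_all_zero_raw_rejected(self):
        with pytest.raises(RoiRejectedError):
            subtract_background(_trace(np.zeros(100), np.zeros(100)))


def _planted_trace(event_times, amplitude, f0=100.0, noise_sd=0.0,
                   duration=60.0, tau=1.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    t = np.arange(n) / FS
    f = np.full(n, f0)
    for t_e in event_times:
        mask = t >= t_e
        f[mask] += amplitude * f0 * np.exp(-(t[mask] - t_e) / tau)
    return f + rng.normal(0.0, noise_sd, n)


class TestDetectTransients:
    def test_false_positive_control_on_flat_noise(self):
        """Pure noise yields zero transients in at least 99% of seeds."""
        clean = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            f = 100.0 + rng.normal(0.0, 5.0, int(300 * FS))
            if not detect_transients(f, 5.0, FS):
                clean += 1
        assert clean / n_seeds >= 0.99

    def test_single_noiseless_transient_amplitude_within_2pct(self):
        t_e = 10.0 + 0.5 / FS  # mid-frame onset: the generic case
        f = _planted_trace([t_e], amplitude=0.8)
        det = detect_transients(f, 0.0, FS)
        assert len(det) == 1
        assert det[0].amplitude == pytest.approx(0.8, rel=0.02)
        assert det[0].f0 == pytest.approx(100.0, rel=1e-6)

    def test_planted_events_at_snr_10(self):
        """Counts exact and amplitudes within 5% on average at SNR 10."""
        params = CaSimParams(n_rois=1, shared_scale_sd=0.0, private_sd=0.0,
                             participation_prob=1.0, event_rate=5.0,
                             noise_sd=0.5 / 10 / np.sqrt(2.0))
        errs = []
        for seed in range(10):
            traces, truth = simulate_fluorescence(params, seed=seed)
            det = analyze_trace(traces[0])
            planted = sorted(truth["transients"]["ROI01"], key=lambda e: e[1])
            assert len(det) == len(planted)
            # events are >= 4 s apart, so index-wise matching is exact
            for ev, (_, t, a) in zip(sorted(det, key=lambda e: e.onset_frame),
                                     planted):
                assert abs(ev.onset_frame / FS - t) < 0.5
                errs.append(abs(ev.amplitude - a) / a)
        assert np.mean(errs) <= 0.05

    def test_count_monotone_in_threshold_multiple(self):
        f = _planted_trace([5.0, 15.0, 25.0], amplitude=0.3, noise_sd=3.0,
                           seed=3)
        counts = [len(detect_transients(f, 5.0, FS, k=k))
                  for k in (1.5, 2.0, 3.0, 5.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_amplitude_scale_invariant(self):
        f = _planted_trace([10.0], amplitude=0.6)
        a1 = detect_transients(f, 0.0, FS)[0].amplitude
        a2 = detect_transients(3.7 * f, 0.0, FS)[0].amplitude
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_trace_shorter_than_f0_window_rejected(self):
        with pytest.raises(ValueError, match="F0 window"):
            detect_transients(np.ones(10), 1.0, FS)


class TestTransientStats:
    def test_frequency_per_minute(self):
        evs = [Transient(10 * i + 20, 10 * i + 21, 10 * i + 25, 0.5, 100.0)
               for i in range(10)]
        stats = transient_stats({"ROI1": evs}, duration=300.0)
        assert stats.loc[0, "frequency_per_min"] == pytest.approx(2.0)

    def test_zero_transient_roi_excluded(self):
        stats = transient_stats({"ROI1": [], "ROI2": [
            Transient(20, 21, 25, 1.0, 100.0)]}, duration=300.0)
        by = stats.set_index("roi_id")
        assert not by.loc["ROI1", "included"]
        assert by.loc["ROI2", "included"]

    def test_mean_amplitude(self):
        evs = [Transient(20, 21, 25, 0.5, 100.0),
               Transient(40, 41, 45, 1.5, 100.0)]
        stats = transient_stats({"R": evs}, duration=300.0)
        assert stats.loc[0, "mean_amplitude"] == pytest.approx(1.0)


class TestAmplitudeCorrelation:
    def test_proportional_profiles_r_one(self):
        a = [Transient(20 * i, 20 * i + 1, 20 * i + 5, amp, 100.0)
             for i, amp in enumerate([0.5, 1.0, 1.5, 0.8], start=1)]
        b = [Transient(20 * i, 20 * i + 1, 20 * i + 5, 2 * amp, 100.0)
             for i, amp in enumerate([0.5, 1.0, 1.5, 0.8], start=1)]
        profiles = amplitude_profiles({"A": a, "B": b})
        assert len(profiles) == 4
        results, counts = amplitude_correlation(profiles)
        assert results[0].r == pytest.approx(1.0)
        assert counts.counts["positive"] == 1

    def test_missing_neuron_contributes_zero(self):
        a = [Transient(20, 21, 25, 0.5, 100.0),
             Transient(60, 61, 65, 1.0, 100.0)]
        b = [Transient(20, 21, 25, 0.7, 100.0)]
        profiles = amplitude_profiles({"A": a, "B": b})
        assert profiles.loc[1, "B"] == 0.0

    def test_independent_amplitudes_type_one_calibration(self, rng):
        """Independent profiles: positive fraction ~ alpha/2 (two-sided)."""
        hits = total = 0
        while total < 300:
            n_events = 40
            frames = (np.arange(n_events) * 20 + 30).astype(int)
            prof = {}
            for roi in ("A", "B"):
                amps = rng.lognormal(0.0, 0.4, n_events)
                prof[roi] = [Transient(f, f + 1, f + 5, a, 100.0)
                             for f, a in zip(frames, amps)]
            results, _ = amplitude_correlation(amplitude_profiles(prof))
            hits += results[0].category == "positive"
            total += 1
        assert abs(hits / total - 0.025) < 0.02

    def test_shared_scale_model_mostly_positive(self):
        """The shared lognormal event scale induces positive correlation."""
        params = CaSimParams(n_rois=6, shared_scale_sd=0.6, private_sd=0.15,
                             participation_prob=1.0, event_rate=4.0)
        positive = total = 0
        for seed in range(5):
            traces, _ = simulate_fluorescence(params, seed=seed)
            transients = {tr.roi_id: analyze_trace(tr) for tr in traces}
            results, counts = amplitude_correlation(
                amplitude_profiles(transients))
            positive += counts.counts["positive"]
            total += sum(counts.counts[c] for c in
                         ("positive", "negative", "non_correlated"))
        assert positive / total >= 0.8

    def test_mean_r_monotone_in_shared_scale(self):
        """The shared-scale dial: mean pairwise r grows with its variance."""
        mean_rs = []
        for shared in (0.05, 0.3, 0.6):
            rs = []
            for seed in range(8):
                params = CaSimParams(n_rois=5, shared_scale_sd=shared,
                                     private_sd=0.2, participation_prob=1.0,
                                     event_rate=4.0)
                traces, _ = simulate_fluorescence(params, seed=seed)
                transients = {tr.roi_id: analyze_trace(tr) for tr in traces}
                results, _ = amplitude_correlation(
                    amplitude_profiles(transients))
                rs.extend(r.r for r in results if np.isfinite(r.r))
            mean_rs.append(np.mean(rs))
        assert mean_rs[0] < mean_rs[1] < mean_rs[2]
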