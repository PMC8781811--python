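"""Filtering, R-peak detection, derived signals and segmentation."""

import numpy as np
import pytest
from scipy.signal import freqz

from msapnea import (ECGRecord, FilterSpec, RPeakSeries, SynthConfig,
                     bandpass, derive_series, detect_r_peaks,
                     generate_record, preprocess_record, resample_uniform,
                     segment_and_filter)
from conftest import match_peaks

FS = 100.0


def _sine_record(freq, fs=FS, seconds=30.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return ECGRecord("sine", amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_passband_gain_near_unity(self):
        rec = bandpass(_sine_record(10.0))
        core = rec.samples[int(2 * FS):-int(2 * FS)]  # skip edge transients
        # RMS-based amplitude: the sample grid never hits the sine crest
        measured = np.sqrt(2) * core.std()
        assert abs(measured - 1.0) < 0.05
        # frequency-response oracle: the designed taps say the same
        w, h = freqz(FilterSpec().taps(FS), worN=[10.0], fs=FS)
        assert abs(np.abs(h[0]) - measured) < 0.02

    def test_dc_is_rejected(self):
        t = np.arange(int(30 * FS)) / FS
        rec = bandpass(ECGRecord("dc", np.full(len(t), 2.0), FS))
        core = rec.samples[int(2 * FS):-int(2 * FS)]
        assert np.abs(core).max() < 0.02  # < 1% of the 2.0 input level

    def test_stopband_attenuation_at_0p1_hz(self):
        rec = bandpass(_sine_record(0.1, seconds=60.0))
        core = rec.samples[int(5 * FS):-int(5 * FS)]
        assert np.abs(core).max() < 10 ** (-20 / 20)  # >= 20 dB down
        w, h = freqz(FilterSpec().taps(FS), worN=[0.1], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) < -20

    def test_output_aligned_and_same_length(self):
        rec = _sine_record(10.0)
        out = bandpass(rec)
        assert len(out.samples) == len(rec.samples)
        # group-delay compensation: in-band sine keeps its phase
        core = slice(int(2 * FS), -int(2 * FS))
        corr = np.corrcoef(rec.samples[core], out.samples[core])[0, 1]
        assert corr > 0.999

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(low_cut=45, high_cut=3)
        with pytest.raises(ValueError):
            FilterSpec(high_cut=60).taps(FS)  # above Nyquist


class TestDetectRPeaks:
    def test_perfect_on_clean_synthetic(self, clean_record, clean_peaks):
        _, truth = clean_record
        recall, precision = match_peaks(truth.true_peak_times,
                                        clean_peaks.times)
        assert recall == 1.0 and precision == 1.0

    def test_all_zero_signal_gives_empty_series(self):
        rec = ECGRecord("flat", np.zeros(int(10 * FS)), FS)
        peaks = detect_r_peaks(rec)
        assert len(peaks) == 0

    def test_short_record_errors(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(ECGRecord("short", np.random.randn(50), FS))

    def test_refractory_merges_close_deflections(self):
        # two identical spikes 120 ms apart, then isolated spikes: the pair
        # must yield a single detection (200 ms refractory)
        x = np.zeros(int(10 * FS))
        spike = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
        for t in [2.0, 2.12, 4.0, 6.0, 8.0]:
            i = int(t * FS)
            x[i - 2:i + 3] += spike
        peaks = detect_r_peaks(ECGRecord("pair", x, FS))
        in_pair = np.sum((peaks.times > 1.8) & (peaks.times < 2.4))
        assert in_pair == 1

    def test_amplitudes_read_from_signal(self, clean_record, clean_peaks):
        record, truth = clean_record
        # amplitudes should correlate strongly with the generated truth
        recall, _ = match_peaks(truth.true_peak_times, clean_peaks.times)
        assert recall == 1.0
        assert len(clean_peaks) == len(truth.true_peak_amplitudes)
        corr = np.corrcoef(clean_peaks.amplitudes,
                           truth.true_peak_amplitudes)[0, 1]
        assert corr > 0.9


class TestDeriveSeries:
    def test_rr_points_by_definition(self):
        peaks = RPeakSeries(times=[1.0, 1.8, 2.7], amplitudes=[1, 1, 1])
        rr, amp = derive_series(peaks)
        assert np.allclose(rr, [[1.8, 0.8], [2.7, 0.9]])
        assert amp.shape == (3, 2)

    def test_constant_train_gives_constant_rr(self):
        times = np.arange(1, 11, dtype=float)
        rr, _ = derive_series(RPeakSeries(times=times,
                                          amplitudes=np.ones(10)))
        assert np.allclose(rr[:, 1], 1.0)

    def test_single_peak_errors(self):
        with pytest.raises(ValueError):
            derive_series(RPeakSeries(times=[1.0], amplitudes=[1.0]))


def _natural_spline_oracle(t, y, query):
    """Independent natural cubic spline via the tridiagonal moment system."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    n = len(t)
    h = np.diff(t)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0  # natural: second derivative zero at ends
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1] / 6
        A[i, i] = (h[i - 1] + h[i]) / 3
        A[i, i + 1] = h[i] / 6
        b[i] = (y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1]
    m = np.linalg.solve(A, b)  # second derivatives at knots
    out = np.empty(len(query))
    for j, x in enumerate(query):
        i = min(max(np.searchsorted(t, x) - 1, 0), n - 2)
        hi = h[i]
        a1, a2 = t[i + 1] - x, x - t[i]
        out[j] = (m[i] * a1 ** 3 / (6 * hi) + m[i + 1] * a2 ** 3 / (6 * hi)
                  + (y[i] / hi - m[i] * hi / 6) * a1
                  + (y[i + 1] / hi - m[i + 1] * hi / 6) * a2)
    return out


class TestResampleUniform:
    def test_knots_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 8))
        v = rng.normal(size=8)
        points = np.column_stack([t, v])
        # grid containing an exact knot time
        grid_rate = 1.0 / (t[3] - t[0]) if t[3] > t[0] else 5.0
        out = resample_uniform(points, grid_rate, (t[0], t[0] + 2 / grid_rate))
        assert abs(out[0] - v[0]) < 1e-12

    def test_linear_points_stay_linear(self):
        t = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        v = 2.0 * t + 1.0
        out = resample_uniform(np.column_stack([t, v]), 5.0, (0.0, 6.0))
        grid = np.arange(len(out)) / 5.0
        assert np.allclose(out, 2.0 * grid + 1.0, atol=1e-9)

    def test_matches_tridiagonal_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 10, 5))
        v = rng.normal(size=5)
        grid_rate = 7.0
        out = resample_uniform(np.column_stack([t, v]), grid_rate,
                               (t[0], t[-1]))
        grid = t[0] + np.arange(len(out)) / grid_rate
        expected = _natural_spline_oracle(t, v, np.clip(grid, t[0], t[-1]))
        assert np.allclose(out, expected, atol=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            resample_uniform(np.array([[0, 1], [1, 2], [2, 3]]), 5.0, (0, 2))


class TestSegmentAndFilter:
    def test_clean_minutes_all_kept(self, clean_record, clean_peaks):
        record, _ = clean_record
        ds = segment_and_filter(record, clean_peaks)
        assert len(ds) == record.n_full_minutes
        assert ds.segments.shape == (len(ds), 2, 300)
        assert sum(ds.n_rejected.values()) == 0

    def test_flatline_minute_rejected(self):
        cfg = SynthConfig(n_minutes=5, apnea_fraction=0.0, seed=21).noise_free()
        record, _ = generate_record(cfg)
        # 20 s dropout inside minute 2 -> an RR gap > 2 s there
        fs = int(record.sampling_rate)
        record.samples[140 * fs:160 * fs] = 0.0
        filtered = bandpass(record)
        peaks = detect_r_peaks(filtered)
        ds = segment_and_filter(filtered, peaks)
        assert 2 not in set(ds.minute_indices.tolist())
        assert len(ds) + sum(ds.n_rejected.values()) == 5

    def test_channels_are_z_scored(self, clean_record, clean_peaks):
        record, _ = clean_record
        ds = segment_and_filter(record, clean_peaks)
        means = ds.segments.mean(axis=2)
        stds = ds.segments.std(axis=2)
        assert np.all(np.abs(means) < 1e-5)
        assert np.all(np.abs(stds - 1.0) < 1e-5)

    def test_missing_labels_error(self, clean_record, clean_peaks):
        record, _ = clean_record
        bare = ECGRecord("bare", record.samples, record.sampling_rate)
        with pytest.raises(ValueError, match="labels"):
            segment_and_filter(bare, clean_peaks)

    def test_denormalized_rr_mean_matches_generator(self, clean_record,
                                                    clean_peaks):
        record, truth = clean_record
        ds = segment_and_filter(record, clean_peaks)
        normal = [i for i, k in enumerate(ds.minute_indices)
                  if truth.minute_labels[k] == "N"]
        rr_means = ds.norm_mean[normal, 0]
        assert np.all(np.abs(rr_means - 0.85) < 0.03)

    def test_noise_budget_preserves_recall(self, clean_record, noisy_record):
        _, truth = clean_record
        noisy, _ = noisy_record
        peaks_clean_recall = 1.0  # established above on the clean record
        peaks = detect_r_peaks(bandpass(noisy))
        recall, _ = match_peaks(truth.true_peak_times, peaks.times)
        assert peaks_clean_recall - recall < 0.05

    def test_round_trip_save_load(self, tmp_path, small_dataset):
        path = tmp_path / "segments.npz"
        small_dataset.save(path)
        back = type(small_dataset).load(path)
        assert np.array_equal(back.segments, small_dataset.segments)
        assert np.array_equal(back.labels, small_dataset.labels)
        assert list(back.record_ids) == list(small_dataset.record_ids)
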