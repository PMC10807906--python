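import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respiro import (
    ParameterError,
    Waveform,
    compute_ibi,
    find_peaks,
    gen_respiration,
    lowpass_filter,
    moving_average,
)
from respiro.preprocess_peaks import PeakSeries


class TestMovingAverage:
    def test_edge_shrinking_window(self):
        np.testing.assert_allclose(moving_average([1, 2, 3], 3), [1.5, 2, 2.5])

    def test_window_one_is_identity_and_constants_fixed(self):
        x = np.random.default_rng(0).standard_normal(20)
        np.testing.assert_array_equal(moving_average(x, 1), x)
        np.testing.assert_allclose(moving_average(np.full(11, 2.5), 5), 2.5)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_rejects_even_or_nonpositive_window(self, window):
        with pytest.raises(ParameterError):
            moving_average(np.ones(10), window)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([1, 3, 5]),
           st.floats(-5, 5))
    def test_length_preserved_and_commutes_with_offset(self, seed, window, c):
        x = np.random.default_rng(seed).standard_normal(17)
        y = moving_average(x, window)
        assert y.size == x.size
        np.testing.assert_allclose(moving_average(x + c, window), y + c, atol=1e-10)


class TestLowpass:
    def test_dc_passes(self):
        np.testing.assert_allclose(lowpass_filter(np.full(500, 1.3), 50, 1), 1.3)

    def test_passband_and_stopband_attenuation(self):
        fs, n = 50.0, 50 * 120
        t = np.arange(n) / fs
        slow = np.sin(2 * np.pi * 0.2 * t)
        fast = np.sin(2 * np.pi * 10.0 * t)
        mid = slice(n // 4, 3 * n // 4)  # avoid edge transients
        out_slow = lowpass_filter(slow, fs, 1.0)
        assert np.abs(out_slow[mid] - slow[mid]).max() < 0.01
        out_both = lowpass_filter(slow + fast, fs, 1.0)
        # the 10 Hz component must be suppressed by > 99%
        assert np.abs(out_both[mid] - out_slow[mid]).max() < 0.01

    def test_rejects_cutoff_at_or_above_nyquist(self):
        with pytest.raises(ParameterError):
            lowpass_filter(np.ones(100), 50, 25)

    def test_commutes_with_offset(self):
        x = np.random.default_rng(1).standard_normal(300)
        np.testing.assert_allclose(
            lowpass_filter(x + 3.0, 50, 2.0), lowpass_filter(x, 50, 2.0) + 3.0,
            atol=1e-9)


class TestFindPeaks:
    def test_constant_waveform_yields_no_peaks(self):
        w = Waveform(0.0, 50.0, np.ones(500))
        assert len(find_peaks(w, "none")) == 0

    def test_single_triangular_pulse(self):
        x = np.concatenate([np.zeros(100), np.linspace(0, 1, 51),
                            np.linspace(1, 0, 51)[1:], np.zeros(100)])
        p = find_peaks(Waveform(0.0, 50.0, x), "none")
        assert len(p) == 1 and p.indices[0] == 150

    def test_sinusoid_peak_count_and_spacing(self):
        t = np.arange(0, 60, 1 / 50.0)
        w = Waveform(0.0, 50.0, np.sin(2 * np.pi * 0.25 * t))
        p = find_peaks(w, "ma", min_distance_s=2)
        assert len(p) == 15
        assert np.all(np.abs(np.diff(p.times) - 4.0) <= 1 / 50.0 + 1e-12)

    def test_invalid_method(self):
        with pytest.raises(ParameterError):
            find_peaks(Waveform(0.0, 50.0, np.ones(100)), "median")

    def test_min_height_filters_raw_heights(self):
        t = np.arange(0, 20, 1 / 50.0)
        x = np.sin(2 * np.pi * 0.25 * t) * np.where(t < 10, 1.0, 0.3)
        p = find_peaks(Waveform(0.0, 50.0, x), "ma", min_height=0.5)
        assert np.all(p.heights >= 0.5) and len(p) == 3
        assert np.allclose(p.times, [1.0, 5.0, 9.0], atol=0.1)

    def test_noisy_respiration_recovery(self):
        # 20% noise: >= 95% of apexes within 0.2 s and no noise-induced
        # extra peaks (detections never outnumber true apexes)
        w, truth = gen_respiration(600, 50, 4.0, 0.3, 1.0, 0.2, seed=11)
        p = find_peaks(w, "ma", window_s=1.0)
        d = np.abs(truth.peak_times[:, None] - p.times[None, :])
        assert (d.min(axis=1) <= 0.2).mean() >= 0.95
        assert len(p) <= len(truth.peak_times)


class TestComputeIBI:
    def test_pairwise_differences(self):
        p = PeakSeries(indices=[0, 1, 2], times=[2.0, 6.1, 10.0],
                       heights=[1, 1, 1])
        ibi = compute_ibi(p)
        np.testing.assert_allclose(ibi.intervals, [4.1, 3.9])
        np.testing.assert_allclose(ibi.times, [6.1, 10.0])

    def test_single_peak_empty(self):
        p = PeakSeries(indices=[5], times=[1.0], heights=[2.0])
        assert len(compute_ibi(p)) == 0

    def test_intervals_sum_telescopes(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(rng.uniform(2, 6, size=40))
        p = PeakSeries(indices=np.arange(40), times=times, heights=np.ones(40))
        ibi = compute_ibi(p)
        assert ibi.intervals.sum() == pytest.approx(times[-1] - times[0])

    def test_sinusoid_mean_ibi_matches_period(self):
        t = np.arange(0, 60, 1 / 50.0)
        w = Waveform(0.0, 50.0, np.sin(2 * np.pi * 0.25 * t))
        ibi = compute_ibi(find_peaks(w, "ma", min_distance_s=2))
        assert abs(ibi.intervals.mean() - 4.0) / 4.0 < 0.02
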