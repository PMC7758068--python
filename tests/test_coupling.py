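import numpy as np
import pytest

from nvsleep.core import Event, TimeSeries
from nvsleep.coupling import (bilateral_coherence_summary, bilateral_pearson,
                              xcorr_lfp_matrix, xcorr_neural_hbt, _xcorr_pair)


def _events(kind, n, length, gap=5.0):
    return [Event(kind, i * (length + gap), i * (length + gap) + length)
            for i in range(n)]


class TestScalarXcorr:
    def test_pure_delay_peaks_at_exactly_the_delay(self, rng):
        rate, delay_s = 30.0, 1.2
        n = int(600 * rate)
        from scipy import ndimage
        x = ndimage.gaussian_filter1d(rng.standard_normal(n), 10)
        y = np.roll(x, int(delay_s * rate))
        ev = _events("contiguous_NREM", 10, 30.0, gap=20.0)
        res = xcorr_neural_hbt(ev, TimeSeries(x, rate), TimeSeries(y, rate))
        assert res.peak == pytest.approx(1.0, abs=0.02)
        assert res.peak_lag_s == pytest.approx(delay_s, abs=1 / rate + 1e-9)

    def test_independent_channels_peak_below_point_one(self, rng):
        rate = 30.0
        n = int(1600 * rate)
        x = TimeSeries(rng.standard_normal(n), rate)
        y = TimeSeries(rng.standard_normal(n), rate)
        ev = _events("rest", 100, 10.0, gap=5.9)
        res = xcorr_neural_hbt(ev, x, y)
        assert res.n_events == 100
        assert abs(res.peak) < 0.1

    def test_short_events_skipped_with_count(self, rng):
        x = TimeSeries(rng.standard_normal(3000), 30.0)
        ev = _events("whisk_brief", 3, 1.0)  # class minimum 0.5 s < 2*max lag
        res = xcorr_neural_hbt(ev, x, x)
        assert res.n_events == 0

    def test_generator_hrf_lag_recovered(self, main_session, main_derived):
        from nvsleep.scoring import contiguity_filter
        cat = contiguity_filter(main_session.truth_hypnogram,
                                main_session.stim_times)
        nrem = cat.of_kind("contiguous_NREM")
        assert nrem, "default chain should produce contiguous NREM in 1 hr"
        res = xcorr_neural_hbt(nrem, main_derived["ctxL_gamma"],
                               main_derived["hbt_L"])
        truth_lag = main_session.truth_params.hrf_peak_lag_s
        assert res.peak > 0.2
        assert res.peak_lag_s == pytest.approx(truth_lag, abs=0.2)


class TestMatrixXcorr:
    def test_matrix_row_consistent_with_scalar_for_pure_delay(self, rng):
        # a frequency row whose power trace is a delayed copy of the target
        # must reproduce the scalar cross-correlation
        rate = 30.0
        from scipy import ndimage
        base = ndimage.gaussian_filter1d(rng.standard_normal(3200), 8)
        x = base[100:3100]
        y = base[64:3064]  # y(t) = x(t - 36 samples), no wraparound
        lags, c = _xcorr_pair(x - x.mean(), y - y.mean(), rate, 5.0)
        i = np.argmax(c)
        assert c[i] == pytest.approx(1.0, abs=1e-6)
        assert lags[i] == pytest.approx(1.2, abs=1 / rate + 1e-9)

    def test_gamma_driven_hbt_maximizes_in_gamma_rows(self, main_session,
                                                      main_derived):
        from nvsleep.scoring import contiguity_filter
        cat = contiguity_filter(main_session.truth_hypnogram,
                                main_session.stim_times)
        nrem = cat.of_kind("contiguous_NREM")[:6]
        res = xcorr_lfp_matrix(nrem, main_session.channels["neural_cortex_L"],
                               main_derived["hbt_L"])
        assert res.n_events > 0
        row_peak = np.abs(res.correlation).max(axis=1)
        gamma_rows = (res.frequencies >= 30) & (res.frequencies <= 100)
        low_rows = res.frequencies < 13
        assert row_peak[gamma_rows].max() > row_peak[low_rows].max()

    def test_independent_hbt_gives_flat_matrix(self, rng):
        rate20k = 2000.0
        n = int(200 * rate20k)
        lfp = TimeSeries(rng.standard_normal(n), rate20k)
        hbt = TimeSeries(rng.standard_normal(int(200 * 30)), 30.0)
        ev = _events("contiguous_NREM", 5, 30.0)
        res = xcorr_lfp_matrix(ev, lfp, hbt)
        assert np.abs(res.correlation).max() < 0.25  # (1,1) tapers are noisy
        assert np.abs(res.correlation).mean() < 0.1


class TestBilateral:
    def test_identical_channels_fully_correlated(self, rng):
        x = TimeSeries(rng.standard_normal(30 * 300), 30.0)
        ev = _events("rest", 5, 10.0)
        r, per = bilateral_pearson(ev, x, x)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(per, 1.0)

    def test_shared_variance_construction_tracks_fraction(self, rng):
        # equal-variance mixture: r should approximate the shared fraction
        s, rate = 0.6, 30.0
        n = int(1800 * rate)
        from scipy import ndimage
        def slow():
            return ndimage.gaussian_filter1d(rng.standard_normal(n), 15)
        c0, a, b = slow(), slow(), slow()
        left = TimeSeries(np.sqrt(s) * c0 + np.sqrt(1 - s) * a, rate)
        right = TimeSeries(np.sqrt(s) * c0 + np.sqrt(1 - s) * b, rate)
        ev = _events("contiguous_NREM", 30, 30.0, gap=29.9)
        r, _ = bilateral_pearson(ev, left, right)
        assert r == pytest.approx(s, abs=0.05)

    def test_sleep_elevated_shared_variance_orders_r(self, main_session,
                                                     main_derived):
        # defaults share more variance in sleep: r(NREM) must exceed r(rest),
        # mirroring the larger bilateral coupling observed during sleep
        from nvsleep.events import extract_state_events
        ses, der = main_session, main_derived
        cat = extract_state_events(ses.truth_hypnogram, der["whisk_train"],
                                   der["move_train"], ses.stim_times,
                                   ses.truth["true_awake_bins"])
        rest = cat.of_kind("rest")
        nrem = cat.of_kind("contiguous_NREM")
        assert rest and nrem
        r_rest, _ = bilateral_pearson(rest, der["hbt_L"], der["hbt_R"])
        r_nrem, _ = bilateral_pearson(nrem, der["hbt_L"], der["hbt_R"])
        assert r_nrem > r_rest


class TestBilateralCoherence:
    def test_identical_channels_unit_coherence_at_readouts(self, rng):
        x = TimeSeries(rng.standard_normal(30 * 1000), 30.0)
        ev = _events("asleep15", 1, 900.0)
        res = bilateral_coherence_summary(ev, x, x)
        assert res["readouts"][0.1] == pytest.approx(1.0, abs=1e-6)
        assert res["readouts"][0.01] == pytest.approx(1.0, abs=1e-6)

    def test_low_frequency_readout_refused_for_short_events(self, rng):
        x = TimeSeries(rng.standard_normal(30 * 300), 30.0)
        y = TimeSeries(rng.standard_normal(30 * 300), 30.0)
        ev = _events("rest", 10, 10.0, gap=19.9)
        res = bilateral_coherence_summary(ev, x, y)
        assert res["readouts"][0.01] is None
        assert "minimum resolvable" in res["refused"][0.01]
        assert res["min_resolvable_hz"] == pytest.approx(0.1)

    def test_swap_and_rescale_invariance(self, rng):
        x = TimeSeries(rng.standard_normal(30 * 1000), 30.0)
        y = TimeSeries(0.5 * x.values + rng.standard_normal(x.n), 30.0)
        ev = _events("asleep15", 1, 900.0)
        a = bilateral_coherence_summary(ev, x, y)["readouts"][0.1]
        b = bilateral_coherence_summary(ev, y, x)["readouts"][0.1]
        c = bilateral_coherence_summary(
            ev, TimeSeries(3.0 * x.values, 30.0), y)["readouts"][0.1]
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-9)

    def test_null_stays_below_confidence_level(self, rng):
        below = []
        for trial in range(10):
            x = TimeSeries(rng.standard_normal(30 * 950), 30.0)
            y = TimeSeries(rng.standard_normal(30 * 950), 30.0)
            ev = _events("asleep15", 1, 900.0)
            res = bilateral_coherence_summary(ev, x, y)
            below.append(res["readouts"][0.1] < res["confidence_level_95"])
        assert np.mean(below) >= 0.9
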