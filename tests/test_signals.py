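import numpy as np
import pytest

from nvsleep.core import TimeSeries
from nvsleep.signals import (BANDS, BeerLambertParams, band_power,
                             beer_lambert, correct_drift, emg_envelope,
                             hbt_to_reflectance, lowpass_resample,
                             select_roi_by_gamma)

RATE = 20000.0


def _tone(freq, dur=20.0, rate=RATE, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), rate, label="tone")


class TestBandPower:
    def test_in_band_sinusoid_power_is_half_amplitude_squared(self):
        bp = band_power(_tone(50.0, amp=2.0), BANDS["gamma"])
        mid = bp.values[bp.n // 4: 3 * bp.n // 4]
        assert np.allclose(mid, 2.0**2 / 2, rtol=0.05)

    def test_out_of_band_sinusoid_rejected(self):
        in_band = band_power(_tone(50.0), BANDS["gamma"]).values
        out_band = band_power(_tone(200.0), BANDS["gamma"]).values
        mid = slice(len(in_band) // 4, 3 * len(in_band) // 4)
        assert out_band[mid].mean() < 0.01 * in_band[mid].mean()

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        raw = TimeSeries(rng.standard_normal(int(120 * RATE)), RATE)
        ratios = []
        for name in ("delta", "theta", "alpha", "beta", "gamma", "mua"):
            b = BANDS[name]
            p = band_power(raw, b).values
            mid = p[p.size // 10: -p.size // 10]
            ratios.append(mid.mean() / (b.high - b.low))
        ratios = np.array(ratios) / np.mean(ratios)
        assert np.all(np.abs(ratios - 1) < 0.10)

    def test_power_scales_quadratically(self, rng):
        x = rng.standard_normal(int(30 * RATE))
        p1 = band_power(TimeSeries(x, RATE), BANDS["gamma"]).values
        p3 = band_power(TimeSeries(3 * x, RATE), BANDS["gamma"]).values
        assert np.allclose(p3, 9 * p1, rtol=1e-6, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(TimeSeries(np.zeros(1000), 1000.0), BANDS["mua"])


class TestEmgEnvelope:
    def test_amplitude_doubling_raises_envelope_by_log10_4(self, rng):
        x = rng.standard_normal(int(30 * RATE))
        e1 = emg_envelope(TimeSeries(x, RATE)).values
        e2 = emg_envelope(TimeSeries(2 * x, RATE)).values
        mid = slice(len(e1) // 4, 3 * len(e1) // 4)
        assert np.median(e2[mid] - e1[mid]) == pytest.approx(np.log10(4), abs=0.02)

    def test_variance_step_transitions_over_half_second(self, rng):
        n = int(20 * RATE)
        x = rng.standard_normal(n)
        x[n // 2:] *= 10
        env = emg_envelope(TimeSeries(x, RATE)).values
        t = np.arange(env.size) / 30.0
        lo = env[(t > 4) & (t < 9)].mean()
        hi = env[(t > 11) & (t < 16)].mean()
        # crossing midpoint within ~1 s of the step (Gaussian sigma 0.5 s)
        crossing = t[np.argmin(np.abs(env - (lo + hi) / 2))]
        assert abs(crossing - 10.0) < 1.0

    def test_sleep_bins_have_lower_envelope_than_awake(self, short_session, short_derived):
        env = short_derived["emg_power"].values
        codes = short_session.truth_hypnogram.as_codes()
        st = np.repeat(codes, 150)[: env.size]
        awake, nrem = env[st == 0], env[st == 1]
        assert np.median(nrem) < np.median(awake)


class TestBeerLambert:
    def test_zero_reflectance_change_is_zero_hbt(self):
        assert beer_lambert(0.0) == 0.0

    def test_printed_stimulus_worked_example(self):
        # -2.4% reflectance decrease corresponds to ~16.8 uM with the default
        # 530 nm extinction and pathlength constants
        assert beer_lambert(-0.024) == pytest.approx(16.8, abs=0.5)

    def test_log_asymmetry_and_monotonicity(self):
        up = beer_lambert(-0.024)
        down = beer_lambert(+0.024)
        assert down < 0 and abs(down) < up
        x = np.linspace(-0.1, 0.1, 101)
        assert np.all(np.diff(beer_lambert(x)) < 0)

    def test_nonphysical_reflectance_rejected(self):
        with pytest.raises(ValueError):
            beer_lambert(-1.0)
        with pytest.raises(ValueError):
            BeerLambertParams(epsilon_hbt_530=-1.0)

    def test_roundtrip_with_encoding(self):
        hbt = np.linspace(-20, 100, 50)
        r = hbt_to_reflectance(hbt, r0=1.0)
        back = beer_lambert(r / 1.0 - 1.0)
        assert np.max(np.abs(back - hbt)) < 1e-9


class TestLowpassResample:
    def test_dc_unchanged(self):
        ts = TimeSeries(np.full(3000, 2.5), 30.0)
        out = lowpass_resample(ts, 1.0, 4, 30.0)
        assert np.allclose(out.values, 2.5, atol=1e-9)

    def test_stopband_attenuation_exceeds_20db(self):
        t = np.arange(30 * 60) / 30.0
        mix = np.sin(2 * np.pi * 0.5 * t) + np.sin(2 * np.pi * 5.0 * t)
        out = lowpass_resample(TimeSeries(mix, 30.0), 1.0, 4, 30.0).values
        resid = out - np.sin(2 * np.pi * 0.5 * t)
        # 5 Hz component amplitude reduced by > 20 dB (factor 10)
        assert np.abs(resid[200:-200]).max() < 0.1

    def test_passband_roundtrip_identity(self, rng):
        from scipy import signal as sg
        x = rng.standard_normal(30 * 120)
        sos = sg.butter(8, 5.0 / 15.0, output="sos")
        x = sg.sosfiltfilt(sos, x)  # band-limited well inside 14 Hz
        out = lowpass_resample(TimeSeries(x, 30.0), 14.0, 4, 30.0).values
        rms = np.sqrt(np.mean((out[100:-100] - x[100:-100]) ** 2))
        assert rms < 1e-3 * np.std(x)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_resample(TimeSeries(np.zeros(100), 30.0), 15.0, 4, 30.0)


class TestCorrectDrift:
    def test_constant_reference_leaves_input_unchanged(self, rng):
        x = TimeSeries(1.0 + 0.01 * rng.standard_normal(30 * 300), 30.0)
        ref = TimeSeries(np.full(x.n, 3.0), 30.0)
        out, info = correct_drift(x, ref)
        assert np.allclose(out.values, x.values, rtol=1e-6)

    def test_two_exponent_drift_recovered(self, rng):
        t = np.arange(30 * 1200) / 30.0
        drift = 1.0 + 0.05 * np.exp(-t / 100.0) + 0.08 * np.exp(-t / 900.0)
        truth = 1.0 + 0.01 * np.sin(2 * np.pi * 0.1 * t)
        x = TimeSeries(truth * drift, 30.0)
        ref = TimeSeries(2.0 * drift, 30.0)
        out, info = correct_drift(x, ref)
        scale = out.values[: 30 * 60].mean() / truth[: 30 * 60].mean()
        rms = np.sqrt(np.mean((out.values / scale - truth) ** 2))
        assert rms < 0.005 * truth.mean()
        # output preserves the first-minute level of the input
        assert out.values[: 30 * 60].mean() == pytest.approx(
            x.values[: 30 * 60].mean(), rel=1e-3)

    def test_fit_is_deterministic(self, rng):
        t = np.arange(30 * 600) / 30.0
        ref = TimeSeries(1 + 0.1 * np.exp(-t / 200.0) + 0.001 * rng.standard_normal(t.size), 30.0)
        x = TimeSeries(np.ones(t.size), 30.0)
        _, i1 = correct_drift(x, ref)
        _, i2 = correct_drift(x, ref)
        assert i1["params"] == i2["params"]


class TestRoiSelection:
    def _planted_stack(self, rng, lag_s=1.5, n=30 * 1000, h=8, w=8, px=(5, 2)):
        g = rng.standard_normal(n)
        from scipy import ndimage
        g = ndimage.gaussian_filter1d(g, 6)
        stack = 0.1 * rng.standard_normal((n, h, w))
        lag = int(lag_s * 30)
        sig = np.roll(-g, lag)  # reflectance drops when gamma rises, lagged
        stack[:, px[0], px[1]] += sig
        from nvsleep.core import TimeSeries as TS
        return stack, TS(g, 30.0)

    def test_mask_centers_on_planted_pixel_with_correct_lag(self, rng):
        stack, gamma = self._planted_stack(rng)
        mask, info = select_roi_by_gamma(stack, gamma, px_per_mm=4.0)
        assert info["center"] == (5, 2)
        assert mask[5, 2]
        assert abs(info["peak_lag_s"] - 1.5) <= 1.5 / 30 + 1e-9

    def test_uniform_stack_flagged_low_confidence(self):
        stack = np.ones((30 * 60, 4, 4))
        gamma = TimeSeries(np.sin(np.arange(30 * 60) / 10.0), 30.0)
        with pytest.warns(UserWarning):
            mask, info = select_roi_by_gamma(stack, gamma, px_per_mm=2.0)
        assert info["low_confidence"]
        assert info["center"] == (0, 0)  # documented tie-break


def test_zero_phase_conditioning_preserves_pulse_symmetry(rng):
    # a symmetric input pulse must come out symmetric (peak shift < 1 sample)
    n = int(20 * RATE)
    t = np.arange(n) / RATE
    carrier = np.sin(2 * np.pi * 50 * t)
    env = np.exp(-0.5 * ((t - 10.0) / 1.0) ** 2)
    bp = band_power(TimeSeries(carrier * env, RATE), BANDS["gamma"])
    peak_t = bp.times()[np.argmax(bp.values)]
    assert abs(peak_t - 10.0) < 1.0 / 30.0 + 1e-9
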