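"""Multitaper spectral estimation (Slepian tapers) and heart-rate tracking.

Estimates follow the classic multitaper recipe: the demeaned signal is
multiplied by K discrete prolate spheroidal sequences with time-bandwidth
product TW, each tapered copy is Fourier transformed with padding to a power
of two, and the eigenspectra are averaged.  Taper pairs are written (TW, K);
a valid pair satisfies K <= 2 TW - 1.  ``pad_level = p`` pads the FFT to
``2 ** (ceil(log2 N) + p)`` samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal
from scipy.signal.windows import dpss

from .core import TimeSeries
from .signals import ANALYSIS_RATE, _butter_sos


@dataclass(frozen=True)
class TaperSpec:
    """Multitaper parameters: time-bandwidth TW, taper count K, FFT padding."""

    time_bandwidth: float = 3.0
    n_tapers: int = 5
    pad_level: int = 1

    def __post_init__(self):
        if self.pad_level < 0:
            raise ValueError("pad_level must be >= 0")
        if self.n_tapers < 1 or self.time_bandwidth <= 0:
            raise ValueError("need n_tapers >= 1 and time_bandwidth > 0")

    def effective_k(self) -> int:
        kmax = int(np.floor(2 * self.time_bandwidth - 1))
        if self.n_tapers > kmax:
            warnings.warn(
                f"K={self.n_tapers} exceeds 2*TW-1={kmax}; clipping to {kmax}"
            )
            return kmax
        return self.n_tapers


@dataclass
class SpectralResult:
    """Frequency grid plus a power density or squared-coherence estimate."""

    frequencies: np.ndarray
    estimate: np.ndarray
    dof: float
    kind: str = "psd"  # "psd" or "coherence"
    confidence_level_95: float | None = None


def _nfft(n: int, pad_level: int) -> int:
    return int(2 ** (np.ceil(np.log2(n)) + pad_level))


def _eigenspectra(x: np.ndarray, rate: float, tapers: TaperSpec):
    """Tapered one-sided FFTs of a demeaned 1-D segment.

    Returns (freqs, J) where J has shape (K, n_freqs) and is scaled so that
    ``mean_k |J_k|^2`` is a one-sided power density in units^2/Hz.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    k = tapers.effective_k()
    wins = dpss(n, tapers.time_bandwidth, Kmax=k)
    if wins.ndim == 1:
        wins = wins[None, :]
    nfft = _nfft(n, tapers.pad_level)
    xd = x - x.mean()
    j = np.fft.rfft(wins * xd[None, :], n=nfft, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    # one-sided density scaling: double all bins except DC (and Nyquist)
    scale = np.full(freqs.size, 2.0 / rate)
    scale[0] = 1.0 / rate
    if nfft % 2 == 0:
        scale[-1] = 1.0 / rate
    return freqs, j * np.sqrt(scale)[None, :]


def multitaper_psd(ts: TimeSeries, tapers: TaperSpec | None = None) -> SpectralResult:
    """One-sided multitaper power spectral density.

    Satisfies Parseval approximately: the integral of the density over
    frequency matches the demeaned signal variance.
    """
    tapers = tapers or TaperSpec()
    if ts.n < 8:
        raise ValueError("need at least 8 samples for a spectral estimate")
    freqs, j = _eigenspectra(ts.values, ts.rate, tapers)
    psd = np.mean(np.abs(j) ** 2, axis=0)
    return SpectralResult(freqs, psd, dof=2 * j.shape[0], kind="psd")


def multitaper_spectrogram(
    ts: TimeSeries,
    window_s: float,
    step_s: float,
    tapers: TaperSpec | None = None,
    fpass: tuple[float, float] | None = (1.0, 100.0),
):
    """Sliding-window multitaper spectrogram.

    Returns (times, frequencies, power) with power shaped (n_freqs, n_frames)
    and frame times at window centers.  Frame count is
    ``floor((n - n_window) / n_step) + 1``.  ``fpass`` restricts the output
    band (default 1-100 Hz, the LFP band of interest); pass None to keep all.
    """
    tapers = tapers or TaperSpec(5.0, 9, pad_level=0)
    n_win = int(round(window_s * ts.rate))
    n_step = int(round(step_s * ts.rate))
    if n_win > ts.n:
        raise ValueError("window longer than the signal")
    if n_step > n_win:
        warnings.warn("step larger than window leaves unanalyzed gaps")
    n_frames = (ts.n - n_win) // n_step + 1
    k = tapers.effective_k()
    wins = dpss(n_win, tapers.time_bandwidth, Kmax=k)
    if wins.ndim == 1:
        wins = wins[None, :]
    nfft = _nfft(n_win, tapers.pad_level)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / ts.rate)
    scale = np.full(freqs.size, 2.0 / ts.rate)
    scale[0] = 1.0 / ts.rate
    if nfft % 2 == 0:
        scale[-1] = 1.0 / ts.rate

    idx = np.arange(n_win)[None, :] + n_step * np.arange(n_frames)[:, None]
    segs = ts.values[idx]  # (frames, n_win)
    segs = segs - segs.mean(axis=1, keepdims=True)
    # (frames, K, nfreq)
    j = np.fft.rfft(segs[:, None, :] * wins[None, :, :], n=nfft, axis=2)
    power = (np.abs(j) ** 2).mean(axis=1) * scale[None, :]
    power = power.T  # (freq, frames)
    times = ts.t0 + (idx[:, 0] + n_win / 2.0) / ts.rate
    if fpass is not None:
        keep = (freqs >= fpass[0]) & (freqs <= fpass[1])
        freqs, power = freqs[keep], power[keep]
    return times, freqs, power


def coherence_confidence_95(dof: float) -> float:
    """Analytic 95% significance level for squared coherence.

    For dof tapered/trial degrees of freedom the null (independent signals)
    squared-coherence threshold at p = 0.05 is ``1 - 0.05 ** (1 / (dof/2 - 1))``.
    """
    if dof <= 2:
        return 1.0
    return float(1.0 - 0.05 ** (1.0 / (dof / 2.0 - 1.0)))


def multitaper_coherence(
    x: TimeSeries | np.ndarray,
    y: TimeSeries | np.ndarray,
    tapers: TaperSpec | None = None,
    rate: float | None = None,
) -> SpectralResult:
    """Magnitude-squared coherence (MoC^2) between two signals.

    ``x`` and ``y`` may be single TimeSeries or 2-D arrays of equal-length
    trials (n_trials, n_samples); cross- and auto-spectra are averaged over
    tapers and trials before forming the ratio, giving dof = 2 K n_trials.
    """
    tapers = tapers or TaperSpec(3.0, 5, pad_level=1)
    if isinstance(x, TimeSeries):
        rate = x.rate
        if not isinstance(y, TimeSeries) or y.rate != rate or y.n != x.n:
            raise ValueError("x and y must share rate and length")
        xt, yt = x.values[None, :], y.values[None, :]
    else:
        if rate is None:
            raise ValueError("rate is required for array input")
        xt, yt = np.atleast_2d(np.asarray(x, float)), np.atleast_2d(np.asarray(y, float))
        if xt.shape != yt.shape:
            raise ValueError("trial arrays must have identical shape")
    if np.ptp(xt) == 0 or np.ptp(yt) == 0:
        raise ValueError("coherence is undefined for a constant input")
    n_trials = xt.shape[0]
    sxx = syy = sxy = None
    freqs = None
    for i in range(n_trials):
        freqs, jx = _eigenspectra(xt[i], rate, tapers)
        _, jy = _eigenspectra(yt[i], rate, tapers)
        pxx = (np.abs(jx) ** 2).sum(axis=0)
        pyy = (np.abs(jy) ** 2).sum(axis=0)
        pxy = (jx * np.conj(jy)).sum(axis=0)
        sxx = pxx if sxx is None else sxx + pxx
        syy = pyy if syy is None else syy + pyy
        sxy = pxy if sxy is None else sxy + pxy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh2 = np.abs(sxy) ** 2 / (sxx * syy)
    coh2 = np.clip(np.nan_to_num(coh2), 0.0, 1.0)
    k = tapers.effective_k()
    dof = 2.0 * k * n_trials
    return SpectralResult(
        freqs, coh2, dof=dof, kind="coherence",
        confidence_level_95=coherence_confidence_95(dof),
    )


def track_heart_rate(
    reflectance_l: TimeSeries,
    reflectance_r: TimeSeries,
    window_s: float = 10.0 / 3.0,
    step_s: float = 1.0,
    tapers: TaperSpec | None = None,
    band: tuple[float, float] = (5.0, 15.0),
    out_rate: float = ANALYSIS_RATE,
) -> TimeSeries:
    """Heart rate from the cardiac spectral peak of the reflectance signals.

    Per hemisphere, a multitaper spectrogram (3.33 s window, 1 s step,
    (2, 3) tapers) is computed and the frequency of maximum power in the
    5-15 Hz band extracted per frame (ties break toward the lower frequency).
    The two hemispheres are averaged, flat-spectrum frames are interpolated,
    and the trace is zero-phase lowpass filtered (< 2 Hz, 3rd order) after
    interpolation onto the 30 Hz analysis grid.
    """
    tapers = tapers or TaperSpec(2.0, 3, pad_level=1)
    if reflectance_l.rate < 30 or reflectance_l.rate != reflectance_r.rate:
        raise ValueError("need matched reflectance rates of at least 30 Hz")
    traces = []
    times = None
    for ts in (reflectance_l, reflectance_r):
        t, f, p = multitaper_spectrogram(ts, window_s, step_s, tapers, fpass=band)
        if f.size == 0:
            raise ValueError("empty heart-rate band; check rates")
        peak = f[np.argmax(p, axis=0)]
        flat = p.max(axis=0) <= 0
        peak = peak.astype(float)
        peak[flat] = np.nan
        traces.append(peak)
        times = t
    hr = np.nanmean(np.vstack(traces), axis=0)
    bad = ~np.isfinite(hr)
    if bad.all():
        raise ValueError("no resolvable cardiac peak anywhere in the session")
    if bad.any():
        good = ~bad
        hr = np.interp(np.arange(hr.size), np.flatnonzero(good), hr[good])
    # align to the analysis grid of the full session, edge-held
    n_out = int(round(reflectance_l.duration * out_rate))
    t_out = reflectance_l.t0 + np.arange(n_out) / out_rate
    fill = interpolate.interp1d(
        times, hr, bounds_error=False, fill_value=(hr[0], hr[-1])
    )
    hr30 = fill(t_out)
    sos = _butter_sos(3, 2.0, out_rate, "low")
    hr30 = signal.sosfiltfilt(sos, hr30)
    return TimeSeries(hr30, out_rate, reflectance_l.t0, "Hz", "heart_rate")
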