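"""Conditioning of raw channels into analysis-rate (30 Hz) derived signals.

All filtering is zero-phase (forward-backward), so the effective attenuation
corresponds to twice the nominal filter order; stated orders below are the
nominal one-pass orders.  Resampling is polyphase and anti-aliased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, optimize, signal

from .core import TimeSeries

ANALYSIS_RATE = 30.0  # Hz, the common rate of all derived channels

# ---------------------------------------------------------------------------
# band definitions


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with (low, high) edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


#: Standard LFP/MUA bands.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 10.0),
    "alpha": BandSpec("alpha", 10.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 100.0),
    "mua": BandSpec("mua", 300.0, 3000.0),
}


# ---------------------------------------------------------------------------
# Beer-Lambert conversion


@dataclass(frozen=True)
class BeerLambertParams:
    """Constants of the 530 nm isosbestic Beer-Lambert conversion.

    epsilon_hbt_530 : molar extinction coefficient of total hemoglobin at
        530 nm, in 1/(M cm).
    pathlength : estimated photon pathlength through tissue, in cm.

    Defaults follow the calibration literature conventionally used for
    thinned-skull IOS at 530 nm.
    """

    epsilon_hbt_530: float = 39036.4
    pathlength: float = 0.037

    def __post_init__(self):
        if self.epsilon_hbt_530 <= 0 or self.pathlength <= 0:
            raise ValueError("extinction and pathlength must be positive")

    @property
    def epsilon_x(self) -> float:
        """Product epsilon * pathlength, in 1/M."""
        return self.epsilon_hbt_530 * self.pathlength


def beer_lambert(delta_r_over_r, params: BeerLambertParams | None = None):
    """Convert fractional reflectance change to total-hemoglobin change.

    ``dHbT = -ln(1 + dR/R) / (epsilon * X)``, reported in micromolar.  At the
    530 nm isosbestic point reflectance falls as blood volume rises, so a
    negative dR/R maps to a positive dHbT.

    Parameters
    ----------
    delta_r_over_r : array_like
        Fractional reflectance change, must be > -1 everywhere.
    params : BeerLambertParams, optional

    Returns
    -------
    ndarray or float
        dHbT in uM.
    """
    params = params or BeerLambertParams()
    x = np.asarray(delta_r_over_r, dtype=float)
    if np.any(x <= -1):
        raise ValueError("dR/R <= -1 is non-physical (reflectance would vanish)")
    out = -np.log1p(x) / params.epsilon_x * 1e6
    return out if out.ndim else float(out)


def hbt_to_reflectance(hbt_um, r0: float = 1.0, params: BeerLambertParams | None = None):
    """Inverse of :func:`beer_lambert`: encode dHbT (uM) as reflectance.

    ``R = R0 * exp(-epsilon * X * dHbT)`` with dHbT converted to molar. The
    round trip ``beer_lambert(R/R0 - 1)`` is exact up to floating point.
    """
    params = params or BeerLambertParams()
    return r0 * np.exp(-params.epsilon_x * np.asarray(hbt_um, dtype=float) * 1e-6)


# ---------------------------------------------------------------------------
# filtering / resampling primitives


def _butter_sos(order: int, cutoff, rate: float, btype: str):
    nyq = rate / 2.0
    wn = np.atleast_1d(np.asarray(cutoff, dtype=float)) / nyq
    if np.any(wn >= 1.0):
        raise ValueError(
            f"cutoff {cutoff} Hz at or above Nyquist ({nyq} Hz) of rate {rate} Hz"
        )
    return signal.butter(order, wn if wn.size > 1 else wn[0], btype=btype, output="sos")


def _resample(values: np.ndarray, rate: float, out_rate: float) -> np.ndarray:
    if rate == out_rate:
        return values
    frac = Fraction(out_rate / rate).limit_denominator(10**6)
    return signal.resample_poly(values, frac.numerator, frac.denominator)


def lowpass_resample(
    ts: TimeSeries, cutoff: float, order: int = 4, out_rate: float = ANALYSIS_RATE
) -> TimeSeries:
    """Zero-phase Butterworth lowpass followed by polyphase resampling."""
    if cutoff >= min(ts.rate, out_rate) / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist of input or output rate")
    sos = _butter_sos(order, cutoff, ts.rate, "low")
    filt = signal.sosfiltfilt(sos, ts.values)
    out = _resample(filt, ts.rate, out_rate)
    return TimeSeries(out, out_rate, ts.t0, ts.units, ts.label)


def _working_rate(raw_rate: float, band_high: float) -> float:
    """Rate at which a band can be filtered without loss: the band's content
    is untouched as long as its upper edge stays well inside Nyquist, so low
    bands are processed on an anti-alias-decimated copy for speed."""
    target = max(6.0 * band_high, 120.0)
    return raw_rate if raw_rate <= target else target


def band_power(raw: TimeSeries, band: BandSpec, out_rate: float = ANALYSIS_RATE) -> TimeSeries:
    """Band-limited power of a raw neural signal at the analysis rate.

    Zero-phase 3rd-order Butterworth bandpass, pointwise square, zero-phase
    3rd-order lowpass < 10 Hz, then polyphase resampling.  Low bands are
    bandpassed on an anti-alias-decimated copy of the raw signal (identical
    output: the decimation filter only removes content the bandpass rejects).
    Output can dip slightly below zero from filter ringing; it is not clipped.
    """
    if raw.rate < 2 * band.high:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz above Nyquist of {raw.rate} Hz"
        )
    wr = _working_rate(raw.rate, band.high)
    x = np.asarray(raw.values, dtype=float)
    if wr < raw.rate:
        x = _resample(x, raw.rate, wr)
    sos_bp = _butter_sos(3, (band.low, band.high), wr, "bandpass")
    x = signal.sosfiltfilt(sos_bp, x)
    x *= x
    sos_lp = _butter_sos(3, 10.0, wr, "low")
    x = signal.sosfiltfilt(sos_lp, x)
    out = _resample(x, wr, out_rate)
    n_expect = int(round(raw.duration * out_rate))
    out = out[:n_expect]
    return TimeSeries(out, out_rate, raw.t0, "a.u.", f"{raw.label}_{band.name}_power")


def emg_envelope(
    raw: TimeSeries, out_rate: float = ANALYSIS_RATE, floor: float = 1e-12
) -> TimeSeries:
    """Log-power envelope of the nuchal EMG.

    Zero-phase 3rd-order Butterworth bandpass 300-3000 Hz, square, Gaussian
    smoothing (sigma = 0.5 s, unit-area kernel), log10, resample to 30 Hz.
    The squared signal is anti-alias decimated to 300 Hz before the Gaussian
    (the 0.5 s kernel passes nothing above a few Hz, so this is lossless).
    ``floor`` guards the logarithm on silent stretches.
    """
    if raw.rate < 6000:
        raise ValueError("EMG conditioning needs a sampling rate >= 6 kHz")
    sos = _butter_sos(3, (300.0, min(3000.0, raw.rate / 2 * 0.99)), raw.rate, "bandpass")
    x = signal.sosfiltfilt(sos, np.asarray(raw.values, dtype=float))
    x *= x
    mid_rate = 300.0
    x = _resample(x, raw.rate, mid_rate)
    x = ndimage.gaussian_filter1d(x, sigma=0.5 * mid_rate)
    x = np.log10(np.maximum(x, floor))
    out = _resample(x, mid_rate, out_rate)[: int(round(raw.duration * out_rate))]
    return TimeSeries(out, out_rate, raw.t0, "log10(a.u.)", "emg_power")


# ---------------------------------------------------------------------------
# drift correction


def _two_exp(t, a, tau1, b, tau2, c):
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + c


def _one_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def correct_drift(
    reflectance: TimeSeries, reference_roi: TimeSeries
) -> tuple[TimeSeries, dict]:
    """Remove slow camera-sensitivity drift using a reference region.

    A two-exponent function ``a exp(-t/tau1) + b exp(-t/tau2) + c`` is fit to
    the reference trace (a region without hemodynamic signal); the reflectance
    is divided by the fit normalized to its mean over the first minute.  The
    model is multiplicative, matching a light-source / camera-gain mechanism.

    Returns the corrected series and a dict of fit parameters.
    """
    if reference_roi.rate != reflectance.rate or reference_roi.n != reflectance.n:
        raise ValueError("reference must share rate and length with reflectance")
    t = reference_roi.times() - reference_roi.t0
    y = reference_roi.values
    dur = t[-1] if t[-1] > 0 else 1.0
    c0 = float(y[-max(1, y.size // 20):].mean())
    a0 = float(y[0] - c0)
    info: dict = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _two_exp,
                t,
                y,
                p0=[a0 / 2, dur / 10, a0 / 2, dur, c0],
                bounds=([-np.inf, 1e-3, -np.inf, 1e-3, -np.inf], np.inf),
                maxfev=20000,
            )
        fit = _two_exp(t, *popt)
        info["model"] = "two_exponent"
        info["params"] = dict(zip(("a", "tau1", "b", "tau2", "c"), map(float, popt)))
    except RuntimeError:
        warnings.warn("two-exponent drift fit did not converge; using single exponential")
        popt, _ = optimize.curve_fit(
            _one_exp, t, y, p0=[a0, dur, c0],
            bounds=([-np.inf, 1e-3, -np.inf], np.inf), maxfev=20000,
        )
        fit = _one_exp(t, *popt)
        info["model"] = "one_exponent"
        info["params"] = dict(zip(("a", "tau", "c"), map(float, popt)))
    first_min = slice(0, max(1, int(min(60.0, dur) * reflectance.rate)))
    norm = fit / fit[first_min].mean()
    corrected = reflectance.values / norm
    info["reference_rms_residual"] = float(np.sqrt(np.mean((y - fit) ** 2)))
    return (
        TimeSeries(corrected, reflectance.rate, reflectance.t0, reflectance.units,
                   reflectance.label),
        info,
    )


# ---------------------------------------------------------------------------
# ROI selection


def select_roi_by_gamma(
    reflectance_stack: np.ndarray,
    gamma_power: TimeSeries,
    stack_rate: float = ANALYSIS_RATE,
    roi_diameter_mm: float = 1.0,
    px_per_mm: float = 30.0,
    lag_range_s: tuple[float, float] = (1.0, 2.0),
) -> tuple[np.ndarray, dict]:
    """Place a circular ROI on the pixels most correlated with gamma power.

    For each pixel the cross-correlation between the negated reflectance
    (so that vasodilation correlates positively with neural activity) and the
    gamma band power is evaluated at lags of 1-2 s (hemodynamics trailing
    neural activity); the mask of the stated diameter is centered on the pixel
    with the maximal correlation.

    Parameters
    ----------
    reflectance_stack : ndarray, shape (T, H, W)
    gamma_power : TimeSeries at the stack rate.

    Returns
    -------
    mask : boolean ndarray (H, W)
    info : dict with center, peak correlation, best lag and a low-confidence
        flag for degenerate (e.g. uniform) stacks.
    """
    stack = np.asarray(reflectance_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    nt, h, w = stack.shape
    if nt != gamma_power.n:
        raise ValueError("stack and gamma power must cover the same interval")
    if nt / stack_rate < 15 * 60:
        warnings.warn("ROI selection on less than 15 min of data; placement may be noisy")

    g = gamma_power.values - gamma_power.values.mean()
    g_sd = g.std()
    x = -(stack - stack.mean(axis=0))  # negated: dilation -> positive
    x_sd = x.std(axis=0)
    lag_lo = int(round(lag_range_s[0] * stack_rate))
    lag_hi = int(round(lag_range_s[1] * stack_rate))
    best_r = np.full((h, w), -np.inf)
    best_lag = np.zeros((h, w), dtype=int)
    for lag in range(lag_lo, lag_hi + 1):
        n = nt - lag
        # hemodynamics at t+lag vs neural at t
        num = np.tensordot(g[:n], x[lag:], axes=(0, 0)) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / (g_sd * x_sd)
        r = np.where(np.isfinite(r), r, -np.inf)
        upd = r > best_r
        best_lag[upd] = lag
        best_r = np.where(upd, r, best_r)

    low_confidence = not np.isfinite(best_r).any() or np.all(x_sd == 0)
    if low_confidence:
        center = (0, 0)  # documented tie-break: lowest row-major index
        peak_r, peak_lag = 0.0, lag_lo
    else:
        flat = int(np.argmax(best_r))
        center = np.unravel_index(flat, (h, w))
        peak_r = float(best_r[center])
        peak_lag = int(best_lag[center])

    yy, xx = np.ogrid[:h, :w]
    radius_px = roi_diameter_mm * px_per_mm / 2.0
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2
    info = {
        "center": (int(center[0]), int(center[1])),
        "peak_correlation": peak_r,
        "peak_lag_s": peak_lag / stack_rate,
        "low_confidence": bool(low_confidence),
    }
    return mask, info
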