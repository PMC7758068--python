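"""Neurovascular cross-correlation and bilateral connectivity.

All pairwise statistics share one preprocessing contract: per event, both
signals are truncated to the minimum duration of the event class (so every
event contributes an equal-length segment), mean-subtracted, and zero-phase
lowpass filtered (< 1 Hz, 4th-order Butterworth).  Aggregation is always
within subject/hemisphere first, then across subjects.

Sign convention for lags: positive lag means the hemodynamic signal follows
the neural signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .core import Event, TimeSeries
from .events import lowpass_1hz
from .spectral import SpectralResult, TaperSpec, multitaper_coherence, multitaper_spectrogram

#: minimum event duration per class (s); events are truncated to these
CLASS_MIN_S = {
    "rest": 10.0,
    "whisk_brief": 0.5,
    "whisk_moderate": 2.0,
    "whisk_extended": 5.0,
    "stim": 2.0,
    "contiguous_NREM": 30.0,
    "contiguous_REM": 60.0,
    "alert15": 900.0,
    "asleep15": 900.0,
    "all15": 900.0,
}


@dataclass
class XCorrResult:
    """Normalized cross-correlation over a symmetric lag grid."""

    lags_s: np.ndarray
    correlation: np.ndarray  # (n_lags,) or (n_freqs, n_lags)
    peak: float
    peak_lag_s: float
    n_events: int
    frequencies: np.ndarray | None = None


def _class_min(events: Sequence[Event]) -> float:
    kinds = {e.kind for e in events}
    if len(kinds) > 1:
        raise ValueError(f"events must be of one class, got {sorted(kinds)}")
    kind = kinds.pop()
    return CLASS_MIN_S.get(kind, min(e.duration for e in events))


def _prep_segment(ts: TimeSeries, start: float, length_s: float) -> np.ndarray | None:
    i0 = int(round((start - ts.t0) * ts.rate))
    i1 = i0 + int(round(length_s * ts.rate))
    if i0 < 0 or i1 > ts.n:
        return None
    seg = ts.values[i0:i1]
    return seg - seg.mean()


def _xcorr_pair(x: np.ndarray, y: np.ndarray, rate: float, max_lag_s: float):
    """Normalized cross-correlation of y (follower) against x (leader).

    ``c[k]`` estimates corr(x(t), y(t + k/rate)).  Normalization is unbiased
    (each lag divided by its overlap count and the segment SDs), so a pure
    delay peaks at exactly 1; values are clipped to [-1, 1].
    """
    n = x.size
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("cross-correlation undefined for a constant segment")
    full = _sig.correlate(y, x, mode="full")
    lags = np.arange(-n + 1, n)
    overlap = n - np.abs(lags)
    full = full / (overlap * sx * sy)
    max_lag = int(round(max_lag_s * rate))
    keep = (lags >= -max_lag) & (lags <= max_lag)
    return lags[keep] / rate, np.clip(full[keep], -1.0, 1.0)


def xcorr_neural_hbt(
    events: Sequence[Event],
    neural: TimeSeries,
    hbt: TimeSeries,
    max_lag_s: float = 5.0,
) -> XCorrResult:
    """Cross-correlation between a neural power trace and dHbT over events.

    Events shorter than twice the maximum lag are skipped (counted in the
    result).  The per-event correlations are averaged; the peak and its lag
    are taken from the averaged curve.
    """
    if neural.rate != hbt.rate:
        raise ValueError("neural and hemodynamic channels must share a rate")
    trunc = _class_min(events)
    nl = lowpass_1hz(neural)
    hl = lowpass_1hz(hbt)
    curves = []
    lags = None
    for ev in events:
        if trunc < 2 * max_lag_s:
            break
        x = _prep_segment(nl, ev.start, trunc)
        y = _prep_segment(hl, ev.start, trunc)
        if x is None or y is None or x.std() == 0 or y.std() == 0:
            continue
        lags, c = _xcorr_pair(x, y, neural.rate, max_lag_s)
        curves.append(c)
    if not curves:
        return XCorrResult(np.array([]), np.array([]), np.nan, np.nan, 0)
    mean_c = np.mean(curves, axis=0)
    i = int(np.argmax(np.abs(mean_c)))
    return XCorrResult(lags, mean_c, float(mean_c[i]), float(lags[i]), len(curves))


def xcorr_lfp_matrix(
    events: Sequence[Event],
    lfp_raw: TimeSeries,
    hbt: TimeSeries,
    max_lag_s: float = 5.0,
    window_s: float = 1.0,
    step_s: float = 1.0 / 30.0,
    tapers: TaperSpec | None = None,
) -> XCorrResult:
    """Lag x frequency cross-correlation between the LFP spectrogram and dHbT.

    Per event, a multitaper spectrogram of the raw LFP (1 s window, 1/30 s
    step, (1, 1) tapers, 1-100 Hz) is computed and each frequency row
    cross-correlated with the < 1 Hz filtered dHbT on the common 30 Hz frame
    grid.  Matrices are averaged over events.
    """
    tapers = tapers or TaperSpec(1.0, 1, pad_level=0)
    trunc = _class_min(events)
    hl = lowpass_1hz(hbt)
    frame_rate = 1.0 / step_s
    mats = []
    freqs = None
    lags = None
    for ev in events:
        i0 = int(round((ev.start - lfp_raw.t0) * lfp_raw.rate))
        i1 = i0 + int(round(trunc * lfp_raw.rate))
        if i0 < 0 or i1 > lfp_raw.n:
            continue
        seg = TimeSeries(lfp_raw.values[i0:i1], lfp_raw.rate, ev.start)
        times, freqs, power = multitaper_spectrogram(seg, window_s, step_s, tapers)
        y = _prep_segment(hl, ev.start + window_s / 2.0, times.size / frame_rate)
        if y is None:
            y = _prep_segment(hl, ev.start, times.size / frame_rate)
        if y is None or y.std() == 0:
            continue
        n = min(power.shape[1], y.size)
        rows = []
        for r in range(power.shape[0]):
            x = power[r, :n] - power[r, :n].mean()
            if x.std() == 0:
                rows.append(np.zeros_like(_xcorr_pair(y[:n], y[:n], frame_rate,
                                                      max_lag_s)[1]))
                continue
            lags, c = _xcorr_pair(x, y[:n], frame_rate, max_lag_s)
            rows.append(c)
        mats.append(np.vstack(rows))
    if not mats:
        return XCorrResult(np.array([]), np.array([]), np.nan, np.nan, 0)
    mean_m = np.mean(mats, axis=0)
    flat = int(np.argmax(np.abs(mean_m)))
    fi, li = np.unravel_index(flat, mean_m.shape)
    return XCorrResult(lags, mean_m, float(mean_m[fi, li]), float(lags[li]),
                       len(mats), frequencies=freqs)


def bilateral_pearson(
    events: Sequence[Event], left: TimeSeries, right: TimeSeries
) -> tuple[float, np.ndarray]:
    """Pearson correlation between hemispheres over events of one class.

    Returns the mean r and the per-event values (within-session average;
    cross-subject averaging is the caller's job).
    """
    trunc = _class_min(events)
    ll = lowpass_1hz(left)
    rl = lowpass_1hz(right)
    rs = []
    for ev in events:
        x = _prep_segment(ll, ev.start, trunc)
        y = _prep_segment(rl, ev.start, trunc)
        if x is None or y is None or x.std() == 0 or y.std() == 0:
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    rs = np.asarray(rs)
    return (float(rs.mean()) if rs.size else np.nan), rs


def bilateral_coherence_summary(
    events: Sequence[Event],
    left: TimeSeries,
    right: TimeSeries,
    tapers: TaperSpec | None = None,
    readout_hz: Sequence[float] = (0.1, 0.01),
) -> dict:
    """Trial-averaged MoC^2 spectrum between hemispheres, with scalar
    read-outs at the target frequencies (nearest grid point).

    The lowest resolvable frequency is the inverse of the (truncated) event
    duration; a read-out below it is refused with the minimum stated.
    """
    tapers = tapers or TaperSpec(3.0, 5, pad_level=1)
    trunc = _class_min(events)
    ll = lowpass_1hz(left)
    rl = lowpass_1hz(right)
    xs, ys = [], []
    for ev in events:
        x = _prep_segment(ll, ev.start, trunc)
        y = _prep_segment(rl, ev.start, trunc)
        if x is None or y is None or x.std() == 0 or y.std() == 0:
            continue
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no usable events for coherence")
    res: SpectralResult = multitaper_coherence(
        np.vstack(xs), np.vstack(ys), tapers, rate=left.rate
    )
    f_min = 1.0 / trunc
    readouts: dict[float, float | None] = {}
    errors: dict[float, str] = {}
    for f in readout_hz:
        if f < f_min:
            readouts[f] = None
            errors[f] = (
                f"{f} Hz is below the minimum resolvable frequency "
                f"{f_min:.4g} Hz (inverse of the {trunc:.0f} s event duration)"
            )
            continue
        i = int(np.argmin(np.abs(res.frequencies - f)))
        readouts[f] = float(res.estimate[i])
    return {
        "spectrum": res,
        "readouts": readouts,
        "refused": errors,
        "confidence_level_95": res.confidence_level_95,
        "n_events": len(xs),
        "min_resolvable_hz": f_min,
    }
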