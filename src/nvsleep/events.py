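"""Baseline establishment, arousal-state event extraction, per-state
summaries, transition-triggered averages, and probability curves.

Event classes and their duration rules:

* ``rest``: >= 10 s of wakefulness with no whisking, body movement, or
  stimulation, inside manually flagged *true awake* periods, and at least 5 s
  after any whisker stimulus.
* ``whisk_brief`` (0.5-2 s), ``whisk_moderate`` (2-5 s), ``whisk_extended``
  (> 5 s): whisking bouts inside true-awake periods, >= 5 s post-stimulus.
* ``stim``: individual whisker stimuli.
* ``contiguous_NREM`` (>= 30 s), ``contiguous_REM`` (>= 60 s): from the
  scored hypnogram after REM gap-linking.
* ``alert15`` / ``asleep15`` / ``all15``: non-overlapping 15 min windows with
  >= 80% of bins awake (resp. asleep) and no stimulation; ``all15`` requires
  only the absence of stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .behavior import BinaryEventTrain
from .core import (AWAKE, BIN_S, NREM, REM, STATES, Event, EventCatalog,
                   Hypnogram, TimeSeries, runs)
from .scoring import contiguity_filter
from .signals import ANALYSIS_RATE, _butter_sos
from scipy import signal as _sig

POST_STIM_BUFFER_S = 5.0
MIN_REST_S = 10.0
WINDOW_15MIN_S = 900.0
ALERT_FRACTION = 0.8


# ---------------------------------------------------------------------------
# baseline


@dataclass
class BaselineSet:
    """Per-day scalar baselines from flagged true-awake rest segments."""

    means: dict[str, float]
    rest_mask: np.ndarray  # 30 Hz boolean
    rate: float = ANALYSIS_RATE
    fallback_used: bool = False

    def r0(self, channel: str = "reflectance_L") -> float:
        return self.means[channel]


def _activity_free_mask(
    n30: int,
    whisk: BinaryEventTrain,
    move: BinaryEventTrain | None,
    stim_times: Sequence[float],
    rate: float = ANALYSIS_RATE,
) -> np.ndarray:
    quiet = ~whisk.as_bool(n30)
    if move is not None:
        quiet &= ~move.as_bool(n30)
    for s in np.asarray(stim_times, dtype=float):
        lo = int(s * rate)
        hi = int((s + POST_STIM_BUFFER_S) * rate)
        quiet[max(lo, 0): hi] = False
    return quiet


def _mask_to_spans(mask: np.ndarray, rate: float, min_s: float) -> list[tuple[float, float]]:
    spans = []
    for a, b, lab in runs(mask.astype(object)):
        if lab and (b - a) / rate >= min_s:
            spans.append((a / rate, b / rate))
    return spans


def establish_baseline(
    channels: Mapping[str, TimeSeries],
    true_awake_bins: np.ndarray,
    whisk_train: BinaryEventTrain,
    move_train: BinaryEventTrain | None = None,
    stim_times: Sequence[float] = (),
    min_rest_s: float = 5.0,
    min_total_s: float = 60.0,
) -> BaselineSet:
    """Mean of every 30 Hz channel over true-awake rest, one value per day.

    Rest segments are >= ``min_rest_s`` stretches inside manually flagged
    true-awake bins with no whisking, movement, or recent stimulation.  If
    fewer than ``min_total_s`` of rest qualify, the quietest decile of the
    session (by whisking/movement occupancy) is used instead and the result
    flagged.
    """
    ref = next(iter(channels.values()))
    n30 = min(ts.n for ts in channels.values())
    rate = ref.rate
    quiet = _activity_free_mask(n30, whisk_train, move_train, stim_times, rate)
    awake30 = np.repeat(np.asarray(true_awake_bins, bool), int(rate * BIN_S))[:n30]
    if awake30.size < n30:
        awake30 = np.pad(awake30, (0, n30 - awake30.size))
    eligible = quiet & awake30
    mask = np.zeros(n30, dtype=bool)
    for t0, t1 in _mask_to_spans(eligible, rate, min_rest_s):
        mask[int(t0 * rate): int(t1 * rate)] = True
    fallback = mask.sum() / rate < min_total_s
    if fallback:
        warnings.warn(
            "insufficient true-awake rest for a baseline; "
            "falling back to the quietest decile of the session"
        )
        activity = whisk_train.as_bool(n30).astype(float)
        if move_train is not None:
            activity += move_train.as_bool(n30)
        # bin occupancy per 5 s and take the quietest 10% of bins
        per_bin = int(rate * BIN_S)
        nb = n30 // per_bin
        occ = activity[: nb * per_bin].reshape(nb, per_bin).mean(axis=1)
        k = max(1, nb // 10)
        quietest = np.argsort(occ, kind="stable")[:k]
        mask = np.zeros(n30, dtype=bool)
        for i in quietest:
            mask[i * per_bin: (i + 1) * per_bin] = True
    means = {name: float(ts.values[:n30][mask].mean()) for name, ts in channels.items()}
    return BaselineSet(means, mask, rate, fallback_used=fallback)


# ---------------------------------------------------------------------------
# event extraction


def lowpass_1hz(ts: TimeSeries, order: int = 4) -> TimeSeries:
    """The < 1 Hz 4th-order zero-phase lowpass used for event summaries."""
    sos = _butter_sos(order, 1.0, ts.rate, "low")
    return ts.copy_with(values=_sig.sosfiltfilt(sos, ts.values))


def extract_state_events(
    hypnogram: Hypnogram,
    whisk_train: BinaryEventTrain,
    move_train: BinaryEventTrain | None,
    stim_times: Sequence[float],
    true_awake_bins: np.ndarray | None = None,
    duration_s: float | None = None,
) -> EventCatalog:
    """Catalog every analyzable epoch of the session (see module docstring)."""
    stim_times = np.asarray(stim_times, dtype=float)
    duration = duration_s if duration_s is not None else hypnogram.duration
    n30 = int(round(duration * ANALYSIS_RATE))
    if true_awake_bins is None:
        true_awake_bins = hypnogram.labels == AWAKE
    catalog = EventCatalog()

    # contiguous sleep epochs
    for ev in contiguity_filter(hypnogram, stim_times):
        catalog.add(ev)

    # stimulation events
    for s in stim_times:
        if s < duration:
            catalog.add(Event("stim", float(s), float(s) + 2.0))

    # awake rest: quiet spans >= 10 s in true-awake periods
    quiet = _activity_free_mask(n30, whisk_train, move_train, stim_times)
    awake30 = np.repeat(np.asarray(true_awake_bins, bool), int(ANALYSIS_RATE * BIN_S))[:n30]
    if awake30.size < n30:
        awake30 = np.pad(awake30, (0, n30 - awake30.size))
    for t0, t1 in _mask_to_spans(quiet & awake30, ANALYSIS_RATE, MIN_REST_S):
        catalog.add(Event("rest", t0, t1))

    # whisking bouts by duration class
    last_stim = -np.inf
    stim_sorted = np.sort(stim_times)
    for onset, offset in zip(whisk_train.onset_times(), whisk_train.offset_times()):
        dur = offset - onset
        prior = stim_sorted[stim_sorted <= onset]
        if prior.size and onset - prior[-1] < POST_STIM_BUFFER_S:
            continue
        bin0 = hypnogram.bin_of_time(onset)
        if not (0 <= bin0 < len(true_awake_bins)) or not true_awake_bins[bin0]:
            continue
        if 0.5 <= dur < 2.0:
            kind = "whisk_brief"
        elif 2.0 <= dur <= 5.0:
            kind = "whisk_moderate"
        elif dur > 5.0:
            kind = "whisk_extended"
        else:
            continue
        catalog.add(Event(kind, float(onset), float(offset)))

    # 15-min windows tiling the session
    n_windows = int(duration // WINDOW_15MIN_S)
    bins_per_win = int(WINDOW_15MIN_S // hypnogram.bin_s)
    for w in range(n_windows):
        t0, t1 = w * WINDOW_15MIN_S, (w + 1) * WINDOW_15MIN_S
        if np.any((stim_times >= t0) & (stim_times < t1)):
            continue
        lab = hypnogram.labels[w * bins_per_win: (w + 1) * bins_per_win]
        frac_awake = np.mean(lab == AWAKE)
        frac_asleep = np.mean((lab == NREM) | (lab == REM))
        catalog.add(Event("all15", t0, t1))
        if frac_awake >= ALERT_FRACTION:
            catalog.add(Event("alert15", t0, t1))
        if frac_asleep >= ALERT_FRACTION:
            catalog.add(Event("asleep15", t0, t1))
    return catalog


def summarize_events(
    catalog: EventCatalog,
    ts: TimeSeries,
    key: str | None = None,
    prefilter: bool = True,
) -> dict[str, np.ndarray]:
    """Per-event summary values of one signal, stored on the events.

    The signal is lowpass filtered (< 1 Hz, 4th order, zero phase) first.
    Summary windows: whisk events use onset to onset+5 s with the mean of the
    2 s before onset subtracted; ``stim`` events use +1 to +2 s after the
    stimulus; all other classes use the event mean.  Values are written into
    ``event.summary[key]`` and returned grouped by class.
    """
    key = key or ts.label or "value"
    sig = lowpass_1hz(ts) if prefilter else ts
    v, rate = sig.values, sig.rate
    out: dict[str, list[float]] = {}
    for ev in catalog:
        if ev.kind.startswith("whisk"):
            i0 = int(ev.start * rate)
            i1 = min(int((ev.start + 5.0) * rate), v.size)
            pre0 = max(int((ev.start - 2.0) * rate), 0)
            if i1 <= i0 or i0 <= pre0:
                continue
            val = v[i0:i1].mean() - v[pre0:i0].mean()
        elif ev.kind == "stim":
            i0 = int((ev.start + 1.0) * rate)
            i1 = min(int((ev.start + 2.0) * rate), v.size)
            if i1 <= i0:
                continue
            val = v[i0:i1].mean()
        else:
            i0, i1 = int(ev.start * rate), min(int(ev.stop * rate), v.size)
            if i1 <= i0:
                continue
            val = v[i0:i1].mean()
        ev.summary[key] = float(val)
        out.setdefault(ev.kind, []).append(float(val))
    return {k: np.asarray(vals) for k, vals in out.items()}


# ---------------------------------------------------------------------------
# transition-triggered averages


def transition_triggered_average(
    hypnogram: Hypnogram,
    channels: Mapping[str, TimeSeries],
    pair: tuple[str, str],
    side_bins: int = 6,
    prefilter: bool = True,
) -> dict:
    """Average channel traces around qualifying state transitions.

    A qualifying transition has ``side_bins`` consecutive bins (default 6,
    i.e. 30 s) of ``pair[0]`` immediately followed by ``side_bins`` bins of
    ``pair[1]``.  Returns relative times, the per-channel mean trace over
    transitions within this session, and the transition count.
    """
    a_state, b_state = pair
    labels = hypnogram.labels
    side = side_bins
    boundaries = []
    for i in range(side, len(labels) - side + 1):
        if (np.all(labels[i - side: i] == a_state)
                and np.all(labels[i: i + side] == b_state)):
            boundaries.append(hypnogram.t0 + i * hypnogram.bin_s)
    window_s = side * hypnogram.bin_s
    result: dict = {"pair": pair, "n_transitions": len(boundaries),
                    "boundaries_s": np.asarray(boundaries)}
    if not boundaries:
        result["traces"] = {}
        result["t"] = np.array([])
        return result
    traces = {}
    t_rel = None
    for name, ts in channels.items():
        sig = lowpass_1hz(ts) if prefilter else ts
        half = int(window_s * sig.rate)
        segs = []
        for b in boundaries:
            c = int((b - sig.t0) * sig.rate)
            if c - half < 0 or c + half > sig.n:
                continue
            segs.append(sig.values[c - half: c + half])
        if segs:
            traces[name] = np.mean(segs, axis=0)
            t_rel = (np.arange(-half, half) + 0.5) / sig.rate
    result["traces"] = traces
    result["t"] = t_rel if t_rel is not None else np.array([])
    return result


def aggregate_transition_averages(per_subject: Sequence[dict]) -> dict:
    """Unweighted mean of per-subject transition averages (fixed order:
    within subject first, then across subjects)."""
    usable = [r for r in per_subject if r["n_transitions"] > 0 and r["traces"]]
    if not usable:
        return {"traces": {}, "t": np.array([]), "n_subjects": 0}
    names = set.intersection(*(set(r["traces"]) for r in usable))
    traces = {
        name: np.mean([r["traces"][name] for r in usable], axis=0) for name in names
    }
    return {"traces": traces, "t": usable[0]["t"], "n_subjects": len(usable)}


# ---------------------------------------------------------------------------
# probability curves


def _exp_fit(t: np.ndarray, y: np.ndarray) -> dict:
    """Robust single-exponential fit a*exp(-t/tau) + c.

    Initialization: a = range, tau = duration/3, c = final value; soft-L1
    robust least squares.  Flat inputs are flagged unidentifiable.
    """
    good = np.isfinite(y)
    t, y = t[good], y[good]
    if t.size < 4 or np.ptp(y) < 1e-9:
        return {"a": 0.0, "tau": np.nan, "c": float(np.mean(y)) if y.size else np.nan,
                "identifiable": False}
    a0 = y[0] - y[-1]
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-6)
    c0 = y[-1]

    def resid(p):
        a, tau, c = p
        return a * np.exp(-t / tau) + c - y

    try:
        res = optimize.least_squares(
            resid, x0=[a0, tau0, c0], loss="soft_l1",
            bounds=([-np.inf, 1e-9, -np.inf], np.inf),
        )
        a, tau, c = res.x
        return {"a": float(a), "tau": float(tau), "c": float(c),
                "identifiable": bool(res.success and abs(a) > 1e-6)}
    except Exception:
        return {"a": np.nan, "tau": np.nan, "c": np.nan, "identifiable": False}


def state_probability_vs_time(hypnograms: Sequence[Hypnogram]) -> dict:
    """P(state | elapsed session time) per state, with exponential fits.

    Each hypnogram is one subject/session; probabilities are averaged across
    hypnograms per bin index (shorter sessions contribute to the bins they
    cover), then each state's curve is fit with ``a exp(-t/tau) + c``.
    """
    if not hypnograms:
        raise ValueError("need at least one hypnogram")
    n_max = max(h.n_bins for h in hypnograms)
    counts = np.zeros((3, n_max))
    totals = np.zeros(n_max)
    for h in hypnograms:
        codes = h.as_codes()
        for i, c in enumerate(codes):
            counts[c, i] += 1
        totals[: h.n_bins] += 1
    with np.errstate(invalid="ignore"):
        probs = counts / totals[None, :]
    t = (np.arange(n_max) + 0.5) * hypnograms[0].bin_s
    fits = {s: _exp_fit(t, probs[i]) for i, s in enumerate(STATES)}
    return {"t": t, "probability": {s: probs[i] for i, s in enumerate(STATES)},
            "fits": fits}


def quiescent_periods(
    whisk_train: BinaryEventTrain,
    move_train: BinaryEventTrain | None,
    duration_s: float,
    min_s: float = 5.0,
) -> list[tuple[float, float]]:
    """Spans without whisking or body movement, >= min_s long."""
    n30 = int(round(duration_s * ANALYSIS_RATE))
    quiet = _activity_free_mask(n30, whisk_train, move_train, ())
    return _mask_to_spans(quiet, ANALYSIS_RATE, min_s)


def p_awake_vs_quiescence(
    hypnogram: Hypnogram,
    quiescent: Sequence[tuple[float, float]],
    max_bin: int = 12,
) -> dict:
    """Probability the animal stayed awake through a quiescent period, as a
    function of the period's duration.

    Each quiescent event falls into the 5 s duration bin containing its length
    (a 7.5 s event falls in the 5-10 s bin, index 1).  An event is asleep if
    any hypnogram bin it overlaps is NREM or REM.  Returns the per-duration-bin
    awake fraction, counts, and an exponential fit over the bin centers.
    """
    n_awake = np.zeros(max_bin)
    n_total = np.zeros(max_bin)
    for t0, t1 in quiescent:
        dur = t1 - t0
        d_bin = int(dur // BIN_S)
        if d_bin >= max_bin:
            d_bin = max_bin - 1
        b0 = max(hypnogram.bin_of_time(t0), 0)
        b1 = min(hypnogram.bin_of_time(t1 - 1e-9) + 1, hypnogram.n_bins)
        lab = hypnogram.labels[b0:b1]
        asleep = np.any((lab == NREM) | (lab == REM))
        n_total[d_bin] += 1
        if not asleep:
            n_awake[d_bin] += 1
    with np.errstate(invalid="ignore"):
        frac = n_awake / n_total
    centers = (np.arange(max_bin) + 0.5) * BIN_S
    fit = _exp_fit(centers, frac)
    return {"duration_bin_centers_s": centers, "p_awake": frac,
            "n_events": n_total, "fit": fit}


def median_smooth(y: np.ndarray, window: int = 10) -> np.ndarray:
    """Median filter with shrinking windows at edges, NaN-aware."""
    out = np.empty_like(y, dtype=float)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    for i in range(y.size):
        win = y[max(0, i - half_lo): min(y.size, i + half_hi + 1)]
        win = win[np.isfinite(win)]
        out[i] = np.median(win) if win.size else np.nan
    return out


def state_probability_vs_signal(
    hypnogram: Hypnogram,
    ts: TimeSeries,
    bin_width: float = 1.0,
    smooth_window: int = 10,
) -> dict:
    """Per-state probability as a function of a binned signal value.

    5 s bin means of the signal are histogrammed at ``bin_width`` resolution
    (1 uM for dHbT, 1% for dD/D); within each histogram bin the fraction of
    each arousal state is computed (fractions sum to 1 where occupied) and
    smoothed with a 10-point median filter.  Empty bins propagate as NaN.
    """
    per_bin = int(round(ts.rate * BIN_S))
    nb = min(hypnogram.n_bins, ts.n // per_bin)
    means = ts.values[: nb * per_bin].reshape(nb, per_bin).mean(axis=1)
    codes = hypnogram.as_codes()[:nb]
    lo = np.floor(means.min() / bin_width) * bin_width
    hi = np.ceil(means.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(means, edges) - 1, 0, edges.size - 2)
    n_hist = edges.size - 1
    counts = np.zeros((3, n_hist))
    for c, i in zip(codes, idx):
        counts[c, i] += 1
    tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = counts / tot[None, :]
    smoothed = {s: median_smooth(frac[i], smooth_window) for i, s in enumerate(STATES)}
    centers = (edges[:-1] + edges[1:]) / 2.0
    return {"bin_centers": centers, "raw": {s: frac[i] for i, s in enumerate(STATES)},
            "probability": smoothed, "counts_per_bin": tot}


def hbt_gamma_histogram2d(
    hypnogram: Hypnogram,
    hbt: TimeSeries,
    gamma_dpp: TimeSeries,
    bins: int | tuple = 40,
) -> dict:
    """2-D histogram of (mean dHbT, mean gamma dP/P) per 5 s bin, by state."""
    per_bin = int(round(hbt.rate * BIN_S))
    nb = min(hypnogram.n_bins, hbt.n // per_bin, gamma_dpp.n // per_bin)
    h_means = hbt.values[: nb * per_bin].reshape(nb, per_bin).mean(axis=1)
    g_means = gamma_dpp.values[: nb * per_bin].reshape(nb, per_bin).mean(axis=1)
    codes = hypnogram.as_codes()[:nb]
    h_edges = np.histogram_bin_edges(h_means, bins if np.isscalar(bins) else bins[0])
    g_edges = np.histogram_bin_edges(g_means, bins if np.isscalar(bins) else bins[1])
    out = {"hbt_edges": h_edges, "gamma_edges": g_edges, "counts": {}}
    for i, s in enumerate(STATES):
        sel = codes == i
        cnt, _, _ = np.histogram2d(h_means[sel], g_means[sel],
                                   bins=(h_edges, g_edges))
        out["counts"][s] = cnt
    return out
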