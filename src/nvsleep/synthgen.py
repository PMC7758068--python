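"""Synthetic multimodal sessions with the statistical structure the analysis
assumes: state-dependent LFP band powers, EMG atonia in sleep, state-dependent
whisking and heart rate, and hemodynamics built from a lagged-kernel
convolution of the gamma-band envelope plus state offsets and a ~0.1 Hz
oscillation gated to NREM.

The arousal-state sequence is a semi-Markov chain on 5 s bins: after entering
a state the chain dwells a state-specific minimum number of bins before
transitions are drawn from the row of the transition matrix, which gives the
contiguity filters downstream realistic material.

Signal model (per hemisphere h, lowercase t at 30 Hz):

* slow drive ``m_h(t)``: unit-variance Gaussian process, lowpass < 1 Hz,
  mixed across hemispheres as ``m_h = sqrt(s) m0 + sqrt(1-s) u_h`` where s is
  the shared-variance fraction (possibly per state).  The bilateral Pearson
  correlation of anything linear in the drive is then ~s and the squared
  coherence ~s^2.
* gamma-band amplitude is modulated by the envelope ``e_h = 1 + 2 depth m_h``
  (plus whisking/stimulus bumps), so the measured 30 Hz gamma band power
  fluctuates with m_h.
* latent hemodynamics:
  ``dHbT_h = offset(state) + sd_fluct * standardize(HRF (x) m_h)
  + A sin(2 pi f_vaso t) gate_NREM + evoked terms + noise``
  with the HRF a gamma-shaped kernel parameterized by peak lag and width.
* reflectance encodes the latent dHbT through the Beer-Lambert relation
  ``R = R0 exp(-eps X dHbT)`` times a two-exponent drift and a multiplicative
  cardiac modulation at the state-dependent heart rate, so the conditioning
  chain (drift correction, Beer-Lambert inversion) recovers the latent signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal, stats

from .core import AWAKE, BIN_S, NREM, REM, STATES, Hypnogram, TimeSeries
from .signals import (BANDS, BeerLambertParams, _butter_sos, _resample,
                      hbt_to_reflectance)

# ---------------------------------------------------------------------------
# configuration


def _default_transition_matrix() -> np.ndarray:
    # rows/cols in STATES order; direct AWAKE->REM is 0
    return np.array(
        [
            [0.92, 0.08, 0.00],
            [0.10, 0.88, 0.02],
            [0.30, 0.00, 0.70],
        ]
    )


def _default_band_gain() -> dict:
    # cortical per-state variance multipliers; NREM is delta-dominated,
    # REM shows elevated gamma and suppressed delta
    return {
        AWAKE: {},
        NREM: {"delta": 4.0, "theta": 1.5, "beta": 1.5},
        REM: {"delta": 0.5, "gamma": 2.0, "mua": 1.5},
    }


def _default_hipp_gain() -> dict:
    # hippocampal theta is the REM signature
    return {AWAKE: {}, NREM: {"delta": 2.0}, REM: {"theta": 4.0}}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    All gains are variance multipliers relative to the awake state; offsets
    are in uM; rates in Hz or events/s.  ``bilateral_shared_frac`` may be a
    scalar or a per-state mapping.
    """

    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    dwell_min: Mapping[str, int] = field(
        default_factory=lambda: {AWAKE: 1, NREM: 6, REM: 12}
    )
    band_power_gain: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_band_gain
    )
    hipp_band_power_gain: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_hipp_gain
    )
    emg_gain: Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 1.0, NREM: 0.1, REM: 0.02}
    )
    hbt_offset: Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 0.0, NREM: 32.2, REM: 77.1}
    )
    nrem_osc_amplitude: float = 10.0  # uM
    nrem_osc_freq: float = 0.1  # Hz, the vasomotion band
    hrf_peak_lag_s: float = 1.2
    hrf_width_s: float = 0.4
    hbt_fluct_sd: float = 5.0  # uM, SD of the drive-locked component
    heart_rate: Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 9.5, NREM: 7.5, REM: 9.0}
    )
    heart_amp: float = 0.01  # multiplicative reflectance modulation (1% of R0)
    whisk_rate: Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 0.10, NREM: 0.01, REM: 0.03}
    )
    move_rate: Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 0.05, NREM: 0.005, REM: 0.01}
    )
    bilateral_shared_frac: float | Mapping[str, float] = field(
        default_factory=lambda: {AWAKE: 0.75, NREM: 0.90, REM: 0.90}
    )
    drive_depth: float = 0.25  # gamma-envelope modulation depth
    drift_amplitudes: tuple[float, float] = (0.02, 0.03)
    drift_taus_s: tuple[float, float] = (300.0, 3000.0)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "reflectance": 0.0005,
            "hbt": 1.0,
            "whisker_angle": 0.5,
            "force": 1.0,
            "ldf": 0.05,
        }
    )
    r0: float = 1.0
    neural_rate: float = 20000.0
    whisker_rate: float = 150.0
    stim_every_s: float | None = None  # air-puff interval; None disables
    stim_hbt_amplitude: float = 16.8  # uM evoked response
    whisk_hbt_amplitude: float = 4.0  # uM at full whisk drive
    include_ldf: bool = False
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3 in AWAKE/NREM/REM order")
        for i, row in enumerate(p):
            if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"transition_matrix row {i} ({STATES[i]}) is not stochastic: {row}"
                )
        self.transition_matrix = p
        if isinstance(self.bilateral_shared_frac, Mapping):
            vals = self.bilateral_shared_frac.values()
        else:
            vals = [self.bilateral_shared_frac]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("bilateral_shared_frac must lie in [0, 1]")
        for name, m in (("emg_gain", self.emg_gain), ("heart_rate", self.heart_rate),
                        ("whisk_rate", self.whisk_rate)):
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} entries must be >= 0")

    def shared_frac_of(self, state: str) -> float:
        if isinstance(self.bilateral_shared_frac, Mapping):
            return float(self.bilateral_shared_frac[state])
        return float(self.bilateral_shared_frac)


@dataclass
class SyntheticSession:
    """Generated channels plus the ground truth used by recovery tests."""

    channels: dict[str, TimeSeries]
    truth_hypnogram: Hypnogram
    truth_params: GeneratorConfig
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    truth: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.truth_hypnogram.duration


# ---------------------------------------------------------------------------
# hypnogram simulation


def simulate_hypnogram(
    config: GeneratorConfig, duration_s: float, seed: int | None = None
) -> Hypnogram:
    """Semi-Markov arousal-state sequence on 5 s bins.

    After entering a state the chain dwells ``dwell_min[state]`` bins, then
    draws successor states from the transition matrix row each bin.  With the
    default matrix, direct AWAKE->REM transitions have probability 0, so REM
    bins only ever follow NREM (or REM) bins.
    """
    if duration_s < BIN_S:
        raise ValueError(f"duration must be at least one bin ({BIN_S} s)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_bins = int(duration_s // BIN_S)
    p = config.transition_matrix
    labels = np.empty(n_bins, dtype=object)
    state = 0  # start AWAKE
    dwell_left = config.dwell_min.get(STATES[state], 1) - 1
    labels[0] = STATES[state]
    for i in range(1, n_bins):
        if dwell_left > 0:
            dwell_left -= 1
        else:
            nxt = int(rng.choice(3, p=p[state]))
            if nxt != state:
                dwell_left = config.dwell_min.get(STATES[nxt], 1) - 1
            state = nxt
        labels[i] = STATES[state]
    return Hypnogram(labels, BIN_S, 0.0, source="manual")


def expected_state_fractions(config: GeneratorConfig) -> dict[str, float]:
    """Analytic stationary occupancy of the semi-Markov chain.

    The embedded jump chain has transition probabilities
    ``q_ij = p_ij / (1 - p_ii)``; the expected dwell in state i is
    ``(dwell_min_i - 1) + 1 / (1 - p_ii)`` bins.  Occupancy is the jump-chain
    stationary distribution weighted by expected dwell.  With all dwell
    minimums equal to 1 this reduces to the stationary eigenvector of the
    transition matrix.
    """
    p = config.transition_matrix
    stay = np.diag(p)
    if np.any(stay >= 1.0):
        # absorbing state: all mass there once entered; report eigenvector
        w, v = np.linalg.eig(p.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = pi / pi.sum()
        return dict(zip(STATES, map(float, pi)))
    q = p / (1 - stay)[:, None]
    np.fill_diagonal(q, 0.0)
    w, v = np.linalg.eig(q.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi) / np.abs(pi).sum()
    dwell = np.array(
        [config.dwell_min.get(s, 1) - 1 + 1.0 / (1 - stay[i]) for i, s in enumerate(STATES)]
    )
    occ = pi * dwell
    occ /= occ.sum()
    return dict(zip(STATES, map(float, occ)))


# ---------------------------------------------------------------------------
# helpers


def hrf_kernel(peak_lag_s: float, width_s: float, rate: float = 30.0) -> np.ndarray:
    """Gamma-distribution-shaped hemodynamic response kernel (unit area).

    Parameterized by the lag of the kernel peak (mode) and its width (SD):
    ``theta = (-peak + sqrt(peak^2 + 4 width^2)) / 2``, ``k = peak/theta + 1``.
    """
    theta = (-peak_lag_s + np.sqrt(peak_lag_s**2 + 4 * width_s**2)) / 2.0
    k = peak_lag_s / theta + 1.0
    t = np.arange(0, peak_lag_s + 8 * width_s, 1.0 / rate)
    h = stats.gamma.pdf(t, a=k, scale=theta)
    return h / h.sum()


def _slow_process(rng: np.random.Generator, n: int, rate: float,
                  cutoff: float = 1.0) -> np.ndarray:
    """Unit-variance Gaussian process, lowpass < cutoff Hz."""
    x = rng.standard_normal(n + int(4 * rate))
    sos = _butter_sos(2, cutoff, rate, "low")
    x = signal.sosfiltfilt(sos, x)[int(2 * rate): int(2 * rate) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_per_sample(codes: np.ndarray, rate: float, n: int) -> np.ndarray:
    idx = np.minimum((np.arange(n) / (rate * BIN_S)).astype(int), len(codes) - 1)
    return codes[idx]


def _poisson_bouts(rng, rate_per_state: Mapping[str, float], labels: np.ndarray,
                   dur_lo: float, dur_hi: float) -> list[tuple[float, float]]:
    """Bout (start, stop) pairs drawn per 5 s bin with state-dependent rate."""
    bouts = []
    for i, lab in enumerate(labels):
        lam = rate_per_state.get(lab, 0.0) * BIN_S
        for _ in range(rng.poisson(lam)):
            start = i * BIN_S + rng.uniform(0, BIN_S)
            dur = rng.uniform(dur_lo, dur_hi)
            bouts.append((start, start + dur))
    bouts.sort()
    return bouts


def _band_noise(rng, n: int, rate: float, low: float, high: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise.

    Low bands are synthesized at a reduced rate and polyphase-upsampled; the
    band content is identical and the cost independent of the raw rate.
    """
    from .signals import _resample, _working_rate

    wr = _working_rate(rate, high)
    n_w = int(np.ceil(n * wr / rate)) + int(2 * wr)
    x = rng.standard_normal(n_w)
    sos = _butter_sos(3, (low, min(high, wr / 2 * 0.99)), wr, "bandpass")
    x = signal.sosfilt(sos, x)
    sd = x.std()  # normalize at the working rate (variance is band-limited)
    if sd > 0:
        x /= sd
    if wr < rate:
        x = _resample(x, wr, rate)
    x = x[: n]
    if x.size < n:
        x = np.pad(x, (0, n - x.size))
    return x


#: relative base SD per band, a 1/f-flavored profile
_BAND_BASE_SD = {
    "delta": 1.0, "theta": 0.7, "alpha": 0.5,
    "beta": 0.4, "gamma": 0.3, "mua": 0.2,
}


# ---------------------------------------------------------------------------
# main synthesis


def synthesize_signals(
    hypnogram: Hypnogram,
    config: GeneratorConfig,
    seed: int | None = None,
) -> SyntheticSession:
    """Render all raw channels for a given hypnogram.  See module docstring
    for the signal model."""
    if hypnogram.n_bins == 0:
        raise ValueError("hypnogram is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = hypnogram.labels
    codes = hypnogram.as_codes()
    n_bins = hypnogram.n_bins
    duration = hypnogram.duration

    rate30 = 30.0
    n30 = int(round(duration * rate30))
    t30 = np.arange(n30) / rate30
    nr = config.neural_rate
    if nr <= 0 or abs(nr * BIN_S - round(nr * BIN_S)) > 1e-9:
        raise ValueError("neural_rate must yield an integer number of samples per bin")
    n_nr = int(round(duration * nr))

    state30 = _state_per_sample(codes, rate30, n30)
    noise = config.noise_sd

    # ---- stimulation timestamps
    if config.stim_every_s:
        stim_times = np.arange(config.stim_every_s, duration - 5.0, config.stim_every_s)
    else:
        stim_times = np.array([])

    # ---- behavioral bouts (ground truth)
    whisk_bouts = _poisson_bouts(rng, config.whisk_rate, labels, 0.3, 6.0)
    move_bouts = _poisson_bouts(rng, config.move_rate, labels, 0.3, 2.0)
    whisk30 = np.zeros(n30)
    for a, b in whisk_bouts:
        whisk30[int(a * rate30): int(b * rate30)] = 1.0
    move30 = np.zeros(n30)
    for a, b in move_bouts:
        move30[int(a * rate30): int(b * rate30)] = 1.0
    stim30 = np.zeros(n30)
    for s in stim_times:
        stim30[int(s * rate30): int((s + 0.1) * rate30)] = 1.0

    # ---- shared/independent slow drives
    s_frac30 = np.array([config.shared_frac_of(s) for s in STATES])[state30]
    m0 = _slow_process(rng, n30, rate30)
    m_l = np.sqrt(s_frac30) * m0 + np.sqrt(1 - s_frac30) * _slow_process(rng, n30, rate30)
    m_r = np.sqrt(s_frac30) * m0 + np.sqrt(1 - s_frac30) * _slow_process(rng, n30, rate30)

    # ---- gamma envelopes (variance modulation of the gamma/MUA band noise)
    awake30 = (state30 == 0).astype(float)
    evoked_drive = 0.5 * whisk30 * awake30 + 0.8 * stim30
    evoked_drive = ndimage.gaussian_filter1d(evoked_drive, 0.3 * rate30)
    env_l = np.clip(1.0 + 2 * config.drive_depth * m_l + evoked_drive, 0.05, None)
    env_r = np.clip(1.0 + 2 * config.drive_depth * m_r + evoked_drive, 0.05, None)

    # ---- latent hemodynamics
    kern = hrf_kernel(config.hrf_peak_lag_s, config.hrf_width_s, rate30)
    offset30 = ndimage.gaussian_filter1d(
        np.array([config.hbt_offset[s] for s in STATES], dtype=float)[state30],
        sigma=1.0 * rate30,
    )
    nrem_gate = ndimage.gaussian_filter1d((state30 == 1).astype(float), 2.0 * rate30)
    vaso = config.nrem_osc_amplitude * np.sin(2 * np.pi * config.nrem_osc_freq * t30)
    evoked_hbt = np.convolve(
        config.whisk_hbt_amplitude * whisk30 * awake30
        + config.stim_hbt_amplitude * stim30 * 10.0,  # 0.1 s pulse -> ~unit peak
        kern, mode="full",
    )[:n30]

    def _latent(m):
        f = signal.fftconvolve(m, kern, mode="full")[:n30]
        sd = f.std()
        return config.hbt_fluct_sd * (f / sd if sd > 0 else f)

    hbt_l = offset30 + _latent(m_l) + nrem_gate * vaso + evoked_hbt
    hbt_r = offset30 + _latent(m_r) + nrem_gate * vaso + evoked_hbt
    hbt_l_noisy = hbt_l + noise.get("hbt", 0.0) * rng.standard_normal(n30)
    hbt_r_noisy = hbt_r + noise.get("hbt", 0.0) * rng.standard_normal(n30)

    # ---- reflectance encoding
    drift = _drift_curve(t30, config)
    hr30 = ndimage.gaussian_filter1d(
        np.array([config.heart_rate[s] for s in STATES], dtype=float)[state30],
        2.0 * rate30,
    )
    phase = 2 * np.pi * np.cumsum(hr30) / rate30
    cardiac = 1.0 + config.heart_amp * np.sin(phase)
    bl = BeerLambertParams()

    def _reflectance(hbt, label):
        r = hbt_to_reflectance(hbt, config.r0, bl) * drift * cardiac
        r = r + noise.get("reflectance", 0.0) * config.r0 * rng.standard_normal(n30)
        return TimeSeries(r, rate30, 0.0, "a.u.", label)

    # cement-region reference ROI: carries the drift but no hemodynamics
    ref_roi = config.r0 * drift + 0.2 * noise.get("reflectance", 0.0) * (
        config.r0 * rng.standard_normal(n30)
    )
    channels: dict[str, TimeSeries] = {
        "reflectance_L": _reflectance(hbt_l_noisy, "reflectance_L"),
        "reflectance_R": _reflectance(hbt_r_noisy, "reflectance_R"),
        "reference_roi": TimeSeries(ref_roi, rate30, 0.0, "a.u.", "reference_roi"),
    }

    # ---- neural channels at the raw rate
    state_nr = _state_per_sample(codes, nr, n_nr)
    t_nr = np.arange(n_nr) / nr

    # LFP bands are synthesized on a common 600 Hz tier and upsampled once
    # per channel; only the MUA band needs the full raw rate.
    tier = min(600.0, nr)
    n_tier = int(round(duration * tier))
    t_tier = np.arange(n_tier) / tier
    state_tier = _state_per_sample(codes, tier, n_tier)

    def _band_gains(gain_map, band_name):
        return np.array(
            [gain_map.get(s, {}).get(band_name, 1.0) for s in STATES], dtype=float
        )

    def _neural(gain_map, envelope30, label):
        acc_t = np.zeros(n_tier)
        env_t = np.interp(t_tier, t30, envelope30) if envelope30 is not None else None
        for name, base_sd in _BAND_BASE_SD.items():
            band = BANDS[name]
            if name == "mua" or band.high >= tier / 2:
                continue
            x = _band_noise(rng, n_tier, tier, band.low, band.high)
            g = _band_gains(gain_map, name)
            amp = base_sd * (np.sqrt(g[state_tier]) if np.ptp(g) else np.sqrt(g[0]))
            if env_t is not None and name == "gamma":
                amp = amp * np.sqrt(env_t)
            np.multiply(x, amp, out=x)
            acc_t += x
        acc = _resample(acc_t, tier, nr)[:n_nr]
        if acc.size < n_nr:
            acc = np.pad(acc, (0, n_nr - acc.size))
        band = BANDS["mua"]
        if band.high < nr / 2:
            x = _band_noise(rng, n_nr, nr, band.low, band.high)
            g = _band_gains(gain_map, "mua")
            amp = _BAND_BASE_SD["mua"] * (
                np.sqrt(g[state_nr]) if np.ptp(g) else np.sqrt(g[0])
            )
            if envelope30 is not None:
                amp = amp * np.sqrt(np.interp(t_nr, t30, envelope30))
            np.multiply(x, amp, out=x)
            acc += x
        return TimeSeries(acc.astype(np.float32), nr, 0.0, "uV", label)

    channels["neural_cortex_L"] = _neural(config.band_power_gain, env_l, "neural_cortex_L")
    channels["neural_cortex_R"] = _neural(config.band_power_gain, env_r, "neural_cortex_R")
    channels["neural_hipp"] = _neural(config.hipp_band_power_gain, None, "neural_hipp")

    # ---- EMG: 300-3000 Hz noise with state-dependent variance
    emg_g = np.array([config.emg_gain[s] for s in STATES], dtype=float)[state_nr]
    emg = np.sqrt(emg_g) * _band_noise(rng, n_nr, nr, 300.0, min(3000.0, nr / 2 * 0.99))
    emg += 0.01 * rng.standard_normal(n_nr)  # amplifier noise floor
    channels["emg"] = TimeSeries(emg.astype(np.float32), nr, 0.0, "uV", "emg")

    # ---- force sensor: noise floor plus movement bouts
    force = noise.get("force", 1.0) * 0.01 * rng.standard_normal(n_nr)
    for a, b in move_bouts:
        i0, i1 = int(a * nr), min(int(b * nr), n_nr)
        if i1 <= i0:
            continue
        burst = rng.standard_normal(i1 - i0)
        sos = _butter_sos(2, 15.0, nr, "low")
        force[i0:i1] += 0.5 * signal.sosfilt(sos, burst) / max(
            1e-12, signal.sosfilt(sos, burst).std()
        )
    channels["force"] = TimeSeries(force.astype(np.float32), nr, 0.0, "V", "force")

    # ---- whisker angle at the camera rate
    wr = config.whisker_rate
    n_w = int(round(duration * wr))
    t_w = np.arange(n_w) / wr
    angle = noise.get("whisker_angle", 0.5) * _slow_process(rng, n_w, wr, 2.0)
    for a, b in whisk_bouts:
        i0, i1 = int(a * wr), min(int(b * wr), n_w)
        if i1 <= i0:
            continue
        tt = np.arange(i1 - i0) / wr
        envelope = np.sin(np.pi * np.linspace(0, 1, i1 - i0)) ** 2
        f_whisk = rng.uniform(8.0, 14.0)
        angle[i0:i1] += 12.0 * envelope * np.sin(2 * np.pi * f_whisk * tt)
    channels["whisker_angle"] = TimeSeries(angle, wr, 0.0, "degrees", "whisker_angle")

    if config.include_ldf:
        flow = 1.0 + 0.003 * (hbt_l + hbt_r) / 2.0
        flow = flow + noise.get("ldf", 0.05) * rng.standard_normal(n30)
        channels["ldf"] = TimeSeries(flow, rate30, 0.0, "a.u.", "ldf")

    true_awake_bins = labels == AWAKE
    truth = {
        "hbt_L": TimeSeries(hbt_l, rate30, 0.0, "uM", "hbt_L_latent"),
        "hbt_R": TimeSeries(hbt_r, rate30, 0.0, "uM", "hbt_R_latent"),
        "drive_L": m_l,
        "drive_R": m_r,
        "gamma_env_L": env_l,
        "gamma_env_R": env_r,
        "whisk_bouts": np.array(whisk_bouts).reshape(-1, 2),
        "move_bouts": np.array(move_bouts).reshape(-1, 2),
        "true_awake_bins": true_awake_bins,
        "r0": config.r0,
        "drift": drift,
        "heart_rate": TimeSeries(hr30, rate30, 0.0, "Hz", "hr_latent"),
    }
    return SyntheticSession(channels, hypnogram, config, stim_times, truth)


def _drift_curve(t: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    a1, a2 = config.drift_amplitudes
    tau1, tau2 = config.drift_taus_s
    return 1.0 + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def simulate_session(
    config: GeneratorConfig | None = None,
    duration_s: float = 3600.0,
    seed: int | None = None,
) -> SyntheticSession:
    """Convenience wrapper: hypnogram plus signals with one seed."""
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    hyp = simulate_hypnogram(config, duration_s, seed)
    return synthesize_signals(hyp, config, seed + 1)


# ---------------------------------------------------------------------------
# image fixtures


def render_whisker_frames(
    angles_deg: Sequence[float],
    shape: tuple[int, int] = (30, 350),
    dropped: np.ndarray | None = None,
    line_value: float = 0.1,
    background: float = 0.9,
    n_whiskers: int = 1,
    spacing_px: int = 8,
) -> np.ndarray:
    """Frames of dark whisker lines on a bright background.

    Each frame shows ``n_whiskers`` parallel dark lines through (near) the
    frame center at the requested angle from horizontal (protraction
    positive).  Dropped frames are rendered uniform bright.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    h, w = shape
    n = angles.size
    dropped = np.zeros(n, bool) if dropped is None else np.asarray(dropped, bool)
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.full((n, h, w), background, dtype=float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    for i, a in enumerate(angles):
        if dropped[i]:
            continue
        rad = np.deg2rad(a)
        # image y grows downward; protraction-positive angle from horizontal
        nx, ny = np.sin(rad), np.cos(rad)  # unit normal to the line
        for k in range(n_whiskers):
            off = (k - (n_whiskers - 1) / 2.0) * spacing_px
            dist = np.abs((xx - cx) * nx + (yy - (cy + off)) * ny)
            frames[i] = np.where(dist <= 0.8, line_value, frames[i])
    return frames


def render_vessel_fixture(
    diameter_px: float,
    kind: str = "disk_frame",
    noise_sd: float = 0.0,
    shape: tuple[int, int] | int = 128,
    profile: str = "plateau",
    ellipticity: float = 1.0,
    angle_deg: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Vessel image fixtures for the diameter estimators (synthetic).

    ``line_profile``: a 1-D cross-sectional profile — a bright plateau of the
    stated width with soft (1 px Gaussian) edges, or a Gaussian bump whose
    FWHM equals ``diameter_px`` when ``profile='gaussian'``.

    ``disk_frame``: a bright disk (or ellipse with axis ratio ``ellipticity``,
    rotated by ``angle_deg``) of the stated diameter on a dark background;
    ``diameter_px`` is the minor-to-major geometric reference: the ellipse has
    axes ``diameter_px * ellipticity`` and ``diameter_px``.
    """
    if diameter_px <= 2:
        raise ValueError("diameter must exceed 2 px")
    rng = np.random.default_rng(seed)
    if kind == "line_profile":
        n = shape if isinstance(shape, int) else shape[0]
        x = np.arange(n) - (n - 1) / 2.0
        if profile == "gaussian":
            sigma = diameter_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            prof = np.exp(-(x**2) / (2 * sigma**2))
        else:
            prof = ((x >= -diameter_px / 2.0) & (x < diameter_px / 2.0)).astype(float)
            prof = ndimage.gaussian_filter1d(prof, 1.0)
        return prof + noise_sd * rng.standard_normal(n)
    if kind == "disk_frame":
        hw = (shape, shape) if isinstance(shape, int) else shape
        h, w = hw
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        a = diameter_px / 2.0  # semi-axis along rotated x
        b = diameter_px * ellipticity / 2.0
        rad = np.deg2rad(angle_deg)
        xr = (xx - cx) * np.cos(rad) + (yy - cy) * np.sin(rad)
        yr = -(xx - cx) * np.sin(rad) + (yy - cy) * np.cos(rad)
        img = ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).astype(float)
        img = ndimage.gaussian_filter(img, 0.8)
        return img + noise_sd * rng.standard_normal((h, w))
    raise ValueError(f"unknown fixture kind {kind!r}")
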