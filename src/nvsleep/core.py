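"""Core containers shared across the pipeline.

Conventions: time is measured in seconds from session start, sample indices
are 0-based, and event intervals are half-open ``[start, stop)``.  Arousal
states are scored on non-overlapping 5 s bins anchored at t = 0; a partial
trailing bin is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical arousal-state labels, in fixed reporting order.
AWAKE = "AWAKE"
NREM = "NREM"
REM = "REM"
STATES: tuple[str, str, str] = (AWAKE, NREM, REM)

#: Width of one hypnogram bin in seconds.
BIN_S = 5.0


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values.
    rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in seconds from session start.
    units : str
        Physical units of the samples (e.g. "uM", "a.u.", "degrees").
    label : str
        Channel name.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        arr = np.asarray(self.values)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(float)
        self.values = arr

    @property
    def n(self) -> int:
        return self.values.shape[-1]

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n samples at `rate`)."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def copy_with(self, **kwargs) -> "TimeSeries":
        return replace(self, **kwargs)


@dataclass
class Hypnogram:
    """Per-bin arousal-state labels.

    labels are strings from :data:`STATES`; ``source`` records whether the
    scores are manual or produced by the classifier.  ``probabilities`` (bins
    x 3, column order AWAKE/NREM/REM) is present only for classifier output.
    """

    labels: np.ndarray
    bin_s: float = BIN_S
    t0: float = 0.0
    source: str = "manual"
    probabilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(map(str, bad))}")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.labels), len(STATES)):
                raise ValueError("probabilities must be (n_bins, 3)")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("probabilities must sum to 1 per bin")
            self.probabilities = p

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_s

    def as_codes(self) -> np.ndarray:
        """Integer codes in STATES order (AWAKE=0, NREM=1, REM=2)."""
        lut = {s: i for i, s in enumerate(STATES)}
        return np.array([lut[s] for s in self.labels], dtype=int)

    def state_fractions(self) -> dict[str, float]:
        n = max(self.n_bins, 1)
        return {s: float(np.sum(self.labels == s)) / n for s in STATES}

    def bin_of_time(self, t: float) -> int:
        return int((t - self.t0) // self.bin_s)


@dataclass
class Event:
    """A typed epoch with half-open interval [start, stop) in seconds."""

    kind: str
    start: float
    stop: float
    summary: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class EventCatalog:
    """Collection of typed epochs (rest, whisk classes, stim, contiguous
    NREM/REM, 15-min alert/asleep/all windows)."""

    events: list[Event] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def kinds(self) -> list[str]:
        return sorted({e.kind for e in self.events})

    def add(self, event: Event) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def runs(labels: Sequence) -> list[tuple[int, int, object]]:
    """Run-length encode a label sequence.

    Returns a list of ``(start_idx, stop_idx, label)`` with half-open index
    intervals covering the sequence in order.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(a), int(b), labels[a]) for a, b in zip(starts, stops)]
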