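"""Arousal-state classification on 5 s bins with bagged decision trees,
validation against manual scores, and the contiguity filters that define
contiguous NREM/REM sleep epochs.

Features per bin (7): cortical delta/beta/gamma band power (each the larger
of the two hemispheres' bin means), hippocampal theta power, EMG log-power,
heart rate, and the number of binarized whisking events in the bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import AWAKE, BIN_S, NREM, REM, STATES, Event, EventCatalog, Hypnogram, runs
from .behavior import BinaryEventTrain
from .core import TimeSeries

FEATURE_COLUMNS = [
    "cortical_delta",
    "cortical_beta",
    "cortical_gamma",
    "hipp_theta",
    "emg_power",
    "heart_rate",
    "whisk_count",
]

#: run-length thresholds for contiguous sleep epochs, in 5 s bins
MIN_NREM_BINS = 6   # 30 s
MIN_REM_BINS = 12   # 60 s
#: REM classifications separated by at most this many non-REM bins are linked
REM_LINK_BINS = 2   # 10 s


def _bin_means(ts: TimeSeries, n_bins: int) -> np.ndarray:
    per_bin = int(round(ts.rate * BIN_S))
    usable = ts.values[: n_bins * per_bin]
    return usable.reshape(n_bins, per_bin).mean(axis=1)


def build_features(
    cortical_delta: tuple[TimeSeries, TimeSeries],
    cortical_beta: tuple[TimeSeries, TimeSeries],
    cortical_gamma: tuple[TimeSeries, TimeSeries],
    hipp_theta: TimeSeries,
    emg_power: TimeSeries,
    heart_rate: TimeSeries,
    whisk_train: BinaryEventTrain,
    bin_s: float = BIN_S,
) -> pd.DataFrame:
    """Per-bin classifier features from the 30 Hz derived channels.

    Cortical band powers take the larger of the two hemispheres' bin means;
    the hippocampal theta, EMG and heart-rate features are bin means; the
    whisking feature counts binarized whisking onsets per bin.  A partial
    trailing bin is dropped.
    """
    if bin_s != BIN_S:
        raise ValueError("scoring bins are fixed at 5 s")
    all_ts = [*cortical_delta, *cortical_beta, *cortical_gamma,
              hipp_theta, emg_power, heart_rate]
    n_bins = min(int(ts.duration // bin_s) for ts in all_ts)
    cols = {}
    for name, pair in (
        ("cortical_delta", cortical_delta),
        ("cortical_beta", cortical_beta),
        ("cortical_gamma", cortical_gamma),
    ):
        cols[name] = np.maximum(_bin_means(pair[0], n_bins), _bin_means(pair[1], n_bins))
    cols["hipp_theta"] = _bin_means(hipp_theta, n_bins)
    cols["emg_power"] = _bin_means(emg_power, n_bins)
    cols["heart_rate"] = _bin_means(heart_rate, n_bins)
    cols["whisk_count"] = np.array(
        [whisk_train.count_in(i * bin_s, (i + 1) * bin_s) for i in range(n_bins)],
        dtype=float,
    )
    df = pd.DataFrame(cols, columns=FEATURE_COLUMNS)
    if df.isna().any().any():
        raise ValueError("NaNs in feature table; impute or flag before scoring")
    return df


def train_classifier(
    features: pd.DataFrame,
    labels: Hypnogram | np.ndarray,
    n_trees: int = 128,
    seed: int = 0,
):
    """Bagged decision trees (bootstrap aggregation) with out-of-bag error.

    Each of the ``n_trees`` trees is grown on an independent bootstrap replica
    of the labeled bins; the out-of-bag error is the fraction of bins
    misclassified by the vote of the trees whose bootstrap sample excluded
    them.

    Returns (model, oob_error).
    """
    y = labels.labels if isinstance(labels, Hypnogram) else np.asarray(labels, object)
    x = features[FEATURE_COLUMNS].to_numpy()
    if len(y) != len(x):
        raise ValueError("features and labels disagree in bin count")
    if len(y) < 50:
        raise ValueError("need at least 50 labeled bins")
    if len(np.unique(list(map(str, y)))) < 2:
        raise ValueError("need at least 2 classes in the training labels")
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(x, y.astype(str))
    return model, float(1.0 - model.oob_score_)


def shuffle_baseline(
    features: pd.DataFrame,
    labels: Hypnogram | np.ndarray,
    n_shuffles: int = 100,
    n_trees: int = 128,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean (and SD) out-of-bag error over label-shuffled training sets.

    Shuffling destroys the feature-label association, so the resulting error
    approximates matching-by-chance, ``1 - sum_c p_c^2`` for class
    proportions p.  Returns (mean, sd) across shuffles.
    """
    y = labels.labels if isinstance(labels, Hypnogram) else np.asarray(labels, object)
    rng = np.random.default_rng(seed)
    errs = []
    for i in range(n_shuffles):
        perm = rng.permutation(len(y))
        _, err = train_classifier(features, y[perm], n_trees=n_trees,
                                  seed=int(rng.integers(2**31 - 1)))
        errs.append(err)
    return float(np.mean(errs)), float(np.std(errs))


def predict_hypnogram(model, features: pd.DataFrame, t0: float = 0.0) -> Hypnogram:
    """Score a session with a trained model, keeping class probabilities."""
    x = features[FEATURE_COLUMNS].to_numpy()
    pred = model.predict(x)
    proba = model.predict_proba(x)
    # reorder probability columns into STATES order, padding absent classes
    full = np.zeros((len(pred), len(STATES)))
    for j, cls in enumerate(model.classes_):
        full[:, STATES.index(cls)] = proba[:, j]
    full /= full.sum(axis=1, keepdims=True)
    return Hypnogram(pred.astype(object), BIN_S, t0, source="classifier",
                     probabilities=full)


def evaluate(model, features: pd.DataFrame, labels: Hypnogram | np.ndarray):
    """Confusion matrix (row-normalized, AWAKE/NREM/REM order) and accuracy.

    Rows are true states, columns predicted; rows with no examples are NaN.
    """
    y = labels.labels if isinstance(labels, Hypnogram) else np.asarray(labels, object)
    pred = model.predict(features[FEATURE_COLUMNS].to_numpy())
    cm = np.zeros((3, 3))
    idx = {s: i for i, s in enumerate(STATES)}
    for t, p in zip(y, pred):
        cm[idx[str(t)], idx[str(p)]] += 1
    acc = float(np.trace(cm) / max(cm.sum(), 1))
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_norm = cm / row_sums
    return cm_norm, acc


# ---------------------------------------------------------------------------
# contiguity filtering


def link_rem(labels: np.ndarray, max_gap_bins: int = REM_LINK_BINS) -> np.ndarray:
    """Bridge short non-REM gaps between REM classifications.

    Gaps of at most ``max_gap_bins`` bins (10 s) between REM runs are relabeled
    REM, unless a gap bin belongs to a qualifying contiguous-NREM run (>= 30 s
    of NREM is treated as genuine NREM, not a scoring hiccup).
    """
    labels = np.asarray(labels, dtype=object).copy()
    protected = np.zeros(labels.size, dtype=bool)
    for a, b, lab in runs(labels):
        if lab == NREM and (b - a) >= MIN_NREM_BINS:
            protected[a:b] = True
    rem_runs = [(a, b) for a, b, lab in runs(labels) if lab == REM]
    for (a1, b1), (a2, b2) in zip(rem_runs[:-1], rem_runs[1:]):
        gap = a2 - b1
        if 0 < gap <= max_gap_bins and not protected[b1:a2].any():
            labels[b1:a2] = REM
    return labels


def contiguity_filter(
    hypnogram: Hypnogram,
    stim_times: np.ndarray | None = None,
) -> EventCatalog:
    """Contiguous NREM/REM sleep epochs from a scored hypnogram.

    REM gap-bridging (<= 2 bins) is applied first, then run-length thresholds:
    6 consecutive bins (30 s) for contiguous NREM, 12 (60 s) for contiguous
    REM.  Epochs overlapping any whisker stimulus are excluded.
    """
    stim_times = np.asarray([] if stim_times is None else stim_times, dtype=float)
    labels = link_rem(hypnogram.labels)
    catalog = EventCatalog()
    for a, b, lab in runs(labels):
        if lab == NREM and (b - a) >= MIN_NREM_BINS:
            kind = "contiguous_NREM"
        elif lab == REM and (b - a) >= MIN_REM_BINS:
            kind = "contiguous_REM"
        else:
            continue
        start = hypnogram.t0 + a * hypnogram.bin_s
        stop = hypnogram.t0 + b * hypnogram.bin_s
        if np.any((stim_times >= start) & (stim_times < stop)):
            continue
        catalog.add(Event(kind, start, stop))
    return catalog
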