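"""Session container (HDF5), conditioning/orchestration, and run manifests.

Layout of a session file::

    /raw/<channel>        raw arrays with `rate` and `units` attributes
    /derived/<channel>    30 Hz conditioned channels
    /hypnogram/<name>     labels (+ bin_s, source attrs, probabilities)
    /events               JSON event catalog
    /analysis/<name>      analysis products
    /truth/...            generator ground truth (synthetic sessions only)
    /manifest             config hash, seeds, schema + software version

Time convention: seconds from session start, 0-based sample indices,
half-open event intervals [start, stop).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal as _sig

from . import __version__
from .behavior import BinaryEventTrain, binarize_movement, binarize_whisking
from .core import BIN_S, STATES, Event, EventCatalog, Hypnogram, TimeSeries
from .events import BaselineSet, establish_baseline, extract_state_events, summarize_events
from .scoring import build_features, evaluate, predict_hypnogram, train_classifier
from .signals import (ANALYSIS_RATE, BANDS, BeerLambertParams, _butter_sos,
                      _resample, band_power, beer_lambert, correct_drift,
                      emg_envelope)
from .spectral import track_heart_rate
from .synthgen import GeneratorConfig, SyntheticSession, simulate_session

SCHEMA_VERSION = 1


@dataclass
class SessionContainer:
    """In-memory mirror of the HDF5 session layout."""

    raw: dict[str, TimeSeries] = field(default_factory=dict)
    derived: dict[str, TimeSeries] = field(default_factory=dict)
    hypnograms: dict[str, Hypnogram] = field(default_factory=dict)
    events: EventCatalog = field(default_factory=EventCatalog)
    analysis: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def config_hash(config) -> str:
    payload = yaml.safe_dump(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


# ---------------------------------------------------------------------------
# HDF5 round trip


def write_session(container: SessionContainer, path: str | Path) -> None:
    if not container.manifest:
        container.manifest = {"schema": SCHEMA_VERSION, "version": __version__}
    container.manifest.setdefault("schema", SCHEMA_VERSION)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = container.manifest["schema"]
        man = f.create_group("manifest")
        man.attrs["json"] = json.dumps(_jsonable(container.manifest))
        for group, chans in (("raw", container.raw), ("derived", container.derived)):
            g = f.create_group(group)
            for name, ts in chans.items():
                d = g.create_dataset(name, data=ts.values)
                d.attrs["rate"] = ts.rate
                d.attrs["t0"] = ts.t0
                d.attrs["units"] = ts.units
        hg = f.create_group("hypnogram")
        for name, h in container.hypnograms.items():
            d = hg.create_dataset(name, data=np.array(
                [s.encode() for s in h.labels]))
            d.attrs["bin_s"] = h.bin_s
            d.attrs["t0"] = h.t0
            d.attrs["source"] = h.source
            if h.probabilities is not None:
                hg.create_dataset(name + "_proba", data=h.probabilities)
        f.create_dataset("events", data=json.dumps([
            {"kind": e.kind, "start": e.start, "stop": e.stop,
             "summary": _jsonable(e.summary)}
            for e in container.events
        ]))
        ag = f.create_group("analysis")
        for name, arr in container.analysis.items():
            ag.create_dataset(name, data=np.asarray(arr))
        tg = f.create_group("truth")
        for name, val in container.truth.items():
            if isinstance(val, TimeSeries):
                d = tg.create_dataset(name, data=val.values)
                d.attrs["rate"] = val.rate
            elif isinstance(val, np.ndarray):
                tg.create_dataset(name, data=val)


def read_session(path: str | Path) -> SessionContainer:
    container = SessionContainer()
    with h5py.File(path, "r") as f:
        schema = int(f.attrs.get("schema", -1))
        if schema != SCHEMA_VERSION:
            raise ValueError(
                f"session file schema {schema} != supported {SCHEMA_VERSION}; "
                "regenerate the session or migrate it with a matching release"
            )
        container.manifest = json.loads(f["manifest"].attrs["json"])
        for group, target in (("raw", container.raw), ("derived", container.derived)):
            for name, d in f[group].items():
                target[name] = TimeSeries(
                    d[()], float(d.attrs["rate"]), float(d.attrs["t0"]),
                    str(d.attrs["units"]), name,
                )
        for name, d in f["hypnogram"].items():
            if name.endswith("_proba"):
                continue
            proba = f["hypnogram"].get(name + "_proba")
            container.hypnograms[name] = Hypnogram(
                np.array([s.decode() for s in d[()]], dtype=object),
                float(d.attrs["bin_s"]), float(d.attrs["t0"]),
                str(d.attrs["source"]),
                probabilities=None if proba is None else proba[()],
            )
        for rec in json.loads(f["events"][()].decode()):
            container.events.add(Event(rec["kind"], rec["start"], rec["stop"],
                                       rec.get("summary", {})))
        for name, d in f["analysis"].items():
            container.analysis[name] = d[()]
        for name, d in f["truth"].items():
            if "rate" in d.attrs:
                container.truth[name] = TimeSeries(d[()], float(d.attrs["rate"]))
            else:
                container.truth[name] = d[()]
    return container


def write_tiff_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write an image stack (frames, h, w) or single frame as float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF image stack written by :func:`write_tiff_stack`."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def require_channels(container: SessionContainer, names: list[str], stage: str):
    missing = [n for n in names if n not in container.raw]
    if missing:
        raise KeyError(
            f"stage {stage!r} needs raw channel(s) {missing}; "
            f"present: {sorted(container.raw)}"
        )


# ---------------------------------------------------------------------------
# conditioning (the signals stage applied to a whole session)


def condition_session(
    session: SyntheticSession,
    bands=("delta", "theta", "beta", "gamma", "mua"),
) -> dict:
    """All 30 Hz derived channels and behavioral trains for one session.

    Returns a dict with keys: heart_rate, whisker_angle, whisk_train,
    move_train, emg_power, per-band cortical powers (``ctx{L,R}_<band>``),
    hipp_theta, drift-corrected reflectance, baseline set, and dHbT per
    hemisphere (``hbt_L``, ``hbt_R``) against the awake-rest baseline.
    """
    ch = session.channels
    out: dict = {}

    # heart rate first: uses the cardiac modulation still present in raw
    out["heart_rate"] = track_heart_rate(ch["reflectance_L"], ch["reflectance_R"])

    # drift correction against the cement reference ROI
    refl = {}
    for side in ("L", "R"):
        corrected, fit_info = correct_drift(ch[f"reflectance_{side}"], ch["reference_roi"])
        refl[side] = corrected
        out[f"drift_fit_{side}"] = fit_info

    # whisker angle: < 20 Hz 2nd order zero-phase, then down to 30 Hz
    wa = ch["whisker_angle"]
    if wa.rate != ANALYSIS_RATE:
        sos = _butter_sos(2, 20.0, wa.rate, "low")
        vals = _sig.sosfiltfilt(sos, wa.values)
        wa = TimeSeries(_resample(vals, wa.rate, ANALYSIS_RATE), ANALYSIS_RATE,
                        wa.t0, wa.units, wa.label)
    out["whisker_angle"] = wa
    out["whisk_train"] = binarize_whisking(wa)
    out["move_train"] = binarize_movement(ch["force"])

    # neural band powers
    for side in ("L", "R"):
        raw = ch[f"neural_cortex_{side}"]
        for name in bands:
            if BANDS[name].high >= raw.rate / 2:
                continue
            out[f"ctx{side}_{name}"] = band_power(raw, BANDS[name])
    out["hipp_theta"] = band_power(ch["neural_hipp"], BANDS["theta"])
    out["emg_power"] = emg_envelope(ch["emg"])

    # awake-rest baseline, then Beer-Lambert conversion against daily R0
    true_awake = session.truth.get(
        "true_awake_bins", session.truth_hypnogram.labels == "AWAKE"
    )
    baseline_channels = {
        "reflectance_L": refl["L"], "reflectance_R": refl["R"],
        "emg_power": out["emg_power"], "heart_rate": out["heart_rate"],
    }
    baseline_channels.update(
        {k: v for k, v in out.items()
         if k.startswith("ctx") or k == "hipp_theta"}
    )
    out["baseline"] = establish_baseline(
        baseline_channels, true_awake, out["whisk_train"], out["move_train"],
        session.stim_times,
    )
    bl_params = BeerLambertParams()
    for side in ("L", "R"):
        r0 = out["baseline"].means[f"reflectance_{side}"]
        out[f"hbt_{side}"] = TimeSeries(
            beer_lambert(refl[side].values / r0 - 1.0, bl_params),
            ANALYSIS_RATE, refl[side].t0, "uM", f"hbt_{side}",
        )
        out[f"reflectance_{side}"] = refl[side]

    # normalized gamma dP/P against the resting baseline
    for side in ("L", "R"):
        key = f"ctx{side}_gamma"
        if key in out:
            base = out["baseline"].means[key]
            out[f"gamma_dpp_{side}"] = TimeSeries(
                (out[key].values - base) / base, ANALYSIS_RATE, 0.0, "dP/P",
                f"gamma_dpp_{side}",
            )
    return out


def features_from_derived(derived: dict) -> pd.DataFrame:
    """Classifier feature table from :func:`condition_session` output."""
    return build_features(
        (derived["ctxL_delta"], derived["ctxR_delta"]),
        (derived["ctxL_beta"], derived["ctxR_beta"]),
        (derived["ctxL_gamma"], derived["ctxR_gamma"]),
        derived["hipp_theta"],
        derived["emg_power"],
        derived["heart_rate"],
        derived["whisk_train"],
    )


def alternating_split(n_bins: int, block_bins: int = 180):
    """Alternating 15 min blocks (180 five-second bins): train on even blocks,
    validate on odd ones — mirroring manual-scoring-session splits."""
    block = np.arange(n_bins) // block_bins
    train = block % 2 == 0
    return train, ~train


def run_pipeline(
    config: GeneratorConfig | None = None,
    duration_s: float = 3600.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict:
    """simulate -> condition -> score -> events -> per-state summaries.

    Returns a results dict; when ``outdir`` is given, summary CSVs, the scored
    hypnogram and a manifest are written there.  Deterministic for fixed
    seeds: rerunning writes byte-identical CSV/JSON outputs.
    """
    config = config or GeneratorConfig(seed=seed)
    session = simulate_session(config, duration_s, seed)
    derived = condition_session(session)
    features = features_from_derived(derived)
    truth = session.truth_hypnogram
    n = min(len(features), truth.n_bins)
    features = features.iloc[:n]

    train_mask, test_mask = alternating_split(n)
    model, oob = train_classifier(features[train_mask], truth.labels[:n][train_mask],
                                  seed=seed)
    cm, acc = evaluate(model, features[test_mask], truth.labels[:n][test_mask])
    hyp = predict_hypnogram(model, features)

    catalog = extract_state_events(
        hyp, derived["whisk_train"], derived["move_train"], session.stim_times,
        true_awake_bins=session.truth.get("true_awake_bins"),
        duration_s=truth.duration,
    )
    hbt_mean = TimeSeries(
        (derived["hbt_L"].values + derived["hbt_R"].values) / 2.0,
        ANALYSIS_RATE, 0.0, "uM", "hbt_mean",
    )
    by_kind = summarize_events(catalog, hbt_mean, key="hbt")

    results = {
        "session": session,
        "derived": derived,
        "features": features,
        "model": model,
        "oob_error": oob,
        "confusion": cm,
        "accuracy": acc,
        "hypnogram": hyp,
        "catalog": catalog,
        "hbt_by_kind": by_kind,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema": SCHEMA_VERSION,
            "version": __version__,
            "seed": seed,
            "duration_s": duration_s,
            "config_hash": config_hash(config),
            "oob_error": oob,
            "held_out_accuracy": acc,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        features.to_csv(outdir / "features.csv", index=False)
        pd.DataFrame(
            {"kind": [e.kind for e in catalog],
             "start_s": [e.start for e in catalog],
             "stop_s": [e.stop for e in catalog],
             "hbt": [e.summary.get("hbt", np.nan) for e in catalog]}
        ).to_csv(outdir / "events.csv", index=False)
        summary = pd.DataFrame(
            [{"kind": k, "mean": float(v.mean()), "sd": float(v.std(ddof=1))
              if v.size > 1 else np.nan, "n": int(v.size)}
             for k, v in sorted(by_kind.items())]
        )
        summary.to_csv(outdir / "state_summary.csv", index=False)
        (outdir / "hypnogram.json").write_text(json.dumps(
            {"t0": hyp.t0, "bin_s": hyp.bin_s, "labels": list(hyp.labels)}
        ))
        results["outdir"] = outdir
    return results


def session_to_container(session: SyntheticSession) -> SessionContainer:
    """Wrap a generated session in the HDF5-mirroring container."""
    c = SessionContainer()
    c.raw = dict(session.channels)
    c.hypnograms["truth"] = session.truth_hypnogram
    c.truth = {
        k: v for k, v in session.truth.items()
        if isinstance(v, (TimeSeries, np.ndarray))
    }
    c.truth["stim_times"] = np.asarray(session.stim_times)
    c.manifest = {
        "schema": SCHEMA_VERSION,
        "version": __version__,
        "seed": session.truth_params.seed,
        "config_hash": config_hash(session.truth_params),
    }
    return c
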