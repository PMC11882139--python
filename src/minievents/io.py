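"""File I/O: traces (HDF5 / ABF / delimited text), event tables, models."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .nn.network import ConvBlockSpec, EventClassifier, ModelSpec
from .quantify import EventStats, RecordingSummary
from .trace import Trace

__all__ = ["read_trace", "write_trace", "write_event_table",
           "read_event_table", "save_model", "load_model"]

EVENT_COLUMNS = ["event_idx", "position_s", "amplitude", "rise_10_90_ms",
                 "half_decay_ms", "charge", "score"]

_MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path, dataset: str = "data") -> None:
    """HDF5 layout: one dataset plus sampling_rate_hz / units attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset(dataset, data=trace.samples)
        d.attrs["sampling_rate_hz"] = trace.sampling_rate
        d.attrs["units"] = trace.units
        d.attrs["polarity"] = trace.polarity


def read_trace(path, sampling_rate: float | None = None,
               dataset: str | None = None, channel: int = 0,
               units: str | None = None, polarity: str = "negative",
               delimiter: str | None = None) -> Trace:
    """Read a trace from HDF5, ABF or delimited text (by file suffix).

    HDF5 files carry their sampling rate as a dataset or group attribute;
    text files need an explicit ``sampling_rate``.  ABF reading requires
    the optional ``pyabf`` package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf", ".nwb"):
        return _read_hdf5(path, dataset, sampling_rate, units, polarity)
    if suffix == ".abf":
        return _read_abf(path, channel, units, polarity)
    if suffix in (".csv", ".txt", ".tsv", ".dat", ".asc"):
        if sampling_rate is None:
            raise ValueError(
                "delimited-text traces carry no metadata: pass sampling_rate")
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        col = channel if data.shape[1] > channel else 0
        return Trace(data[:, col], sampling_rate, units=units or "pA",
                     polarity=polarity, name=path.stem)
    raise ValueError(f"unknown trace format '{suffix}' for {path}")


def _read_hdf5(path, dataset, sampling_rate, units, polarity) -> Trace:
    with h5py.File(path, "r") as f:
        if dataset is None:
            keys = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
            if len(keys) != 1:
                raise ValueError(
                    f"{path} holds {len(keys)} datasets; pass the dataset key")
            dataset = keys[0]
        if dataset not in f:
            raise KeyError(f"dataset '{dataset}' not found in {path}")
        d = f[dataset]
        samples = np.asarray(d[()], dtype=np.float64).ravel()
        rate = d.attrs.get("sampling_rate_hz",
                           f.attrs.get("sampling_rate_hz", sampling_rate))
        if rate is None:
            raise ValueError(
                f"{path}:{dataset} has no 'sampling_rate_hz' attribute; "
                f"pass sampling_rate explicitly")
        u = units or d.attrs.get("units", "pA")
        p = d.attrs.get("polarity", polarity)
        p = p.decode() if isinstance(p, bytes) else str(p)
        u = u.decode() if isinstance(u, bytes) else str(u)
    return Trace(samples, float(rate), units=u, polarity=p, name=path.stem)


def _read_abf(path, channel, units, polarity) -> Trace:
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading Axon Binary Format files requires the optional "
            "'pyabf' package (pip install minievents[abf])") from exc
    abf = pyabf.ABF(str(path))
    abf.setSweep(0, channel=channel)
    return Trace(np.asarray(abf.sweepY, dtype=np.float64), abf.dataRate,
                 units=units or abf.sweepUnitsY, polarity=polarity,
                 name=path.stem)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_event_table(events: list[EventStats], summary: RecordingSummary,
                      path) -> None:
    """Event CSV plus a one-row summary CSV alongside (<stem>_summary.csv)."""
    path = Path(path)
    rows = [{"event_idx": i, "position_s": e.position_s,
             "amplitude": e.amplitude, "rise_10_90_ms": e.rise_10_90_ms,
             "half_decay_ms": e.half_decay_ms, "charge": e.charge,
             "score": e.score} for i, e in enumerate(events)]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)

    srow = {"n_events": summary.n_events, "duration_s": summary.duration_s,
            "frequency_hz": summary.frequency_hz}
    for stat, d in (("mean", summary.mean), ("median", summary.median)):
        for k, v in d.items():
            srow[f"{stat}_{k}"] = v
    pd.DataFrame([srow]).to_csv(path.with_name(path.stem + "_summary.csv"),
                                index=False)


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def save_model(model: EventClassifier, path) -> None:
    """Single .npz container of every tensor + a JSON provenance sidecar."""
    path = Path(path)
    arrays = {f"p{i}:{p.name}": p.value for i, p in
              enumerate(model.parameters())}
    np.savez(path, **arrays)
    spec = asdict(model.spec)
    sidecar = {
        "format_version": _MODEL_FORMAT_VERSION,
        "spec": spec,
        "seed": model.seed,
        "provenance": _jsonable(model.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> EventClassifier:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar_path = _sidecar_path(path)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        version = sidecar.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {version} is not supported "
                f"(expected {_MODEL_FORMAT_VERSION})")
        blocks = tuple(ConvBlockSpec(**b) for b in sidecar["spec"].pop(
            "conv_blocks"))
        spec = ModelSpec(conv_blocks=blocks, **sidecar["spec"])
        seed = sidecar.get("seed", 0)
    else:
        warnings.warn(f"no provenance sidecar next to {path}; assuming the "
                      f"default architecture", stacklevel=2)
        spec, seed, sidecar = ModelSpec(), 0, {}
    model = EventClassifier(spec, seed=seed)
    with np.load(path) as data:
        keys = sorted(data.files, key=lambda k: int(k.split(":")[0][1:]))
        model.set_weights([data[k] for k in keys])
    model.provenance.update(sidecar.get("provenance", {}))
    return model


def _sidecar_path(path: Path) -> Path:
    if not path.suffix:
        path = path.with_suffix(".npz")
    return path.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_history(history: dict, path) -> None:
    """Training history as delimited text (one row per epoch)."""
    df = pd.DataFrame(history)
    df.insert(0, "epoch", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
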