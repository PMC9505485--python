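"""Reading and writing signal traces and event schedules.

Two storage dialects are supported:

* CSV with a ``# key: value`` metadata header block followed by one column
  per channel (lossless to full float precision via ``repr``).
* HDF5 with one dataset per signal under ``/signals/<name>`` and ``rate``,
  ``units``, ``t0`` and ``channel_labels`` stored as attributes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import EventSchedule, FormatError, SignalTrace

log = logging.getLogger("physioload")

_REQUIRED_META = ("rate", "units")
_KNOWN_META = ("rate", "units", "t0", "channels")
_TIME_TOL_S = 1e-6


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_signal(trace: SignalTrace, path: str | Path, fmt: str | None = None,
                 name: str = "signal") -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# rate: {trace.rate!r}\n")
            fh.write(f"# units: {trace.units}\n")
            fh.write(f"# t0: {trace.t0!r}\n")
            fh.write(f"# channels: {','.join(trace.channel_labels)}\n")
            fh.write(",".join(trace.channel_labels) + "\n")
            for row in trace.values.T:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
    elif fmt == "hdf5":
        with h5py.File(path, "a") as fh:
            grp = fh.require_group("signals")
            if name in grp:
                del grp[name]
            # track_times off so identical writes are byte-identical
            ds = grp.create_dataset(name, data=trace.values, track_times=False)
            ds.attrs["rate"] = trace.rate
            ds.attrs["units"] = trace.units
            ds.attrs["t0"] = trace.t0
            ds.attrs["channel_labels"] = list(trace.channel_labels)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_signal(path: str | Path, fmt: str | None = None, name: str = "signal") -> SignalTrace:
    """Read a validated :class:`SignalTrace` from CSV or HDF5.

    Raises
    ------
    FormatError
        If required metadata (rate, units) is absent, or a ``time`` column is
        present whose stamps deviate from uniform sampling by more than 1 µs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path, name)
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path) -> SignalTrace:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].partition(":")
            key = key.strip()
            meta[key] = value.strip()
            if key not in _KNOWN_META:
                log.warning("ignoring unknown metadata key %r in %s", key, path)
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"{path}: missing required metadata {key!r}")
    try:
        rate = float(meta["rate"])
    except ValueError as exc:
        raise FormatError(f"{path}: invalid rate {meta['rate']!r}") from exc
    t0 = float(meta.get("t0", 0.0))

    frame = pd.read_csv(path, skiprows=n_header)
    channels = [c.strip() for c in meta["channels"].split(",")] if "channels" in meta else None
    if channels is None:
        channels = [c for c in frame.columns if c != "time"]
    unknown = [c for c in frame.columns if c not in channels and c != "time"]
    if unknown:
        log.warning("ignoring unknown columns %s in %s", unknown, path)
    if "time" in frame.columns:
        t = frame["time"].to_numpy(dtype=float)
        expected = t[0] + np.arange(len(t)) / rate
        if np.max(np.abs(t - expected)) > _TIME_TOL_S:
            raise FormatError(f"{path}: timestamps deviate from uniform sampling")
        t0 = float(t[0])
    missing = [c for c in channels if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: declared channels {missing} not found")
    values = frame[channels].to_numpy(dtype=float).T
    return SignalTrace(values, rate=rate, t0=t0,
                       channel_labels=tuple(channels), units=meta["units"])


def _read_hdf5(path: Path, name: str) -> SignalTrace:
    with h5py.File(path, "r") as fh:
        if "signals" not in fh or name not in fh["signals"]:
            raise FormatError(f"{path}: no dataset /signals/{name}")
        ds = fh["signals"][name]
        for key in _REQUIRED_META:
            if key not in ds.attrs:
                raise FormatError(f"{path}: dataset missing attribute {key!r}")
        labels = tuple(
            lbl.decode() if isinstance(lbl, bytes) else str(lbl)
            for lbl in ds.attrs.get("channel_labels", ())
        )
        return SignalTrace(
            values=ds[()],
            rate=float(ds.attrs["rate"]),
            t0=float(ds.attrs.get("t0", 0.0)),
            channel_labels=labels,
            units=str(ds.attrs["units"]),
        )


def list_signals(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as fh:
        if "signals" not in fh:
            return []
        return sorted(fh["signals"].keys())


def write_schedule(schedule: EventSchedule, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"onset_s": schedule.onsets, "level": schedule.levels, "soa_s": schedule.soa}
    )
    frame.to_csv(path, index=False)


def read_schedule(path: str | Path) -> EventSchedule:
    frame = pd.read_csv(path)
    for col in ("onset_s", "level", "soa_s"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return EventSchedule(
        onsets=frame["onset_s"].to_numpy(dtype=float),
        levels=frame["level"].to_numpy(dtype=int),
        soa=frame["soa_s"].to_numpy(dtype=float),
    )
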