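"""On-disk layout for a simulated study: HDF5 signals + CSV schedule + JSON truth.

A study directory contains ``signals.h5`` (one dataset per trial and
modality under ``/signals/trial<i>_<modality>``), ``schedule.csv`` and
``truth.json`` (generator ground truth, kept for detector scoring)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .io import list_signals, read_schedule, read_signal, write_schedule, write_signal
from .simulate import GroundTruth, StudyDataset, Trial

MODALITIES = ("pupil", "gaze", "eeg", "abp")


def save_study(dataset: StudyDataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5 = out_dir / "signals.h5"
    if h5.exists():
        h5.unlink()
    for i, trial in enumerate(dataset.trials):
        for mod in MODALITIES:
            write_signal(getattr(trial, mod), h5, fmt="hdf5", name=f"trial{i:04d}_{mod}")
    write_schedule(dataset.schedule, out_dir / "schedule.csv")
    truth = [
        {mod: _truth_to_json(trial.truth[mod]) for mod in MODALITIES}
        for trial in dataset.trials
    ]
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True)


def load_study(in_dir: str | Path) -> StudyDataset:
    in_dir = Path(in_dir)
    schedule = read_schedule(in_dir / "schedule.csv")
    truth_path = in_dir / "truth.json"
    truths = None
    if truth_path.exists():
        with open(truth_path) as fh:
            truths = json.load(fh)
    h5 = in_dir / "signals.h5"
    n_trials = len(schedule)
    names = set(list_signals(h5))
    trials = []
    for i in range(n_trials):
        traces = {}
        for mod in MODALITIES:
            name = f"trial{i:04d}_{mod}"
            if name not in names:
                raise FileNotFoundError(f"{h5}: missing dataset {name}")
            traces[mod] = read_signal(h5, fmt="hdf5", name=name)
        truth = ({mod: _truth_from_json(truths[i][mod]) for mod in MODALITIES}
                 if truths else {mod: GroundTruth() for mod in MODALITIES})
        trials.append(Trial(level=int(schedule.levels[i]),
                            soa=float(schedule.soa[i]), truth=truth, **traces))
    return StudyDataset(trials=trials, schedule=schedule)


def _truth_to_json(truth: GroundTruth) -> dict:
    out = {}
    for key, value in asdict(truth).items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        out[key] = value
    return out


def _truth_from_json(d: dict) -> GroundTruth:
    kwargs = dict(d)
    for key in ("beat_times", "true_ibi_ms", "sp_values", "dp_values",
                "dp_times", "band_power_true"):
        if kwargs.get(key) is not None:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    kwargs["blink_intervals"] = [tuple(b) for b in kwargs.get("blink_intervals", [])]
    return GroundTruth(**kwargs)
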