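"""Shared data model: signal traces, event schedules, trial windows, feature tables.

Conventions used throughout the package: time in seconds, 0-based sample
indexing, half-open windows ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EEG_CHANNELS = ("FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6")

WORKLOAD_LEVELS = (0, 1, 2)
SOA_SET = (0.0, 0.5, 1.0)


class PhysioLoadError(Exception):
    """Base class for package errors."""


class FormatError(PhysioLoadError):
    """A file is missing required metadata or is malformed."""


class WindowBoundsError(PhysioLoadError):
    """A requested trial window falls outside the parent trace."""


class UnusableTrialError(PhysioLoadError):
    """A trial contains no usable samples."""


class InsufficientBeatsError(PhysioLoadError):
    """Too few accepted heartbeats to proceed."""


class InsufficientDataError(PhysioLoadError):
    """Too few events for spectral or statistical estimation."""


class DegenerateDatasetError(PhysioLoadError):
    """A workload class was emptied by quality filtering."""


@dataclass
class SignalTrace:
    """A uniformly sampled multichannel signal.

    Parameters
    ----------
    values : ndarray, shape (channels, samples)
        Per-sample amplitudes. Pupil diameter in mm, EEG in µV, arterial
        blood pressure in mmHg, gaze position in normalized screen units.
    rate : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample in seconds.
    channel_labels : tuple of str
        One label per channel.
    units : str
        Physical units of ``values``.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    channel_labels: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]

    def copy_with(self, **kwargs) -> "SignalTrace":
        fields = dict(
            values=self.values.copy(),
            rate=self.rate,
            t0=self.t0,
            channel_labels=self.channel_labels,
            units=self.units,
        )
        fields.update(kwargs)
        return SignalTrace(**fields)


@dataclass
class EventSchedule:
    """Trial onsets with workload level and, for level 2, an SOA label.

    SOA (stimulus onset asynchrony) is the lag between braking-event onset
    and question completion; it is defined only for level-2 trials and is
    NaN elsewhere.
    """

    onsets: np.ndarray
    levels: np.ndarray
    soa: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        self.soa = np.asarray(self.soa, dtype=float)
        if not (len(self.onsets) == len(self.levels) == len(self.soa)):
            raise ValueError("onsets, levels and soa must have equal length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if not np.all(np.isin(self.levels, WORKLOAD_LEVELS)):
            raise ValueError("levels must be in {0, 1, 2}")
        lvl2 = self.levels == 2
        if lvl2.any() and not np.all(np.isin(self.soa[lvl2], SOA_SET)):
            raise ValueError(f"level-2 SOA must be in {SOA_SET}")
        if (~lvl2).any() and not np.all(np.isnan(self.soa[~lvl2])):
            raise ValueError("levels 0/1 carry no SOA (use NaN)")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass(frozen=True)
class TrialWindow:
    """A half-open analysis window ``[onset, onset + duration)`` in seconds."""

    onset: float
    duration: float
    level: int = -1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("window duration must be positive")


def extract_window(trace: SignalTrace, window: TrialWindow) -> SignalTrace:
    """Cut a trial window out of a trace.

    The returned trace has exactly ``round(duration * rate)`` samples; the
    sample at ``onset`` is included and the sample at ``onset + duration``
    excluded.

    Raises
    ------
    WindowBoundsError
        If the window is not fully inside the trace extent.
    """
    start = int(round((window.onset - trace.t0) * trace.rate))
    n = int(round(window.duration * trace.rate))
    if start < 0 or start + n > trace.n_samples:
        raise WindowBoundsError(
            f"window [{window.onset}, {window.onset + window.duration}) outside "
            f"trace extent [{trace.t0}, {trace.t_end})"
        )
    return SignalTrace(
        values=trace.values[:, start : start + n].copy(),
        rate=trace.rate,
        t0=trace.t0 + start / trace.rate,
        channel_labels=trace.channel_labels,
        units=trace.units,
    )


@dataclass
class FeatureTable:
    """Per-trial feature rows with workload labels.

    The interface between feature extraction, the statistical suite, and the
    classifiers. ``data`` holds named feature columns (one row per trial),
    ``labels`` the workload level per row.
    """

    data: pd.DataFrame
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels must have equal length")
        if self.data.columns.duplicated().any():
            raise ValueError("feature column names must be unique")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def select(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            meta=dict(self.meta),
        )

    def subset_levels(self, levels: Sequence[int]) -> "FeatureTable":
        mask = np.isin(self.labels, list(levels))
        return self.select(np.flatnonzero(mask))

    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "level", self.labels)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "FeatureTable":
        labels = frame["level"].to_numpy(dtype=int)
        return cls(frame.drop(columns=["level"]).reset_index(drop=True), labels, meta or {})


def assemble_dataset(
    features: FeatureTable,
    quality_flags: np.ndarray,
    balance: bool = True,
    seed: int | None = None,
) -> FeatureTable:
    """Drop low-quality trials and optionally equalize class counts.

    Trials whose quality flag is False are discarded. With ``balance=True``
    each workload class is subsampled (without replacement, seeded) to the
    size of the smallest class, mirroring the construction of a balanced
    dataset after noisy-sample removal. Discard counts are recorded in the
    returned table's metadata.

    Raises
    ------
    DegenerateDatasetError
        If any class present before filtering ends up with zero good trials.
    """
    quality_flags = np.asarray(quality_flags, dtype=bool)
    if len(quality_flags) != len(features):
        raise ValueError("one quality flag per trial is required")
    keep = np.flatnonzero(quality_flags)
    n_dropped = len(features) - len(keep)
    levels_before = set(np.unique(features.labels).tolist())
    kept = features.select(keep)
    levels_after = set(np.unique(kept.labels).tolist())
    empty = levels_before - levels_after
    if empty:
        raise DegenerateDatasetError(f"levels {sorted(empty)} have no good trials")

    selected = keep
    if balance:
        counts = kept.class_counts()
        n_min = min(counts.values())
        rng = np.random.default_rng(seed)
        idx_parts = []
        for level in sorted(counts):
            level_idx = np.flatnonzero(kept.labels == level)
            if len(level_idx) > n_min:
                level_idx = np.sort(rng.choice(level_idx, size=n_min, replace=False))
            idx_parts.append(level_idx)
        sub = np.sort(np.concatenate(idx_parts))
        kept = kept.select(sub)
        selected = keep[sub]

    kept.meta.update(
        {
            "n_discarded_quality": int(n_dropped),
            "class_counts": kept.class_counts(),
            "balanced": bool(balance),
            "selected_indices": selected.tolist(),
        }
    )
    return kept
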