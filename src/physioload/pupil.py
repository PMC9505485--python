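"""Pupillometry: preprocessing, percentage change in pupil size, fixations.

The percentage change in pupil size (PCPS) for sample ``i`` is

    PCPS_i = (x_i - baseline) / baseline * 100,

with the baseline the mean diameter over the 1 s segment preceding stimulus
onset; APCPS is the arithmetic mean of PCPS over the 2.5 s post-onset
window. PCPS is invariant to global scaling of the diameter, which removes
subject-level differences in absolute pupil size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import SignalTrace, TrialWindow, UnusableTrialError, extract_window

PUPIL_MIN_MM = 0.8
PUPIL_MAX_MM = 10.0


@dataclass
class PupilTrial:
    """Preprocessed pupil trial with its PCPS series."""

    clean: SignalTrace
    pcps: np.ndarray
    baseline_mm: float
    interpolated_fraction: float


@dataclass
class FixationSummary:
    count: int
    mean_duration_s: float


def preprocess_pupil(raw: SignalTrace, lowpass_hz: float = 10.0,
                     order: int = 5) -> tuple[SignalTrace, float]:
    """Clean a single-channel pupil-diameter trace.

    Steps: (1) samples strictly below 0.8 mm or above 10 mm (blink artifacts
    and implausible dilation) are marked invalid; (2) invalid runs are
    linearly interpolated between the nearest valid neighbours (edge runs
    held at the nearest valid value); (3) zero-phase 5th-order Butterworth
    low-pass at 10 Hz removes residual high-frequency noise. The filtered
    output is clamped to the valid range so edge ringing cannot reintroduce
    out-of-range samples.

    Returns the cleaned trace and the fraction of samples interpolated.

    Raises
    ------
    UnusableTrialError
        If every sample is outside the valid range.
    ValueError
        If the trace is not single-channel or the rate cannot support the
        10 Hz cutoff.
    """
    if raw.n_channels != 1:
        raise ValueError("pupil preprocessing expects a single-channel trace")
    if raw.rate <= 2 * lowpass_hz:
        raise ValueError(f"rate {raw.rate} Hz too low for a {lowpass_hz} Hz cutoff")
    x = raw.values[0].copy()
    valid = (x >= PUPIL_MIN_MM) & (x <= PUPIL_MAX_MM)
    if not valid.any():
        raise UnusableTrialError("all pupil samples outside [0.8, 10] mm")
    frac = 1.0 - valid.mean()
    if not valid.all():
        idx = np.arange(x.size)
        x = np.interp(idx, idx[valid], x[valid])  # edge runs held at nearest valid
    sos = signal.butter(order, lowpass_hz, btype="low", fs=raw.rate, output="sos")
    x = signal.sosfiltfilt(sos, x, padlen=min(x.size - 1, 3 * int(raw.rate)))
    x = np.clip(x, PUPIL_MIN_MM, PUPIL_MAX_MM)
    clean = raw.copy_with(values=x[None, :])
    return clean, float(frac)


def compute_pcps(clean: SignalTrace, onset: float, baseline_s: float = 1.0,
                 window_s: float = 2.5, interpolated_fraction: float = 0.0
                 ) -> PupilTrial:
    """Percentage change in pupil size over the post-onset window.

    The baseline is the mean diameter over ``[onset - baseline_s, onset)``;
    PCPS is computed per sample over ``[onset, onset + window_s)``.

    Raises
    ------
    WindowBoundsError
        If the trace does not cover baseline and post-onset windows.
    ValueError
        If the baseline is non-positive.
    """
    base = extract_window(clean, TrialWindow(onset - baseline_s, baseline_s))
    post = extract_window(clean, TrialWindow(onset, window_s))
    baseline = float(base.values[0].mean())
    if baseline <= 0:
        raise ValueError(f"non-positive pupil baseline {baseline}")
    pcps = (post.values[0] - baseline) / baseline * 100.0
    return PupilTrial(clean=clean, pcps=pcps, baseline_mm=baseline,
                      interpolated_fraction=interpolated_fraction)


def apcps(pcps: np.ndarray) -> float:
    """Average percentage change in pupil size: the mean of the PCPS series."""
    pcps = np.asarray(pcps, dtype=float)
    if pcps.size == 0:
        raise ValueError("APCPS requires at least one PCPS sample")
    return float(pcps.mean())


def detect_fixations(gaze: SignalTrace, window: TrialWindow | None = None,
                     dispersion: float = 0.01, min_dur_s: float = 0.1
                     ) -> FixationSummary:
    """Dispersion-threshold (I-DT) fixation identification.

    A maximal sample run whose spatial dispersion — (max - min) in x plus
    (max - min) in y — stays within ``dispersion`` and that lasts at least
    ``min_dur_s`` counts as one fixation. Returns the fixation count and the
    mean fixation duration (0 when no fixation is found).
    """
    trace = extract_window(gaze, window) if window is not None else gaze
    if trace.n_channels != 2:
        raise ValueError("gaze trace must have exactly two channels (x, y)")
    x, y = trace.values
    n = trace.n_samples
    min_len = int(np.ceil(min_dur_s * trace.rate))
    durations: list[float] = []
    i = 0
    while i + min_len <= n:
        j = i + min_len
        if _dispersion(x[i:j], y[i:j]) > dispersion:
            i += 1
            continue
        while j < n and _dispersion(x[i:j + 1], y[i:j + 1]) <= dispersion:
            j += 1
        durations.append((j - i) / trace.rate)
        i = j
    count = len(durations)
    mean_dur = float(np.mean(durations)) if durations else 0.0
    return FixationSummary(count=count, mean_duration_s=mean_dur)


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return float((x.max() - x.min()) + (y.max() - y.min()))


def pupil_feature_vector(trial: PupilTrial, mode: str = "mean_var") -> np.ndarray:
    """Classification features from a pupil trial.

    ``mode="series"`` returns the full fixed-length PCPS sample vector (the
    time-series input for pupil models); ``mode="mean_var"`` returns
    ``[mean, variance]`` of PCPS (the handcrafted 2-d feature used in
    feature-level fusion). Variance is the sample variance (ddof=1).
    """
    if mode == "series":
        return trial.pcps.copy()
    if mode == "mean_var":
        var = float(trial.pcps.var(ddof=1)) if trial.pcps.size > 1 else 0.0
        return np.array([float(trial.pcps.mean()), var])
    raise ValueError(f"unknown mode {mode!r}")
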