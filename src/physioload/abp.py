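"""Arterial blood pressure: preprocessing and systolic/diastolic detection.

Systolic pressure (SP) points serve as heartbeat markers; interbeat
intervals (IBI) are SP-to-SP times and heart rate is HR = 6e4 / IBI(ms).
Detection accepts a DP->SP pair only if the pulse amplitude SP - DP reaches
10 mmHg, and accepts an SP only if its preceding IBI lies within
[500, 2000] ms (120 down to 30 bpm — deliberately wider than the resting
60-90 bpm range to tolerate subject variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import InsufficientBeatsError, SignalTrace

MIN_PULSE_AMP_MMHG = 10.0
IBI_RANGE_MS = (500.0, 2000.0)


@dataclass
class BeatSeries:
    """Accepted systolic/diastolic points and derived IBI/HR sequences."""

    sp_times: np.ndarray
    sp_values: np.ndarray
    dp_times: np.ndarray
    dp_values: np.ndarray

    @property
    def ibi_ms(self) -> np.ndarray:
        return np.diff(self.sp_times) * 1000.0

    @property
    def hr_bpm(self) -> np.ndarray:
        return 6.0e4 / self.ibi_ms


def preprocess_abp(raw: SignalTrace, target_rate: float = 250.0,
                   lowpass_hz: float = 5.0, order: int = 5) -> SignalTrace:
    """Linear resample to 250 Hz, then zero-phase 5th-order low-pass at 5 Hz.

    Raises
    ------
    ValueError
        If the trace is shorter than 2 s.
    """
    if raw.duration < 2.0:
        raise ValueError("ABP preprocessing requires at least 2 s of data")
    if raw.n_channels != 1:
        raise ValueError("ABP preprocessing expects a single-channel trace")
    t_old = raw.times()
    n_new = int(round(raw.duration * target_rate))
    t_new = raw.t0 + np.arange(n_new) / target_rate
    t_new = t_new[t_new <= t_old[-1]]
    x = np.interp(t_new, t_old, raw.values[0])
    sos = signal.butter(order, lowpass_hz, btype="low", fs=target_rate, output="sos")
    x = signal.sosfiltfilt(sos, x)
    return SignalTrace(x[None, :], rate=target_rate, t0=raw.t0,
                       channel_labels=raw.channel_labels, units=raw.units)


def detect_beats(clean: SignalTrace,
                 min_amp_mmHg: float = MIN_PULSE_AMP_MMHG,
                 ibi_range_ms: tuple[float, float] = IBI_RANGE_MS) -> BeatSeries:
    """Detect systolic and diastolic points from a preprocessed ABP trace.

    Algorithm:

    1. all strict local maxima are SP candidates and strict local minima DP
       candidates;
    2. the merged candidate sequence is forced to strictly alternate DP/SP
       by keeping, within any same-type run, the most extreme candidate
       (highest SP, lowest DP; ties broken by earlier time);
    3. a DP->SP pair is accepted only if SP - DP >= 10 mmHg; otherwise the
       weaker pair member (the one with the smaller prominence relative to
       its opposite-type neighbours) is deleted and alternation restored;
    4. IBIs between consecutive accepted SPs must lie in [500, 2000] ms; an
       SP whose preceding IBI fails the gate is dropped (the later one) and
       the sequence re-evaluated, iterating to a fixed point.

    Raises
    ------
    InsufficientBeatsError
        If fewer than 2 SPs survive.
    """
    x = clean.values[0]
    t = clean.times()
    interior = np.arange(1, x.size - 1)
    is_max = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    is_min = (x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])
    # events: (sample index, type) with type +1 = SP, -1 = DP
    events = [(int(i), +1) for i in interior[is_max]]
    events += [(int(i), -1) for i in interior[is_min]]
    events.sort()
    events = _realternate(events, x)

    # amplitude gate, iterated to a fixed point
    while True:
        bad = _first_weak_pair(events, x, min_amp_mmHg)
        if bad is None:
            break
        del events[bad]
        events = _realternate(events, x)
        if sum(1 for _, typ in events if typ == +1) < 2:
            raise InsufficientBeatsError("all pulse pairs fail the amplitude gate")

    # IBI gate: drop the later SP of the first violating interval, repeat
    lo_s, hi_s = ibi_range_ms[0] / 1000.0, ibi_range_ms[1] / 1000.0
    while True:
        sp_idx = [i for i, typ in events if typ == +1]
        if len(sp_idx) < 2:
            raise InsufficientBeatsError("fewer than 2 systolic points accepted")
        ibis = np.diff(t[sp_idx])
        viol = np.flatnonzero((ibis < lo_s) | (ibis > hi_s))
        if viol.size == 0:
            break
        drop_sample = sp_idx[viol[0] + 1]
        events = [(i, typ) for i, typ in events if not (typ == +1 and i == drop_sample)]
        events = _realternate(events, x)

    sp = np.array([i for i, typ in events if typ == +1], dtype=int)
    dp = np.array([i for i, typ in events if typ == -1], dtype=int)
    return BeatSeries(sp_times=t[sp], sp_values=x[sp], dp_times=t[dp], dp_values=x[dp])


def _realternate(events: list[tuple[int, int]], x: np.ndarray) -> list[tuple[int, int]]:
    """Collapse same-type runs, keeping the most extreme candidate."""
    out: list[tuple[int, int]] = []
    for i, typ in events:
        if out and out[-1][1] == typ:
            prev_i = out[-1][0]
            better = (x[i] > x[prev_i]) if typ == +1 else (x[i] < x[prev_i])
            if better:
                out[-1] = (i, typ)
        else:
            out.append((i, typ))
    return out


def _first_weak_pair(events: list[tuple[int, int]], x: np.ndarray,
                     min_amp: float) -> int | None:
    """Index (into events) of the weaker member of the first failing DP->SP pair."""
    for k in range(len(events) - 1):
        i, typ = events[k]
        j, typ2 = events[k + 1]
        if typ == -1 and typ2 == +1 and x[j] - x[i] < min_amp:
            # SP prominence: height above the failing DP. DP prominence:
            # depth below the preceding SP (when one exists). The smaller
            # prominence marks the weaker member; ties delete the SP, which
            # preserves the earlier event.
            sp_prom = x[j] - x[i]
            if k > 0 and events[k - 1][1] == +1:
                dp_prom = x[events[k - 1][0]] - x[i]
            else:
                dp_prom = sp_prom
            return k + 1 if sp_prom <= dp_prom else k
    return None


def write_beats(series: BeatSeries, path) -> None:
    """Write detected beats as CSV with columns ``time_s,type,value_mmHg``."""
    events = sorted(
        [(t, "SP", v) for t, v in zip(series.sp_times, series.sp_values)]
        + [(t, "DP", v) for t, v in zip(series.dp_times, series.dp_values)]
    )
    with open(path, "w") as fh:
        fh.write("time_s,type,value_mmHg\n")
        for t, typ, v in events:
            fh.write(f"{float(t)!r},{typ},{float(v)!r}\n")


def read_beats(path) -> BeatSeries:
    import pandas as pd

    frame = pd.read_csv(path)
    sp = frame[frame["type"] == "SP"]
    dp = frame[frame["type"] == "DP"]
    return BeatSeries(
        sp_times=sp["time_s"].to_numpy(float), sp_values=sp["value_mmHg"].to_numpy(float),
        dp_times=dp["time_s"].to_numpy(float), dp_values=dp["value_mmHg"].to_numpy(float),
    )


def ibi_hr(series: BeatSeries | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interbeat intervals (ms) and heart rate (bpm) from systolic times.

    ``ibi_k = (t_{k+1} - t_k) * 1000``; ``hr_k = 6e4 / ibi_k``.
    """
    if isinstance(series, BeatSeries):
        sp_times = series.sp_times
    else:
        sp_times = np.asarray(series, dtype=float)
    ibi = np.diff(sp_times) * 1000.0
    return ibi, 6.0e4 / ibi
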