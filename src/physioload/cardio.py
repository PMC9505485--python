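"""Heart-rate and blood-pressure variability features from 30 s beat series.

Time-domain HRV: mean/SD of IBI, mean/SD of HR, and

    RMSSD = sqrt( 1/(M-1) * sum_t (IBI_{t+1} - IBI_t)^2 ),

with M the number of interbeat intervals. Time-domain BPV (computed for
both systolic and diastolic series): sample SD, successive variation
SV = sqrt(mean of squared successive differences), coefficient of variation
CV = SD / mean * 100, and average real variability ARV = mean absolute
successive difference.

Frequency-domain features for both: the beat-indexed series is cubic-spline
interpolated onto a uniform 4 Hz grid, mean-removed, and its one-sided FFT
power spectrum summed over VLF (0, 0.04), LF [0.04, 0.15) and
HF [0.15, 0.4) Hz. Normalized units: LFnu = LF/(LF+HF)*100 and
HFnu = HF/(LF+HF)*100. With a 30 s window the VLF band resolves at most one
FFT bin; this resolution caveat is recorded in the feature metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .abp import BeatSeries
from .core import InsufficientDataError

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

HRV_COLUMNS = ("hrv_mean_ibi_ms", "hrv_sd_ibi_ms", "hrv_mean_hr_bpm",
               "hrv_sd_hr_bpm", "hrv_rmssd_ms", "hrv_vlf_ms2", "hrv_lf_ms2",
               "hrv_hf_ms2", "hrv_tp_ms2", "hrv_lfnu_pct", "hrv_hfnu_pct")
BPV_COLUMNS = tuple(
    f"bpv_{which}_{name}"
    for which in ("sp", "dp")
    for name in ("sd_mmHg", "sv_mmHg", "cv_pct", "arv_mmHg", "vlf_mmHg2",
                 "lf_mmHg2", "hf_mmHg2", "tp_mmHg2", "lfnu_pct", "hfnu_pct")
)


@dataclass
class VariabilityBands:
    vlf: float
    lf: float
    hf: float

    @property
    def tp(self) -> float:
        return self.vlf + self.lf + self.hf

    @property
    def lfnu(self) -> float:
        denom = self.lf + self.hf
        return 100.0 * self.lf / denom if denom > 0 else 0.0

    @property
    def hfnu(self) -> float:
        # complement of LFnu so the two normalized units sum to 100 exactly
        return 100.0 - self.lfnu if (self.lf + self.hf) > 0 else 0.0


def hrv_time(ibi_ms: np.ndarray) -> dict[str, float]:
    """Time-domain HRV features from an IBI sequence (ms). Needs >= 2 IBIs."""
    ibi = np.asarray(ibi_ms, dtype=float)
    if ibi.size < 2:
        raise InsufficientDataError("time-domain HRV requires at least 2 IBIs")
    hr = 6.0e4 / ibi
    d = np.diff(ibi)
    return {
        "hrv_mean_ibi_ms": float(ibi.mean()),
        "hrv_sd_ibi_ms": float(ibi.std(ddof=1)),
        "hrv_mean_hr_bpm": float(hr.mean()),
        "hrv_sd_hr_bpm": float(hr.std(ddof=1)),
        "hrv_rmssd_ms": float(np.sqrt(np.mean(d * d))),
    }


def variability_spectrum(times_s: np.ndarray, values: np.ndarray,
                         resample_hz: float = 4.0) -> VariabilityBands:
    """Band powers of a beat-indexed series (IBI in ms or pressure in mmHg).

    Cubic-spline interpolation onto a uniform ``resample_hz`` grid spanning
    the event times, mean removal, then one-sided FFT power with bins summed
    per band. The returned powers carry the squared units of ``values``.

    Raises
    ------
    InsufficientDataError
        If fewer than 4 events or a span shorter than 10 s is supplied.
    """
    times = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise InsufficientDataError("spectral estimation requires >= 4 events")
    span = times[-1] - times[0]
    if span < 10.0:
        raise InsufficientDataError("spectral estimation requires a span >= 10 s")
    n = int(np.floor(span * resample_hz)) + 1
    grid = times[0] + np.arange(n) / resample_hz
    series = CubicSpline(times, values)(grid)
    series = series - series.mean()
    spec = np.fft.rfft(series)
    freqs = np.fft.rfftfreq(n, d=1.0 / resample_hz)
    # one-sided power normalized so the bins sum to the series variance
    power = (np.abs(spec) ** 2) * 2.0 / (n * n)
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not doubled
    power[0] = 0.0
    bands = []
    for lo, hi in (VLF_BAND, LF_BAND, HF_BAND):
        mask = (freqs > lo) & (freqs < hi) if lo == 0.0 else (freqs >= lo) & (freqs < hi)
        bands.append(float(power[mask].sum()))
    return VariabilityBands(*bands)


def bpv_time(values: np.ndarray) -> dict[str, float]:
    """Time-domain variability of a pressure series (SD, SV, CV, ARV)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("time-domain BPV requires at least 2 values")
    d = np.diff(x)
    sd = float(x.std(ddof=1))
    return {
        "sd_mmHg": sd,
        "sv_mmHg": float(np.sqrt(np.mean(d * d))),
        "cv_pct": 100.0 * sd / float(x.mean()),
        "arv_mmHg": float(np.mean(np.abs(d))),
    }


def _bands_dict(prefix: str, bands: VariabilityBands, unit: str) -> dict[str, float]:
    return {
        f"{prefix}vlf_{unit}": bands.vlf,
        f"{prefix}lf_{unit}": bands.lf,
        f"{prefix}hf_{unit}": bands.hf,
        f"{prefix}tp_{unit}": bands.tp,
        f"{prefix}lfnu_pct": bands.lfnu,
        f"{prefix}hfnu_pct": bands.hfnu,
    }


def hrv_bpv_features(beats: BeatSeries, window: tuple[float, float] | None = None
                     ) -> tuple[dict[str, float], dict[str, float]]:
    """All HRV (11) and BPV (20) features from beats inside a time window.

    ``window`` is a half-open ``(start, end)`` interval in seconds; ``None``
    uses every beat. IBIs are indexed at the time of their closing systolic
    point for spectral interpolation.
    """
    sp_t, sp_v = beats.sp_times, beats.sp_values
    dp_t, dp_v = beats.dp_times, beats.dp_values
    if window is not None:
        lo, hi = window
        keep_sp = (sp_t >= lo) & (sp_t < hi)
        keep_dp = (dp_t >= lo) & (dp_t < hi)
        sp_t, sp_v = sp_t[keep_sp], sp_v[keep_sp]
        dp_t, dp_v = dp_t[keep_dp], dp_v[keep_dp]
    if sp_t.size < 5:
        raise InsufficientDataError(
            f"only {sp_t.size} systolic points in window; need >= 5")
    ibi = np.diff(sp_t) * 1000.0

    hrv = hrv_time(ibi)
    hrv.update(_bands_dict("hrv_", variability_spectrum(sp_t[1:], ibi), "ms2"))

    bpv: dict[str, float] = {}
    for which, t_b, v_b in (("sp", sp_t, sp_v), ("dp", dp_t, dp_v)):
        td = bpv_time(v_b)
        bpv.update({f"bpv_{which}_{k}": v for k, v in td.items()})
        bpv.update(_bands_dict(f"bpv_{which}_", variability_spectrum(t_b, v_b),
                               "mmHg2"))
    return hrv, bpv
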