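"""Synthetic pupil, gaze, EEG and arterial-blood-pressure generator.

Each generator emits a :class:`~physioload.core.SignalTrace` together with a
:class:`GroundTruth` record (true beat times, blink intervals, fixation
layout, per-band powers, programmed dilation) rich enough to score every
detector in the package. All draws flow through a caller-supplied
``numpy.random.Generator``, so a dataset is fully determined by (seed, spec).

The default parameters encode the study conditions the analysis assumes:

* trial-mean pupil dilation (percentage change from a 1 s pre-onset
  baseline) distributed per level as (0.24, 6.08), (5.75, 7.36),
  (8.85, 6.71) percent (mean, SD);
* pulsatile arterial pressure around 120/80 mmHg with configurable heart
  rate, interbeat-interval SD, and 0.1 Hz / 0.25 Hz sinusoidal modulation of
  the interbeat intervals;
* 8-channel EEG as 1/f background plus band-limited oscillations whose
  alpha/beta amplitudes are elevated for levels 1-2, plus shared
  frontal-dominant blink spikes (rank-1 across channels);
* gaze as piecewise-constant fixations whose number rises and whose dwell
  time falls with workload level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventSchedule, SignalTrace, EEG_CHANNELS, SOA_SET

# ---------------------------------------------------------------------------
# Specs


@dataclass
class PupilSpec:
    rate: float = 200.0  # Hz per eye (binocular camera)
    baseline_mean_mm: float = 4.0
    baseline_sd_mm: float = 0.5
    # trial-mean percentage change in pupil size per level: (mean %, SD %)
    dilation_pct: dict = field(
        default_factory=lambda: {0: (0.24, 6.08), 1: (5.75, 7.36), 2: (8.85, 6.71)}
    )
    blink_rate_per_min: float = 8.0
    blink_dur_s: float = 0.15
    blink_floor_mm: float = 0.3
    noise_sd_mm: float = 0.02
    baseline_s: float = 1.0
    window_s: float = 2.5
    onset_ramp_s: float = 0.2


@dataclass
class AbpSpec:
    rate: float = 20.0  # Hz, fingertip plethysmography
    # mean heart rate does not separate the levels; the variability measures
    # (IBI SD, LF modulation, diastolic SD) shift mildly between rest and
    # task levels — subtle enough that these modalities remain far weaker
    # workload markers than the pupil
    hr_bpm: dict = field(default_factory=lambda: {0: 72.0, 1: 72.0, 2: 72.0})
    sd_ibi_ms: dict = field(default_factory=lambda: {0: 40.0, 1: 42.5, 2: 43.0})
    sp_mmHg: float = 120.0
    dp_mmHg: float = 80.0
    sd_sp_mmHg: dict = field(default_factory=lambda: {0: 4.0, 1: 4.15, 2: 4.15})
    sd_dp_mmHg: dict = field(default_factory=lambda: {0: 2.5, 1: 2.7, 2: 2.8})
    # fractional IBI modulation amplitudes at 0.1 Hz (LF) and 0.25 Hz (HF)
    lf_amp: dict = field(default_factory=lambda: {0: 0.015, 1: 0.018, 2: 0.018})
    hf_amp: dict = field(default_factory=lambda: {0: 0.025, 1: 0.025, 2: 0.025})
    peak_frac: float = 0.30  # systolic latency as a fraction of the mean IBI
    decay_tau: float = 0.25  # diastolic decay constant, decay-phase fractions


@dataclass
class EegSpec:
    rate: float = 500.0
    window_s: float = 2.5
    noise_uV: float = 4.0  # RMS of the 1/f background
    # oscillation amplitude (µV) per band per level; alpha/beta mildly
    # elevated for levels 1-2, theta flat, delta shifted between 1 and 2 —
    # weak effects, as band powers are a noisy workload marker
    band_amp_uV: dict = field(
        default_factory=lambda: {
            "delta": (4.0, 4.0, 4.2),
            "theta": (3.0, 3.0, 3.0),
            "alpha": (5.0, 5.5, 5.6),
            "beta": (2.0, 2.3, 2.35),
        }
    )
    # per-trial lognormal factor on each band's amplitude (band power in
    # real EEG fluctuates by factors between trials, not by percent)
    amp_trial_sigma: float = 0.35
    blink_rate_per_min: float = 8.0
    blink_amp_uV: float = 150.0
    blink_dur_s: float = 0.2
    # rank-1 spatial pattern, frontal (FC*) dominant
    blink_weights: tuple = (1.0, 1.0, 0.9, 0.9, 0.25, 0.25, 0.2, 0.2)


@dataclass
class GazeSpec:
    rate: float = 200.0
    window_s: float = 2.5
    dwell_mean_s: dict = field(default_factory=lambda: {0: 0.34, 1: 0.31, 2: 0.24})
    dwell_jitter: float = 0.25  # lognormal sigma on the per-trial mean dwell
    dwell_min_s: float = 0.12
    saccade_min: float = 0.05  # minimum fixation-center jump, screen units
    tremor_sd: float = 0.001


@dataclass
class GeneratorSpec:
    """Study-level configuration; the per-modality specs carry the physics."""

    seed: int = 0
    n_trials_per_level: int = 116
    pupil: PupilSpec = field(default_factory=PupilSpec)
    abp: AbpSpec = field(default_factory=AbpSpec)
    eeg: EegSpec = field(default_factory=EegSpec)
    gaze: GazeSpec = field(default_factory=GazeSpec)
    abp_window_s: float = 30.0
    soa_set: tuple = SOA_SET
    trial_spacing_s: float = 35.0


@dataclass
class GroundTruth:
    """Generator-side truth used to score detectors."""

    level: int = -1
    dilation_pct: float | None = None
    baseline_mm: float | None = None
    blink_intervals: list = field(default_factory=list)
    beat_times: np.ndarray | None = None  # true systolic instants, s
    true_ibi_ms: np.ndarray | None = None
    sp_values: np.ndarray | None = None
    dp_values: np.ndarray | None = None
    dp_times: np.ndarray | None = None
    band_power_true: np.ndarray | None = None  # (channels, bands), µV²
    fixation_count: int | None = None
    fixation_durations: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pupil


def gen_pupil_trial(spec: GeneratorSpec, level: int, rng: np.random.Generator
                    ) -> tuple[SignalTrace, GroundTruth]:
    """One pupil-diameter trial: 1 s pre-onset baseline + 2.5 s post-onset.

    The post-onset diameter is ``baseline * (1 + d/100 * g(t))`` where the
    trial dilation ``d`` is drawn from the level's (mean, SD) and ``g`` is a
    raised-cosine onset ramp normalized to unit mean over the window, so the
    noise-free trial-mean percentage change equals ``d`` exactly. Blinks are
    inserted as short dips below 0.8 mm at the configured rate.
    """
    if level not in spec.pupil.dilation_pct:
        raise ValueError(f"unknown level {level}")
    ps = spec.pupil
    baseline = float(np.clip(rng.normal(ps.baseline_mean_mm, ps.baseline_sd_mm), 2.0, 8.0))
    mean_d, sd_d = ps.dilation_pct[level]
    d = float(rng.normal(mean_d, sd_d))

    n_pre = int(round(ps.baseline_s * ps.rate))
    n_post = int(round(ps.window_s * ps.rate))
    t_post = np.arange(n_post) / ps.rate
    ramp = np.minimum(t_post / ps.onset_ramp_s, 1.0)
    g = 0.5 * (1 - np.cos(np.pi * ramp))
    g = g / g.mean()  # unit mean -> trial-mean PCPS == d

    diam = np.concatenate([np.full(n_pre, baseline), baseline * (1 + d / 100.0 * g)])
    diam = diam + rng.normal(0.0, ps.noise_sd_mm, size=diam.size)

    total_s = ps.baseline_s + ps.window_s
    n_blinks = rng.poisson(ps.blink_rate_per_min * total_s / 60.0)
    blink_intervals = []
    t = np.arange(diam.size) / ps.rate - ps.baseline_s
    for _ in range(n_blinks):
        start = rng.uniform(-ps.baseline_s, ps.window_s - ps.blink_dur_s)
        end = start + ps.blink_dur_s
        mask = (t >= start) & (t < end)
        if not mask.any():
            continue
        u = (t[mask] - start) / ps.blink_dur_s
        dip = 0.5 * (1 - np.cos(2 * np.pi * u))  # 0 -> 1 -> 0
        diam[mask] = diam[mask] * (1 - dip) + ps.blink_floor_mm * dip
        blink_intervals.append((float(start), float(end)))

    trace = SignalTrace(diam[None, :], rate=ps.rate, t0=-ps.baseline_s,
                        channel_labels=("pupil_left",), units="mm")
    truth = GroundTruth(level=level, dilation_pct=d, baseline_mm=baseline,
                        blink_intervals=sorted(blink_intervals))
    return trace, truth


# ---------------------------------------------------------------------------
# Arterial blood pressure


def gen_abp_trace(spec: GeneratorSpec, level: int, duration_s: float,
                  rng: np.random.Generator) -> tuple[SignalTrace, GroundTruth]:
    """A pulsatile arterial-pressure trace at 20 Hz with known SP/DP points.

    Beat boundaries follow an interbeat-interval process with the configured
    mean and SD plus sinusoidal LF (0.1 Hz) and HF (0.25 Hz) modulation; per
    beat the waveform is a raised-cosine upstroke to the systolic peak
    followed by an exponential diastolic decay. Per-beat systolic/diastolic
    values and instants are recorded as ground truth; SP - DP >= 20 mmHg by
    construction.
    """
    if duration_s < 10:
        raise ValueError("ABP generation requires duration >= 10 s")
    ab = spec.abp
    mean_ibi = 60.0 / ab.hr_bpm[level]
    sd_ibi = ab.sd_ibi_ms[level] / 1000.0
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, size=2)

    # beat boundaries; the first beat starts before t=0 so the trace opens
    # mid-beat at a random phase
    onsets = [float(rng.uniform(0, mean_ibi)) - mean_ibi]
    ibis = []
    while onsets[-1] < duration_s:
        t = onsets[-1]
        mod = (1.0 + ab.lf_amp[level] * np.sin(2 * np.pi * 0.1 * t + phi_lf)
               + ab.hf_amp[level] * np.sin(2 * np.pi * 0.25 * t + phi_hf))
        ibi = mean_ibi * mod + rng.normal(0.0, sd_ibi)
        ibi = float(np.clip(ibi, 0.52, 1.95))  # keep within the 30-120 bpm gate
        ibis.append(ibi)
        onsets.append(t + ibi)
    onsets = np.asarray(onsets)
    ibis = np.asarray(ibis)
    n_beats = len(ibis)

    sp = rng.normal(ab.sp_mmHg, ab.sd_sp_mmHg[level], size=n_beats)
    dp = rng.normal(ab.dp_mmHg, ab.sd_dp_mmHg[level], size=n_beats)
    dp = np.minimum(dp, sp - 20.0)

    # the systolic peak sits at a fixed latency after the beat onset, so the
    # SP-to-SP intervals reproduce the programmed IBI process exactly
    tpk = np.minimum(ab.peak_frac * mean_ibi, 0.6 * ibis)

    n = int(round(duration_s * ab.rate))
    t_samp = np.arange(n) / ab.rate
    beat_idx = np.clip(np.searchsorted(onsets, t_samp, side="right") - 1, 0, n_beats - 1)
    t_rel = np.clip(t_samp - onsets[beat_idx], 0.0, ibis[beat_idx])
    shape = _pulse_shape(t_rel, tpk[beat_idx], ibis[beat_idx], ab.decay_tau)
    pressure = dp[beat_idx] + (sp[beat_idx] - dp[beat_idx]) * shape

    sp_times = onsets[:-1] + tpk
    keep = (sp_times >= 0.0) & (sp_times < duration_s)
    trace = SignalTrace(pressure[None, :], rate=ab.rate, t0=0.0,
                        channel_labels=("abp",), units="mmHg")
    truth = GroundTruth(
        level=level,
        beat_times=sp_times[keep],
        true_ibi_ms=np.diff(sp_times[keep]) * 1000.0,
        sp_values=sp[keep],
        dp_values=dp[keep],
        dp_times=onsets[:-1][keep],
    )
    return trace, truth


def _pulse_shape(t_rel: np.ndarray, tpk: np.ndarray, ibi: np.ndarray,
                 tau: float) -> np.ndarray:
    """Normalized beat waveform: 0 at the onset and end, 1 at the systolic peak.

    Raised-cosine upstroke over ``[0, tpk)`` then an exponential diastolic
    decay over ``[tpk, ibi)``, rescaled to reach 0 at the beat end so that
    consecutive beats join continuously at their diastolic values.
    """
    s = np.empty_like(t_rel)
    rising = t_rel < tpk
    s[rising] = 0.5 * (1 - np.cos(np.pi * t_rel[rising] / tpk[rising]))
    dec = ~rising
    v = (t_rel[dec] - tpk[dec]) / (ibi[dec] - tpk[dec])  # decay phase in [0, 1]
    decay_end = np.exp(-1.0 / tau)
    s[dec] = (np.exp(-v / tau) - decay_end) / (1 - decay_end)
    return s


# ---------------------------------------------------------------------------
# EEG

_BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def gen_eeg_trial(spec: GeneratorSpec, level: int, rng: np.random.Generator
                  ) -> tuple[SignalTrace, GroundTruth]:
    """One 8-channel, 2.5 s EEG trial at 500 Hz.

    Signal = 1/f background + per-band sinusoid mixtures (amplitudes scaled
    per level) + shared blink spikes with a rank-1 frontal-dominant spatial
    pattern (there for the ICA stage to find). True per-band oscillation
    powers (sum of a^2/2 per channel) are recorded.
    """
    es = spec.eeg
    n = int(round(es.window_s * es.rate))
    n_ch = len(EEG_CHANNELS)
    t = np.arange(n) / es.rate

    x = _pink_noise((n_ch, n), rng) * es.noise_uV
    band_names = list(_BAND_EDGES)
    power_true = np.zeros((n_ch, len(band_names)))
    # oscillations are shared sources mixed into channels (volume conduction):
    # per band two tone sources, each with its own channel-weight vector
    for bi, band in enumerate(band_names):
        lo, hi = _BAND_EDGES[band]
        amp_level = es.band_amp_uV[band][level]
        if amp_level == 0:
            continue
        amp_level = amp_level * float(np.exp(rng.normal(0.0, es.amp_trial_sigma)))
        for _ in range(2):  # two tone sources per band
            # tone frequencies sit on the trial's frequency grid so the
            # recorded per-band powers are exact (no spectral leakage)
            df = 1.0 / es.window_s
            k_lo = int(np.ceil((lo + df) / df))
            k_hi = int(np.floor((hi - df) / df))
            f = df * int(rng.integers(k_lo, k_hi + 1))
            phase = rng.uniform(0, 2 * np.pi)
            tone = np.sin(2 * np.pi * f * t + phase)
            w = amp_level * rng.uniform(0.8, 1.2, size=n_ch) / np.sqrt(2)
            x += w[:, None] * tone[None, :]
            power_true[:, bi] += w * w / 2.0
    blink_intervals = []
    n_blinks = rng.poisson(es.blink_rate_per_min * es.window_s / 60.0)
    w = np.asarray(es.blink_weights)
    for _ in range(n_blinks):
        start = rng.uniform(0, es.window_s - es.blink_dur_s)
        mask = (t >= start) & (t < start + es.blink_dur_s)
        u = (t[mask] - start) / es.blink_dur_s
        waveform = es.blink_amp_uV * np.sin(np.pi * u) ** 2
        x[:, mask] += w[:, None] * waveform[None, :]
        blink_intervals.append((float(start), float(start + es.blink_dur_s)))

    trace = SignalTrace(x, rate=es.rate, t0=0.0, channel_labels=EEG_CHANNELS, units="uV")
    truth = GroundTruth(level=level, band_power_true=power_true,
                        blink_intervals=sorted(blink_intervals))
    return trace, truth


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-power background noise, independent per channel."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


# ---------------------------------------------------------------------------
# Gaze


def gen_gaze_trace(spec: GeneratorSpec, level: int, rng: np.random.Generator,
                   dwell_times: list[float] | None = None
                   ) -> tuple[SignalTrace, GroundTruth]:
    """2-D gaze as piecewise-constant fixations + saccadic jumps + tremor.

    ``dwell_times`` overrides the level-dependent random dwell draws with a
    programmed fixation layout (used by recovery tests). Fixations truncated
    by the window edge are counted only if their realized duration reaches
    100 ms, matching the detector's default minimum duration.
    """
    gs = spec.gaze
    n = int(round(gs.window_s * gs.rate))
    t = np.arange(n) / gs.rate

    if dwell_times is None:
        dwells = []
        total = 0.0
        # per-trial variation around the level's mean dwell (attention state
        # fluctuates between trials)
        mean_dwell = gs.dwell_mean_s[level] * float(
            np.exp(rng.normal(0.0, gs.dwell_jitter)))
        mean_dwell = max(mean_dwell, gs.dwell_min_s * 1.05)
        while total < gs.window_s:
            dwell = max(rng.exponential(mean_dwell - gs.dwell_min_s) + gs.dwell_min_s,
                        gs.dwell_min_s)
            dwells.append(dwell)
            total += dwell
    else:
        dwells = list(dwell_times)

    x = np.zeros(n)
    y = np.zeros(n)
    cx, cy = rng.uniform(0.2, 0.8, size=2)
    pos = 0.0
    realized: list[float] = []
    for dwell in dwells:
        mask = (t >= pos) & (t < pos + dwell)
        x[mask] = cx
        y[mask] = cy
        realized_dur = min(pos + dwell, gs.window_s) - pos
        if realized_dur > 0:
            realized.append(realized_dur)
        pos += dwell
        if pos >= gs.window_s:
            break
        # saccade: jump at least saccade_min in each coordinate
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(gs.saccade_min * 2, 0.2)
        cx = float(np.clip(cx + r * np.cos(ang), 0.05, 0.95))
        cy = float(np.clip(cy + r * np.sin(ang), 0.05, 0.95))
    x += rng.normal(0, gs.tremor_sd, size=n)
    y += rng.normal(0, gs.tremor_sd, size=n)

    counted = [d for d in realized if d >= 0.1]
    trace = SignalTrace(np.vstack([x, y]), rate=gs.rate, t0=0.0,
                        channel_labels=("gaze_x", "gaze_y"), units="screen")
    truth = GroundTruth(level=level, fixation_count=len(counted),
                        fixation_durations=counted)
    return trace, truth


# ---------------------------------------------------------------------------
# Full study


@dataclass
class Trial:
    level: int
    soa: float  # NaN for levels 0/1
    pupil: SignalTrace
    gaze: SignalTrace
    eeg: SignalTrace
    abp: SignalTrace
    truth: dict  # modality -> GroundTruth


@dataclass
class StudyDataset:
    trials: list[Trial]
    schedule: EventSchedule

    def __len__(self) -> int:
        return len(self.trials)


def gen_study_dataset(spec: GeneratorSpec) -> StudyDataset:
    """Generate the full multimodal study: n trials per level, all modalities.

    Level-2 trials draw their SOA uniformly from ``spec.soa_set``. The whole
    dataset is deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.repeat([0, 1, 2], spec.n_trials_per_level)
    trials = []
    onsets = []
    soas = []
    for i, level in enumerate(levels):
        level = int(level)
        soa = float(rng.choice(spec.soa_set)) if level == 2 else float("nan")
        pupil, tr_p = gen_pupil_trial(spec, level, rng)
        gaze, tr_g = gen_gaze_trace(spec, level, rng)
        eeg, tr_e = gen_eeg_trial(spec, level, rng)
        abp, tr_a = gen_abp_trace(spec, level, spec.abp_window_s, rng)
        trials.append(Trial(level=level, soa=soa, pupil=pupil, gaze=gaze,
                            eeg=eeg, abp=abp,
                            truth={"pupil": tr_p, "gaze": tr_g,
                                   "eeg": tr_e, "abp": tr_a}))
        onsets.append(i * spec.trial_spacing_s)
        soas.append(soa)
    schedule = EventSchedule(onsets=np.asarray(onsets), levels=levels,
                             soa=np.asarray(soas))
    return StudyDataset(trials=trials, schedule=schedule)
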