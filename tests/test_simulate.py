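import numpy as np
import pytest

from physioload import GeneratorSpec, gen_study_dataset
from physioload.simulate import (gen_abp_trace, gen_eeg_trial, gen_gaze_trace,
                                 gen_pupil_trial)


def test_pupil_trial_shape_and_rate(spec, rng):
    trace, truth = gen_pupil_trial(spec, 1, rng)
    assert trace.rate == 200.0
    assert trace.n_samples == 700  # 1 s baseline + 2.5 s window
    assert trace.t0 == -1.0
    assert truth.level == 1


def test_pupil_level0_mean_matches_configured_dilation(spec):
    # trial-mean PCPS over many trials should sit within 3 SE of the
    # configured level-0 mean (0.24 %)
    rng = np.random.default_rng(7)
    means = []
    for _ in range(1000):
        trace, truth = gen_pupil_trial(spec, 0, rng)
        x = trace.values[0]
        base = x[:200].mean()
        means.append((x[200:] - base).mean() / base * 100.0)
    mean, sd = spec.pupil.dilation_pct[0]
    se = sd / np.sqrt(len(means))
    assert abs(np.mean(means) - mean) < 3 * se


def test_pupil_zero_dilation_sd_gives_exact_trial_mean(spec, rng):
    spec.pupil.dilation_pct[1] = (10.0, 0.0)
    spec.pupil.blink_rate_per_min = 0.0
    spec.pupil.noise_sd_mm = 0.0
    trace, truth = gen_pupil_trial(spec, 1, rng)
    x = trace.values[0]
    base = x[:200].mean()
    trial_mean = (x[200:] - base).mean() / base * 100.0
    assert trial_mean == pytest.approx(10.0, abs=1e-9)


def test_pupil_no_blinks_means_no_subthreshold_samples(spec, rng):
    spec.pupil.blink_rate_per_min = 0.0
    for level in (0, 1, 2):
        trace, _ = gen_pupil_trial(spec, level, rng)
        assert trace.values.min() >= 0.8


def test_pupil_blinks_dip_below_threshold(spec):
    spec.pupil.blink_rate_per_min = 60.0
    rng = np.random.default_rng(3)
    trace, truth = gen_pupil_trial(spec, 0, rng)
    assert truth.blink_intervals
    assert trace.values.min() < 0.8


def test_abp_beat_count_at_fixed_rate(spec):
    spec.abp.hr_bpm[0] = 60.0
    spec.abp.sd_ibi_ms[0] = 0.0
    spec.abp.lf_amp[0] = 0.0
    spec.abp.hf_amp[0] = 0.0
    rng = np.random.default_rng(2)
    trace, truth = gen_abp_trace(spec, 0, 30.0, rng)
    assert trace.rate == 20.0
    assert len(truth.beat_times) in (30, 31)
    np.testing.assert_allclose(truth.true_ibi_ms, 1000.0, atol=1e-6)


def test_abp_sdibi_recovers_configured_value(spec):
    spec.abp.sd_ibi_ms[0] = 50.0
    spec.abp.lf_amp[0] = 0.0
    spec.abp.hf_amp[0] = 0.0
    rng = np.random.default_rng(5)
    _, truth = gen_abp_trace(spec, 0, 600.0, rng)
    sd = np.std(truth.true_ibi_ms, ddof=1)
    assert abs(sd - 50.0) / 50.0 < 0.10


def test_abp_short_duration_rejected(spec, rng):
    with pytest.raises(ValueError):
        gen_abp_trace(spec, 0, 5.0, rng)


def test_abp_pulse_amplitude_floor(spec, rng):
    _, truth = gen_abp_trace(spec, 2, 60.0, rng)
    assert np.all(truth.sp_values - truth.dp_values >= 20.0)


def test_eeg_alpha_only_concentrates_power(spec, rng):
    for band in spec.eeg.band_amp_uV:
        spec.eeg.band_amp_uV[band] = (0.0, 0.0, 0.0)
    spec.eeg.band_amp_uV["alpha"] = (1.0, 1.0, 1.0)
    spec.eeg.noise_uV = 0.0
    spec.eeg.blink_rate_per_min = 0.0
    trace, truth = gen_eeg_trial(spec, 0, rng)
    # Parseval: nearly all 1-30 Hz power should be in 8-12 Hz
    from physioload.eeg import psd_feature_vector

    bp = psd_feature_vector(trace)
    assert (bp.power[:, 2] / bp.power.sum(axis=1)).min() > 0.99
    assert truth.band_power_true[:, [0, 1, 3]].sum() == 0.0


def test_eeg_no_blinks_keeps_amplitude_bounded(spec, rng):
    spec.eeg.blink_rate_per_min = 0.0
    trace, _ = gen_eeg_trial(spec, 1, rng)
    envelope = sum(2 * np.sqrt(2) * a[1] for a in spec.eeg.band_amp_uV.values())
    assert np.abs(trace.values).max() < 5 * (envelope + spec.eeg.noise_uV)


def test_eeg_deterministic_under_seed(spec):
    a, _ = gen_eeg_trial(spec, 2, np.random.default_rng(11))
    b, _ = gen_eeg_trial(spec, 2, np.random.default_rng(11))
    np.testing.assert_array_equal(a.values, b.values)


def test_gaze_programmed_fixations(spec, rng):
    trace, truth = gen_gaze_trace(spec, 0, rng, dwell_times=[0.5, 0.5, 0.5])
    assert truth.fixation_count == 3
    assert trace.n_channels == 2


def test_gaze_single_dwell_spans_window(spec, rng):
    _, truth = gen_gaze_trace(spec, 0, rng, dwell_times=[2.5])
    assert truth.fixation_count == 1
    assert truth.fixation_durations == [2.5]


def test_study_dataset_counts_and_determinism():
    spec = GeneratorSpec(seed=99, n_trials_per_level=4)
    ds = gen_study_dataset(spec)
    assert len(ds) == 12
    levels, counts = np.unique(ds.schedule.levels, return_counts=True)
    assert counts.tolist() == [4, 4, 4]
    lvl2 = ds.schedule.levels == 2
    assert np.all(np.isin(ds.schedule.soa[lvl2], [0.0, 0.5, 1.0]))
    assert np.all(np.isnan(ds.schedule.soa[~lvl2]))

    ds2 = gen_study_dataset(GeneratorSpec(seed=99, n_trials_per_level=4))
    for t1, t2 in zip(ds.trials, ds2.trials):
        np.testing.assert_array_equal(t1.pupil.values, t2.pupil.values)
        np.testing.assert_array_equal(t1.eeg.values, t2.eeg.values)
        np.testing.assert_array_equal(t1.abp.values, t2.abp.values)


def test_study_dataset_empty():
    ds = gen_study_dataset(GeneratorSpec(seed=1, n_trials_per_level=0))
    assert len(ds) == 0
    assert len(ds.schedule) == 0
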