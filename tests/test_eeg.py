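import numpy as np
import pytest
from scipy import signal as sg

from physioload.core import EEG_CHANNELS, SignalTrace
from physioload.eeg import (kalman_smooth, preprocess_eeg, psd_feature_vector,
                            total_power, welch_band_power)
from physioload.simulate import GeneratorSpec, gen_eeg_trial


def _eeg(values, rate=500.0):
    values = np.atleast_2d(values)
    if values.shape[0] == 1:
        labels = ("FC1",)
    else:
        labels = EEG_CHANNELS[: values.shape[0]]
    return SignalTrace(values, rate=rate, channel_labels=labels, units="uV")


def test_chain_passes_in_band_content():
    t = np.arange(1250) / 500.0
    rng = np.random.default_rng(0)
    clean = np.tile(10 * np.sin(2 * np.pi * 10 * t), (8, 1))
    x = clean + rng.normal(0, 0.5, clean.shape)
    trace = SignalTrace(x, 500.0, channel_labels=EEG_CHANNELS, units="uV")
    out, info = preprocess_eeg(trace)
    # the chain must preserve the 10 Hz oscillation (it may well remove the
    # broadband noise, so correlate against the in-band component); the
    # 0.1 Hz high-pass edge settles over ~10 s, so judge the central region
    c = slice(250, -250)
    for ch in range(8):
        assert np.corrcoef(out.values[ch, c], clean[ch, c])[0, 1] > 0.99


def test_blink_spikes_suppressed():
    spec = GeneratorSpec()
    spec.eeg.blink_rate_per_min = 20.0  # most trials then carry a blink
    suppressed = 0
    checked = 0
    for seed in range(12):
        rng = np.random.default_rng(seed)
        trace, truth = gen_eeg_trial(spec, 1, rng)
        if not truth.blink_intervals:
            continue
        checked += 1
        clean, info = preprocess_eeg(trace, smooth=False)
        if info.ica_skipped:
            continue
        t = trace.times()
        mask = np.zeros(trace.n_samples, bool)
        for a, b in truth.blink_intervals:
            mask |= (t >= a) & (t < b)
        pre = np.abs(trace.values[:, mask]).max()
        post = np.abs(clean.values[:, mask]).max()
        if post < 0.25 * pre:
            suppressed += 1
    assert checked >= 2
    assert suppressed == checked  # every converged run cleans the spikes


def test_50hz_contamination_attenuated():
    t = np.arange(2500) / 500.0
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, (8, t.size))
    tone = 10 * np.sin(2 * np.pi * 50 * t)
    trace = SignalTrace(base + tone, 500.0, channel_labels=EEG_CHANNELS,
                        units="uV")
    out, _ = preprocess_eeg(trace, remove_blinks=False, smooth=False)
    # measure the 50 Hz component via its FFT bin (50 Hz is exactly on-bin)
    bin50 = 250
    before = np.abs(np.fft.rfft(trace.values[0]))[bin50]
    after = np.abs(np.fft.rfft(out.values[0]))[bin50]
    assert 20 * np.log10(after / before) < -40.0


def test_welch_sine_power_lands_in_alpha():
    t = np.arange(5000) / 500.0
    trace = _eeg(np.sin(2 * np.pi * 10 * t))
    bp = welch_band_power(trace)
    assert bp.power[0, 2] / bp.power[0].sum() > 0.99


def test_welch_zero_signal_zero_power():
    bp = welch_band_power(_eeg(np.zeros(4000)))
    np.testing.assert_array_equal(bp.power, 0.0)


def test_welch_too_short_raises():
    with pytest.raises(ValueError):
        welch_band_power(_eeg(np.zeros(500)))  # < one 2 s segment


def test_band_additivity():
    rng = np.random.default_rng(2)
    trace = _eeg(rng.standard_normal((8, 1250)))
    bp = psd_feature_vector(trace)
    freqs, psd = sg.periodogram(trace.values, fs=500.0, window="boxcar",
                                detrend="constant", scaling="density", axis=1)
    mask = (freqs >= 1.0) & (freqs <= 30.0)
    full = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    np.testing.assert_allclose(bp.power.sum(axis=1), full, rtol=1e-6)


def test_parseval_total_power_matches_variance():
    rng = np.random.default_rng(3)
    trace = _eeg(rng.standard_normal((2, 2000)))
    tp = total_power(trace)
    var = trace.values.var(axis=1)
    np.testing.assert_allclose(tp, var, rtol=0.01)


def test_psd_feature_vector_is_32d():
    rng = np.random.default_rng(4)
    trace = SignalTrace(rng.standard_normal((8, 1250)), 500.0,
                        channel_labels=EEG_CHANNELS, units="uV")
    bp = psd_feature_vector(trace)
    assert bp.flattened().shape == (32,)
    assert len(bp.feature_names()) == 32
    assert bp.feature_names()[0] == "psd_FC1_delta"
    assert (bp.flattened() >= 0).all()


def test_ica_leaves_spike_free_signal_unchanged():
    spec = GeneratorSpec()
    spec.eeg.blink_rate_per_min = 0.0
    rng = np.random.default_rng(6)
    trace, _ = gen_eeg_trial(spec, 1, rng)
    clean, info = preprocess_eeg(trace, smooth=False)
    band, _ = preprocess_eeg(trace, remove_blinks=False, smooth=False)
    if not info.ica_skipped:
        for ch in range(8):
            assert np.corrcoef(clean.values[ch], band.values[ch])[0, 1] > 0.99


def test_kalman_smoother_denoises_but_tracks():
    rng = np.random.default_rng(5)
    t = np.arange(1000) / 500.0
    truth = np.cumsum(rng.normal(0, 0.05, t.size))
    y = truth + rng.normal(0, 1.0, t.size)
    s = kalman_smooth(y)
    assert np.mean((s - truth) ** 2) < 0.5 * np.mean((y - truth) ** 2)
    # constant input is a fixed point
    np.testing.assert_array_equal(kalman_smooth(np.full(100, 2.0)),
                                  np.full(100, 2.0))


def test_manual_component_override():
    spec = GeneratorSpec()
    rng = np.random.default_rng(8)
    trace, _ = gen_eeg_trial(spec, 0, rng)
    clean, info = preprocess_eeg(trace, smooth=False, manual_reject=[0])
    if not info.ica_skipped:
        assert info.n_blink_components == 1
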