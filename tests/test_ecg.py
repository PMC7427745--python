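import numpy as np
import pytest

from wearcon import ecg as E


def synth_ecg(hr_bpm=80.0, rr_bpm=18.0, duration_s=120.0, fs=250.0,
              modulation=0.2, noise=0.0, start_s=0.0, rng=None):
    """Constant-rate stylised ECG with respiratory amplitude modulation."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    samples = np.zeros(n)
    if noise > 0:
        samples += (rng or np.random.default_rng(0)).normal(0, noise, n)
    beat_times = np.arange(0.5, duration_s - 0.5, 60.0 / hr_bpm)
    sigma = 0.010
    for bt in beat_times:
        mod = 1.0 + modulation * np.sin(2 * np.pi * rr_bpm / 60.0 * bt)
        for center, amp in ((bt, 1.0 * mod), (bt + 0.040, -0.3 * mod)):
            idx = np.abs(t - center) < 4 * sigma
            samples[idx] += amp * np.exp(-0.5 * ((t[idx] - center) / sigma) ** 2)
    return E.ECGRecord(fs, samples, start_s)


def test_bandpass_removes_dc_offset():
    rec = synth_ecg()
    rec.samples += 5.0  # large DC offset
    out = E.bandpass_filter(rec)
    assert abs(np.mean(out.samples[1000:-1000])) < 0.05


def test_bandpass_is_linear_in_amplitude():
    rec = synth_ecg()
    out1 = E.bandpass_filter(rec)
    rec2 = E.ECGRecord(rec.sampling_rate, 3.0 * rec.samples, rec.start_s)
    out2 = E.bandpass_filter(rec2)
    assert np.allclose(out2.samples, 3.0 * out1.samples, atol=1e-9)


def test_low_sampling_rate_rejected():
    with pytest.raises(E.ECGError):
        E.ECGRecord(50.0, np.zeros(100))


def test_beat_detection_recovers_constant_heart_rate():
    rec = synth_ecg(hr_bpm=90.0, duration_s=60.0)
    beats = E.detect_beats(E.bandpass_filter(rec))
    intervals = np.diff(beats.times)
    assert np.median(60.0 / intervals) == pytest.approx(90.0, abs=1.0)


def test_beat_detection_on_flat_signal_finds_nothing():
    rec = E.ECGRecord(250.0, np.zeros(250 * 30))
    beats = E.detect_beats(rec)
    assert len(beats) == 0


def test_respiration_from_constant_amplitude_has_no_breaths():
    times = np.arange(0.0, 60.0, 0.75)
    beats = E.BeatSeries(times, np.ones_like(times), -0.3 * np.ones_like(times))
    resp = E.derive_respiration(beats)
    assert resp.breath_times.size == 0


def test_respiration_rate_recovered_from_modulated_amplitudes():
    rr_true = 20.0
    times = np.arange(0.0, 120.0, 60.0 / 85.0)
    mod = 1.0 + 0.2 * np.sin(2 * np.pi * rr_true / 60.0 * times)
    beats = E.BeatSeries(times, mod, -0.3 * mod)
    resp = E.derive_respiration(beats)
    rate = 60.0 / np.median(np.diff(resp.breath_times))
    assert rate == pytest.approx(rr_true, abs=1.0)


def test_rate_series_requires_beats():
    with pytest.raises(E.ECGError):
        E.build_rate_series(E.BeatSeries(np.array([]), np.array([]), np.array([])), None)


def test_day_night_windows_split_by_hour_of_day():
    t = np.arange(0.0, 86400.0, 60.0)
    hr = np.where((t / 3600.0 % 24 >= 8) & (t / 3600.0 % 24 < 20), 100.0, 70.0)
    rates = E.RateSeries(t, hr, np.full_like(t, 18.0))
    feats = E.day_night_summaries(rates)
    assert feats["daytime_hr"] == pytest.approx(100.0)
    assert feats["night_hr"] == pytest.approx(70.0)


def test_window_with_mostly_masked_samples_is_nan():
    t = np.arange(8 * 3600.0, 20 * 3600.0, 1.0)
    hr = np.full_like(t, 90.0)
    mask = np.zeros(t.size, dtype=bool)
    mask[: t.size // 4] = True  # only 25% usable
    rates = E.RateSeries(t, hr, np.full_like(t, 18.0), hr_mask=mask,
                         rr_mask=np.ones(t.size, dtype=bool))
    feats = E.day_night_summaries(rates)
    assert np.isnan(feats["daytime_hr"])
    assert np.isfinite(feats["daytime_rr"])


def _decay_series(baseline, peak, tau, bout_start=600.0, bout_end=900.0,
                  total=3000.0):
    t = np.arange(0.0, total, 1.0)
    v = np.full_like(t, baseline)
    rise = (t >= bout_start) & (t <= bout_end)
    v[rise] = peak
    after = t > bout_end
    v[after] = baseline + (peak - baseline) * np.exp(-(t[after] - bout_end) / tau)
    return E.RateSeries(t, v, v.copy()), bout_start, bout_end


def test_recovery_time_tracks_decay_time_constant():
    slow = _decay_series(70.0, 140.0, tau=60.0)
    fast = _decay_series(70.0, 140.0, tau=15.0)
    r_slow = E.recovery_time(slow[0], slow[1], slow[2], "hr")
    r_fast = E.recovery_time(fast[0], fast[1], fast[2], "hr")
    assert r_slow.converged and r_fast.converged
    assert r_slow.recovery_time_s > r_fast.recovery_time_s


def test_recovery_zero_when_no_excursion_above_baseline():
    t = np.arange(0.0, 2000.0, 1.0)
    v = np.full_like(t, 80.0)
    rates = E.RateSeries(t, v, v.copy())
    res = E.recovery_time(rates, 600.0, 900.0, "hr")
    assert res.converged and res.recovery_time_s == 0.0


def test_recovery_unconverged_when_rate_never_returns():
    t = np.arange(0.0, 2000.0, 1.0)
    v = np.where(t < 600.0, 70.0, 140.0)  # steps up and stays up
    rates = E.RateSeries(t, v, v.copy())
    res = E.recovery_time(rates, 600.0, 900.0, "hr")
    assert not res.converged and np.isnan(res.recovery_time_s)


def test_completeness_gate_at_three_quarters():
    x = np.ones(100)
    x[:25] = np.nan
    assert E.completeness_gate(x)          # exactly 75% present
    x[25] = np.nan
    assert not E.completeness_gate(x)


def test_feature_extraction_recovers_rates_from_clean_segment():
    rec = synth_ecg(hr_bpm=95.0, rr_bpm=22.0, duration_s=300.0,
                    start_s=10 * 3600.0)
    feats = E.extract_ecg_features([rec], exercise_schedule=[])
    assert feats["daytime_hr"] == pytest.approx(95.0, abs=2.0)
    assert feats["daytime_rr"] == pytest.approx(22.0, abs=1.5)
    assert np.isnan(feats["night_hr"])
    assert np.isnan(feats["hr_recovery_s"])
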