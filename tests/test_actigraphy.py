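import numpy as np
import pytest

from wearcon import actigraphy as A


def series(axis1, start_s=0.0, vm=None, wear=None):
    axis1 = np.asarray(axis1, dtype=float)
    return A.EpochSeries(start_s, axis1, 1.5 * axis1 if vm is None else vm, wear)


def test_intensity_cutpoints_are_strict_thresholds():
    eps = series([100.0, 101.0, 2295.0, 2296.0, 4011.0, 4012.0])
    level = A.classify_intensity(eps)
    assert list(level) == [A.SEDENTARY, A.LIGHT, A.LIGHT, A.MODERATE,
                           A.MODERATE, A.VIGOROUS]


def test_negative_counts_rejected():
    with pytest.raises(A.ActigraphyError):
        series([-1.0, 5.0])


def test_intensity_minutes_average_over_days():
    # day 0: 2 moderate epochs; day 1: 4 moderate epochs -> mean 3 min/day
    counts = np.zeros(2 * 1440)
    counts[10:12] = 3000.0
    counts[1440 + 10:1440 + 14] = 3000.0
    feats = A.intensity_minutes(series(counts))
    assert feats["moderate_min"] == pytest.approx(3.0)


def test_bout_durations_are_maximal_runs_of_moderate_or_above():
    level = np.array([0, 2, 2, 3, 0, 0, 2, 0])
    mean_s, durations = A.bout_statistics(level)
    assert sorted(durations) == [60.0, 180.0]
    assert mean_s == pytest.approx(120.0)


def test_weibull_scale_needs_enough_bouts():
    assert np.isnan(A.weibull_scale(np.full(5, 120.0)))


def test_weibull_scale_of_identical_bouts_is_their_length():
    assert A.weibull_scale(np.full(20, 120.0)) == pytest.approx(2.0)


def test_zero_counts_score_as_sleep():
    sleep = A.cole_kripke(np.zeros(120))
    assert sleep.all()


def test_sustained_high_counts_score_as_wake():
    sleep = A.cole_kripke(np.full(60, 500.0))
    assert not sleep.any()


def test_webster_rescoring_after_long_wake_run():
    # 15 min of wake followed by sleep: the first 4 sleep epochs are rescored
    counts = np.concatenate([np.zeros(30), np.full(15, 500.0), np.zeros(30)])
    raw = A.cole_kripke(counts, rescore=False)
    rescored = A.cole_kripke(counts, rescore=True)
    wake_end = np.flatnonzero(~raw).max() + 1
    assert raw[wake_end:wake_end + 4].all()          # scored sleep before rule
    assert not rescored[wake_end:wake_end + 4].any()  # rescored as wake
    assert rescored[wake_end + 4:].all()


def test_main_sleep_period_needs_consolidated_runs():
    sleep = np.array([True] * 3 + [False] + [True] * 30 + [False] * 5 + [True] * 12)
    period = A.find_sleep_period(sleep)
    assert period is not None
    onset, offset = period
    assert onset == 4            # first run of >= 5 sleep epochs
    assert offset == len(sleep) - 1


def test_sleep_metrics_on_a_constructed_night():
    # one night: sleep 22:00-06:00 with a 10-min awakening at 02:00
    n = 2 * 1440
    counts = np.full(n, 800.0)
    onset = 22 * 60
    wake = 30 * 60  # 06:00 next day
    counts[onset:wake] = 0.0
    counts[26 * 60:26 * 60 + 10] = 500.0
    eps = series(counts)
    summary, in_period = A.sleep_period_and_metrics(eps)
    assert summary.n_nights == 1
    assert summary.wakeup_min == pytest.approx(360.0, abs=2.0)
    assert summary.awake_min >= 10.0
    assert summary.tst_min + summary.awake_min == pytest.approx(
        in_period.sum(), abs=1e-9)
    assert 0.0 < summary.sleep_eff_pct < 100.0
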