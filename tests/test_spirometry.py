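import numpy as np
import pytest

from wearcon import spirometry as S


def maneuver(t=0.0, tag=S.PRE_EXERCISE, fev1=1.8, fvc=2.2, pef=4.0,
             fef=2.0, fet=4.0, bev=0.05):
    return S.SpirometryManeuver(t, tag, fev1, fvc, pef, fef, fet, bev)


def test_fev1_cannot_exceed_fvc():
    with pytest.raises(S.SpirometryError):
        maneuver(fev1=2.5, fvc=2.0)


def test_unknown_tag_rejected():
    with pytest.raises(S.SpirometryError):
        maneuver(tag="morning")


def test_quality_control_flags_back_extrapolation_and_short_blow():
    ok, reasons = S.qc_maneuver(maneuver(bev=0.30))
    assert not ok and "back-extrapolated" in reasons[0]
    ok, reasons = S.qc_maneuver(maneuver(fet=1.0))
    assert not ok and "short expiration" in reasons[0]
    ok, _ = S.qc_maneuver(maneuver())
    assert ok


def test_percent_predicted_is_a_pure_ratio():
    ref = S.DEFAULT_REFERENCE
    pred = ref.predicted("fev1", "m", 10.0, 140.0)
    assert S.percent_predicted(pred, "fev1", "m", 10.0, 140.0) == pytest.approx(100.0)
    assert S.percent_predicted(0.5 * pred, "fev1", "m", 10.0, 140.0) == pytest.approx(50.0)


def test_reference_rejects_age_outside_support():
    with pytest.raises(S.SpirometryError):
        S.DEFAULT_REFERENCE.predicted("fev1", "m", 25.0, 170.0)


def test_fev1_variation_is_the_range_of_baseline_values():
    assert S.fev1_variation([92.0, 85.0, 101.0]) == pytest.approx(16.0)
    assert np.isnan(S.fev1_variation([92.0]))


def test_fev1_variation_shift_invariance():
    base = np.array([80.0, 90.0, 100.0])
    assert S.fev1_variation(base + 7.0) == pytest.approx(S.fev1_variation(base))


def test_exercise_change_averages_percentage_falls():
    # 2.0 -> 1.8 is -10%; 2.0 -> 2.0 is 0%
    assert S.exercise_change([(2.0, 1.8), (2.0, 2.0)]) == pytest.approx(-5.0)
    assert np.isnan(S.exercise_change([]))


def test_symptom_change_relative_to_baseline():
    assert S.symptom_change([1.5], 2.0) == pytest.approx(-25.0)
    assert np.isnan(S.symptom_change([], 2.0))


def test_feature_extraction_pairs_sessions_and_drops_failed_maneuvers():
    bout = (1000.0, 1600.0)
    ms = [
        maneuver(t=400.0, fev1=2.0, fvc=2.4),                    # pre, paired
        maneuver(t=1900.0, tag=S.POST_EXERCISE, fev1=1.8, fvc=2.4),  # post, 3-6 min
        maneuver(t=5000.0, fev1=2.1, fvc=2.4),                   # second baseline
        maneuver(t=6000.0, fev1=2.2, fvc=2.6, fet=1.0),          # fails QC
    ]
    feats = S.extract_spirometry_features(ms, "m", 10.0, 140.0,
                                          exercise_schedule=[bout])
    assert feats["fev1_change_exercise_pct"] == pytest.approx(-10.0)
    # variation from the two accepted baselines only
    pcts = [S.percent_predicted(v, "fev1", "m", 10.0, 140.0) for v in (2.0, 2.1)]
    assert feats["fev1_variation_pct"] == pytest.approx(max(pcts) - min(pcts))
    assert np.isnan(feats["fev1_change_symptom_pct"])
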