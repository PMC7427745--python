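import numpy as np
import pytest

from wearcon import inhaler as I


def ev(t, kind=I.RELIEVER):
    return I.InhalerEvent(t, kind)


def test_unknown_inhaler_type_rejected():
    with pytest.raises(I.InhalerError):
        ev(0.0, "nebuliser")


def test_rapid_double_actuations_collapse_to_one_dose():
    events = [ev(0.0), ev(30.0), ev(120.0), ev(130.0, I.CONTROLLER)]
    out = I.deduplicate(events)
    assert len(out) == 3  # the 30 s repeat merges, the controller survives


def test_adherence_is_doses_taken_over_prescribed():
    rx = I.Prescription(2, 14)
    events = [ev(i * 3600.0, I.CONTROLLER) for i in range(14)]
    assert I.controller_adherence(events, rx) == pytest.approx(50.0)


def test_overuse_reported_above_hundred_percent():
    rx = I.Prescription(1, 2)
    events = [ev(i * 3600.0, I.CONTROLLER) for i in range(3)]
    assert I.controller_adherence(events, rx) == pytest.approx(150.0)


def test_adherence_undefined_without_prescription():
    assert np.isnan(I.controller_adherence([], I.Prescription(0, 14)))


def test_reliever_events_assigned_to_activity_windows():
    bout = (10000.0, 11000.0)
    events = [ev(9000.0),    # 1000 s before the start -> before
              ev(11500.0),   # 500 s after the end -> after
              ev(50000.0)]   # unrelated
    total, before, after = I.reliever_counts(events, [bout])
    assert (total, before, after) == (3, 1, 1)


def test_event_in_both_windows_counted_once_to_nearer_boundary():
    # two close bouts: the event is 200 s after bout 1 and 400 s before bout 2
    bouts = [(0.0, 1000.0), (1600.0, 2600.0)]
    total, before, after = I.reliever_counts([ev(1200.0)], bouts)
    assert (total, before, after) == (1, 0, 1)


def test_all_features_nan_without_prescription():
    feats = I.extract_inhaler_features([], None, [])
    assert all(np.isnan(v) for v in feats.values())


def test_feature_extraction_counts_and_adherence():
    rx = I.Prescription(2, 14)
    events = ([ev(9000.0)] +
              [ev(t, I.CONTROLLER) for t in np.arange(0, 14 * 86400.0, 86400.0)])
    feats = I.extract_inhaler_features(events, rx, [(10000.0, 11000.0)])
    assert feats["reliever_total"] == 1.0
    assert feats["reliever_before_activity"] == 1.0
    assert feats["controller_adherence_pct"] == pytest.approx(50.0)
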