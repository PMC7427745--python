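import numpy as np
import pandas as pd
import pytest

from wearcon import io as wio
from wearcon.cohort import apply_missingness, generate_cohort, render_bundle
from wearcon.config import FEATURE_NAMES, MEDICATION_PARAMS
from wearcon.imputation import monotonicity_check
from wearcon.pipeline import extract_features


@pytest.fixture(scope="module")
def closed_loop(degenerate_config):
    """One rendered noiseless subject per group plus extracted features."""
    profiles = generate_cohort(degenerate_config)
    out = {}
    for p in profiles:
        bundle = render_bundle(p, degenerate_config, noise=False)
        feats = extract_features(bundle, p.sex, p.age_y, p.height_cm, p.prescription)
        out[p.group] = (p, bundle, feats)
    return out


def test_cohort_generation_is_deterministic(tiny_config):
    a = generate_cohort(tiny_config)
    b = generate_cohort(tiny_config)
    assert [p.subject_id for p in a] == [p.subject_id for p in b]
    assert a[0].true == b[0].true
    assert a[0].exercise_schedule == b[0].exercise_schedule


def test_group_sizes_and_medication_truth(tiny_config):
    profiles = generate_cohort(tiny_config)
    groups = [p.group for p in profiles]
    assert groups == ["uncontrolled", "controlled", "non_asthmatic"]
    control = next(p for p in profiles if p.group == "non_asthmatic")
    assert control.prescription is None
    assert all(np.isnan(control.true[k]) for k in MEDICATION_PARAMS)


def test_extraction_recovers_event_based_truth(closed_loop):
    profile, _, feats = closed_loop["uncontrolled"]
    assert feats["reliever_total"] == profile.true["reliever_total"]
    # adherence is quantised to whole doses out of 28
    assert feats["controller_adherence_pct"] == pytest.approx(
        profile.true["controller_adherence_pct"], abs=100.0 / 28)
    assert feats["wakeup_min"] == pytest.approx(profile.true["wakeup_min"], abs=1.5)


def test_extraction_recovers_rate_truth(closed_loop):
    profile, _, feats = closed_loop["controlled"]
    assert feats["daytime_hr"] == pytest.approx(profile.true["daytime_hr"], abs=2.0)
    assert feats["night_rr"] == pytest.approx(profile.true["night_rr"], abs=1.5)
    assert feats["rr_recovery_s"] == pytest.approx(profile.true["rr_recovery_s"],
                                                   abs=10.0)


def test_extraction_recovers_spirometry_truth(closed_loop):
    profile, _, feats = closed_loop["uncontrolled"]
    assert feats["pre_fev1_pct"] == pytest.approx(profile.true["pre_fev1_pct"], abs=0.5)
    assert feats["fev1_change_exercise_pct"] == pytest.approx(
        profile.true["fev1_change_exercise_pct"], abs=1.0)


def test_all_features_defined_for_asthmatics(closed_loop):
    _, _, feats = closed_loop["uncontrolled"]
    assert set(feats) == set(FEATURE_NAMES)
    missing = [k for k, v in feats.items() if not np.isfinite(v)]
    assert missing == []


def test_nonasthmatic_medication_features_are_structurally_missing(closed_loop):
    _, _, feats = closed_loop["non_asthmatic"]
    for k in ("reliever_total", "controller_adherence_pct",
              "fev1_change_symptom_pct"):
        assert np.isnan(feats[k])


def test_bundle_round_trip_through_csv(closed_loop, tmp_path):
    _, bundle, feats = closed_loop["controlled"]
    wio.write_bundle(bundle, tmp_path)
    loaded = wio.read_bundle(tmp_path / bundle.subject_id)
    assert len(loaded.ecg_segments) == len(bundle.ecg_segments)
    assert loaded.actigraphy.n_epochs == bundle.actigraphy.n_epochs
    np.testing.assert_allclose(loaded.actigraphy.axis1, bundle.actigraphy.axis1,
                               atol=0.01)
    assert len(loaded.spirometry) == len(bundle.spirometry)
    assert len(loaded.inhaler) == len(bundle.inhaler)
    np.testing.assert_allclose(np.asarray(loaded.exercise_schedule),
                               np.asarray(bundle.exercise_schedule), rtol=1e-9)


def test_missingness_hits_exact_cell_count():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(30, 10)))
    masked = apply_missingness(df, 0.115, seed=1)
    assert int(masked.isna().sum().sum()) == round(0.115 * 300)


def test_structural_missingness_not_double_counted():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(20, 5)))
    df.iloc[:, 0] = np.nan  # structurally undefined column
    masked = apply_missingness(df, 0.1, seed=1)
    assert int(masked.isna().sum().sum()) == 20 + round(0.1 * 100)


def test_monotone_missingness_pattern_is_monotone():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(30, 8)))
    masked = apply_missingness(df, 0.2, seed=2, pattern="monotone")
    ok, _ = monotonicity_check(masked.isna().to_numpy())
    assert ok
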