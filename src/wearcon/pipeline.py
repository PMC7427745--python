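"""End-to-end study pipeline: simulate, extract, impute, fit, classify.

`run_study` performs the whole analysis on a synthetic cohort: sensor
bundles are rendered per subject, the ~28 home-monitoring parameters are
extracted from the raw streams, missingness is injected into the asthmatic
feature matrix, five imputed data sets are created, and the stepwise
logistic model of asthma control is selected, pooled and evaluated against
the clinically assigned labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import actigraphy as act
from . import ecg as ecgmod
from . import inhaler as inh
from . import spirometry as spiro
from .cohort import SensorBundle, SubjectProfile, apply_missingness, generate_cohort, render_bundle
from .config import FEATURE_BOUNDS, FEATURE_NAMES, CohortConfig
from .imputation import ImputedSet, impute
from .model import (CONTROLLED, NON_ASTHMATIC, UNCONTROLLED, BPTResult, ControlLabel,
                    GinaSymptoms, LogisticModel, classification_metrics, label_control,
                    score, stepwise_logistic, univariate_report)

#: skewed parameters imputed on the log scale
LOG_SCALE_FEATURES = ("rr_recovery_s", "hr_recovery_s", "restlessness_counts", "wakeup_min")

#: the published four-covariate model of uncontrolled asthma; coefficients
#: are per %pred point of pre-exercise FEV1 variation, per minute of
#: wake-up time after midnight, per reliever inhalation over two weeks and
#: per second of respiratory-rate recovery time
PUBLISHED_COEFFICIENTS = {
    "fev1_variation_pct": 0.292,
    "wakeup_min": -0.053,
    "reliever_total": 0.100,
    "rr_recovery_s": 0.113,
}

#: default intercept for the published slope-only model, calibrated by
#: maximum likelihood on a synthetic cohort (seed 1, default configuration);
#: NOT a published value — replace via `calibrate_intercept` where possible
SYNTHETIC_CALIBRATION_INTERCEPT = 13.047


def published_model(intercept: float | None = None) -> LogisticModel:
    """The published four-feature model; supply or calibrate an intercept."""
    feats = list(PUBLISHED_COEFFICIENTS)
    beta = np.array([PUBLISHED_COEFFICIENTS[f] for f in feats])
    return LogisticModel(feats, beta,
                         SYNTHETIC_CALIBRATION_INTERCEPT if intercept is None else intercept)


def calibrate_intercept(model: LogisticModel, X: pd.DataFrame, y: np.ndarray) -> float:
    """Maximum-likelihood intercept with the model's slopes held fixed."""
    from scipy.optimize import minimize_scalar

    eta0 = X[model.features].to_numpy(dtype=float) @ model.coefficients
    y = np.asarray(y, dtype=float)

    def nll(b0):
        p = 1.0 / (1.0 + np.exp(-(b0 + eta0)))
        eps = 1e-12
        return -np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

    res = minimize_scalar(nll, bounds=(-60.0, 60.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(bundle: SensorBundle, sex: str, age_y: float, height_cm: float,
                     prescription=None) -> dict[str, float]:
    """All home-monitoring parameters of one subject from raw streams."""
    feats: dict[str, float] = {}
    feats.update(ecgmod.extract_ecg_features(bundle.ecg_segments, bundle.exercise_schedule))
    feats.update(act.extract_actigraphy_features(bundle.actigraphy))
    feats.update(spiro.extract_spirometry_features(
        bundle.spirometry, sex, age_y, height_cm, bundle.exercise_schedule))
    feats.update(inh.extract_inhaler_features(
        bundle.inhaler, prescription, bundle.exercise_schedule))
    return {name: feats.get(name, np.nan) for name in FEATURE_NAMES}


def extract_cohort_features(profiles: list[SubjectProfile], config: CohortConfig,
                            noise: bool = True) -> tuple[pd.DataFrame, list[SensorBundle]]:
    """Feature matrix (subjects x parameters) for a whole cohort."""
    rows, bundles = [], []
    for profile in profiles:
        bundle = render_bundle(profile, config, noise=noise)
        bundles.append(bundle)
        rows.append(extract_features(bundle, profile.sex, profile.age_y,
                                     profile.height_cm, profile.prescription))
    features = pd.DataFrame(rows, index=[p.subject_id for p in profiles])
    return features, bundles


# ---------------------------------------------------------------------------
# Clinical assessment of the synthetic subjects
# ---------------------------------------------------------------------------

def assign_clinical_assessment(profile: SubjectProfile, rng
                               ) -> tuple[GinaSymptoms, BPTResult]:
    """Symptom items and a provocation-test fall consistent with the group.

    Uncontrolled subjects meet the symptom clause, the provocation clause
    or both (roughly in the proportions observed clinically); controlled
    asthmatics and non-asthmatic controls meet neither.
    """
    group = profile.group
    if group == UNCONTROLLED:
        basis = rng.choice(["BPT", "GINA", "both"], p=[13 / 27, 3 / 27, 11 / 27])
        n_items = int(rng.integers(3, 5)) if basis in ("GINA", "both") \
            else int(rng.integers(0, 3))
        fall = float(rng.uniform(14.0, 45.0)) if basis in ("BPT", "both") \
            else float(rng.uniform(0.0, 11.0))
    else:
        n_items = int(rng.integers(0, 3))
        hi = 10.0 if group == CONTROLLED else 6.0
        fall = float(rng.uniform(0.0, hi))
    items = [True] * n_items + [False] * (4 - n_items)
    return GinaSymptoms(*items), BPTResult(fall)


def clinical_labels(profiles: list[SubjectProfile], seed: int) -> pd.Series:
    """Paediatrician-style control label per subject (non-asthmatics pass through)."""
    rng = np.random.default_rng([seed, 97])
    labels = {}
    for profile in profiles:
        if profile.group == NON_ASTHMATIC:
            labels[profile.subject_id] = NON_ASTHMATIC
            continue
        gina, bpt = assign_clinical_assessment(profile, rng)
        labels[profile.subject_id] = label_control(gina, bpt).label
    return pd.Series(labels, name="label")


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    features: pd.DataFrame          # extracted, complete
    masked_features: pd.DataFrame   # asthmatic subjects with missingness
    labels: pd.Series
    imputed: ImputedSet
    model: LogisticModel
    metrics: "object"               # ClassificationMetrics
    predictions: pd.Series
    univariate: pd.DataFrame


def run_study(config: CohortConfig, m: int = 5, noise: bool = True,
              candidates: list[str] | None = None,
              with_univariate: bool = True) -> StudyResult:
    """Simulate a cohort and run the complete asthma-control analysis."""
    profiles = generate_cohort(config)
    features, _ = extract_cohort_features(profiles, config, noise=noise)
    labels = clinical_labels(profiles, config.seed)

    groups = pd.Series({p.subject_id: p.group for p in profiles}, name="group")
    asthmatic = labels.index[labels != NON_ASTHMATIC]
    X = features.loc[asthmatic]
    masked = apply_missingness(X, config.missingness_fraction,
                               seed=config.seed + 1, pattern="mcar")
    imputed = impute(masked, m=m, seed=config.seed + 2, bounds=FEATURE_BOUNDS,
                     log_columns=LOG_SCALE_FEATURES)
    y = (labels.loc[asthmatic] == UNCONTROLLED).to_numpy(dtype=float)
    model = stepwise_logistic(imputed, y, candidates=candidates)

    probs = np.mean([score(model, ds)["probability"].to_numpy()
                     for ds in imputed.datasets], axis=0)
    predictions = pd.Series(np.where(probs > 0.5, UNCONTROLLED, CONTROLLED),
                            index=asthmatic, name="predicted")
    metrics = classification_metrics(labels.loc[asthmatic], predictions)

    univariate = (univariate_report(features, groups) if with_univariate
                  else pd.DataFrame())
    return StudyResult(features, masked, labels, imputed, model, metrics,
                       predictions, univariate)
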