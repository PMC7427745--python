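"""Home-spirometry quality control and %-predicted summaries.

Maneuvers are summary records (FEV1, FVC, PEF, FEF25-75, back-extrapolated
volume, forced expiratory time) tagged by the self-reported context:
pre-exercise, post-exercise or symptom. Quality control applies the
data-available subset of the ATS/ERS acceptability criteria; flow-volume
curve shape checks require raw curves and are out of scope.

Predicted values come from a configurable reference table, linear in height
per sex, so %-predicted arithmetic stays a pure ratio and reference sets
(e.g. GLI) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PRE_EXERCISE, POST_EXERCISE, SYMPTOM = "pre-exercise", "post-exercise", "symptom"
TAGS = (PRE_EXERCISE, POST_EXERCISE, SYMPTOM)


class SpirometryError(ValueError):
    pass


@dataclass
class SpirometryManeuver:
    """One home-spirometry attempt (volumes L, flows L/s, times s)."""

    timestamp_s: float
    tag: str
    fev1_l: float
    fvc_l: float
    pef_ls: float
    fef2575_ls: float
    fet_s: float
    bev_l: float

    def __post_init__(self):
        if self.tag not in TAGS:
            raise SpirometryError(f"unknown maneuver tag {self.tag!r}")
        if min(self.fev1_l, self.fvc_l, self.pef_ls, self.fef2575_ls) <= 0:
            raise SpirometryError("volumes and flows must be positive")
        if self.fev1_l > self.fvc_l + 1e-9:
            raise SpirometryError("FEV1 cannot exceed FVC")


@dataclass(frozen=True)
class ReferenceEquations:
    """Predicted spirometric indices, linear in standing height per sex.

    ``coefficients`` maps index -> sex -> (intercept, slope_per_cm). The
    defaults give plausible paediatric predicted values over 4-14 y
    (heights ~100-175 cm) and are meant to be replaced by a published
    reference set for real data.
    """

    coefficients: dict = None
    age_support: tuple[float, float] = (4.0, 14.0)

    def __post_init__(self):
        if self.coefficients is None:
            object.__setattr__(self, "coefficients", {
                "fev1": {"m": (-2.87, 0.0357), "f": (-2.76, 0.0342)},
                "fvc": {"m": (-3.48, 0.0437), "f": (-3.32, 0.0416)},
                "pef": {"m": (-6.60, 0.0780), "f": (-6.40, 0.0750)},
                "fef2575": {"m": (-3.10, 0.0420), "f": (-2.95, 0.0400)},
            })

    def predicted(self, index: str, sex: str, age_y: float, height_cm: float) -> float:
        lo, hi = self.age_support
        if not lo <= age_y <= hi:
            raise SpirometryError(f"age {age_y} y outside reference support [{lo}, {hi}]")
        intercept, slope = self.coefficients[index][sex]
        value = intercept + slope * height_cm
        if value <= 0:
            raise SpirometryError(f"non-positive predicted {index} at height {height_cm} cm")
        return value


DEFAULT_REFERENCE = ReferenceEquations()


def qc_maneuver(m: SpirometryManeuver, min_fet_s: float = 3.0,
                pef_plausible: bool = True) -> tuple[bool, list[str]]:
    """ATS/ERS acceptability on the available summary indices.

    Accepted iff back-extrapolated volume <= max(0.15 L, 5% FVC), forced
    expiratory time >= ``min_fet_s`` (paediatric relaxation of the adult
    6 s rule) and the device's PEF rise-time plausibility flag is set.
    """
    reasons = []
    if m.bev_l > max(0.15, 0.05 * m.fvc_l):
        reasons.append("excessive back-extrapolated volume")
    if m.fet_s < min_fet_s:
        reasons.append("short expiration")
    if not pef_plausible:
        reasons.append("implausible PEF rise time")
    return (not reasons), reasons


def percent_predicted(value: float, index: str, sex: str, age_y: float,
                      height_cm: float, ref: ReferenceEquations = DEFAULT_REFERENCE) -> float:
    """100 x measured / predicted for one spirometric index."""
    return 100.0 * value / ref.predicted(index, sex, age_y, height_cm)


def fev1_variation(pre_pct: np.ndarray) -> float:
    """Absolute range (max - min) of accepted pre-exercise FEV1 %pred.

    NaN when fewer than two accepted pre-exercise maneuvers exist.
    """
    pre_pct = np.asarray(pre_pct, dtype=float)
    pre_pct = pre_pct[np.isfinite(pre_pct)]
    if pre_pct.size < 2:
        return np.nan
    return float(np.max(pre_pct) - np.min(pre_pct))


def exercise_change(sessions: list[tuple[float, float]]) -> float:
    """Mean percentage FEV1 change across exercise sessions.

    Each session is a (pre_fev1, post_fev1) pair in litres; falls are
    negative. Sessions with a missing member are excluded by the caller.
    """
    if not sessions:
        return np.nan
    changes = [100.0 * (post - pre) / pre for pre, post in sessions]
    return float(np.mean(changes))


def symptom_change(symptom_fev1: np.ndarray, baseline_fev1: float) -> float:
    """Mean percentage FEV1 change of symptom maneuvers vs baseline.

    The baseline is the subject's mean accepted pre-exercise FEV1. NaN when
    the subject recorded no symptom maneuvers.
    """
    symptom_fev1 = np.asarray(symptom_fev1, dtype=float)
    symptom_fev1 = symptom_fev1[np.isfinite(symptom_fev1)]
    if symptom_fev1.size == 0 or not np.isfinite(baseline_fev1) or baseline_fev1 <= 0:
        return np.nan
    return float(np.mean(100.0 * (symptom_fev1 - baseline_fev1) / baseline_fev1))


def extract_spirometry_features(maneuvers: list[SpirometryManeuver], sex: str,
                                age_y: float, height_cm: float,
                                exercise_schedule=None,
                                post_window_s: tuple[float, float] = (180.0, 360.0),
                                pre_window_s: float = 1800.0,
                                ref: ReferenceEquations = DEFAULT_REFERENCE,
                                qc_flags: dict | None = None) -> dict[str, float]:
    """All spirometry features of one subject.

    ``qc_flags`` optionally maps maneuver timestamps to a device PEF
    plausibility flag. Exercise sessions pair each bout with its accepted
    pre-exercise maneuver (within ``pre_window_s`` before the bout) and the
    post-exercise maneuver 3-6 min after the bout end.
    """
    accepted = []
    for m in maneuvers:
        ok, _ = qc_maneuver(m, pef_plausible=(qc_flags or {}).get(m.timestamp_s, True))
        if ok:
            accepted.append(m)

    pre = [m for m in accepted if m.tag == PRE_EXERCISE]
    post = [m for m in accepted if m.tag == POST_EXERCISE]
    symptoms = [m for m in accepted if m.tag == SYMPTOM]

    def pct(m, index, value):
        return percent_predicted(value, index, sex, age_y, height_cm, ref)

    pre_fev1_pct = np.array([pct(m, "fev1", m.fev1_l) for m in pre])
    feats = {
        "pre_fev1_pct": float(np.mean(pre_fev1_pct)) if pre else np.nan,
        "pre_fef2575_pct": float(np.mean([pct(m, "fef2575", m.fef2575_ls) for m in pre]))
        if pre else np.nan,
        "pre_pef_pct": float(np.mean([pct(m, "pef", m.pef_ls) for m in pre])) if pre else np.nan,
        "fev1_variation_pct": fev1_variation(pre_fev1_pct),
    }

    sessions = []
    if exercise_schedule:
        for start, end in exercise_schedule:
            pre_m = [m for m in pre if start - pre_window_s <= m.timestamp_s < start]
            post_m = [m for m in post
                      if end + post_window_s[0] <= m.timestamp_s <= end + post_window_s[1]]
            if pre_m and post_m:
                sessions.append((pre_m[-1].fev1_l, post_m[0].fev1_l))
    feats["fev1_change_exercise_pct"] = exercise_change(sessions)

    baseline = float(np.mean([m.fev1_l for m in pre])) if pre else np.nan
    feats["fev1_change_symptom_pct"] = symptom_change(
        np.array([m.fev1_l for m in symptoms]), baseline)
    return feats
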