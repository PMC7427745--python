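"""Cohort configuration and default calibration of the simulated study.

The synthetic cohort emulates a two-week home-monitoring study of children
with controlled or uncontrolled asthma plus non-asthmatic controls.  Each
home-monitoring parameter is described, per group, by a simple parametric
distribution:

* ``normal`` — truncated normal, parameterised by mean and SD.  Used for
  parameters that are approximately symmetric on their natural scale.
* ``lognormal`` — matched to a median and interquartile range.  Used for
  right-skewed, positive parameters (recovery times, reliever counts,
  wake-up times, restlessness counts).

The default locations and scales reproduce the group-level summaries of the
clinical study the simulator is calibrated against.  All values can be
overridden through :class:`CohortConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

GROUPS = ("uncontrolled", "controlled", "non_asthmatic")
ASTHMATIC_GROUPS = ("uncontrolled", "controlled")

#: z-score of the 75th percentile of the standard normal; converts an IQR of
#: a lognormal into the sigma of the underlying normal.
_Z75 = 0.6744897501960817


class ConfigurationError(ValueError):
    """Raised for invalid cohort or distribution configuration."""


@dataclass(frozen=True)
class DistSpec:
    """Distribution of one parameter in one study group.

    ``family`` is one of ``normal`` (loc = mean, scale = SD), ``lognormal``
    (loc = mu, scale = sigma of the underlying normal) or ``poisson``
    (loc = rate, scale ignored).  ``bounds`` clip the sampled values to a
    physiologically admissible range.
    """

    name: str
    family: str
    loc: float
    scale: float
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self):
        if self.family not in ("normal", "lognormal", "poisson"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.scale < 0:
            raise ConfigurationError(f"{self.name}: scale must be >= 0")

    def sample(self, rng, size=None):
        """Draw from the distribution, clipped to ``bounds``."""
        if self.family == "normal":
            x = rng.normal(self.loc, self.scale, size=size)
        elif self.family == "lognormal":
            x = rng.lognormal(self.loc, self.scale, size=size)
        else:  # poisson
            x = rng.poisson(self.loc, size=size).astype(float)
        import numpy as np

        return np.clip(x, self.bounds[0], self.bounds[1])


def lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Mu/sigma of a lognormal matched to a median and interquartile range.

    ``sigma`` is taken as the average log-distance of the two quartiles from
    the median, scaled by the 75th-percentile z-score, which keeps the match
    sensible when the printed IQR is not exactly log-symmetric.
    """
    if median <= 0 or q1 <= 0 or q3 <= 0:
        raise ConfigurationError("lognormal quartile match requires positive quartiles")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return mu, max(sigma, 0.0)


# ---------------------------------------------------------------------------
# Default per-group calibration
# ---------------------------------------------------------------------------
# Bounds
_PCT_PRED = (20.0, 160.0)
_NONNEG = (0.0, math.inf)

# (family, {group: params}, bounds); normal params are (mean, sd),
# lognormal params are (median, q1, q3) in natural units.
_DEFAULT_TABLE: dict[str, tuple[str, dict, tuple[float, float]]] = {
    # -- home spirometry ----------------------------------------------------
    "pre_fev1_pct": ("normal", {"uncontrolled": (82.2, 16.0), "controlled": (86.1, 8.9),
                                "non_asthmatic": (98.0, 9.5)}, _PCT_PRED),
    "pre_fef2575_pct": ("normal", {"uncontrolled": (66.9, 20.9), "controlled": (75.3, 17.7),
                                   "non_asthmatic": (90.0, 20.5)}, (10.0, 180.0)),
    "pre_pef_pct": ("normal", {"uncontrolled": (77.4, 22.2), "controlled": (81.7, 14.4),
                               "non_asthmatic": (98.1, 18.2)}, (20.0, 180.0)),
    "fev1_variation_pct": ("normal", {"uncontrolled": (18.0, 10.3), "controlled": (9.4, 5.4),
                                      "non_asthmatic": (7.6, 4.3)}, (0.0, 80.0)),
    "fev1_change_exercise_pct": ("normal", {"uncontrolled": (-11.5, 11.9), "controlled": (-0.6, 7.6),
                                            "non_asthmatic": (-1.6, 3.7)}, (-60.0, 30.0)),
    "fev1_change_symptom_pct": ("normal", {"uncontrolled": (-30.2, 21.4),
                                           "controlled": (-6.1, 8.1)}, (-75.0, 30.0)),
    # -- physical activity --------------------------------------------------
    "sedentary_min": ("normal", {"uncontrolled": (568.0, 97.0), "controlled": (566.0, 90.0),
                                 "non_asthmatic": (573.0, 89.0)}, (120.0, 1200.0)),
    "light_min": ("normal", {"uncontrolled": (270.0, 50.0), "controlled": (274.0, 51.0),
                             "non_asthmatic": (270.0, 47.0)}, (30.0, 720.0)),
    "moderate_min": ("normal", {"uncontrolled": (97.0, 35.0), "controlled": (88.0, 33.0),
                                "non_asthmatic": (92.0, 30.0)}, (5.0, 400.0)),
    "vigorous_min": ("normal", {"uncontrolled": (7.4, 8.5), "controlled": (6.0, 7.9),
                                "non_asthmatic": (9.4, 9.2)}, (0.0, 120.0)),
    "bout_len_s": ("normal", {"uncontrolled": (22.7, 2.3), "controlled": (21.9, 2.4),
                              "non_asthmatic": (22.5, 2.3)}, (5.0, 120.0)),
    "weibull_scale": ("normal", {"uncontrolled": (12.9, 1.9), "controlled": (12.2, 1.9),
                                 "non_asthmatic": (12.7, 1.8)}, (1.0, 40.0)),
    # -- sleep --------------------------------------------------------------
    # wake-up time in minutes after midnight: 6:28 (6:17-6:59) etc.
    "wakeup_min": ("lognormal", {"uncontrolled": (388.0, 377.0, 419.0),
                                 "controlled": (438.0, 420.0, 454.0),
                                 "non_asthmatic": (421.0, 405.0, 440.0)}, (240.0, 720.0)),
    "awake_min": ("normal", {"uncontrolled": (59.9, 19.9), "controlled": (51.6, 16.5),
                             "non_asthmatic": (53.1, 17.5)}, (2.0, 180.0)),
    "time_per_awakening_min": ("normal", {"uncontrolled": (2.66, 0.82), "controlled": (2.40, 0.87),
                                          "non_asthmatic": (2.36, 0.53)}, (1.0, 10.0)),
    "sleep_eff_pct": ("normal", {"uncontrolled": (89.0, 3.8), "controlled": (91.2, 5.0),
                                 "non_asthmatic": (90.4, 3.0)}, (60.0, 100.0)),
    "tst_min": ("normal", {"uncontrolled": (496.0, 62.0), "controlled": (514.0, 81.0),
                           "non_asthmatic": (498.0, 54.0)}, (300.0, 720.0)),
    "restlessness_counts": ("lognormal", {"uncontrolled": (3.37, 2.56, 4.87),
                                          "controlled": (2.79, 1.91, 4.12),
                                          "non_asthmatic": (2.76, 2.48, 3.18)}, (0.1, 50.0)),
    # -- medication use (asthmatic groups only) -----------------------------
    "reliever_total": ("lognormal", {"uncontrolled": (16.5, 1.0, 34.0),
                                     "controlled": (3.0, 0.5, 5.0)}, (0.0, 80.0)),
    "controller_adherence_pct": ("normal", {"uncontrolled": (81.1, 30.9),
                                            "controlled": (92.7, 19.1)}, (5.0, 130.0)),
    # -- heart rate / respiratory rate --------------------------------------
    "daytime_hr": ("normal", {"uncontrolled": (101.0, 17.0), "controlled": (97.0, 16.0),
                              "non_asthmatic": (102.0, 10.0)}, (60.0, 160.0)),
    "daytime_rr": ("normal", {"uncontrolled": (19.7, 2.9), "controlled": (18.5, 2.2),
                              "non_asthmatic": (19.3, 2.0)}, (10.0, 40.0)),
    "night_hr": ("normal", {"uncontrolled": (79.0, 16.0), "controlled": (72.0, 14.0),
                            "non_asthmatic": (71.0, 9.0)}, (45.0, 130.0)),
    "night_rr": ("normal", {"uncontrolled": (17.5, 2.6), "controlled": (15.6, 1.6),
                            "non_asthmatic": (15.2, 2.2)}, (8.0, 35.0)),
    "hr_recovery_s": ("lognormal", {"uncontrolled": (54.4, 36.2, 111.5),
                                    "controlled": (27.5, 22.0, 51.5),
                                    "non_asthmatic": (29.0, 20.2, 35.1)}, (5.0, 420.0)),
    "rr_recovery_s": ("lognormal", {"uncontrolled": (60.7, 35.8, 101.3),
                                    "controlled": (23.1, 15.7, 30.5),
                                    "non_asthmatic": (16.2, 11.1, 20.3)}, (5.0, 420.0)),
}

#: Parameters that are only defined for asthmatic subjects.
MEDICATION_PARAMS = ("reliever_total", "controller_adherence_pct", "fev1_change_symptom_pct")

#: Reliever events associated with exercise bouts are derived from the total
#: count via per-group placement probabilities rather than drawn separately
#: (the before/after medians are dominated by zeros, which a positive
#: continuous family cannot represent).
RELIEVER_PLACEMENT = {
    "uncontrolled": {"before": 0.12, "after": 0.18},
    "controlled": {"before": 0.08, "after": 0.10},
}

FEATURE_NAMES = tuple(_DEFAULT_TABLE) + ("reliever_before_activity", "reliever_after_activity")

#: Bounds used both for clipping synthetic draws and for constraining
#: imputation; before/after counts inherit the non-negativity of totals.
FEATURE_BOUNDS = {name: _DEFAULT_TABLE[name][2] for name in _DEFAULT_TABLE}
FEATURE_BOUNDS["reliever_before_activity"] = _NONNEG
FEATURE_BOUNDS["reliever_after_activity"] = _NONNEG


def default_parameter_specs() -> dict[str, dict[str, DistSpec]]:
    """Default per-group distribution specs, keyed ``group -> parameter``."""
    specs: dict[str, dict[str, DistSpec]] = {g: {} for g in GROUPS}
    for name, (family, per_group, bounds) in _DEFAULT_TABLE.items():
        for group, params in per_group.items():
            if family == "lognormal":
                median, q1, q3 = params
                mu, sigma = lognormal_from_quartiles(median, q1, q3)
                specs[group][name] = DistSpec(name, "lognormal", mu, sigma, bounds)
            else:
                loc, scale = params
                specs[group][name] = DistSpec(name, family, loc, scale, bounds)
    return specs


@dataclass
class ECGRenderConfig:
    """Knobs of the stylised ECG renderer."""

    sampling_rate: float = 250.0
    r_amplitude_mv: float = 1.0
    s_amplitude_mv: float = -0.3
    #: fractional sinusoidal modulation of the R and S amplitudes at the
    #: instantaneous respiratory frequency (the EDR ground truth)
    respiratory_modulation: float = 0.20
    noise_mv: float = 0.015
    baseline_wander_mv: float = 0.15
    baseline_wander_hz: float = 0.20
    #: HR / RR increments at peak exercise, beats(breaths)/min
    exercise_hr_boost: float = 55.0
    exercise_rr_boost: float = 14.0
    #: analysis segments rendered inside the 2-day ECG window (seconds)
    day_segment_s: float = 1800.0
    night_segment_s: float = 1800.0
    bout_pre_s: float = 360.0
    bout_post_s: float = 960.0


@dataclass
class CohortConfig:
    """Full configuration of one simulated cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"uncontrolled": 27, "controlled": 32, "non_asthmatic": 30})
    parameter_specs: dict[str, dict[str, DistSpec]] = field(default_factory=default_parameter_specs)
    missingness_fraction: float = 0.115
    monitoring_days: int = 14
    ecg_days: int = 2
    seed: int = 0
    ecg: ECGRenderConfig = field(default_factory=ECGRenderConfig)
    #: fraction of rendered spirometry maneuvers failing quality control
    qc_fail_fraction: float = 0.261
    #: spirometry sessions (pre+post pair) performed over the fortnight;
    #: drawn uniformly from this inclusive range per subject (~9 maneuvers)
    spiro_sessions_range: tuple[int, int] = (4, 5)
    #: prescribed controller doses per day
    controller_doses_per_day: int = 2
    #: exercise bouts per day and bout duration range (minutes)
    bouts_per_day: int = 1
    bout_duration_min: tuple[float, float] = (6.0, 30.0)
    #: window (minutes) associating reliever events with activity bouts
    reliever_window_min: float = 30.0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError("group sizes must be >= 0")
        if not 0.0 <= self.missingness_fraction < 1.0:
            raise ConfigurationError("missingness_fraction must be in [0, 1)")
        for group in GROUPS:
            if self.group_sizes.get(group, 0) == 0:
                continue
            have = set(self.parameter_specs.get(group, {}))
            need = set(_DEFAULT_TABLE) - (
                set(MEDICATION_PARAMS) if group == "non_asthmatic" else set())
            missing = need - have
            if missing:
                raise ConfigurationError(
                    f"group {group!r} lacks distribution specs for {sorted(missing)}")


def load_config(path) -> CohortConfig:
    """Load a cohort configuration from YAML, overriding defaults.

    Only scalar fields and ``group_sizes`` may be overridden from YAML;
    distribution overrides use ``parameters: {group: {name: {family, loc,
    scale, bounds}}}`` applied on top of the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = CohortConfig()
    if "group_sizes" in raw:
        cfg.group_sizes = {**cfg.group_sizes, **raw.pop("group_sizes")}
    overrides = raw.pop("parameters", {})
    for group, params in overrides.items():
        for name, d in params.items():
            base = cfg.parameter_specs[group].get(name)
            bounds = tuple(d.get("bounds", base.bounds if base else (-math.inf, math.inf)))
            cfg.parameter_specs[group][name] = DistSpec(
                name, d.get("family", base.family if base else "normal"),
                float(d["loc"]), float(d.get("scale", 0.0)), bounds)
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


def with_degenerate_scales(cfg: CohortConfig) -> CohortConfig:
    """Copy of the config with every distribution collapsed to its location.

    Useful for closed-loop tests: all subjects of a group share identical
    true parameter values.
    """
    specs = {
        g: {n: replace(s, scale=0.0) for n, s in params.items()}
        for g, params in cfg.parameter_specs.items()
    }
    return replace(cfg, parameter_specs=specs)
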