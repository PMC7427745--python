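"""Synthetic two-week home-monitoring cohort.

Subjects are drawn from per-group parameter distributions (see
:mod:`wearcon.config`) into :class:`SubjectProfile` objects carrying the
ground-truth value of every home-monitoring parameter plus the exercise and
sleep schedule. Renderers turn a profile into raw sensor streams — stylised
single-lead ECG, 60-s actigraphy epochs, tagged spirometry maneuvers and a
smart-inhaler event log — constructed so that the corresponding feature
extractors recover the profile's true values (exactly for event-based
features, within stated tolerances for signal-derived ones).

All clock values are seconds since local midnight of the first monitoring
day. The ECG window covers two days and two nights starting at noon of day
0; within it a small set of analysis segments is rendered (resting day and
night segments plus the surroundings of one exercise bout per day), which
is what the downstream rate summaries and recovery times consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actigraphy import DEFAULT_CUTPOINTS, EPOCH_S, EpochSeries
from .config import (ASTHMATIC_GROUPS, GROUPS, MEDICATION_PARAMS, RELIEVER_PLACEMENT,
                     CohortConfig, ConfigurationError)
from .ecg import ECGRecord
from .inhaler import CONTROLLER, RELIEVER, InhalerEvent, Prescription
from .spirometry import (DEFAULT_REFERENCE, POST_EXERCISE, PRE_EXERCISE, SYMPTOM,
                         SpirometryManeuver)

DAY_S = 86400.0

#: exercise-decay band used to convert a target recovery time into the
#: exponential time constant: crossing into the 5% band happens at
#: t = tau * ln(1/0.05) after the bout end.
_LN20 = math.log(20.0)


class RenderingError(RuntimeError):
    pass


@dataclass
class SubjectProfile:
    """Ground truth of one simulated subject."""

    subject_id: str
    group: str
    sex: str
    age_y: float
    height_cm: float
    true: dict[str, float]
    exercise_schedule: list[tuple[float, float]]
    sleep_onsets_s: np.ndarray
    sleep_wakes_s: np.ndarray
    prescription: Prescription | None
    #: per-reliever-dose placement category: before / after / other
    reliever_plan: list[str] = field(default_factory=list)
    #: monitoring-day indices on which spirometry sessions take place
    spiro_session_days: list[int] = field(default_factory=list)


@dataclass
class SensorBundle:
    """Raw sensor streams of one subject plus the ground-truth schedule."""

    subject_id: str
    ecg_segments: list[ECGRecord]
    actigraphy: EpochSeries
    spirometry: list[SpirometryManeuver]
    inhaler: list[InhalerEvent]
    exercise_schedule: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Draw one :class:`SubjectProfile` per subject, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    profiles = []
    idx = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        specs = config.parameter_specs.get(group, {})
        for _ in range(n):
            true = {name: float(spec.sample(rng)) for name, spec in specs.items()}
            if group == "non_asthmatic":
                for name in MEDICATION_PARAMS:
                    true[name] = np.nan
            true["reliever_total"] = (float(round(true["reliever_total"]))
                                      if np.isfinite(true.get("reliever_total", np.nan))
                                      else np.nan)
            age = float(rng.uniform(4.0, 14.0))
            height = float(np.clip(110.0 + 5.5 * (age - 4.0) + rng.normal(0.0, 6.0),
                                   95.0, 180.0))
            sex = "m" if rng.random() < (0.8 if group in ASTHMATIC_GROUPS else 0.5) else "f"
            profile = SubjectProfile(
                subject_id=f"S{idx:03d}", group=group, sex=sex, age_y=age,
                height_cm=height, true=true,
                exercise_schedule=_exercise_schedule(config, rng),
                sleep_onsets_s=np.array([]), sleep_wakes_s=np.array([]),
                prescription=(Prescription(config.controller_doses_per_day,
                                           config.monitoring_days)
                              if group in ASTHMATIC_GROUPS else None),
            )
            _derive_sleep_schedule(profile, config)
            _plan_medication(profile, config, rng)
            _plan_spirometry(profile, config, rng)
            profiles.append(profile)
            idx += 1
    return profiles


def _exercise_schedule(config: CohortConfig, rng) -> list[tuple[float, float]]:
    lo, hi = config.bout_duration_min
    schedule = []
    for day in range(config.monitoring_days):
        for _ in range(config.bouts_per_day):
            start = day * DAY_S + rng.uniform(15.0, 17.5) * 3600.0
            dur = rng.uniform(lo, hi) * 60.0
            schedule.append((start, start + dur))
    return schedule


def _derive_sleep_schedule(profile: SubjectProfile, config: CohortConfig) -> None:
    """Nightly onset/wake times from the true sleep parameters.

    The schedule is deterministic (identical every night): nightly averages
    of the extracted sleep metrics then equal the true values exactly.
    """
    tib_min = profile.true["tst_min"] + profile.true["awake_min"]
    n_nights = config.monitoring_days - 1
    wakes = (np.arange(1, n_nights + 1) * DAY_S
             + profile.true["wakeup_min"] * 60.0)
    onsets = wakes - tib_min * 60.0
    profile.sleep_onsets_s = onsets
    profile.sleep_wakes_s = wakes


def _plan_medication(profile: SubjectProfile, config: CohortConfig, rng) -> None:
    if profile.group not in ASTHMATIC_GROUPS:
        profile.true["reliever_before_activity"] = np.nan
        profile.true["reliever_after_activity"] = np.nan
        return
    placement = RELIEVER_PLACEMENT[profile.group]
    n = int(profile.true["reliever_total"])
    p_before, p_after = placement["before"], placement["after"]
    plan = []
    for _ in range(n):
        u = rng.random()
        plan.append("before" if u < p_before
                    else "after" if u < p_before + p_after else "other")
    profile.reliever_plan = plan
    profile.true["reliever_before_activity"] = float(plan.count("before"))
    profile.true["reliever_after_activity"] = float(plan.count("after"))


def _plan_spirometry(profile: SubjectProfile, config: CohortConfig, rng) -> None:
    lo, hi = config.spiro_sessions_range
    n_sessions = int(rng.integers(lo, hi + 1))
    days = rng.choice(config.monitoring_days, size=min(n_sessions, config.monitoring_days),
                      replace=False)
    profile.spiro_session_days = sorted(int(d) for d in days)


# ---------------------------------------------------------------------------
# Ground-truth HR / RR trajectory
# ---------------------------------------------------------------------------

def true_rate(profile: SubjectProfile, t, which: str, config: CohortConfig):
    """Ground-truth instantaneous HR or RR (per minute) at times ``t``.

    Baseline follows the day/night schedule with 10-min sigmoid
    transitions; exercise bouts add a 60-s ramp to the configured boost
    followed by an exponential decay whose time constant realises the
    profile's true recovery time under the 5%-of-excursion criterion.
    """
    t = np.asarray(t, dtype=float)
    day_v = profile.true["daytime_hr" if which == "hr" else "daytime_rr"]
    night_v = profile.true["night_hr" if which == "hr" else "night_rr"]
    from scipy.special import expit

    asleep = np.zeros(t.shape, dtype=float)
    width = 600.0
    for onset, wake in zip(profile.sleep_onsets_s, profile.sleep_wakes_s):
        if t.size and (t.max() < onset - 8 * width or t.min() > wake + 8 * width):
            continue
        asleep += expit((t - onset) / width) - expit((t - wake) / width)
    asleep = np.clip(asleep, 0.0, 1.0)
    base = day_v + (night_v - day_v) * asleep

    boost = (config.ecg.exercise_hr_boost if which == "hr"
             else config.ecg.exercise_rr_boost)
    recovery = profile.true["hr_recovery_s" if which == "hr" else "rr_recovery_s"]
    tau = max(recovery, 1.0) / _LN20
    effect = np.zeros(t.shape, dtype=float)
    for start, end in profile.exercise_schedule:
        if t.size and (t.max() < start or t.min() > end + 20 * tau):
            continue
        during = (t >= start) & (t < end)
        after = t >= end
        effect[during] = np.maximum(effect[during],
                                    boost * np.minimum((t[during] - start) / 60.0, 1.0))
        decay = -(t[after] - end) / tau
        effect[after] = np.maximum(effect[after], boost * np.exp(np.maximum(decay, -700)))
    return base + effect


# ---------------------------------------------------------------------------
# ECG rendering
# ---------------------------------------------------------------------------

def default_ecg_segments(profile: SubjectProfile, config: CohortConfig
                         ) -> list[tuple[float, float, str]]:
    """(start, duration, kind) of the analysis segments inside the ECG window."""
    ecg = config.ecg
    ecg_start = 0.5 * DAY_S
    ecg_end = ecg_start + config.ecg_days * DAY_S
    segments = [
        (0.0 * DAY_S + 14.0 * 3600.0, ecg.day_segment_s, "day"),
        (1.0 * DAY_S + 10.0 * 3600.0, ecg.day_segment_s, "day"),
        (1.0 * DAY_S + 2.0 * 3600.0, ecg.night_segment_s, "night"),
        (2.0 * DAY_S + 2.0 * 3600.0, ecg.night_segment_s, "night"),
    ]
    bouts = [b for b in profile.exercise_schedule
             if b[0] - ecg.bout_pre_s >= ecg_start and b[1] + ecg.bout_post_s <= ecg_end]
    if not bouts:
        raise RenderingError("no exercise bout inside the ECG window")
    longest = max(e - s for s, e in profile.exercise_schedule)
    if config.ecg_days * DAY_S < 2 * longest:
        raise RenderingError("ECG window shorter than twice the longest bout")
    for start, end in bouts[:2]:
        segments.append((start - ecg.bout_pre_s,
                         (end - start) + ecg.bout_pre_s + ecg.bout_post_s, "bout"))
    return [s for s in segments if s[0] >= ecg_start and s[0] + s[1] <= ecg_end]


def render_ecg_segment(profile: SubjectProfile, start_s: float, duration_s: float,
                       config: CohortConfig, rng, noise: bool = True) -> ECGRecord:
    """Stylised single-lead ECG over one segment.

    QRS-like wavelets (Gaussian R peak, delayed Gaussian S trough) are
    placed at RR-intervals integrating the ground-truth heart rate; the R
    and S amplitudes are modulated sinusoidally at the instantaneous
    respiratory phase, which is the EDR ground truth. Additive Gaussian
    noise and sub-0.45 Hz baseline wander are optional.
    """
    ecg = config.ecg
    fs = ecg.sampling_rate
    end_s = start_s + duration_s

    # beat times by inverting the integrated instantaneous heart rate
    grid = np.arange(start_s, end_s + 0.25, 0.25)
    hr = np.maximum(true_rate(profile, grid, "hr", config), 20.0)
    cum_beats = np.concatenate([[0.0], np.cumsum(0.5 * (hr[1:] + hr[:-1]) / 60.0 * 0.25)])
    n_beats = int(np.floor(cum_beats[-1]))
    beats = np.interp(np.arange(1, n_beats + 1), cum_beats, grid)
    beats = beats[beats < end_s - 0.1]
    if beats.size < 4:
        raise RenderingError("segment too short to place beats")

    # respiratory phase on the same grid
    rr = true_rate(profile, grid, "rr", config)
    phase = 2.0 * np.pi * np.cumsum(rr / 60.0) * 0.25
    beat_phase = np.interp(beats, grid, phase)
    mod = 1.0 + ecg.respiratory_modulation * np.sin(beat_phase)

    n = int(round(duration_s * fs))
    samples = np.zeros(n)
    times = np.arange(n) / fs  # relative to start_s
    if noise and ecg.noise_mv > 0:
        samples += rng.normal(0.0, ecg.noise_mv, size=n)
    if noise and ecg.baseline_wander_mv > 0:
        samples += ecg.baseline_wander_mv * np.sin(
            2.0 * np.pi * ecg.baseline_wander_hz * times + rng.uniform(0, 2 * np.pi))

    sigma = 0.010  # s, QRS wavelet width
    half = int(round(4 * sigma * fs))
    kernel_t = (np.arange(-half, half + 1)) / fs
    r_kernel = np.exp(-0.5 * (kernel_t / sigma) ** 2)
    rel = beats - start_s
    r_idx = np.round(rel * fs).astype(int)
    s_idx = np.round((rel + 0.040) * fs).astype(int)
    for k in range(beats.size):
        _add_wavelet(samples, r_idx[k], r_kernel, ecg.r_amplitude_mv * mod[k])
        _add_wavelet(samples, s_idx[k], r_kernel, ecg.s_amplitude_mv * mod[k])
    return ECGRecord(fs, samples, start_s)


def _add_wavelet(samples, center, kernel, amplitude):
    half = (kernel.size - 1) // 2
    lo, hi = center - half, center + half + 1
    klo = max(0, -lo)
    khi = kernel.size - max(0, hi - samples.size)
    lo, hi = max(lo, 0), min(hi, samples.size)
    if lo < hi:
        samples[lo:hi] += amplitude * kernel[klo:khi]


def render_ecg(profile: SubjectProfile, config: CohortConfig, rng,
               noise: bool = True) -> list[ECGRecord]:
    return [render_ecg_segment(profile, start, dur, config, rng, noise=noise)
            for start, dur, _ in default_ecg_segments(profile, config)]


# ---------------------------------------------------------------------------
# Actigraphy rendering
# ---------------------------------------------------------------------------

#: axis-1 count ranges per intensity level used by the renderer; consistent
#: with the default youth cut-points of the extractor
_LEVEL_COUNTS = {"sedentary": (10.0, 90.0), "light": (150.0, 2000.0),
                 "moderate": (2500.0, 3900.0), "vigorous": (4200.0, 8000.0)}
#: quiet-wake count: scores wake under the one-minute Cole-Kripke weights
#: without dragging neighbouring epochs above the threshold
_QUIET_WAKE = 6.0


def render_actigraphy(profile: SubjectProfile, config: CohortConfig, rng) -> EpochSeries:
    """60-s axis-1 and vector-magnitude counts over the monitoring period.

    Sleep periods carry zero axis-1 counts with short quiet-wake awakening
    runs; transitions into and out of sleep are tapered so the Cole-Kripke
    scorer recovers the true wake-up time to the epoch. Daytime epochs are
    allocated to intensity levels matching the true minutes/day, with the
    scheduled exercise bout rendered as a moderate-to-vigorous run.
    """
    n_epochs = int(config.monitoring_days * DAY_S / EPOCH_S)
    axis1 = np.zeros(n_epochs)
    vm = np.zeros(n_epochs)
    wear = np.ones(n_epochs, dtype=bool)
    in_sleep = np.zeros(n_epochs, dtype=bool)

    def ep(t_s):
        return int(t_s // EPOCH_S)

    # --- sleep architecture -------------------------------------------------
    tpa = max(profile.true["time_per_awakening_min"], 1.0)
    n_awak = max(int(round(profile.true["awake_min"] / tpa)), 1)
    for onset_s, wake_s in zip(profile.sleep_onsets_s, profile.sleep_wakes_s):
        if wake_s > n_epochs * EPOCH_S:
            continue
        onset_e, wake_e = ep(onset_s), ep(wake_s)
        in_sleep[onset_e:wake_e] = True
        axis1[onset_e:wake_e] = 0.0
        vm[onset_e:wake_e] = 0.0
        # quiet-wake taper around the boundaries (see module docstring)
        axis1[max(onset_e - 2, 0):onset_e] = _QUIET_WAKE
        axis1[wake_e:wake_e + 2] = _QUIET_WAKE
        # awakenings in the middle of the night, away from both boundaries
        protected = 12
        span = wake_e - onset_e
        if span > 2 * protected + 4:
            run_len = max(int(round(tpa)), 1)
            placed = 0
            attempts = 0
            used = np.zeros(span, dtype=bool)
            while placed < n_awak and attempts < 20 * n_awak:
                attempts += 1
                pos = int(rng.integers(protected, span - protected - run_len))
                if used[max(pos - 2, 0):pos + run_len + 2].any():
                    continue
                used[pos:pos + run_len] = True
                axis1[onset_e + pos:onset_e + pos + run_len] = _QUIET_WAKE
                vm[onset_e + pos:onset_e + pos + run_len] = 5.0
                placed += 1
        # pre-wake restlessness hour: mean vector magnitude = true value
        vm[wake_e - 60:wake_e] = profile.true["restlessness_counts"]

    # --- daytime activity ---------------------------------------------------
    quiet = np.zeros(n_epochs, dtype=bool)
    for onset_s, wake_s in zip(profile.sleep_onsets_s, profile.sleep_wakes_s):
        onset_e, wake_e = ep(onset_s), ep(wake_s)
        quiet[max(onset_e - 2, 0):onset_e] = True
        quiet[wake_e:min(wake_e + 2, n_epochs)] = True

    targets = {name: int(round(profile.true[f"{name}_min"]))
               for name in ("light", "moderate", "vigorous")}
    days = (np.arange(n_epochs) * EPOCH_S // DAY_S).astype(int)
    for day in range(config.monitoring_days):
        day_sel = np.flatnonzero((days == day) & ~in_sleep & ~quiet)
        if day_sel.size == 0:
            continue
        # default: sedentary background
        axis1[day_sel] = rng.uniform(*_LEVEL_COUNTS["sedentary"], size=day_sel.size)
        free = np.ones(day_sel.size, dtype=bool)

        # exercise bout: two vigorous epochs then moderate
        n_mod_bout = n_vig_bout = 0
        for start, end in profile.exercise_schedule:
            if not (day * DAY_S <= start < (day + 1) * DAY_S):
                continue
            b0, b1 = ep(start), ep(end)
            bout_idx = np.flatnonzero((day_sel >= b0) & (day_sel < b1))
            for j, i in enumerate(bout_idx):
                level = "vigorous" if j < 2 else "moderate"
                axis1[day_sel[i]] = rng.uniform(*_LEVEL_COUNTS[level])
                free[i] = False
                if level == "vigorous":
                    n_vig_bout += 1
                else:
                    n_mod_bout += 1

        need = {"vigorous": max(targets["vigorous"] - n_vig_bout, 0),
                "moderate": max(targets["moderate"] - n_mod_bout, 0),
                "light": targets["light"]}
        if sum(need.values()) > int(free.sum()):
            raise RenderingError(f"day {day}: target activity minutes exceed the waking day")
        # moderate epochs in Weibull-length runs to give bouts some texture
        for level in ("vigorous", "moderate", "light"):
            remaining = need[level]
            while remaining > 0:
                run = 1 if level != "moderate" else max(
                    int(round(rng.weibull(1.5) * 3.0)), 1)
                run = min(run, remaining)
                candidates = np.flatnonzero(free)
                if candidates.size == 0:
                    raise RenderingError("no free epochs left for activity allocation")
                pos = int(rng.choice(candidates))
                hi = pos
                while hi < free.size and free[hi] and hi - pos < run:
                    hi += 1
                for i in range(pos, hi):
                    axis1[day_sel[i]] = rng.uniform(*_LEVEL_COUNTS[level])
                    free[i] = False
                remaining -= hi - pos

        # one daily non-wear gap (water activities), early afternoon
        gap_len = int(rng.integers(20, 41))
        gap_start = ep(day * DAY_S + 12.25 * 3600.0)
        wear[gap_start:gap_start + gap_len] = False
        axis1[gap_start:gap_start + gap_len] = 0.0
        vm[gap_start:gap_start + gap_len] = 0.0

    day_mask = ~in_sleep
    vm[day_mask & (vm == 0.0) & wear] = axis1[day_mask & (vm == 0.0) & wear] * 1.5
    return EpochSeries(0.0, axis1, vm, wear)


# ---------------------------------------------------------------------------
# Spirometry rendering
# ---------------------------------------------------------------------------

def render_spirometry_events(profile: SubjectProfile, config: CohortConfig, rng,
                             reliever_times: dict[str, list[float]] | None = None
                             ) -> list[SpirometryManeuver]:
    """Tagged maneuvers: a pre/post pair per spirometry session plus symptom
    maneuvers before non-activity reliever use.

    Pre-exercise FEV1 %pred values are constructed so that their range
    equals the true pre-exercise FEV1 variation and their mean the true
    pre-exercise FEV1; post and symptom values apply the true relative
    changes. A configured fraction of maneuvers is rendered as failing
    quality control (short expiration).
    """
    bouts_by_day = {}
    for start, end in profile.exercise_schedule:
        bouts_by_day.setdefault(int(start // DAY_S), []).append((start, end))

    k = len(profile.spiro_session_days)
    mean_pct = profile.true["pre_fev1_pct"]
    var = profile.true["fev1_variation_pct"]
    u = np.empty(k)
    if k >= 2:
        u[0], u[1] = 0.0, 1.0
        if k > 2:
            interior = rng.uniform(0.15, 0.85, size=k - 2)
            interior += 0.5 - interior.mean()  # centre so the overall mean is exact
            u[2:] = np.clip(interior, 0.02, 0.98)
        order = rng.permutation(k)
        u = u[order]
    elif k == 1:
        u[0] = 0.5
    pre_pct = mean_pct - var / 2.0 + u * var

    pred = {idx: DEFAULT_REFERENCE.predicted(idx, profile.sex, profile.age_y,
                                             profile.height_cm)
            for idx in ("fev1", "fvc", "pef", "fef2575")}

    def maneuver(t_s, tag, fev1_pct):
        fev1 = fev1_pct / 100.0 * pred["fev1"]
        fail = rng.random() < config.qc_fail_fraction
        return SpirometryManeuver(
            timestamp_s=t_s, tag=tag, fev1_l=fev1, fvc_l=fev1 / 0.85,
            pef_ls=profile.true["pre_pef_pct"] / 100.0 * pred["pef"],
            fef2575_ls=profile.true["pre_fef2575_pct"] / 100.0 * pred["fef2575"],
            fet_s=1.2 if fail else 6.0, bev_l=0.05)

    maneuvers = []
    for i, day in enumerate(profile.spiro_session_days):
        bouts = bouts_by_day.get(day)
        if not bouts:
            continue
        start, end = bouts[0]
        maneuvers.append(maneuver(start - 300.0, PRE_EXERCISE, pre_pct[i]))
        post_pct = pre_pct[i] * (1.0 + profile.true["fev1_change_exercise_pct"] / 100.0)
        maneuvers.append(maneuver(end + 240.0, POST_EXERCISE, post_pct))

    if reliever_times and np.isfinite(profile.true.get("fev1_change_symptom_pct", np.nan)):
        symptom_pct = mean_pct * (1.0 + profile.true["fev1_change_symptom_pct"] / 100.0)
        for t in reliever_times.get("other", []):
            maneuvers.append(maneuver(t - 120.0, SYMPTOM, symptom_pct))
    return sorted(maneuvers, key=lambda m: m.timestamp_s)


# ---------------------------------------------------------------------------
# Inhaler rendering
# ---------------------------------------------------------------------------

def render_inhaler_log(profile: SubjectProfile, config: CohortConfig, rng
                       ) -> tuple[list[InhalerEvent], dict[str, list[float]]]:
    """Controller and reliever events; also returns reliever times by category."""
    events: list[InhalerEvent] = []
    placements: dict[str, list[float]] = {"before": [], "after": [], "other": []}
    if profile.prescription is None:
        return events, placements

    rx = profile.prescription
    dose_hours = np.linspace(8.0, 20.0, rx.doses_per_day) if rx.doses_per_day > 1 \
        else np.array([8.0])
    slots = [day * DAY_S + h * 3600.0
             for day in range(rx.monitoring_days) for h in dose_hours]
    n_taken = int(round(profile.true["controller_adherence_pct"] / 100.0 * len(slots)))
    n_taken = min(n_taken, len(slots))
    taken = rng.choice(len(slots), size=n_taken, replace=False)
    events += [InhalerEvent(slots[i] + float(rng.uniform(-600, 600)), CONTROLLER)
               for i in sorted(taken)]

    bouts = profile.exercise_schedule
    used_times: list[float] = []
    for category in profile.reliever_plan:
        for _ in range(100):
            start, end = bouts[int(rng.integers(len(bouts)))]
            if category == "before":
                t = start - rng.uniform(2.0, 28.0) * 60.0
            elif category == "after":
                t = end + rng.uniform(2.0, 28.0) * 60.0
            else:
                day = int(rng.integers(config.monitoring_days))
                t = day * DAY_S + rng.uniform(9.0, 13.5) * 3600.0
            if all(abs(t - t2) >= 90.0 for t2 in used_times):
                break
        used_times.append(t)
        placements[category].append(t)
        events.append(InhalerEvent(t, RELIEVER))
    return sorted(events, key=lambda e: e.timestamp_s), placements


# ---------------------------------------------------------------------------
# Bundles and missingness
# ---------------------------------------------------------------------------

def render_bundle(profile: SubjectProfile, config: CohortConfig,
                  noise: bool = True) -> SensorBundle:
    """All sensor streams of one subject, deterministic in the config seed."""
    sid = int(profile.subject_id[1:])
    rngs = [np.random.default_rng([config.seed, sid, k]) for k in range(4)]
    inhaler_events, placements = render_inhaler_log(profile, config, rngs[0])
    return SensorBundle(
        subject_id=profile.subject_id,
        ecg_segments=render_ecg(profile, config, rngs[1], noise=noise),
        actigraphy=render_actigraphy(profile, config, rngs[2]),
        spirometry=render_spirometry_events(profile, config, rngs[3], placements),
        inhaler=inhaler_events,
        exercise_schedule=list(profile.exercise_schedule),
    )


def apply_missingness(features: pd.DataFrame, fraction: float, seed: int,
                      pattern: str = "mcar") -> pd.DataFrame:
    """Mask exactly round(fraction x cells) feature cells as missing.

    ``mcar``: cells chosen completely at random. ``monotone``: columns are
    put in a random order and per-row missing tails are grown until the
    target count is reached, producing a monotone missingness pattern.
    Cells that are already NaN (structurally undefined features) do not
    count towards the target.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("missingness fraction must be in [0, 1)")
    out = features.copy()
    rng = np.random.default_rng(seed)
    n_cells = out.shape[0] * out.shape[1]
    k = int(round(fraction * n_cells))
    if k == 0:
        return out
    if pattern == "mcar":
        values = out.to_numpy(dtype=float)
        candidates = np.flatnonzero(np.isfinite(values.ravel()))
        flat = rng.choice(candidates, size=min(k, candidates.size), replace=False)
        rows, cols = np.unravel_index(flat, out.shape)
        values[rows, cols] = np.nan
        out.iloc[:, :] = values
    elif pattern == "monotone":
        order = rng.permutation(out.shape[1])
        tails = np.zeros(out.shape[0], dtype=int)
        masked = 0
        while masked < k:
            row = int(rng.integers(out.shape[0]))
            if tails[row] >= out.shape[1]:
                continue
            tails[row] += 1
            masked += 1
        values = out.to_numpy(dtype=float)
        for row, tail in enumerate(tails):
            if tail:
                values[row, order[out.shape[1] - tail:]] = np.nan
        out.iloc[:, :] = values
    else:
        raise ConfigurationError(f"unknown missingness pattern {pattern!r}")
    return out
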