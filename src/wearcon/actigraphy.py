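"""Wrist-actigraphy features: activity intensity, bouts, and sleep scoring.

Counts are handled at the 60-s epoch level. Intensity classification uses
youth count cut-points (Evenson) by default, bout structure is summarised by
the mean bout length and the scale parameter of a Weibull fit to bout
durations, and sleep is scored with the one-minute Cole-Kripke weighted
window, optionally followed by Webster rescoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

EPOCH_S = 60.0

#: Evenson youth cut-points, counts/min; an epoch belongs to the higher
#: level iff its count strictly exceeds the threshold.
DEFAULT_CUTPOINTS = (100.0, 2295.0, 4011.0)

#: One-minute Cole-Kripke weights for epochs t-4 .. t+2 and overall scale;
#: an epoch is scored sleep when the weighted score is below 1.
COLE_KRIPKE_WEIGHTS = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)
COLE_KRIPKE_SCALE = 0.001

SEDENTARY, LIGHT, MODERATE, VIGOROUS = 0, 1, 2, 3
LEVEL_NAMES = ("sedentary", "light", "moderate", "vigorous")


class ActigraphyError(ValueError):
    pass


@dataclass
class EpochSeries:
    """Contiguous 60-s actigraphy epochs.

    ``start_s`` is the series start in seconds since local midnight of the
    first monitoring day.
    """

    start_s: float
    axis1: np.ndarray
    vector_magnitude: np.ndarray
    wear: np.ndarray = field(default=None)

    def __post_init__(self):
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.vector_magnitude = np.asarray(self.vector_magnitude, dtype=float)
        if self.wear is None:
            self.wear = np.ones(self.axis1.size, dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        if not (self.axis1.size == self.vector_magnitude.size == self.wear.size):
            raise ActigraphyError("axis1, vector magnitude and wear mask must have equal length")
        if np.any(self.axis1 < 0) or np.any(self.vector_magnitude < 0):
            raise ActigraphyError("counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.axis1.size

    @property
    def epoch_starts_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_epochs) * EPOCH_S


@dataclass
class SleepSummary:
    tst_min: float
    wakeup_min: float
    sleep_eff_pct: float
    awake_min: float
    time_per_awakening_min: float
    restlessness_counts: float
    n_nights: int


# ---------------------------------------------------------------------------
# Activity intensity
# ---------------------------------------------------------------------------

def classify_intensity(epochs: EpochSeries, cutpoints=DEFAULT_CUTPOINTS) -> np.ndarray:
    """Per-epoch intensity level (0=sedentary .. 3=vigorous) from axis-1 counts."""
    c1, c2, c3 = cutpoints
    if not (c1 < c2 < c3):
        raise ActigraphyError("cut-points must be strictly increasing")
    counts = epochs.axis1
    level = np.zeros(epochs.n_epochs, dtype=int)
    level[counts > c1] = LIGHT
    level[counts > c2] = MODERATE
    level[counts > c3] = VIGOROUS
    return level


def _day_index(epochs: EpochSeries) -> np.ndarray:
    return (epochs.epoch_starts_s // 86400.0).astype(int)


def intensity_minutes(epochs: EpochSeries, cutpoints=DEFAULT_CUTPOINTS,
                      include_mask: np.ndarray | None = None) -> dict[str, float]:
    """Minutes/day at each intensity level, averaged over monitored days.

    ``include_mask`` restricts the denominator (e.g. worn waking epochs);
    by default only the wear mask applies. Days with no included epochs do
    not contribute.
    """
    level = classify_intensity(epochs, cutpoints)
    include = epochs.wear if include_mask is None else (epochs.wear & include_mask)
    days = _day_index(epochs)
    per_day = {name: [] for name in LEVEL_NAMES}
    for day in np.unique(days):
        sel = (days == day) & include
        if not sel.any():
            continue
        for lv, name in enumerate(LEVEL_NAMES):
            per_day[name].append(float(np.sum(level[sel] == lv)))
    if not per_day["sedentary"]:
        return {f"{name}_min": np.nan for name in LEVEL_NAMES}
    return {f"{name}_min": float(np.mean(v)) for name, v in per_day.items()}


def bout_statistics(level: np.ndarray, include: np.ndarray | None = None,
                    epoch_s: float = EPOCH_S) -> tuple[float, np.ndarray]:
    """Mean bout length (s) and the list of bout durations (s).

    A bout is a maximal run of consecutive included epochs at moderate
    intensity or above. Returns NaN and an empty list when no such epochs
    exist.
    """
    active = np.asarray(level) >= MODERATE
    if include is not None:
        active = active & include
    if not active.any():
        return np.nan, np.array([])
    padded = np.concatenate([[0], active.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    durations = (ends - starts) * epoch_s
    return float(np.mean(durations)), durations.astype(float)


def weibull_scale(durations_s: np.ndarray, min_bouts: int = 10) -> float:
    """Maximum-likelihood Weibull scale (minutes) of bout durations.

    Requires at least ``min_bouts`` bouts; NaN otherwise. Degenerate
    all-equal samples collapse to the common duration (shape -> infinity).
    """
    durations_min = np.asarray(durations_s, dtype=float) / 60.0
    if durations_min.size < min_bouts:
        return np.nan
    if np.ptp(durations_min) < 1e-12:
        return float(durations_min[0])
    _, _, scale = stats.weibull_min.fit(durations_min, floc=0.0)
    return float(scale)


# ---------------------------------------------------------------------------
# Sleep scoring
# ---------------------------------------------------------------------------

def cole_kripke(counts: np.ndarray, weights=COLE_KRIPKE_WEIGHTS,
                scale: float = COLE_KRIPKE_SCALE, rescore: bool = True) -> np.ndarray:
    """Per-epoch sleep (True) / wake (False) by the Cole-Kripke score.

    The score of epoch t is ``scale * sum_k w_k * A[t+k]`` for k = -4 .. +2;
    epochs outside the record contribute zero. Webster rescoring rules
    (wake runs of >=4/10/15 min rescore the next 1/3/4 sleep minutes as
    wake) are applied when ``rescore`` is true.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    score = np.zeros(n)
    for w, k in zip(weights, range(-4, 3)):
        if k < 0:
            score[-k:] += w * counts[:n + k]
        elif k == 0:
            score += w * counts
        else:
            score[:n - k] += w * counts[k:]
    sleep = scale * score < 1.0
    if rescore:
        sleep = _webster_rescore(sleep)
    return sleep


def _webster_rescore(sleep: np.ndarray) -> np.ndarray:
    """Webster rules a-c: rescore short sleep after sustained wake as wake.

    Wake runs of >= 4, 10 or 15 min in the original scoring rescore the
    first 1, 3 or 4 min of the following sleep run; rescored epochs do not
    themselves trigger further rescoring.
    """
    out = sleep.copy()
    for start, stop in _runs(~np.asarray(sleep, dtype=bool)):
        wake_len = stop - start
        if wake_len >= 15:
            k = 4
        elif wake_len >= 10:
            k = 3
        elif wake_len >= 4:
            k = 1
        else:
            continue
        j = stop
        while k > 0 and j < out.size and sleep[j]:
            out[j] = False
            j += 1
            k -= 1
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.diff(padded)
    return list(zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)))


def find_sleep_period(sleep: np.ndarray, onset_run: int = 5,
                      offset_run: int = 10) -> tuple[int, int] | None:
    """Main sleep period inside a night window of sleep/wake epochs.

    Onset is the first epoch of the first run of ``onset_run`` consecutive
    sleep epochs; offset is the last epoch of the last run of
    ``offset_run`` consecutive sleep epochs. Returns (onset, offset)
    inclusive indices, or None.
    """
    runs = _runs(np.asarray(sleep, dtype=bool))
    onset = next((s for s, e in runs if e - s >= onset_run), None)
    offset = next((e - 1 for s, e in reversed(runs) if e - s >= offset_run), None)
    if onset is None or offset is None or offset <= onset:
        return None
    return onset, offset


def sleep_period_and_metrics(epochs: EpochSeries, sleep: np.ndarray | None = None,
                             rescore: bool = True, onset_run: int = 5,
                             offset_run: int = 10,
                             night_window_hours: tuple[float, float] = (18.0, 36.0),
                             ) -> tuple[SleepSummary, np.ndarray]:
    """Nightly sleep metrics averaged over nights with a detected period.

    For each monitored day d, the night window runs from 18:00 on day d to
    12:00 on day d+1. Returns the summary and a boolean mask of epochs that
    belong to a detected main sleep period (useful to restrict daytime
    analyses to waking epochs).
    """
    if sleep is None:
        sleep = cole_kripke(epochs.axis1, rescore=rescore)
    starts = epochs.epoch_starts_s
    days = np.unique((starts // 86400.0).astype(int))
    lo_h, hi_h = night_window_hours

    tst, wakeups, eff, awake, per_awak, restless = [], [], [], [], [], []
    in_period = np.zeros(epochs.n_epochs, dtype=bool)
    for day in days:
        w0 = day * 86400.0 + lo_h * 3600.0
        w1 = day * 86400.0 + hi_h * 3600.0
        sel = np.flatnonzero((starts >= w0) & (starts < w1))
        if sel.size < offset_run:
            continue
        period = find_sleep_period(sleep[sel], onset_run, offset_run)
        if period is None:
            continue
        onset, offset = period
        idx = sel[onset:offset + 1]
        in_period[idx] = True
        night_sleep = sleep[idx]
        n_sleep = int(night_sleep.sum())
        length = idx.size
        tst.append(n_sleep)
        eff.append(100.0 * n_sleep / length)
        wake_runs = _runs(~night_sleep)
        n_awake = int((~night_sleep).sum())
        awake.append(n_awake)
        per_awak.append(n_awake / len(wake_runs) if wake_runs else 0.0)
        # wake-up time: end of the last sleep epoch, minutes after midnight
        wake_s = starts[idx[-1]] + EPOCH_S
        wakeups.append((wake_s - (day + 1) * 86400.0) / 60.0)
        # restlessness: mean vector-magnitude counts in the final hour
        hour = np.flatnonzero((starts >= wake_s - 3600.0) & (starts < wake_s))
        if hour.size:
            restless.append(float(np.mean(epochs.vector_magnitude[hour])))
    if not tst:
        nan = float("nan")
        return SleepSummary(nan, nan, nan, nan, nan, nan, 0), in_period
    return SleepSummary(
        tst_min=float(np.mean(tst)),
        wakeup_min=float(np.mean(wakeups)),
        sleep_eff_pct=float(np.mean(eff)),
        awake_min=float(np.mean(awake)),
        time_per_awakening_min=float(np.mean(per_awak)),
        restlessness_counts=float(np.mean(restless)) if restless else np.nan,
        n_nights=len(tst),
    ), in_period


# ---------------------------------------------------------------------------
# Whole-record feature extraction
# ---------------------------------------------------------------------------

def extract_actigraphy_features(epochs: EpochSeries, cutpoints=DEFAULT_CUTPOINTS,
                                rescore: bool = True) -> dict[str, float]:
    """All activity and sleep features of one subject's epoch series."""
    summary, in_sleep = sleep_period_and_metrics(epochs, rescore=rescore)
    waking = ~in_sleep
    feats = intensity_minutes(epochs, cutpoints, include_mask=waking)
    level = classify_intensity(epochs, cutpoints)
    mean_bout_s, durations = bout_statistics(level, include=epochs.wear & waking)
    feats["bout_len_s"] = mean_bout_s
    feats["weibull_scale"] = weibull_scale(durations)
    feats.update({
        "tst_min": summary.tst_min,
        "wakeup_min": summary.wakeup_min,
        "sleep_eff_pct": summary.sleep_eff_pct,
        "awake_min": summary.awake_min,
        "time_per_awakening_min": summary.time_per_awakening_min,
        "restlessness_counts": summary.restlessness_counts,
    })
    return feats
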