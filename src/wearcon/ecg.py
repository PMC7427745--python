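"""ECG-derived heart-rate and respiratory-rate features.

The processing chain mirrors ambulatory single-lead practice:

1. band-pass FIR filtering (Kaiser window, 0.45–39 Hz) to remove baseline
   wander and high-frequency noise;
2. QRS detection with a derivative-energy detector and adaptive threshold;
3. ECG-derived respiration (EDR): the R-minus-S amplitude of each QRS
   complex is cubic-spline interpolated to a uniform 50 Hz respiratory
   surrogate signal, whose cycles are counted as breaths;
4. uniform 1 Hz heart-rate and respiratory-rate series with a quality mask;
5. day/night averages and post-exertion recovery times.

Respiratory modulation of QRS amplitudes is strongest in the R-S difference
of a single lead, which is why the RS amplitude rather than the R peak alone
is used as the respiratory surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

#: admissible physiological ranges used for the quality mask
HR_RANGE = (30.0, 250.0)
RR_RANGE = (4.0, 80.0)

#: default analysis windows, hours of local time
DAY_WINDOW = (8.0, 20.0)
NIGHT_WINDOW = (0.0, 6.0)

EDR_FS = 50.0  # Hz, resampling rate of the respiratory surrogate
RATE_FS = 1.0  # Hz, resampling rate of the HR/RR series


class ECGError(ValueError):
    """Raised for ECG records that violate an analysis precondition."""


@dataclass
class ECGRecord:
    """A contiguous single-channel ECG segment.

    ``start_s`` is the segment start in seconds since local midnight of the
    first monitoring day, so that hour-of-day windows can be evaluated.
    """

    sampling_rate: float
    samples: np.ndarray  # mV
    start_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate < 100.0:
            raise ECGError("sampling rate must be >= 100 Hz")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class BeatSeries:
    """Detected beats with per-beat R, S and RS amplitudes (mV)."""

    times: np.ndarray  # s, same clock as ECGRecord.start_s
    r_amplitude: np.ndarray
    s_amplitude: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ECGError("beat times must be strictly increasing")

    @property
    def rs_amplitude(self) -> np.ndarray:
        return np.asarray(self.r_amplitude) - np.asarray(self.s_amplitude)

    def __len__(self):
        return self.times.size


@dataclass
class RespiratorySignal:
    """EDR surrogate resampled to a uniform grid, with detected breaths."""

    times: np.ndarray
    values: np.ndarray
    breath_times: np.ndarray  # inspiration-peak times, s


@dataclass
class RateSeries:
    """Uniform 1 Hz heart-rate and respiratory-rate series with a mask."""

    times: np.ndarray
    hr: np.ndarray  # beats/min, NaN where unavailable
    rr: np.ndarray  # breaths/min
    hr_mask: np.ndarray = field(default=None)
    rr_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.hr_mask is None:
            self.hr_mask = np.isfinite(self.hr) & (self.hr >= HR_RANGE[0]) & (self.hr <= HR_RANGE[1])
        if self.rr_mask is None:
            self.rr_mask = np.isfinite(self.rr) & (self.rr >= RR_RANGE[0]) & (self.rr <= RR_RANGE[1])


@dataclass
class RecoveryResult:
    """Outcome of a post-exertion return-to-baseline search."""

    exertion_end_s: float
    peak: float
    baseline: float
    recovery_time_s: float
    converged: bool


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def design_bandpass(sampling_rate: float, low_hz: float = 0.45, high_hz: float = 39.0,
                    ripple_db: float = 60.0, width_hz: float = 0.3) -> np.ndarray:
    """Kaiser-window FIR band-pass taps (default 0.45–39 Hz, 60 dB)."""
    if sampling_rate <= 2 * high_hz:
        raise ECGError(f"sampling rate {sampling_rate} Hz below Nyquist bound for {high_hz} Hz")
    numtaps, beta = signal.kaiserord(ripple_db, width_hz / (0.5 * sampling_rate))
    numtaps |= 1  # odd length -> integer group delay
    return signal.firwin(numtaps, [low_hz, high_hz], window=("kaiser", beta),
                         pass_zero=False, fs=sampling_rate)


def bandpass_filter(ecg: ECGRecord, low_hz: float = 0.45, high_hz: float = 39.0) -> ECGRecord:
    """Zero-phase band-pass: forward FIR with group-delay compensation.

    Output has the same length and start time as the input; edge samples are
    computed against zero padding.
    """
    taps = design_bandpass(ecg.sampling_rate, low_hz, high_hz)
    delay = (taps.size - 1) // 2
    padded = np.concatenate([ecg.samples, np.zeros(delay)])
    filtered = signal.fftconvolve(padded, taps, mode="full")[delay:delay + ecg.samples.size]
    return ECGRecord(ecg.sampling_rate, filtered, ecg.start_s)


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def detect_beats(ecg: ECGRecord, refractory_s: float = 0.2) -> BeatSeries:
    """Derivative-energy QRS detector with an adaptive threshold.

    The squared derivative of the filtered ECG is smoothed with a 150 ms
    moving-average integration window; peaks above an adaptive threshold
    (a fraction of the running 98th percentile of the detection function)
    separated by at least the refractory period are taken as QRS complexes.
    The R peak is refined as the signal maximum within ±50 ms of the
    detection and the S trough as the minimum within 100 ms after R.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    if x.size < fs:  # < 1 s of data
        raise ECGError("record too short for beat detection")
    det = np.gradient(x) ** 2
    win = max(int(round(0.15 * fs)), 1)
    det = np.convolve(det, np.ones(win) / win, mode="same")
    scale = np.percentile(det, 98)
    if scale <= 0:
        return BeatSeries(np.array([]), np.array([]), np.array([]))
    distance = max(int(round(refractory_s * fs)), 1)
    peaks, _ = signal.find_peaks(det, height=0.2 * scale, distance=distance)
    if peaks.size == 0:
        return BeatSeries(np.array([]), np.array([]), np.array([]))

    half = int(round(0.05 * fs))
    s_win = int(round(0.10 * fs))
    r_idx = np.empty(peaks.size, dtype=int)
    r_amp = np.empty(peaks.size)
    s_amp = np.empty(peaks.size)
    for k, p in enumerate(peaks):
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        r_idx[k] = lo + int(np.argmax(x[lo:hi]))
        r_amp[k] = x[r_idx[k]]
        s_lo, s_hi = r_idx[k], min(r_idx[k] + s_win + 1, x.size)
        s_amp[k] = np.min(x[s_lo:s_hi])
    # refinement can merge neighbouring detections onto one R sample
    keep = np.concatenate([[True], np.diff(r_idx) > 0])
    times = ecg.start_s + r_idx[keep] / fs
    return BeatSeries(times, r_amp[keep], s_amp[keep])


# ---------------------------------------------------------------------------
# ECG-derived respiration
# ---------------------------------------------------------------------------

def derive_respiration(beats: BeatSeries, fs: float = EDR_FS,
                       prominence_iqr_fraction: float = 0.2,
                       min_cycle_s: float = 0.75) -> RespiratorySignal:
    """Cubic-spline EDR: RS amplitudes resampled to ``fs`` with breath peaks.

    Breath cycles are detected as peaks of the surrogate with a minimum
    prominence (a fraction of the signal IQR) and a minimum cycle length.
    A constant RS amplitude therefore yields zero breaths.
    """
    if len(beats) < 4:
        raise ECGError("at least 4 beats are required for spline interpolation")
    rs = beats.rs_amplitude
    spline = interpolate.CubicSpline(beats.times, rs)
    grid = np.arange(beats.times[0], beats.times[-1], 1.0 / fs)
    values = spline(grid)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 1e-12:
        return RespiratorySignal(grid, values, np.array([]))
    peaks, _ = signal.find_peaks(values, prominence=prominence_iqr_fraction * iqr,
                                 distance=max(int(min_cycle_s * fs), 1))
    return RespiratorySignal(grid, values, grid[peaks])


def _instantaneous_rate(event_times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Events/min at grid times, from interval-based instantaneous rate."""
    out = np.full(grid.size, np.nan)
    if event_times.size < 2:
        return out
    mids = 0.5 * (event_times[1:] + event_times[:-1])
    rates = 60.0 / np.diff(event_times)
    inside = (grid >= event_times[0]) & (grid <= event_times[-1])
    if mids.size == 1:
        out[inside] = rates[0]
        return out
    out[inside] = np.interp(grid[inside], mids, rates)
    return out


def build_rate_series(beats: BeatSeries, resp: RespiratorySignal | None,
                      start_s: float | None = None, end_s: float | None = None,
                      fs: float = RATE_FS) -> RateSeries:
    """Uniform HR/RR series from beat and breath event times."""
    if len(beats) == 0:
        raise ECGError("no beats available")
    t0 = beats.times[0] if start_s is None else start_s
    t1 = beats.times[-1] if end_s is None else end_s
    grid = np.arange(t0, t1, 1.0 / fs)
    hr = _instantaneous_rate(beats.times, grid)
    breaths = resp.breath_times if resp is not None else np.array([])
    rr = _instantaneous_rate(breaths, grid)
    return RateSeries(grid, hr, rr)


def concatenate_rates(series: list[RateSeries]) -> RateSeries:
    parts = sorted(series, key=lambda s: s.times[0] if s.times.size else np.inf)
    return RateSeries(
        np.concatenate([s.times for s in parts]),
        np.concatenate([s.hr for s in parts]),
        np.concatenate([s.rr for s in parts]),
        np.concatenate([s.hr_mask for s in parts]),
        np.concatenate([s.rr_mask for s in parts]),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _window_mean(times, values, mask, window_hours) -> float:
    hours = (times / 3600.0) % 24.0
    lo, hi = window_hours
    inside = (hours >= lo) & (hours < hi)
    if not inside.any():
        return np.nan
    ok = inside & mask
    if ok.sum() < 0.5 * inside.sum():
        return np.nan
    return float(np.mean(values[ok]))


def day_night_summaries(rates: RateSeries, day_window=DAY_WINDOW,
                        night_window=NIGHT_WINDOW) -> dict[str, float]:
    """Average daytime/night-time HR and RR over masked-in samples.

    A window with fewer than 50% masked-in samples yields NaN.
    """
    return {
        "daytime_hr": _window_mean(rates.times, rates.hr, rates.hr_mask, day_window),
        "daytime_rr": _window_mean(rates.times, rates.rr, rates.rr_mask, day_window),
        "night_hr": _window_mean(rates.times, rates.hr, rates.hr_mask, night_window),
        "night_rr": _window_mean(rates.times, rates.rr, rates.rr_mask, night_window),
    }


def recovery_time(rates: RateSeries, bout_start_s: float, bout_end_s: float,
                  which: str = "hr", baseline_window_s: float = 300.0,
                  band_fraction: float = 0.05, hold_s: float = 10.0,
                  median_window_s: float = 10.0, search_s: float = 900.0) -> RecoveryResult:
    """Seconds for a rate to return to its pre-exertion baseline.

    * baseline: median of the rate over the ``baseline_window_s`` seconds
      immediately preceding the bout start;
    * peak: maximum over [bout_end − 60 s, bout_end + 60 s];
    * recovery: first time at/after the peak at which the 10-s moving median
      stays within ``band_fraction`` of the excursion above baseline for at
      least ``hold_s`` consecutive seconds, reported relative to bout end.

    Returns NaN with ``converged=False`` when the series never re-enters the
    band within ``search_s`` seconds after the bout end.
    """
    values = rates.hr if which == "hr" else rates.rr
    mask = rates.hr_mask if which == "hr" else rates.rr_mask
    t = rates.times
    pre = (t >= bout_start_s - baseline_window_s) & (t < bout_start_s) & mask
    if pre.sum() < 10:
        raise ECGError("insufficient pre-bout data for baseline")
    baseline = float(np.median(values[pre]))

    peak_sel = (t >= bout_end_s - 60.0) & (t <= bout_end_s + 60.0) & mask
    if not peak_sel.any():
        raise ECGError("no data around bout end")
    peak = float(np.max(values[peak_sel]))
    peak_time = float(t[peak_sel][np.argmax(values[peak_sel])])
    if peak <= baseline:
        return RecoveryResult(bout_end_s, peak, baseline, 0.0, True)

    threshold = baseline + band_fraction * (peak - baseline)
    post = (t >= peak_time) & (t <= bout_end_s + search_s)
    tt, vv = t[post], values[post]
    if tt.size == 0:
        return RecoveryResult(bout_end_s, peak, baseline, np.nan, False)
    dt = np.median(np.diff(tt)) if tt.size > 1 else 1.0
    k = max(int(round(median_window_s / dt)) | 1, 1)
    smoothed = signal.medfilt(np.nan_to_num(vv, nan=baseline), kernel_size=k)
    below = smoothed <= threshold
    need = max(int(round(hold_s / dt)), 1)
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= need:
            t_rec = tt[i - need + 1]
            return RecoveryResult(bout_end_s, peak, baseline,
                                  max(float(t_rec - bout_end_s), 0.0), True)
    return RecoveryResult(bout_end_s, peak, baseline, np.nan, False)


def completeness_gate(values: np.ndarray, threshold: float = 0.75) -> bool:
    """Accept a continuous stream iff >= 75% of its samples are non-missing."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return False
    return float(np.mean(np.isfinite(values))) >= threshold


# ---------------------------------------------------------------------------
# Whole-record feature extraction
# ---------------------------------------------------------------------------

def extract_ecg_features(segments: list[ECGRecord], exercise_schedule,
                         day_window=DAY_WINDOW, night_window=NIGHT_WINDOW) -> dict[str, float]:
    """HR/RR summaries and recovery times from a set of ECG segments.

    ``exercise_schedule`` is a list of (start_s, end_s) bouts; recovery times
    are averaged over the bouts whose surroundings are covered by a segment.
    """
    rate_parts = []
    per_segment = []
    for seg in segments:
        if not completeness_gate(seg.samples):
            continue
        filtered = bandpass_filter(seg)
        beats = detect_beats(filtered)
        if len(beats) < 4:
            continue
        resp = derive_respiration(beats)
        rates = build_rate_series(beats, resp)
        rate_parts.append(rates)
        per_segment.append((seg, rates))
    if not rate_parts:
        return {k: np.nan for k in ("daytime_hr", "daytime_rr", "night_hr", "night_rr",
                                    "hr_recovery_s", "rr_recovery_s")}
    combined = concatenate_rates(rate_parts)
    # resting summaries exclude exercise bouts and their 10-min aftermath
    resting = np.ones(combined.times.size, dtype=bool)
    for start, end in exercise_schedule:
        resting &= ~((combined.times >= start - 60.0) & (combined.times <= end + 600.0))
    masked = RateSeries(combined.times, combined.hr, combined.rr,
                        combined.hr_mask & resting, combined.rr_mask & resting)
    feats = day_night_summaries(masked, day_window, night_window)

    hr_recs, rr_recs = [], []
    for start, end in exercise_schedule:
        for seg, rates in per_segment:
            covers = (rates.times[0] <= start - 300.0) and (rates.times[-1] >= end + 600.0)
            if not covers:
                continue
            try:
                hres = recovery_time(rates, start, end, "hr")
                rres = recovery_time(rates, start, end, "rr")
            except ECGError:
                continue
            if hres.converged and np.isfinite(hres.recovery_time_s):
                hr_recs.append(hres.recovery_time_s)
            if rres.converged and np.isfinite(rres.recovery_time_s):
                rr_recs.append(rres.recovery_time_s)
            break
    feats["hr_recovery_s"] = float(np.mean(hr_recs)) if hr_recs else np.nan
    feats["rr_recovery_s"] = float(np.mean(rr_recs)) if rr_recs else np.nan
    return feats
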