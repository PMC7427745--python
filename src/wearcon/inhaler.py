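"""Smart-inhaler event-log features: controller adherence and reliever use."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONTROLLER, RELIEVER = "controller", "reliever"


class InhalerError(ValueError):
    pass


@dataclass(frozen=True)
class InhalerEvent:
    timestamp_s: float
    inhaler_type: str

    def __post_init__(self):
        if self.inhaler_type not in (CONTROLLER, RELIEVER):
            raise InhalerError(f"unknown inhaler type {self.inhaler_type!r}")


@dataclass(frozen=True)
class Prescription:
    doses_per_day: int
    monitoring_days: int

    def __post_init__(self):
        if self.doses_per_day < 0 or self.monitoring_days <= 0:
            raise InhalerError("prescription must be non-negative over a positive period")


def deduplicate(events: list[InhalerEvent], min_gap_s: float = 60.0) -> list[InhalerEvent]:
    """Merge same-type actuations less than ``min_gap_s`` apart into one dose."""
    out: list[InhalerEvent] = []
    last: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: e.timestamp_s):
        prev = last.get(ev.inhaler_type)
        if prev is not None and ev.timestamp_s - prev < min_gap_s:
            continue
        out.append(ev)
        last[ev.inhaler_type] = ev.timestamp_s
    return out


def controller_adherence(events: list[InhalerEvent], rx: Prescription) -> float:
    """100 x controller doses taken / doses prescribed; may exceed 100.

    NaN when nothing was prescribed (non-asthmatic subjects); over-use
    (> 100%) is reported as such rather than capped.
    """
    taken = sum(1 for ev in events if ev.inhaler_type == CONTROLLER)
    prescribed = rx.doses_per_day * rx.monitoring_days
    if prescribed == 0:
        return np.nan
    return 100.0 * taken / prescribed


def reliever_counts(events: list[InhalerEvent], exercise_schedule,
                    window_s: float = 1800.0) -> tuple[int, int, int]:
    """(total, before-activity, after-activity) reliever doses.

    Before-activity: within ``window_s`` before some bout start;
    after-activity: within ``window_s`` after some bout end. An event
    matching both is assigned once, to the nearer bout boundary (tie ->
    before).
    """
    relievers = [ev.timestamp_s for ev in events if ev.inhaler_type == RELIEVER]
    total = len(relievers)
    before = after = 0
    schedule = list(exercise_schedule or [])
    for t in relievers:
        d_before = min((start - t for start, _ in schedule if 0 <= start - t <= window_s),
                       default=np.inf)
        d_after = min((t - end for _, end in schedule if 0 <= t - end <= window_s),
                      default=np.inf)
        if d_before is np.inf and d_after is np.inf:
            continue
        if d_before <= d_after:
            before += 1
        else:
            after += 1
    return total, before, after


def extract_inhaler_features(events: list[InhalerEvent], rx: Prescription | None,
                             exercise_schedule, window_s: float = 1800.0,
                             dedup_gap_s: float = 60.0) -> dict[str, float]:
    """All medication-use features of one subject.

    Non-asthmatic subjects carry no prescription and no inhalers: every
    medication feature is NaN for them.
    """
    if rx is None:
        return {"reliever_total": np.nan, "reliever_before_activity": np.nan,
                "reliever_after_activity": np.nan, "controller_adherence_pct": np.nan}
    events = deduplicate(events, dedup_gap_s)
    total, before, after = reliever_counts(events, exercise_schedule, window_s)
    return {
        "reliever_total": float(total),
        "reliever_before_activity": float(before),
        "reliever_after_activity": float(after),
        "controller_adherence_pct": controller_adherence(events, rx),
    }
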