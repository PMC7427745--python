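"""Plain-text persistence of sensor bundles and cohort manifests.

One directory per subject holding ``ecg_<k>.csv`` (time_s, mV),
``actigraphy.csv`` (epoch_start_iso, axis1, axis2, axis3,
vector_magnitude), ``spirometry.csv`` (timestamp, tag, FEV1_L, FVC_L,
PEF_Ls, FEF2575_Ls, FET_s, BEV_L), ``inhaler.csv`` (timestamp,
inhaler_type) and ``exercise.csv`` (start_s, end_s); a cohort-level
``subjects.csv`` records demographics, group and prescription. ISO
timestamps are anchored at a nominal Monday to make weekday structure
readable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import EpochSeries
from .cohort import SensorBundle, SubjectProfile
from .ecg import ECGRecord
from .inhaler import InhalerEvent, Prescription
from .spirometry import SpirometryManeuver

EPOCH_ORIGIN = pd.Timestamp("2024-01-08 00:00:00")


def _iso(seconds: float) -> str:
    return (EPOCH_ORIGIN + pd.to_timedelta(seconds, unit="s")).isoformat()


def _seconds(iso: str) -> float:
    return (pd.Timestamp(iso) - EPOCH_ORIGIN).total_seconds()


def write_bundle(bundle: SensorBundle, outdir) -> Path:
    outdir = Path(outdir) / bundle.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    for k, seg in enumerate(bundle.ecg_segments):
        t = seg.start_s + np.arange(seg.samples.size) / seg.sampling_rate
        pd.DataFrame({"time_s": t, "mV": seg.samples}).to_csv(
            outdir / f"ecg_{k}.csv", index=False, float_format="%.4f")
    epochs = bundle.actigraphy
    a1 = epochs.axis1
    vm = epochs.vector_magnitude
    axis2 = np.sqrt(np.maximum(vm ** 2 - a1 ** 2, 0.0))
    pd.DataFrame({
        "epoch_start_iso": [_iso(s) for s in epochs.epoch_starts_s],
        "axis1": a1, "axis2": axis2, "axis3": np.zeros_like(a1),
        "vector_magnitude": vm, "wear": epochs.wear.astype(int),
    }).to_csv(outdir / "actigraphy.csv", index=False, float_format="%.2f")
    pd.DataFrame([{
        "timestamp": _iso(m.timestamp_s), "tag": m.tag, "FEV1_L": m.fev1_l,
        "FVC_L": m.fvc_l, "PEF_Ls": m.pef_ls, "FEF2575_Ls": m.fef2575_ls,
        "FET_s": m.fet_s, "BEV_L": m.bev_l,
    } for m in bundle.spirometry]).to_csv(outdir / "spirometry.csv", index=False)
    pd.DataFrame([{"timestamp": _iso(e.timestamp_s), "inhaler_type": e.inhaler_type}
                  for e in bundle.inhaler]).to_csv(outdir / "inhaler.csv", index=False)
    pd.DataFrame(bundle.exercise_schedule, columns=["start_s", "end_s"]).to_csv(
        outdir / "exercise.csv", index=False)
    return outdir


def read_bundle(subject_dir) -> SensorBundle:
    subject_dir = Path(subject_dir)
    segments = []
    for path in sorted(subject_dir.glob("ecg_*.csv")):
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        segments.append(ECGRecord(round(fs, 3), df["mV"].to_numpy(), float(t[0])))
    adf = pd.read_csv(subject_dir / "actigraphy.csv")
    epochs = EpochSeries(
        _seconds(adf["epoch_start_iso"].iloc[0]),
        adf["axis1"].to_numpy(), adf["vector_magnitude"].to_numpy(),
        adf["wear"].to_numpy(dtype=bool) if "wear" in adf else None)
    sdf = pd.read_csv(subject_dir / "spirometry.csv")
    maneuvers = [SpirometryManeuver(_seconds(r.timestamp), r.tag, r.FEV1_L, r.FVC_L,
                                    r.PEF_Ls, r.FEF2575_Ls, r.FET_s, r.BEV_L)
                 for r in sdf.itertuples()] if len(sdf) else []
    idf = pd.read_csv(subject_dir / "inhaler.csv")
    events = [InhalerEvent(_seconds(r.timestamp), r.inhaler_type)
              for r in idf.itertuples()] if len(idf) else []
    xdf = pd.read_csv(subject_dir / "exercise.csv")
    schedule = list(zip(xdf["start_s"], xdf["end_s"]))
    return SensorBundle(subject_dir.name, segments, epochs, maneuvers, events, schedule)


def write_manifest(profiles: list[SubjectProfile], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        rows.append({
            "subject_id": p.subject_id, "group": p.group, "sex": p.sex,
            "age_y": round(p.age_y, 2), "height_cm": round(p.height_cm, 1),
            "doses_per_day": p.prescription.doses_per_day if p.prescription else 0,
            "monitoring_days": p.prescription.monitoring_days if p.prescription else 14,
        })
    path = outdir / "subjects.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index("subject_id")


def prescription_from_row(row) -> Prescription | None:
    if int(row["doses_per_day"]) == 0:
        return None
    return Prescription(int(row["doses_per_day"]), int(row["monitoring_days"]))
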