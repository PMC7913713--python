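"""File formats: cohort directories, annotation tables, labels, flags, models.

A cohort directory holds one compressed numeric container per patient
(``features_<id>.npz`` with the 2-s segment feature matrix), a
``recordings.csv`` (patient_id, duration_s) and an ``annotations.csv``
(patient_id, onset_s, end_s, clear_ictal_start_s; the last column may be
empty).  Times are seconds from recording start; intervals are half-open.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .labeling import SeizureEvent
from .simulate import PatientData, SegmentSeries

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_labels",
    "read_labels",
    "write_flags",
    "save_model",
    "load_model",
]

ANNOTATION_COLUMNS = ["patient_id", "onset_s", "end_s", "clear_ictal_start_s"]


def write_cohort(cohort: list[PatientData], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_rows, ann_rows = [], []
    for p in cohort:
        np.savez_compressed(out / f"features_{p.patient_id}.npz", features=p.segments.features)
        rec_rows.append({"patient_id": p.patient_id, "duration_s": p.duration_s})
        for ev in p.events:
            ann_rows.append(
                {
                    "patient_id": p.patient_id,
                    "onset_s": ev.onset_s,
                    "end_s": ev.end_s,
                    "clear_ictal_start_s": ev.clear_ictal_start_s,
                }
            )
    pd.DataFrame(rec_rows).to_csv(out / "recordings.csv", index=False)
    pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).to_csv(
        out / "annotations.csv", index=False
    )


def read_cohort(in_dir) -> list[PatientData]:
    src = Path(in_dir)
    recs = pd.read_csv(src / "recordings.csv")
    ann_path = src / "annotations.csv"
    ann = (
        pd.read_csv(ann_path)
        if ann_path.exists()
        else pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )
    cohort = []
    for _, row in recs.iterrows():
        pid = str(row.patient_id)
        feats = np.load(src / f"features_{pid}.npz")["features"]
        events = [
            SeizureEvent(
                float(a.onset_s),
                float(a.end_s),
                None if pd.isna(a.clear_ictal_start_s) else float(a.clear_ictal_start_s),
            )
            for a in ann[ann.patient_id.astype(str) == pid].itertuples()
        ]
        cohort.append(
            PatientData(pid, int(row.duration_s), SegmentSeries(feats), events)
        )
    return cohort


def write_labels(labels: dict, path) -> None:
    """Labels CSV: patient_id, segment_start_s, label."""
    rows = [
        {"patient_id": pid, "segment_start_s": t, "label": int(v)}
        for pid, series in labels.items()
        for t, v in enumerate(series)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels(path) -> dict:
    df = pd.read_csv(path)
    return {
        str(pid): grp.sort_values("segment_start_s").label.to_numpy(dtype=np.int8)
        for pid, grp in df.groupby("patient_id")
    }


def write_flags(flags: dict, path) -> None:
    """Flags CSV: patient_id, flag_start_s."""
    rows = [
        {"patient_id": pid, "flag_start_s": f.start_s}
        for pid, fl in flags.items()
        for f in fl
    ]
    pd.DataFrame(rows, columns=["patient_id", "flag_start_s"]).to_csv(path, index=False)


def save_model(model, path) -> None:
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)
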