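"""ECG records, echo exams and labeled cohort tables.

The cohort-building pipeline mirrors standard ECG–echocardiography study
practice: each echocardiogram is paired one-to-one with the closest ECG
from the same patient within 28 days, the pair is labeled for left
ventricular systolic dysfunction (LVSD, ejection fraction < 40%), and
records are split into train/validation/test at the *patient* level so
no patient leaks across splits.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import wfdb_io

#: Canonical 12-lead order used everywhere in the package.
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Columns of a serialized cohort table.
COHORT_COLUMNS = ("record_id", "exam_id", "patient_id", "days_between",
                  "ejection_fraction", "lvsd_label", "split")

DEFAULT_SAMPLING_RATE = 500
RECORD_SECONDS = 10
MAX_PAIR_DAYS = 28


class FormatError(ValueError):
    """Input container does not match the expected ECG layout."""


class RateError(ValueError):
    """Sampling rate differs from 500 Hz and resampling is disabled."""


@dataclass
class ECGRecord:
    """One 12-lead, 10-second voltage matrix with exam metadata.

    ``signal`` is (12, sampling_rate * 10) in millivolts, leads ordered
    as :data:`LEAD_NAMES`.
    """

    record_id: str
    patient_id: str
    acquisition_date: _dt.date | None
    signal: np.ndarray
    sampling_rate: int = DEFAULT_SAMPLING_RATE
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise FormatError(f"expected 12 leads, got shape {self.signal.shape}")
        expected = self.sampling_rate * RECORD_SECONDS
        if self.signal.shape[1] != expected:
            raise FormatError(
                f"expected {expected} samples per lead at {self.sampling_rate} Hz, "
                f"got {self.signal.shape[1]}"
            )
        if not np.isfinite(self.signal).all():
            raise FormatError("signal contains non-finite values")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise FormatError(f"leads must be ordered {LEAD_NAMES}")


@dataclass
class EchoExam:
    """One echocardiography exam; ``ejection_fraction`` in percent or None."""

    exam_id: str
    patient_id: str
    exam_date: _dt.date
    ejection_fraction: float | None = None

    def __post_init__(self):
        ef = self.ejection_fraction
        if ef is not None and isinstance(ef, float) and math.isnan(ef):
            self.ejection_fraction = None
        elif ef is not None and not (0 < ef < 100):
            raise ValueError(f"ejection fraction {ef} outside (0, 100)")


def read_wfdb(path, resample: bool = False) -> ECGRecord:
    """Read a 12-channel WFDB record into canonical lead order.

    Channels are matched to the standard lead names case-insensitively
    and reordered; a missing lead is a :class:`FormatError`.  Rates other
    than 500 Hz raise :class:`RateError` unless ``resample`` is set.
    """
    signal, fs, names = wfdb_io.read_record(path)
    if signal.shape[0] != 12:
        raise FormatError(f"expected 12 channels, got {signal.shape[0]}")
    lookup = {n.upper(): i for i, n in enumerate(names)}
    try:
        order = [lookup[lead.upper()] for lead in LEAD_NAMES]
    except KeyError as err:
        raise FormatError(f"channel {err} missing from {sorted(names)}") from None
    signal = signal[order]
    if fs != DEFAULT_SAMPLING_RATE:
        if not resample:
            raise RateError(f"record sampled at {fs} Hz, expected 500")
        from scipy.signal import resample_poly

        up, down = DEFAULT_SAMPLING_RATE, int(fs)
        g = math.gcd(up, down)
        signal = resample_poly(signal, up // g, down // g, axis=1)
        signal = signal[:, : DEFAULT_SAMPLING_RATE * RECORD_SECONDS]
    path = Path(path)
    return ECGRecord(
        record_id=path.stem,
        patient_id=path.stem,
        acquisition_date=None,
        signal=signal,
    )


def normalize(record: ECGRecord, tol: float = 1e-8) -> ECGRecord:
    """Per-lead z-score; a flat lead (SD below tolerance) becomes zeros.

    No filtering or baseline-wander removal is applied.  Idempotent.
    """
    signal = record.signal
    mean = signal.mean(axis=1, keepdims=True)
    sd = signal.std(axis=1, keepdims=True)
    amax = np.abs(signal).max(axis=1, keepdims=True)
    cutoff = np.maximum(tol * amax, tol)
    out = np.where(sd > cutoff, (signal - mean) / np.where(sd > cutoff, sd, 1.0), 0.0)
    return replace(record, signal=out)


def label_lvsd(ejection_fraction: float | None) -> int | None:
    """LVSD label: 1 if EF < 40%, 0 if EF >= 40%, None if missing."""
    ef = ejection_fraction
    if ef is None or (isinstance(ef, float) and math.isnan(ef)):
        return None
    if not (0 < ef < 100):
        raise ValueError(f"ejection fraction {ef} outside (0, 100)")
    return 1 if ef < 40 else 0


def pair_exams(ecgs, echoes, max_days: int = MAX_PAIR_DAYS) -> pd.DataFrame:
    """One-to-one nearest-in-time pairing of echo exams with ECGs.

    Echoes are processed in chronological order; each takes the unconsumed
    same-patient ECG minimising ``|days_between|`` (ties broken toward the
    earlier ECG), provided the gap is at most ``max_days`` days.  Echoes
    with no eligible ECG or missing ejection fraction yield no row.

    ``ecgs`` may be :class:`ECGRecord` objects or any objects with
    ``record_id``, ``patient_id`` and ``acquisition_date`` attributes.
    """
    rec_ids = [e.record_id for e in ecgs]
    if len(set(rec_ids)) != len(rec_ids):
        raise ValueError("duplicate ECG record_ids")
    exam_ids = [e.exam_id for e in echoes]
    if len(set(exam_ids)) != len(exam_ids):
        raise ValueError("duplicate echo exam_ids")
    for e in ecgs:
        if e.acquisition_date is None:
            raise ValueError(f"ECG {e.record_id} has no acquisition date")

    by_patient: dict[str, list] = {}
    for e in ecgs:
        by_patient.setdefault(e.patient_id, []).append(e)

    rows = []
    consumed: set[str] = set()
    for echo in sorted(echoes, key=lambda e: (e.exam_date, e.exam_id)):
        label = label_lvsd(echo.ejection_fraction)
        if label is None:
            continue
        best = None
        for ecg in by_patient.get(echo.patient_id, ()):
            if ecg.record_id in consumed:
                continue
            days = (ecg.acquisition_date - echo.exam_date).days
            if abs(days) > max_days:
                continue
            key = (abs(days), ecg.acquisition_date, ecg.record_id)
            if best is None or key < best[0]:
                best = (key, ecg, days)
        if best is None:
            continue
        _, ecg, days = best
        consumed.add(ecg.record_id)
        rows.append(
            {
                "record_id": ecg.record_id,
                "exam_id": echo.exam_id,
                "patient_id": echo.patient_id,
                "days_between": days,
                "ejection_fraction": echo.ejection_fraction,
                "lvsd_label": label,
                "split": "",
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def split_cohort(table: pd.DataFrame, ratios=(0.7, 0.15, 0.15), seed: int = 0
                 ) -> pd.DataFrame:
    """Assign train/val/test splits at the patient level.

    Unique patients are shuffled with a seeded generator and partitioned
    at the cumulative-ratio cut points, so every ECG of a patient lands
    in the same split.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError(f"ratios {ratios} do not sum to 1")
    patients = np.array(sorted(table["patient_id"].unique()))
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n = len(patients)
    cut1 = int(round(ratios[0] * n))
    cut2 = int(round((ratios[0] + ratios[1]) * n))
    assignment = {}
    for i, pid in enumerate(patients):
        assignment[pid] = "train" if i < cut1 else ("val" if i < cut2 else "test")
    out = table.copy()
    out["split"] = out["patient_id"].map(assignment)
    return out


def validate_cohort(table: pd.DataFrame) -> None:
    """Raise if a cohort table violates its invariants."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"cohort table missing columns {sorted(missing)}")
    if (table["days_between"].abs() > MAX_PAIR_DAYS).any():
        raise FormatError("pairing gap exceeds 28 days")
    if table["ejection_fraction"].isna().any():
        raise FormatError("cohort contains rows with missing ejection fraction")
    if table["record_id"].duplicated().any() or table["exam_id"].duplicated().any():
        raise FormatError("an ECG or echo appears in more than one row")
    per_patient = table.groupby("patient_id")["split"].nunique()
    if (per_patient > 1).any():
        raise FormatError("a patient appears in more than one split")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"record_id": str, "exam_id": str,
                                     "patient_id": str, "split": str})
    validate_cohort(table)
    return table


# -- fixture containers -------------------------------------------------

def write_hdf5(record: ECGRecord, path_or_group) -> None:
    """Write one record as an HDF5 group: a voltage dataset plus attrs."""
    if isinstance(path_or_group, (str, Path)):
        with h5py.File(path_or_group, "w") as f:
            write_hdf5(record, f)
        return
    g = path_or_group
    g.create_dataset("signal", data=record.signal.astype(np.float32))
    g.attrs["record_id"] = record.record_id
    g.attrs["patient_id"] = record.patient_id
    g.attrs["sampling_rate"] = record.sampling_rate
    g.attrs["lead_names"] = list(record.lead_names)
    if record.acquisition_date is not None:
        g.attrs["acquisition_date"] = record.acquisition_date.isoformat()


def read_hdf5(path_or_group) -> ECGRecord:
    if isinstance(path_or_group, (str, Path)):
        with h5py.File(path_or_group, "r") as f:
            return read_hdf5(f)
    g = path_or_group
    date = g.attrs.get("acquisition_date")
    return ECGRecord(
        record_id=str(g.attrs["record_id"]),
        patient_id=str(g.attrs["patient_id"]),
        acquisition_date=_dt.date.fromisoformat(date) if date else None,
        signal=np.asarray(g["signal"], dtype=np.float64),
        sampling_rate=int(g.attrs.get("sampling_rate", DEFAULT_SAMPLING_RATE)),
    )


def write_record_set(records, path) -> None:
    """Write many records into one HDF5 file, one group per record_id."""
    with h5py.File(path, "w") as f:
        for rec in records:
            write_hdf5(rec, f.create_group(rec.record_id))


def read_record_set(path) -> list[ECGRecord]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            out.append(read_hdf5(f[key]))
    return out


def write_csv_record(record: ECGRecord, path) -> None:
    """Delimited-text alternative for hand-made cases: columns = leads."""
    df = pd.DataFrame(record.signal.T, columns=list(record.lead_names))
    df.to_csv(path, index=False)


def read_csv_record(path, record_id="csv", patient_id="csv",
                    acquisition_date=None) -> ECGRecord:
    df = pd.read_csv(path)
    if list(df.columns) != list(LEAD_NAMES):
        raise FormatError(f"CSV columns must be {LEAD_NAMES}")
    return ECGRecord(record_id, patient_id, acquisition_date, df.to_numpy().T)
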