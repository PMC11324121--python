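"""ECG containers, WFDB reading, normalization, labeling, pairing, splits."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ecgmae import ecg_io
from ecgmae.ecg_io import (ECGRecord, EchoExam, FormatError, LEAD_NAMES,
                           RateError, label_lvsd, normalize, pair_exams,
                           read_wfdb, split_cohort, validate_cohort)
from ecgmae import wfdb_io


def _record(signal, rid="R0", pid="P0", date=None):
    return ECGRecord(rid, pid, date, signal)


class TestECGRecord:
    def test_accepts_canonical_shape(self, rng):
        rec = _record(rng.normal(size=(12, 5000)))
        assert rec.signal.shape == (12, 5000)

    @pytest.mark.parametrize("shape", [(8, 5000), (12, 4999), (12, 5001), (5000, 12)])
    def test_rejects_bad_shapes(self, rng, shape):
        with pytest.raises(FormatError):
            _record(rng.normal(size=shape))

    def test_rejects_non_finite(self, rng):
        sig = rng.normal(size=(12, 5000))
        sig[3, 17] = np.nan
        with pytest.raises(FormatError):
            _record(sig)


class TestWFDB:
    def _write(self, tmp_path, signal, names, fs=500.0):
        path = tmp_path / "rec"
        wfdb_io.write_record(path, signal, fs, names)
        return path

    def test_roundtrip_canonical(self, tmp_path, rng):
        sig = rng.normal(size=(12, 5000))
        path = self._write(tmp_path, sig, list(LEAD_NAMES))
        rec = read_wfdb(path)
        assert rec.signal.shape == (12, 5000)
        # gain 1000 quantization: within half an ADC unit
        assert np.abs(rec.signal - sig).max() < 5.1e-4

    def test_shuffled_channels_are_remapped(self, tmp_path, rng):
        sig = rng.normal(size=(12, 5000))
        order = rng.permutation(12)
        path = self._write(tmp_path, sig[order], [LEAD_NAMES[i] for i in order])
        rec = read_wfdb(path)
        assert np.abs(rec.signal - sig).max() < 5.1e-4

    def test_eight_channels_is_format_error(self, tmp_path, rng):
        path = self._write(tmp_path, rng.normal(size=(8, 5000)),
                           list(LEAD_NAMES[:8]))
        with pytest.raises(FormatError):
            read_wfdb(path)

    def test_missing_lead_name_is_format_error(self, tmp_path, rng):
        names = list(LEAD_NAMES[:11]) + ["X1"]
        path = self._write(tmp_path, rng.normal(size=(12, 5000)), names)
        with pytest.raises(FormatError):
            read_wfdb(path)

    def test_wrong_rate_raises_without_resampling(self, tmp_path, rng):
        path = self._write(tmp_path, rng.normal(size=(12, 2500)),
                           list(LEAD_NAMES), fs=250.0)
        with pytest.raises(RateError):
            read_wfdb(path)

    def test_resampling_opt_in(self, tmp_path, rng):
        path = self._write(tmp_path, rng.normal(size=(12, 2500)),
                           list(LEAD_NAMES), fs=250.0)
        rec = read_wfdb(path, resample=True)
        assert rec.signal.shape == (12, 5000)


class TestNormalize:
    def test_zscore_two_level_lead(self):
        sig = np.zeros((12, 5000))
        sig[0] = np.where(np.arange(5000) % 2 == 0, -1.0, 1.0) * 3 + 5
        out = normalize(_record(sig)).signal
        assert out[0].mean() == pytest.approx(0, abs=1e-12)
        assert out[0].std() == pytest.approx(1, abs=1e-12)

    def test_constant_lead_becomes_zeros(self, rng):
        sig = rng.normal(size=(12, 5000))
        sig[5] = 3.0
        out = normalize(_record(sig)).signal
        assert np.all(out[5] == 0.0)

    def test_idempotent(self, rng):
        rec = _record(rng.normal(size=(12, 5000)) * 2 + 0.3)
        once = normalize(rec)
        twice = normalize(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-12)
        assert np.isfinite(once.signal).all()


class TestLabelLVSD:
    @pytest.mark.parametrize("ef,expected", [
        (39.9, 1), (40.0, 0), (15.0, 1), (61.6, 0), (99.0, 0),
    ])
    def test_threshold_is_strict(self, ef, expected):
        assert label_lvsd(ef) == expected

    def test_missing_stays_missing(self):
        assert label_lvsd(None) is None
        assert label_lvsd(float("nan")) is None

    @pytest.mark.parametrize("ef", [0.0, -5.0, 100.0, 150.0])
    def test_out_of_domain_raises(self, ef):
        with pytest.raises(ValueError):
            label_lvsd(ef)


class _Meta:
    def __init__(self, rid, pid, date):
        self.record_id = rid
        self.patient_id = pid
        self.acquisition_date = date


def _day(d):
    return dt.date(2020, 6, 1) + dt.timedelta(days=d)


class TestPairExams:
    def test_nearest_ecg_wins(self):
        ecgs = [_Meta("a", "P1", _day(-3)), _Meta("b", "P1", _day(2))]
        echoes = [EchoExam("e1", "P1", _day(0), 55.0)]
        table = pair_exams(ecgs, echoes)
        assert list(table["record_id"]) == ["b"]
        assert list(table["days_between"]) == [2]

    def test_beyond_28_days_excluded(self):
        ecgs = [_Meta("a", "P1", _day(29))]
        echoes = [EchoExam("e1", "P1", _day(0), 55.0)]
        assert len(pair_exams(ecgs, echoes)) == 0

    def test_28_days_included(self):
        ecgs = [_Meta("a", "P1", _day(28))]
        echoes = [EchoExam("e1", "P1", _day(0), 55.0)]
        assert len(pair_exams(ecgs, echoes)) == 1

    def test_tie_breaks_to_earlier_ecg(self):
        ecgs = [_Meta("late", "P1", _day(2)), _Meta("early", "P1", _day(-2))]
        echoes = [EchoExam("e1", "P1", _day(0), 55.0)]
        table = pair_exams(ecgs, echoes)
        assert list(table["record_id"]) == ["early"]

    def test_one_to_one_consumption_in_echo_date_order(self):
        # the earlier echo takes the shared nearest ECG; the later one
        # falls back to the remaining ECG
        ecgs = [_Meta("a", "P1", _day(1)), _Meta("b", "P1", _day(5))]
        echoes = [
            EchoExam("late", "P1", _day(4), 50.0),
            EchoExam("early", "P1", _day(0), 30.0),
        ]
        table = pair_exams(ecgs, echoes)
        got = dict(zip(table["exam_id"], table["record_id"]))
        assert got == {"early": "a", "late": "b"}

    def test_missing_ef_produces_no_row(self):
        ecgs = [_Meta("a", "P1", _day(0))]
        echoes = [EchoExam("e1", "P1", _day(0), None)]
        assert len(pair_exams(ecgs, echoes)) == 0

    def test_duplicate_record_ids_rejected(self):
        ecgs = [_Meta("a", "P1", _day(0)), _Meta("a", "P1", _day(1))]
        with pytest.raises(ValueError):
            pair_exams(ecgs, [EchoExam("e1", "P1", _day(0), 50.0)])

    def test_labels_follow_ef(self):
        ecgs = [_Meta("a", "P1", _day(0)), _Meta("b", "P2", _day(0))]
        echoes = [EchoExam("e1", "P1", _day(0), 35.0),
                  EchoExam("e2", "P2", _day(0), 60.0)]
        table = pair_exams(ecgs, echoes)
        got = dict(zip(table["exam_id"], table["lvsd_label"]))
        assert got == {"e1": 1, "e2": 0}


class TestSplitCohort:
    def _table(self, n_patients, rows_per_patient=1):
        rows = []
        for p in range(n_patients):
            for r in range(rows_per_patient):
                rows.append({"record_id": f"R{p}_{r}", "exam_id": f"E{p}_{r}",
                             "patient_id": f"P{p}", "days_between": 0,
                             "ejection_fraction": 60.0, "lvsd_label": 0,
                             "split": ""})
        return pd.DataFrame(rows)

    def test_exact_patient_counts(self):
        table = split_cohort(self._table(1000), (0.7, 0.15, 0.15), seed=3)
        counts = table.groupby("split")["patient_id"].nunique()
        assert counts["train"] == 700
        assert counts["val"] == 150
        assert counts["test"] == 150

    def test_no_patient_in_two_splits(self):
        table = split_cohort(self._table(97, rows_per_patient=3), seed=5)
        validate_cohort(table)
        per = table.groupby("patient_id")["split"].nunique()
        assert (per == 1).all()

    def test_deterministic_per_seed(self):
        a = split_cohort(self._table(50), seed=11)
        b = split_cohort(self._table(50), seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = split_cohort(self._table(50), seed=12)
        assert not a["split"].equals(c["split"])

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            split_cohort(self._table(0))


class TestContainers:
    def test_hdf5_roundtrip(self, tmp_path, rng):
        rec = _record(rng.normal(size=(12, 5000)), date=_day(0))
        rec.acquisition_date = _day(0)
        path = tmp_path / "rec.h5"
        ecg_io.write_hdf5(rec, path)
        back = ecg_io.read_hdf5(path)
        assert back.record_id == rec.record_id
        assert back.acquisition_date == _day(0)
        np.testing.assert_allclose(back.signal, rec.signal, atol=1e-6)

    def test_record_set_roundtrip(self, tmp_path, rng):
        recs = [_record(rng.normal(size=(12, 5000)), rid=f"R{i}")
                for i in range(3)]
        path = tmp_path / "set.h5"
        ecg_io.write_record_set(recs, path)
        back = ecg_io.read_record_set(path)
        assert [r.record_id for r in back] == ["R0", "R1", "R2"]

    def test_csv_record_roundtrip(self, tmp_path, rng):
        rec = _record(rng.normal(size=(12, 5000)))
        path = tmp_path / "rec.csv"
        ecg_io.write_csv_record(rec, path)
        back = ecg_io.read_csv_record(path)
        np.testing.assert_allclose(back.signal, rec.signal, atol=1e-12)

    def test_cohort_csv_roundtrip(self, tmp_path):
        table = TestSplitCohort()._table(10)
        table = split_cohort(table, seed=0)
        path = tmp_path / "cohort.csv"
        ecg_io.write_cohort_csv(table, path)
        back = ecg_io.read_cohort_csv(path)
        assert list(back.columns) == list(ecg_io.COHORT_COLUMNS)
        assert len(back) == 10
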