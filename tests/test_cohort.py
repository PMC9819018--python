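"""Cohort model: truncation, ICD-10 classification, Lexis expansion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcmort as b
from bcmort.cohort import (
    CAUSE4,
    ICD_GROUP_LABELS,
    ClassificationError,
    CohortError,
    PatientRecord,
)
from conftest import make_cohort_frame


def rec(t, cause=None, **kw):
    args = dict(id="x", age_dx=60, year_dx=2004, stage="II", hr_status="unknown")
    args.update(kw)
    return PatientRecord(follow_time=t, event=cause is not None, cause_code=cause, **args)


class TestTruncation:
    def test_death_beyond_horizon_becomes_censoring_without_cause(self):
        out = b.truncate_follow_up(rec(11.2, "I21"))
        assert (out.follow_time, out.event, out.cause_code) == (10.0, False, None)

    def test_death_within_horizon_unchanged(self):
        r = rec(3.4, "C50")
        assert b.truncate_follow_up(r) is r

    def test_alive_at_exact_horizon_censored_at_horizon(self):
        out = b.truncate_follow_up(rec(10.0))
        assert out.follow_time == 10.0 and not out.event

    def test_death_at_exact_horizon_keeps_event(self):
        out = b.truncate_follow_up(rec(10.0, "C50"))
        assert out.event and out.cause_code == "C50"

    def test_nonpositive_follow_time_rejected(self):
        with pytest.raises(CohortError):
            b.truncate_follow_up(rec(0.0))

    @given(t=st.floats(0.01, 40.0), horizon=st.floats(1.0, 15.0))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, t, horizon):
        r = rec(t, "C50")
        once = b.truncate_follow_up(r, horizon)
        assert b.truncate_follow_up(once, horizon) == once

    def test_cohort_frame_truncation_matches_record_level(self):
        df = make_cohort_frame(
            [("a", 50, 2001, "I", "unknown", 12.5, "I21"), ("b", 50, 2001, "I", "unknown", 2.5, "C50")]
        )
        out = b.truncate_cohort(df)
        assert out.loc[0, "follow_time"] == 10.0 and not out.loc[0, "event"]
        assert out.loc[1, "follow_time"] == 2.5 and out.loc[1, "event"]


class TestClassifyCause:
    @pytest.mark.parametrize(
        "code, broad, chapter",
        [
            ("C50", "BC", "Tumours"),
            ("C56", "OtherCancer", "Tumours"),  # ovarian cancer
            ("I50", "CVD", "Cardiovascular disease"),  # heart failure
            ("C509", "BC", "Tumours"),
            ("D48", "OtherCancer", "Tumours"),
            ("D64", "OtherCauses", "Diseases of the blood"),
            ("E11", "OtherCauses", "Endocrine, nutritional-metabolic diseases"),
            ("G30", "OtherCauses", "Nervous system/organs of the senses"),
            ("J44", "OtherCauses", "Respiratory system"),
            ("K74", "OtherCauses", "Digestive system"),
            ("N18", "OtherCauses", "Genitourinary system"),
            ("Q24", "OtherCauses", "Congenital malformations"),
            ("R99", "OtherCauses", "Symptoms, signs and abnormal findings"),
            ("X59", "OtherCauses", "External causes"),
            ("Z99", "OtherCauses", "Other and unclassified"),
        ],
    )
    def test_examples(self, code, broad, chapter):
        assert b.classify_cause(code) == (broad, chapter)

    @pytest.mark.parametrize("bad", ["", "5C0", "cancer", "C5", None])
    def test_unparseable_code_raises_with_code_echoed(self, bad):
        with pytest.raises(ClassificationError):
            b.classify_cause(bad)

    @given(
        letter=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ"),
        num=st.integers(0, 99),
        sub=st.sampled_from(["", "0", "9", ".4"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_function_and_exhaustive_partitions(self, letter, num, sub):
        broad, chapter = b.classify_cause(f"{letter}{num:02d}{sub}")
        assert broad in CAUSE4
        assert chapter in ICD_GROUP_LABELS


class TestLexis:
    def test_aligned_origin_diagonal_traversal(self):
        df = make_cohort_frame([("a", 59, 2005, "I", "unknown", 2.0, None)])
        lt = b.tabulate_person_years(df, entry_offset=0.0)
        assert lt.cells == {(59, 2005): 1.0, (60, 2006): 1.0}

    def test_midyear_entry_splits_cells(self):
        df = make_cohort_frame([("a", 59, 2005, "I", "unknown", 2.0, None)])
        lt = b.tabulate_person_years(df)
        assert lt.cells == pytest.approx(
            {(59, 2005): 0.5, (59, 2006): 0.5, (60, 2006): 0.5, (60, 2007): 0.5}
        )

    def test_empty_cohort(self):
        empty = pd.DataFrame(columns=b.cohort.COHORT_COLUMNS)
        lt = b.tabulate_person_years(empty)
        assert lt.cells == {} and lt.total == 0.0

    def test_three_patient_fractional_times_match_brute_force(self):
        rows = [
            ("a", 59, 2005, "I", "unknown", 2.3, None),
            ("b", 72, 2008, "II", "unknown", 0.4, None),
            ("c", 44, 2000, "III", "unknown", 7.85, None),
        ]
        df = make_cohort_frame(rows)
        lt = b.tabulate_person_years(df)

        # independent brute force: integrate each subject's path in tiny steps
        cells = {}
        dt = 1e-4
        for r in rows:
            age0, year0, T = r[1], r[2] + 0.5, r[5]
            steps = np.arange(0, T, dt)
            for t in steps:
                key = (int(np.floor(age0 + t + dt / 2)), int(np.floor(year0 + t + dt / 2)))
                cells[key] = cells.get(key, 0.0) + dt
        assert set(lt.cells) == set(cells)
        for key in cells:
            assert lt.cells[key] == pytest.approx(cells[key], abs=5e-4)

    @given(
        ages=st.lists(st.integers(15, 84), min_size=1, max_size=6),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_person_year_conservation(self, ages, data):
        times = [
            data.draw(st.floats(0.01, 10.0, allow_nan=False)) for _ in ages
        ]
        years = [data.draw(st.integers(2000, 2009)) for _ in ages]
        df = make_cohort_frame(
            [(str(i), a, y, "I", "unknown", t, None) for i, (a, y, t) in enumerate(zip(ages, years, times))]
        )
        lt = b.tabulate_person_years(df)
        assert lt.total == pytest.approx(sum(times), abs=1e-9)
        assert all(v >= 0 for v in lt.cells.values())

    def test_wide_bands(self):
        df = make_cohort_frame([("a", 62, 2003, "I", "unknown", 6.0, None)])
        lt = b.tabulate_person_years(df, age_band_width=5, year_band_width=5, entry_offset=0.0)
        # ages 62->68 cross the 65 edge at t=3; years 2003->2009 cross 2005 at t=2
        assert lt.cells == pytest.approx({(60, 2000): 2.0, (60, 2005): 1.0, (65, 2005): 3.0})
        assert lt.total == pytest.approx(6.0, abs=1e-9)


class TestIO:
    def test_roundtrip(self, tmp_path, toy5):
        path = tmp_path / "cohort.csv"
        b.write_cohort(toy5, path)
        back = b.read_cohort(path)
        assert len(back) == len(toy5)
        assert back["event"].tolist() == toy5["event"].tolist()
        assert back.loc[0, "cause_code"] == "C50"
        assert back["follow_time"].tolist() == toy5["follow_time"].tolist()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(CohortError):
            b.read_cohort(path)
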