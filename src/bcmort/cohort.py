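"""Cohort data model: follow-up truncation, ICD-10 cause grouping, Lexis expansion.

The analyses in this package operate on a registry-style cohort of breast-cancer
patients.  Each woman enters at diagnosis (age 15-84, calendar years 2000-2009 by
default) and is followed for at most ``HORIZON`` years; a death after the horizon
is administratively censored and its cause discarded.  Deaths are classified both
into four broad competing-cause categories (breast cancer / other cancer /
cardiovascular / other) and into ICD-10 chapter groups used for cause-specific
standardized mortality ratios.

The canonical in-memory container for a cohort is a :class:`pandas.DataFrame`
with columns ``id, age_dx, year_dx, stage, hr_status, follow_time, event,
cause_code``; :class:`PatientRecord` is the record-level view.  All public
functions accept either form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants & configuration
# ---------------------------------------------------------------------------

HORIZON = 10.0  # years of follow-up after which everyone is censored

STAGES = ("I", "II", "III", "IV", "missing")
HR_STATUSES = ("positive", "negative", "unknown")

#: four broad competing causes of death
CAUSE4 = ("BC", "OtherCancer", "CVD", "OtherCauses")

AGE_MIN, AGE_MAX = 15, 84

#: diagnosis dates are known to the year only; mid-year entry is the
#: unbiased default when expanding person-years over the Lexis diagram
MIDYEAR_OFFSET = 0.5

COHORT_COLUMNS = [
    "id",
    "age_dx",
    "year_dx",
    "stage",
    "hr_status",
    "follow_time",
    "event",
    "cause_code",
]


class CohortError(ValueError):
    """Invalid patient record or cohort-level input."""


class ClassificationError(ValueError):
    """Unparseable ICD-10 cause-of-death code."""


# ---------------------------------------------------------------------------
# patient records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One subject: diagnosis covariates, follow-up and (possibly) cause of death.

    ``follow_time`` is years since diagnosis; after truncation it lies in
    ``(0, horizon]``.  ``event`` is True when the subject died *within* the
    follow-up window, in which case ``cause_code`` carries the ICD-10 code of
    the primary cause of death.
    """

    id: str
    age_dx: int
    year_dx: int
    stage: str
    hr_status: str
    follow_time: float
    event: bool
    cause_code: str | None = None

    def validate(self) -> None:
        if not self.follow_time > 0:
            raise CohortError(f"record {self.id}: nonpositive follow_time {self.follow_time}")
        if not (AGE_MIN <= self.age_dx <= AGE_MAX):
            raise CohortError(f"record {self.id}: age_dx {self.age_dx} outside [{AGE_MIN}, {AGE_MAX}]")
        if self.stage not in STAGES:
            raise CohortError(f"record {self.id}: unknown stage {self.stage!r}")
        if self.hr_status not in HR_STATUSES:
            raise CohortError(f"record {self.id}: unknown hr_status {self.hr_status!r}")
        if self.event and not self.cause_code:
            raise CohortError(f"record {self.id}: event without cause_code")


def truncate_follow_up(record: PatientRecord, horizon: float = HORIZON) -> PatientRecord:
    """Apply administrative truncation at ``horizon`` years after diagnosis.

    A death beyond the horizon becomes a censoring at the horizon and its cause
    is discarded; a death at exactly the horizon still counts as an event.
    Idempotent.
    """
    if horizon <= 0:
        raise CohortError(f"horizon must be positive, got {horizon}")
    if not record.follow_time > 0:
        raise CohortError(f"record {record.id}: nonpositive follow_time {record.follow_time}")
    if record.follow_time > horizon:
        return replace(record, follow_time=horizon, event=False, cause_code=None)
    return record


def truncate_cohort(cohort: pd.DataFrame, horizon: float = HORIZON) -> pd.DataFrame:
    """Vectorised :func:`truncate_follow_up` over a cohort frame."""
    if horizon <= 0:
        raise CohortError(f"horizon must be positive, got {horizon}")
    if (cohort["follow_time"] <= 0).any():
        bad = cohort.loc[cohort["follow_time"] <= 0, "id"].tolist()[:5]
        raise CohortError(f"nonpositive follow_time for records {bad}")
    out = cohort.copy()
    over = out["follow_time"] > horizon
    out.loc[over, "follow_time"] = horizon
    out.loc[over, "event"] = False
    out.loc[over, "cause_code"] = None
    return out


def as_cohort_frame(cohort) -> pd.DataFrame:
    """Normalise a cohort (DataFrame or iterable of PatientRecord) to a frame."""
    if isinstance(cohort, pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
        if missing:
            raise CohortError(f"cohort frame missing columns {missing}")
        return cohort
    records = list(cohort)
    for r in records:
        r.validate()
    return pd.DataFrame(
        [
            (r.id, r.age_dx, r.year_dx, r.stage, r.hr_status, r.follow_time, r.event, r.cause_code)
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# ICD-10 cause classification
# ---------------------------------------------------------------------------

_ICD_RE = re.compile(r"^([A-Z])(\d{2})")


def _icd_key(code: str) -> tuple[str, int]:
    """Parse an ICD-10 code into an orderable (letter, 2-digit number) key."""
    if not isinstance(code, str):
        raise ClassificationError(f"not an ICD-10 code: {code!r}")
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ClassificationError(f"unparseable ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


#: ICD-10 chapter groups used for cause-specific SMRs.  Ranges are inclusive
#: on three-character rubrics.  ``Tumours`` deliberately spans C00-D49; the
#: breast-cancer rubric C50 is singled out upstream (it is the index disease,
#: never an SMR cause).  Chapters not named here (O, P, S-T, U, Z and the
#: eye/ear blocks folded into the nervous-system group) fall into a catch-all
#: so the grouping is a total function on valid codes.
ICD_GROUPS: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
    ("Infectious diseases", (("A00", "B99"),)),
    ("Tumours", (("C00", "D49"),)),
    ("Diseases of the blood", (("D50", "D89"),)),
    ("Endocrine, nutritional-metabolic diseases", (("E00", "E89"),)),
    ("Mental and behavioural disorders", (("F00", "F99"),)),
    ("Nervous system/organs of the senses", (("G00", "H95"),)),
    ("Cardiovascular disease", (("I00", "I99"),)),
    ("Respiratory system", (("J00", "J99"),)),
    ("Digestive system", (("K00", "K95"),)),
    ("Skin and subcutaneous tissue", (("L00", "L99"),)),
    ("Musculoskeletal system", (("M00", "M99"),)),
    ("Genitourinary system", (("N00", "N99"),)),
    ("Congenital malformations", (("Q00", "Q99"),)),
    ("Symptoms, signs and abnormal findings", (("R00", "R99"),)),
    ("External causes", (("V01", "Y98"),)),
)

ICD_OTHER_GROUP = "Other and unclassified"

ICD_GROUP_LABELS = tuple(label for label, _ in ICD_GROUPS) + (ICD_OTHER_GROUP,)


def classify_cause(
    cause_code: str,
    icd_groups: Iterable[tuple[str, Iterable[tuple[str, str]]]] = ICD_GROUPS,
) -> tuple[str, str]:
    """Classify an ICD-10 cause of death.

    Returns ``(broad, chapter)`` where ``broad`` is one of :data:`CAUSE4`
    (C50 -> BC; other C00-D49 -> OtherCancer; I00-I99 -> CVD; everything else
    OtherCauses) and ``chapter`` is the ICD-10 chapter-group label.  Both
    partitions are exhaustive on syntactically valid codes.
    """
    key = _icd_key(cause_code)

    chapter = ICD_OTHER_GROUP
    for label, ranges in icd_groups:
        if any(_icd_key(lo) <= key <= _icd_key(hi) for lo, hi in ranges):
            chapter = label
            break

    if key == ("C", 50):
        broad = "BC"
    elif _icd_key("C00") <= key <= _icd_key("D49"):
        broad = "OtherCancer"
    elif key[0] == "I":
        broad = "CVD"
    else:
        broad = "OtherCauses"
    return broad, chapter


def classify_cohort(cohort) -> pd.DataFrame:
    """Attach ``cause4`` and ``cause_icd`` columns to a truncated cohort frame."""
    df = as_cohort_frame(cohort).copy()
    broad = np.full(len(df), None, dtype=object)
    chapter = np.full(len(df), None, dtype=object)
    ev = df["event"].to_numpy(dtype=bool)
    codes = df["cause_code"].to_numpy(dtype=object)
    # classify unique codes once; cohorts repeat a small code pool
    uniq = {c: classify_cause(c) for c in set(codes[ev])}
    for i in np.flatnonzero(ev):
        broad[i], chapter[i] = uniq[codes[i]]
    df["cause4"] = broad
    df["cause_icd"] = chapter
    return df


# ---------------------------------------------------------------------------
# Lexis expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexisTable:
    """Person-years at risk cross-classified by age band x calendar year band.

    ``cells`` maps ``(age_band_start, year_band_start)`` to person-years.
    Band starts are the lower edges (e.g. ``(59, 2005)`` for 1-year bands).
    """

    cells: Mapping[tuple[int, int], float]
    age_band_width: int = 1
    year_band_width: int = 1

    @property
    def total(self) -> float:
        return float(sum(self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, y, py) for (a, y), py in sorted(self.cells.items())]
        return pd.DataFrame(rows, columns=["age_band", "year", "person_years"])


def tabulate_person_years(
    cohort,
    age_band_width: int = 1,
    year_band_width: int = 1,
    entry_offset: float = MIDYEAR_OFFSET,
) -> LexisTable:
    """Split each subject's follow-up across the Lexis cells it traverses.

    Subjects age continuously from their (integer) age at diagnosis while
    calendar time advances from ``year_dx + entry_offset`` (mid-year by
    default, reflecting year-resolution diagnosis dates).  Each follow-up
    interval is partitioned exactly at every age-band and calendar-band
    boundary it crosses, so cell totals conserve total person-time.
    """
    if age_band_width < 1 or year_band_width < 1:
        raise CohortError("band widths must be >= 1 year")
    df = as_cohort_frame(cohort)
    if len(df) == 0:
        return LexisTable({}, age_band_width, year_band_width)
    if (df["follow_time"] <= 0).any():
        raise CohortError("cohort contains nonpositive follow_time")

    age0 = df["age_dx"].to_numpy(dtype=float)
    cal0 = df["year_dx"].to_numpy(dtype=float) + entry_offset
    T = df["follow_time"].to_numpy(dtype=float)
    n = len(df)
    wa, wy = float(age_band_width), float(year_band_width)

    # candidate breakpoints: times at which age (resp. calendar time) crosses
    # a band edge; enough of them to cover the longest follow-up
    ja = int(np.ceil(T.max() / wa)) + 1
    jy = int(np.ceil(T.max() / wy)) + 1
    t_age = (np.floor(age0 / wa)[:, None] + np.arange(1, ja + 1)) * wa - age0[:, None]
    t_cal = (np.floor(cal0 / wy)[:, None] + np.arange(1, jy + 1)) * wy - cal0[:, None]
    brk = np.concatenate(
        [np.zeros((n, 1)), t_age, t_cal, T[:, None]], axis=1
    )
    brk = np.clip(brk, 0.0, T[:, None])
    brk.sort(axis=1)
    seg = np.diff(brk, axis=1)  # (n, m) segment lengths, zeros where clipped
    mid = (brk[:, :-1] + brk[:, 1:]) / 2.0

    keep = seg > 0
    if not keep.any():
        return LexisTable({}, age_band_width, year_band_width)
    ages = (np.floor((age0[:, None] + mid) / wa) * wa).astype(int)[keep]
    years = (np.floor((cal0[:, None] + mid) / wy) * wy).astype(int)[keep]
    lengths = seg[keep]

    tab = pd.DataFrame({"a": ages, "y": years, "py": lengths}).groupby(["a", "y"])["py"].sum()
    cells = {(int(a), int(y)): float(v) for (a, y), v in tab.items()}
    return LexisTable(cells, age_band_width, year_band_width)


# ---------------------------------------------------------------------------
# delimited I/O
# ---------------------------------------------------------------------------


def read_cohort(path) -> pd.DataFrame:
    """Read a patient table (CSV: id, age_dx, year_dx, stage, hr_status,
    follow_time, vital_status, cause_code)."""
    df = pd.read_csv(path, dtype={"id": str, "cause_code": str}, keep_default_na=True)
    required = ["id", "age_dx", "year_dx", "stage", "hr_status", "follow_time", "vital_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"patient table missing columns {missing}")
    out = pd.DataFrame(
        {
            "id": df["id"],
            "age_dx": df["age_dx"].astype(int),
            "year_dx": df["year_dx"].astype(int),
            "stage": df["stage"].fillna("missing"),
            "hr_status": df["hr_status"].fillna("unknown"),
            "follow_time": df["follow_time"].astype(float),
            "event": df["vital_status"].str.strip().str.lower().eq("died"),
            "cause_code": df.get("cause_code", pd.Series([None] * len(df))).where(
                lambda s: s.notna(), None
            ),
        }
    )
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    df = as_cohort_frame(cohort)
    out = df[["id", "age_dx", "year_dx", "stage", "hr_status", "follow_time"]].copy()
    out["vital_status"] = np.where(df["event"], "died", "alive")
    out["cause_code"] = df["cause_code"].fillna("")
    out.to_csv(path, index=False)
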