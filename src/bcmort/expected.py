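"""Observed and expected death counts per cause group.

The standardized mortality ratio compares the deaths observed in the cohort
(O_c) within 10 years of diagnosis with the deaths expected (E_c) had the
cohort experienced reference-population cause-specific rates:

    E_c = sum over Lexis cells of person_years x rate(cause, age band, year).

The index disease (breast cancer) is never an SMR cause: the all-cause
aggregate is "all causes except breast cancer", while women dying of breast
cancer still contribute person-years up to their death (standard indirect-
standardisation convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CAUSE4, ICD_GROUP_LABELS, LexisTable, classify_cohort

ALL_EXCEPT_BC = "All causes (except breast cancer)"

#: broad causes that enter SMR analyses (the index disease is excluded)
SMR_CAUSES4 = ("OtherCancer", "CVD", "OtherCauses")


class CoverageError(ValueError):
    """A Lexis cell has no covering reference-rate cell."""


class CountsError(ValueError):
    pass


@dataclass(frozen=True)
class CauseCount:
    """Observed and expected deaths for one cause group and cohort."""

    cause: str
    observed: int
    expected: float
    cohort_label: str = ""

    def __post_init__(self):
        if self.observed < 0:
            raise CountsError(f"{self.cause}: negative observed count")
        if not self.expected > 0:
            raise CountsError(
                f"{self.cause} ({self.cohort_label or 'cohort'}): expected deaths must be "
                f"strictly positive, got {self.expected} (zero expected invalidates the SMR)"
            )


def observed_count(cohort, cause: str) -> int:
    """Count truncated-cohort deaths classified into ``cause``.

    ``cause`` may be a broad label (BC/OtherCancer/CVD/OtherCauses), an ICD-10
    chapter-group label, or the all-except-breast-cancer aggregate.
    """
    df = cohort if "cause4" in getattr(cohort, "columns", []) else classify_cohort(cohort)
    if cause == ALL_EXCEPT_BC:
        return int((df["event"] & (df["cause4"] != "BC")).sum())
    if cause in CAUSE4:
        return int((df["cause4"] == cause).sum())
    if cause in ICD_GROUP_LABELS:
        # breast-cancer deaths are the index disease, not a competing chapter
        return int(((df["cause_icd"] == cause) & (df["cause4"] != "BC")).sum())
    raise CountsError(f"unknown cause label {cause!r}")


def _rate_lookup(rates: pd.DataFrame, cause: str) -> dict[int, tuple]:
    """Index the rate rows of one cause as year -> sorted age bands."""
    sub = rates[rates["cause"] == cause]
    if len(sub) == 0:
        raise CoverageError(f"no reference rates for cause {cause!r}")
    lookup = {}
    for year, grp in sub.groupby("year"):
        grp = grp.sort_values("age_low")
        lookup[int(year)] = (
            grp["age_low"].to_numpy(),
            grp["age_high"].to_numpy(),
            grp["rate"].to_numpy(dtype=float),
        )
    return lookup


def expected_count(lexis: LexisTable, rates: pd.DataFrame, cause: str) -> float:
    """E_c = sum over Lexis cells of person-years x covering reference rate.

    Each (age, year) cell must fall inside a rate row's [age_low, age_high]
    band; the calendar year is matched exactly, falling back to the nearest
    available year at the table edges.  Cells no rate row covers raise
    :class:`CoverageError` listing the orphans.
    """
    if cause == ALL_EXCEPT_BC:
        return sum(expected_count(lexis, rates, c) for c in SMR_CAUSES4)
    lookup = _rate_lookup(rates, cause)
    years = sorted(lookup)

    total = 0.0
    orphans = []
    for (age, year), py in lexis.cells.items():
        if py == 0:
            continue
        y = year if year in lookup else min(years, key=lambda v: abs(v - year))
        age_low, age_high, rate = lookup[y]
        # the Lexis cell spans [age, age + width); require full band containment
        i = int(age_low.searchsorted(age, side="right")) - 1
        if i < 0 or age + lexis.age_band_width - 1 > age_high[i]:
            orphans.append((age, year))
            continue
        total += py * float(rate[i])
    if orphans:
        raise CoverageError(f"no covering rate cell for Lexis cells {orphans[:10]} (cause {cause!r})")
    return total


def counts_table(
    cohort,
    lexis: LexisTable,
    rates: pd.DataFrame,
    causes=None,
    cohort_label: str = "",
) -> list[CauseCount]:
    """Build the (O_c, E_c) inputs of the Bayesian SMR model.

    By default covers the all-except-breast-cancer aggregate plus every cause
    label present in the rate table (skipping causes with zero expected, which
    cannot enter an SMR).
    """
    df = classify_cohort(cohort)
    if causes is None:
        causes = [ALL_EXCEPT_BC] + [
            c for c in rates["cause"].unique() if c in ICD_GROUP_LABELS or c in SMR_CAUSES4
        ]
    out = []
    for cause in causes:
        e = expected_count(lexis, rates, cause)
        if e <= 0 and cause != ALL_EXCEPT_BC:
            continue  # a cause absent from the reference population has no SMR
        # CauseCount itself refuses a nonpositive aggregate expectation
        out.append(CauseCount(cause, observed_count(df, cause), e, cohort_label))
    return out


def counts_to_frame(counts: list[CauseCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cause, c.cohort_label, c.observed, c.expected) for c in counts],
        columns=["cause", "cohort_label", "observed", "expected"],
    )


def read_counts(path) -> list[CauseCount]:
    df = pd.read_csv(path)
    return [
        CauseCount(r["cause"], int(r["observed"]), float(r["expected"]), str(r.get("cohort_label", "")))
        for _, r in df.iterrows()
    ]
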