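"""Descriptive summaries, table rendering, and the end-to-end pipeline.

Renders the three analysis products of the package as delimited tables:

* a cohort-characteristics summary with period comparison (chi-square /
  Welch t tests, Holm-corrected pairwise proportion comparisons);
* the cause-specific SMR comparison between diagnostic periods (observed
  deaths, cause shares, posterior SMR summaries, and the between-period
  ratio);
* the competing-risks products: HR- vs HR+ relative risks per stage and the
  10-year cause-specific probabilities of death per (stage, HR, age group)
  profile.

``run_pipeline`` chains every stage (truncate -> classify -> Lexis ->
expected deaths -> Bayesian SMR -> competing risks -> rendering) and is
deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import competing, expected, simulate, smr as smr_mod
from .cohort import (
    CAUSE4,
    HORIZON,
    STAGES,
    classify_cohort,
    read_cohort,
    tabulate_person_years,
    truncate_cohort,
    write_cohort,
)

logger = logging.getLogger("bcmort")

PERIODS = ((2000, 2004), (2005, 2009))


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# rounding / percentage helpers (single source of table arithmetic)
# ---------------------------------------------------------------------------


def pct(numerator: float, denominator: float, dp: int = 1) -> float:
    """Percentage of numerator over denominator, rounded to ``dp`` decimals."""
    if denominator == 0:
        return float("nan")
    # plain-float rounding: numpy scalars round ties differently
    return round(float(100.0 * numerator / denominator), dp)


def round2(x: float) -> float:
    return round(float(x), 2)


def plugin_ratio(smr2: float, smr1: float, dp: int = 2) -> float:
    """Plug-in ratio of two point estimates (e.g. period SMR medians)."""
    if smr1 == 0:
        return float("nan")
    return round(smr2 / smr1, dp)


# ---------------------------------------------------------------------------
# descriptive summary (cohort characteristics)
# ---------------------------------------------------------------------------

_CAUSE_LABELS = {
    "BC": "Breast cancer",
    "OtherCancer": "Other cancer",
    "CVD": "Cardiovascular disease",
    "OtherCauses": "Other causes",
}


def _period_label(period: tuple[int, int]) -> str:
    return f"{period[0]}-{period[1]}"


def _section_counts(df: pd.DataFrame, column: str, levels) -> pd.Series:
    return df[column].value_counts().reindex(levels).fillna(0).astype(int)


def describe_cohort(cohort, periods=PERIODS) -> pd.DataFrame:
    """Cohort characteristics with period split and comparison tests.

    Categorical sections (age group, stage, cause of death, molecular
    subtype) report counts and column percentages per period with a
    chi-square test; continuous ones (age, follow-up) report mean (SD) with
    a Welch t test.  Every percentage is derived from the printed counts.
    """
    df = classify_cohort(cohort).copy()
    df["age_grp"] = df["age_dx"].map(competing.age_group)
    df["outcome"] = np.where(df["event"], df["cause4"].astype(str), "Alive")
    parts = [df[(df["year_dx"] >= a) & (df["year_dx"] <= b)] for a, b in periods]
    labels = [_period_label(p) for p in periods]

    rows = []

    def add_categorical(section, column, levels, display=None):
        tot = _section_counts(df, column, levels)
        per = [_section_counts(p, column, levels) for p in parts]
        table = np.array([c.to_numpy() for c in per])
        keep = table.sum(axis=0) > 0
        p_value = np.nan
        if keep.sum() > 1 and all(t.sum() > 0 for t in table):
            p_value = sps.chi2_contingency(table[:, keep])[1]
        for i, lev in enumerate(levels):
            rows.append(
                {
                    "section": section,
                    "level": (display or {}).get(lev, lev),
                    "total_n": int(tot[lev]),
                    "total_pct": pct(tot[lev], len(df)),
                    **{
                        f"{lab}_n": int(per[j][lev])
                        for j, lab in enumerate(labels)
                    },
                    **{
                        f"{lab}_pct": pct(per[j][lev], len(parts[j]))
                        for j, lab in enumerate(labels)
                    },
                    "p_value": p_value if i == 0 else np.nan,
                }
            )

    def add_continuous(section, column):
        x = [p[column].to_numpy(dtype=float) for p in parts]
        p_value = sps.ttest_ind(x[0], x[1], equal_var=False)[1] if all(len(v) > 1 for v in x) else np.nan
        rows.append(
            {
                "section": section,
                "level": "mean (SD)",
                "total_n": len(df),
                "total_pct": round(df[column].mean(), 1),
                **{f"{lab}_n": len(parts[j]) for j, lab in enumerate(labels)},
                **{f"{lab}_pct": round(parts[j][column].mean(), 1) for j, lab in enumerate(labels)},
                "p_value": p_value,
            }
        )

    add_continuous("Age", "age_dx")
    add_categorical("Age group", "age_grp", list(competing.AGE_GROUPS))
    add_categorical("Stage", "stage", list(STAGES))
    add_categorical(
        "Cause of death",
        "outcome",
        ["BC", "OtherCancer", "CVD", "OtherCauses", "Alive"],
        display=_CAUSE_LABELS,
    )
    add_continuous("Follow-up (years)", "follow_time")
    add_categorical("Molecular subtype", "hr_status", ["positive", "negative", "unknown"])
    return pd.DataFrame(rows)


def pairwise_period_tests(summary: pd.DataFrame, section: str, periods=PERIODS) -> pd.DataFrame:
    """Holm-corrected two-proportion z tests per level of one section."""
    labels = [_period_label(p) for p in periods]
    sub = summary[summary["section"] == section]
    raw, levels = [], []
    n_tot = [int(sub[f"{lab}_n"].sum()) for lab in labels]
    for _, row in sub.iterrows():
        k = [int(row[f"{lab}_n"]) for lab in labels]
        if sum(k) == 0:
            continue
        table = np.array([[k[0], n_tot[0] - k[0]], [k[1], n_tot[1] - k[1]]])
        raw.append(sps.chi2_contingency(table, correction=True)[1])
        levels.append(row["level"])
    adj = multipletests(raw, method="holm")[1] if raw else []
    return pd.DataFrame({"level": levels, "p_raw": raw, "p_holm": adj})


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------


def render_table2(
    counts1: list[expected.CauseCount],
    counts2: list[expected.CauseCount],
    post1: dict[str, smr_mod.SMRPosterior],
    post2: dict[str, smr_mod.SMRPosterior],
    ratios: dict[str, smr_mod.RatioPosterior],
) -> pd.DataFrame:
    """SMR comparison between periods, one row per cause group.

    Cause shares are percentages of each period's non-breast-cancer death
    total; SMR summaries and ratios are rounded to 2 decimals.
    """
    o1 = {c.cause: c.observed for c in counts1}
    o2 = {c.cause: c.observed for c in counts2}
    tot1 = o1.get(expected.ALL_EXCEPT_BC, sum(o1.values()))
    tot2 = o2.get(expected.ALL_EXCEPT_BC, sum(o2.values()))
    rows = []
    for cause in [c.cause for c in counts1]:
        p1, p2 = post1.get(cause), post2.get(cause)
        r = ratios.get(cause)
        rows.append(
            {
                "cause": cause,
                "O_1": o1.get(cause, 0),
                "pct_1": pct(o1.get(cause, 0), tot1),
                "SMR_1": round2(p1.smr_median) if p1 else np.nan,
                "CrI_1_low": round2(p1.cri95[0]) if p1 else np.nan,
                "CrI_1_high": round2(p1.cri95[1]) if p1 else np.nan,
                "P_SMR_1": round2(p1.p_smr) if p1 else np.nan,
                "O_2": o2.get(cause, 0),
                "pct_2": pct(o2.get(cause, 0), tot2),
                "SMR_2": round2(p2.smr_median) if p2 else np.nan,
                "CrI_2_low": round2(p2.cri95[0]) if p2 else np.nan,
                "CrI_2_high": round2(p2.cri95[1]) if p2 else np.nan,
                "P_SMR_2": round2(p2.p_smr) if p2 else np.nan,
                "Ratio": round2(r.ratio_median) if r else np.nan,
                "P_Ratio": round2(r.p_ratio) if r else np.nan,
            }
        )
    return pd.DataFrame(rows)


def render_table3(rrs: dict[str, dict[str, competing.RelativeRisk]]) -> pd.DataFrame:
    """HR- vs HR+ relative risks (with 95% CI) per stage and outcome."""
    rows = []
    for stage, per_outcome in rrs.items():
        row = {"stage": stage}
        for outcome, rr in per_outcome.items():
            row[f"RR_{outcome}"] = round2(rr.rr)
            row[f"CI_{outcome}_low"] = round2(rr.ci95[0])
            row[f"CI_{outcome}_high"] = round2(rr.ci95[1])
        rows.append(row)
    return pd.DataFrame(rows)


def render_table4(
    curves: dict[tuple[str, str, str], competing.CIMCurve],
    T: float = HORIZON,
    causes=CAUSE4,
) -> pd.DataFrame:
    """10-year cause-specific probabilities of death (%) per profile.

    ``curves`` maps (stage, hr, age_group) to a predicted curve.  For each
    (stage, age group) with both HR levels, a ratio row HR-/HR+ is added;
    ratios are computed from the unrounded probabilities.
    """
    rows = []
    for (stage, hr, agegrp), curve in curves.items():
        vals = curve.at(T)
        row = {"stage": stage, "hr": hr, "age_group": agegrp}
        for c in causes:
            row[f"P_{c}"] = round(100 * vals[c], 2)
        row["Total"] = round(100 * total_from_values(vals, causes), 2)
        rows.append(row)
    out = pd.DataFrame(rows)

    ratio_rows = []
    for stage in out["stage"].unique():
        for agegrp in out.loc[out["stage"] == stage, "age_group"].unique():
            neg = [
                k for k in curves if k[0] == stage and k[2] == agegrp and k[1] == "negative"
            ]
            pos = [
                k for k in curves if k[0] == stage and k[2] == agegrp and k[1] == "positive"
            ]
            if not (neg and pos):
                continue
            vn, vp = curves[neg[0]].at(T), curves[pos[0]].at(T)
            row = {"stage": stage, "hr": "ratio -/+", "age_group": agegrp}
            for c in causes:
                row[f"P_{c}"] = round2(vn[c] / vp[c]) if vp[c] > 0 else np.nan
            tn, tp = total_from_values(vn, causes), total_from_values(vp, causes)
            row["Total"] = round2(tn / tp) if tp > 0 else np.nan
            ratio_rows.append(row)
    return pd.concat([out, pd.DataFrame(ratio_rows)], ignore_index=True)


def total_from_values(vals: dict[str, float], causes=CAUSE4) -> float:
    return float(sum(vals[c] for c in causes))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    patient_table: str | None = None  # None: simulate
    rates_table: str | None = None
    out_dir: str = "bcmort_out"
    seed: int = 0
    horizon: float = HORIZON
    periods: tuple[tuple[int, int], tuple[int, int]] = PERIODS
    n_patients: int = simulate.DEFAULT_N
    smr_spec: smr_mod.SMRModelSpec = field(default_factory=smr_mod.SMRModelSpec)
    age_adjust_table3: str = "continuous"
    age_adjust_table4: str = "categorical"
    table4_stages: tuple[str, ...] = ("I", "II", "III", "IV")
    verbosity: int = logging.INFO

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "smr_spec":
                cfg.smr_spec = smr_mod.SMRModelSpec(**value)
            elif key == "periods":
                cfg.periods = tuple(tuple(p) for p in value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise PipelineError(f"unknown config key {key!r}")
        return cfg


def _stage(name: str):
    """Decorator-free stage wrapper: time a stage and name it on failure."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write its artifact bundle to out_dir.

    Stages: input (load or simulate) -> truncation/classification ->
    descriptive summary -> Lexis/expected deaths -> Bayesian SMR with period
    ratio -> competing risks (relative risks, profile probabilities,
    nonparametric curves) -> rendered tables + manifest.  Deterministic under
    a fixed config.
    """
    logging.basicConfig(level=config.verbosity, format="%(name)s %(levelname)s %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_of = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))
    artifacts: dict = {"out_dir": str(out_dir)}

    with _stage("input"):
        if config.patient_table is None:
            sim_cfg = simulate.SimulationConfig(n_patients=config.n_patients, seed=seed_of(0))
            cohort, truth = simulate.generate_cohort(sim_cfg)
            rates = simulate.generate_reference_rates(sim_cfg)
            write_cohort(cohort, out_dir / "cohort.csv")
            simulate.write_rates(rates, out_dir / "reference_rates.csv")
            artifacts["ground_truth"] = truth
        else:
            cohort = read_cohort(config.patient_table)
            if config.rates_table is None:
                raise ValueError("rates_table is required when patient_table is given")
            rates = simulate.read_rates(config.rates_table)
        logger.info("cohort: %d records", len(cohort))

    with _stage("cohort_model"):
        cohort = truncate_cohort(cohort, config.horizon)
        cohort = classify_cohort(cohort)

    with _stage("describe"):
        table1 = describe_cohort(cohort, config.periods)
        table1.to_csv(out_dir / "table1.csv", index=False)
        artifacts["table1"] = table1

    with _stage("expected_deaths"):
        parts, counts = [], []
        for period in config.periods:
            part = cohort[(cohort["year_dx"] >= period[0]) & (cohort["year_dx"] <= period[1])]
            lexis = tabulate_person_years(part)
            counts.append(
                expected.counts_table(part, lexis, rates, cohort_label=_period_label(period))
            )
            parts.append(part)
        pd.concat([expected.counts_to_frame(c) for c in counts]).to_csv(
            out_dir / "counts.csv", index=False
        )
        artifacts["counts"] = counts

    with _stage("bayesian_smr"):
        spec1 = smr_mod.SMRModelSpec(**{**config.smr_spec.__dict__, "seed": seed_of(1)})
        spec2 = smr_mod.SMRModelSpec(**{**config.smr_spec.__dict__, "seed": seed_of(2)})
        post1 = smr_mod.fit_smr(counts[0], spec1)
        post2 = smr_mod.fit_smr(counts[1], spec2)
        ratios = {
            cause: smr_mod.smr_ratio(post2[cause], post1[cause], seed=seed_of(3))
            for cause in post1
            if cause in post2
        }
        table2 = render_table2(counts[0], counts[1], post1, post2, ratios)
        table2.to_csv(out_dir / "table2.csv", index=False)
        artifacts.update(table2=table2, posteriors=(post1, post2), ratios=ratios)

    with _stage("competing_risks"):
        hr_cohort = parts[1]  # HR status is informative in the later period
        rrs = {}
        for stage in config.table4_stages:
            try:
                rrs[stage] = competing.relative_risk(hr_cohort, stage, config.age_adjust_table3)
            except competing.CompetingRisksError as exc:
                logger.warning("table3 stage %s skipped: %s", stage, exc)
        table3 = render_table3(rrs)
        table3.to_csv(out_dir / "table3.csv", index=False)

        age_cov = "age" if config.age_adjust_table4 == "continuous" else "age_group"
        curves = {}
        for stage in config.table4_stages:
            sub = hr_cohort[
                (hr_cohort["stage"] == stage)
                & hr_cohort["hr_status"].isin(["positive", "negative"])
            ]
            try:
                fits = [
                    competing.fit_csh_cox(sub, ["hr_status", age_cov], c) for c in CAUSE4
                ]
            except competing.CompetingRisksError as exc:
                logger.warning("table4 stage %s skipped: %s", stage, exc)
                continue
            for hr_val, hr_flag in (("positive", 0.0), ("negative", 1.0)):
                for grp in competing.AGE_GROUPS:
                    profile = {"hr_negative": hr_flag}
                    if age_cov == "age_group":
                        profile["age_50_68"] = float(grp == "50-68")
                        profile["age_ge69"] = float(grp == ">=69")
                    else:
                        profile["age"] = {"<=49": 45.0, "50-68": 59.0, ">=69": 75.0}[grp]
                    curves[(stage, hr_val, grp)] = competing.predict_cim(fits, profile)
        table4 = render_table4(curves, T=config.horizon)
        table4.to_csv(out_dir / "table4.csv", index=False)

        for stage in config.table4_stages:
            sub = cohort[cohort["stage"] == stage]
            if sub["event"].any():
                curve = competing.aalen_johansen(sub)
                frame = pd.DataFrame({"time": curve.times, "survival": curve.survival})
                for c in CAUSE4:
                    frame[f"P_{c}"] = curve.p_cause[c]
                    frame[f"se_{c}"] = curve.se_cause[c]
                frame.to_csv(out_dir / f"curve_stage_{stage}.csv", index=False)
        artifacts.update(table3=table3, table4=table4, curves=curves)

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "horizon": config.horizon,
            "periods": list(map(list, config.periods)),
            "n_records": int(len(cohort)),
            "simulated": config.patient_table is None,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = manifest
    return artifacts
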