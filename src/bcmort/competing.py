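"""Competing-risks analysis: cumulative mortality over four causes of death.

Two estimation routes for the cumulative probability of death P_k(t) from each
competing cause k (breast cancer, other cancer, CVD, other causes):

* nonparametric Aalen-Johansen estimation — at each event time the cause-k
  hazard increment is d_k / n(at risk), the all-cause survivor S is the
  product-limit over the summed increments, and P_k accumulates S(t-) d_k / n;
* semiparametric prediction from cause-specific-hazard (CSH) Cox models — one
  Cox fit per cause (competing deaths censored), combined at a covariate
  profile into the same product-limit/accumulation scheme using Breslow
  baseline hazard increments scaled by exp(beta . x).

Both routes satisfy, at every grid point, the decomposition

    S(t) + P_BC(t) + P_Ca(t) + P_CVD(t) + P_OC(t) = 1,

so Total(t) = sum_k P_k(t) = 1 - S(t) is the absolute risk of death by t —
which the Fine-Gray subdistribution approach does not guarantee and which is
the reason the cause-specific-hazard route is used here.

The Cox partial-likelihood maximisation itself (Efron ties, Wald intervals)
is delegated to :class:`lifelines.CoxPHFitter`; the baseline cumulative
hazard is recomputed in-module with the Breslow estimator so that a null
model collapses exactly onto the nonparametric estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import CAUSE4, as_cohort_frame, classify_cohort

AGE_GROUPS = ("<=49", "50-68", ">=69")


class CompetingRisksError(ValueError):
    pass


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


@dataclass
class CIMCurve:
    """Cumulative incidence of mortality over competing causes.

    ``times`` is the ordered event-time grid; ``p_cause[k][i]`` the cumulative
    probability of death from cause k by ``times[i]``; ``survival[i]`` the
    probability of surviving beyond ``times[i]``.  ``se_cause`` holds
    pointwise standard errors when available.
    """

    times: np.ndarray
    p_cause: dict[str, np.ndarray]
    survival: np.ndarray
    se_cause: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return np.sum(list(self.p_cause.values()), axis=0) if self.p_cause else np.zeros_like(self.times)

    def validate(self, tol: float = 1e-10) -> None:
        for k, p in self.p_cause.items():
            if np.any(np.diff(p) < -tol):
                raise CompetingRisksError(f"P_{k} not nondecreasing")
        if np.any(np.diff(self.survival) > tol):
            raise CompetingRisksError("survival not nonincreasing")
        gap = np.abs(self.survival + self.total - 1.0)
        if gap.size and gap.max() > tol:
            raise CompetingRisksError(f"S + sum P_k deviates from 1 by {gap.max():.2e}")

    def _index_at(self, t: float) -> int:
        if t < 0:
            raise CompetingRisksError(f"negative time {t}")
        return int(np.searchsorted(self.times, t, side="right")) - 1

    def at(self, t: float) -> dict[str, float]:
        """Step-function values (right-continuous) at time t."""
        i = self._index_at(t)
        if i < 0:
            out = {k: 0.0 for k in self.p_cause}
            out["survival"] = 1.0
            return out
        out = {k: float(p[i]) for k, p in self.p_cause.items()}
        out["survival"] = float(self.survival[i])
        return out


def total_probability(curve: CIMCurve, T: float) -> float:
    """Total(T) = sum of the cause-specific cumulative probabilities at T.

    Evaluated at the last grid point <= T; equals 1 - S(T) by construction.
    """
    i = curve._index_at(T)
    if i < 0:
        return 0.0
    return float(curve.total[i])


# ---------------------------------------------------------------------------
# nonparametric estimation
# ---------------------------------------------------------------------------


def _event_table(df: pd.DataFrame, causes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct event times, numbers at risk, and per-cause death counts."""
    t = df["follow_time"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t = t[order]
    ev = df["event"].to_numpy(dtype=bool)[order]
    c4 = df["cause4"].to_numpy(dtype=object)[order]

    times = np.unique(t[ev])
    n_at_risk = t.size - np.searchsorted(t, times, side="left")
    d = np.zeros((len(causes), times.size))
    for j, cause in enumerate(causes):
        tc = t[ev & (c4 == cause)]
        if tc.size:
            d[j] = np.bincount(np.searchsorted(times, tc), minlength=times.size)
    return times, n_at_risk.astype(float), d


def aalen_johansen(cohort, causes=CAUSE4) -> CIMCurve:
    """Nonparametric cumulative incidence over competing causes.

    Subjects dying of a competing cause leave the risk set of every other
    cause; censorings at an event time are still at risk at that time.
    Pointwise variances use the Aalen delta-method estimator.
    """
    df = cohort if "cause4" in getattr(cohort, "columns", []) else classify_cohort(cohort)
    if len(df) == 0:
        raise CompetingRisksError("empty cohort")

    times, n, d = _event_table(df, causes)
    if times.size == 0:
        return CIMCurve(
            times=np.array([0.0]),
            p_cause={k: np.zeros(1) for k in causes},
            survival=np.ones(1),
            se_cause={k: np.zeros(1) for k in causes},
        )

    d_all = d.sum(axis=0)
    haz_all = d_all / n
    S = np.cumprod(1.0 - haz_all)
    S_prev = np.concatenate([[1.0], S[:-1]])

    p_cause, se_cause = {}, {}
    # Greenwood-style factor of the all-cause survivor; zero when the risk
    # set is exhausted (d = n)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n > d_all, d_all / (n * (n - d_all)), 0.0)
    for j, cause in enumerate(causes):
        inc = S_prev * d[j] / n
        cif = np.cumsum(inc)
        p_cause[cause] = cif

        # Aalen (delta-method) pointwise variance, O(k) via cumulative sums:
        #   var(t) = sum_{s<=t} [cif(t)-cif(s)]^2 a_s
        #          + sum_{s<=t} S(s-)^2 (n_s - d_ks) d_ks / n_s^3
        #          - 2 sum_{s<=t} [cif(t)-cif(s)] S(s-) d_ks / n_s^2
        b = S_prev**2 * (n - d[j]) * d[j] / n**3
        c = S_prev * d[j] / n**2
        var = (
            cif**2 * np.cumsum(a)
            - 2 * cif * np.cumsum(cif * a)
            + np.cumsum(cif**2 * a)
            + np.cumsum(b)
            - 2 * (cif * np.cumsum(c) - np.cumsum(cif * c))
        )
        se_cause[cause] = np.sqrt(np.clip(var, 0.0, None))

    curve = CIMCurve(times=times, p_cause=p_cause, survival=S, se_cause=se_cause)
    curve.validate(tol=1e-10)
    return curve


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def age_group(age_dx: float) -> str:
    """Three-level age at diagnosis: <=49, 50-68, >=69 years."""
    if not 15 <= age_dx <= 84:
        raise CompetingRisksError(f"age {age_dx} outside [15, 84]")
    if age_dx <= 49:
        return AGE_GROUPS[0]
    if age_dx <= 68:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def build_design(cohort, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix for Cox fits.

    Understands ``hr_status`` (dummy ``hr_negative``, HR+ reference; rows with
    unknown status are dropped), ``age`` (continuous years), ``age_group``
    (dummies ``age_50_68`` and ``age_ge69``, <=49 reference); any other name
    must be a numeric column of the cohort frame and is passed through.
    """
    df = as_cohort_frame(cohort)
    out = pd.DataFrame(index=df.index)
    keep = pd.Series(True, index=df.index)
    for cov in covariates:
        if cov == "hr_status":
            keep &= df["hr_status"].isin(["positive", "negative"])
            out["hr_negative"] = (df["hr_status"] == "negative").astype(float)
        elif cov == "age":
            out["age"] = df["age_dx"].astype(float)
        elif cov == "age_group":
            grp = df["age_dx"].map(age_group)
            out["age_50_68"] = (grp == AGE_GROUPS[1]).astype(float)
            out["age_ge69"] = (grp == AGE_GROUPS[2]).astype(float)
        elif cov in df.columns:
            out[cov] = pd.to_numeric(df[cov])
        else:
            raise CompetingRisksError(f"unknown covariate {cov!r}")
    return out[keep]


# ---------------------------------------------------------------------------
# cause-specific-hazard Cox models
# ---------------------------------------------------------------------------


@dataclass
class CSHFit:
    """One cause-specific Cox fit: coefficients plus Breslow baseline."""

    cause: str
    coefficients: pd.DataFrame  # index: covariate; columns coef, se, ci_lower, ci_upper
    baseline_times: np.ndarray
    baseline_increments: np.ndarray  # Breslow dH_0 at baseline_times
    n_events: int

    def hazard_multiplier(self, profile: dict[str, float]) -> float:
        missing = [c for c in self.coefficients.index if c not in profile]
        if missing:
            raise CompetingRisksError(
                f"profile missing covariates {missing} for cause {self.cause!r}"
            )
        lp = sum(self.coefficients.loc[c, "coef"] * profile[c] for c in self.coefficients.index)
        return float(np.exp(lp))


def _breslow_baseline(
    t: np.ndarray, is_event: np.ndarray, risk_score: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow dH_0(t) = d(t) / sum of risk scores over the risk set."""
    order = np.argsort(t, kind="stable")
    t, is_event, risk_score = t[order], is_event[order], risk_score[order]
    times = np.unique(t[is_event])
    # risk set at t: subjects with follow-up >= t
    rs_total = np.concatenate([[0.0], np.cumsum(risk_score[::-1])])[::-1]
    at_risk_sum = rs_total[np.searchsorted(t, times, side="left")]
    d = np.bincount(np.searchsorted(times, t[is_event]), minlength=times.size)
    inc = d / at_risk_sum
    return times, inc


def fit_csh_cox(cohort, covariates: list[str], cause: str, ties: str = "efron") -> CSHFit:
    """Cause-specific Cox model: deaths from other causes censored at death.

    ``covariates=[]`` fits the null model (no regression; baseline hazard is
    the nonparametric cause-specific hazard).  Raises when the target cause
    has no events or the partial likelihood cannot be maximised (e.g.
    complete separation).
    """
    df = cohort if "cause4" in getattr(cohort, "columns", []) else classify_cohort(cohort)
    design = build_design(df, covariates)
    df = df.loc[design.index]
    t = df["follow_time"].to_numpy(dtype=float)
    is_event = (df["event"] & (df["cause4"] == cause)).to_numpy(dtype=bool)
    n_events = int(is_event.sum())
    if n_events == 0:
        raise CompetingRisksError(f"no events of cause {cause!r}: cannot fit CSH model")

    if design.shape[1] == 0:
        coef = pd.DataFrame(columns=["coef", "se", "ci_lower", "ci_upper"])
        risk = np.ones(len(df))
    else:
        fit_df = design.copy()
        fit_df["T"] = t
        fit_df["E"] = is_event.astype(int)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(fit_df, duration_col="T", event_col="E")
        except Exception as exc:  # convergence failure / separation
            raise CompetingRisksError(f"CSH fit failed for cause {cause!r}: {exc}") from exc
        if ties != "efron":
            raise CompetingRisksError(f"unsupported tie rule {ties!r} (Efron only)")
        summ = cph.summary
        coef = pd.DataFrame(
            {
                "coef": summ["coef"],
                "se": summ["se(coef)"],
                "ci_lower": summ["coef lower 95%"],
                "ci_upper": summ["coef upper 95%"],
            }
        )
        coef.index.name = None
        if not np.isfinite(coef.to_numpy(dtype=float)).all():
            raise CompetingRisksError(f"non-finite coefficients for cause {cause!r}")
        risk = np.exp(design.to_numpy(dtype=float) @ coef["coef"].to_numpy())

    times, inc = _breslow_baseline(t, is_event, risk)
    return CSHFit(
        cause=cause,
        coefficients=coef,
        baseline_times=times,
        baseline_increments=inc,
        n_events=n_events,
    )


def predict_cim(
    fits: list[CSHFit], profile: dict[str, float], times: np.ndarray | None = None
) -> CIMCurve:
    """Absolute risks at a covariate profile from one CSH fit per cause.

    Cause-k hazard increments are the Breslow baseline increments scaled by
    exp(beta_k . x); the overall survivor is the product-limit over the summed
    increments and P_k accumulates S(t-) h_k(t), so the curve satisfies
    S + sum_k P_k = 1 exactly.
    """
    if not fits:
        raise CompetingRisksError("no CSH fits supplied")
    labels = [f.cause for f in fits]
    if len(set(labels)) != len(labels):
        raise CompetingRisksError(f"duplicate causes in fits: {labels}")

    grid = np.unique(np.concatenate([f.baseline_times for f in fits]))
    if times is not None:
        grid = np.unique(np.concatenate([grid, np.asarray(times, dtype=float)]))

    h = np.zeros((len(fits), grid.size))
    for j, f in enumerate(fits):
        mult = f.hazard_multiplier(profile)
        idx = np.searchsorted(grid, f.baseline_times)
        h[j, idx] = f.baseline_increments * mult

    h_all = h.sum(axis=0)
    if (h_all > 1.0).any():
        warnings.warn("summed hazard increments exceed 1; clipping", stacklevel=2)
        h *= np.where(h_all > 1.0, 1.0 / h_all, 1.0)
        h_all = np.minimum(h_all, 1.0)
    S = np.cumprod(1.0 - h_all)
    S_prev = np.concatenate([[1.0], S[:-1]])
    p_cause = {f.cause: np.cumsum(S_prev * h[j]) for j, f in enumerate(fits)}

    curve = CIMCurve(times=grid, p_cause=p_cause, survival=S)
    curve.validate(tol=1e-8)
    return curve


def bootstrap_cim(
    cohort,
    covariates: list[str],
    profile: dict[str, float],
    causes=CAUSE4,
    n_boot: int = 200,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> CIMCurve:
    """Model-based curve with bootstrap pointwise standard errors.

    Resamples subjects with replacement, refits the per-cause CSH models and
    re-predicts at the profile; the SD over resamples (step-interpolated onto
    the point-estimate grid) is attached as ``se_cause``.
    """
    df = cohort if "cause4" in getattr(cohort, "columns", []) else classify_cohort(cohort)
    fits = [fit_csh_cox(df, covariates, c) for c in causes]
    base = predict_cim(fits, profile, times=times)

    rng = np.random.default_rng(seed)
    acc = {c: [] for c in causes}
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            bfits = [fit_csh_cox(boot, covariates, c) for c in causes]
            curve = predict_cim(bfits, profile)
        except CompetingRisksError:
            continue  # degenerate resample (e.g. a cause with no events)
        for c in causes:
            # step interpolation onto the base grid
            pos = np.searchsorted(curve.times, base.times, side="right") - 1
            vals = np.where(pos >= 0, curve.p_cause[c][np.maximum(pos, 0)], 0.0)
            acc[c].append(vals)
    base.se_cause = {
        c: (np.std(np.vstack(v), axis=0, ddof=1) if len(v) > 1 else np.full(base.times.size, np.nan))
        for c, v in acc.items()
    }
    return base


# ---------------------------------------------------------------------------
# relative risks (HR- vs HR+)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelativeRisk:
    """Age-adjusted hazard ratio for HR-negative vs HR-positive patients."""

    stage: str
    outcome: str  # all_cause | bc | non_bc
    rr: float
    ci95: tuple[float, float]

    def __post_init__(self):
        if not self.rr > 0:
            raise CompetingRisksError(f"nonpositive RR {self.rr}")
        lo, hi = self.ci95
        if not lo <= self.rr <= hi:
            raise CompetingRisksError(f"RR {self.rr} outside its CI {self.ci95}")


def _rr_from_fit(fit: CSHFit, stage: str, outcome: str) -> RelativeRisk:
    row = fit.coefficients.loc["hr_negative"]
    return RelativeRisk(
        stage=stage,
        outcome=outcome,
        rr=float(np.exp(row["coef"])),
        ci95=(float(np.exp(row["ci_lower"])), float(np.exp(row["ci_upper"]))),
    )


def relative_risk(cohort, stage: str, adjust: str = "continuous") -> dict[str, RelativeRisk]:
    """HR- vs HR+ relative risks within one stage stratum.

    Fits three age-adjusted Cox models on patients of the stage with known HR
    status: all-cause mortality, and the two-cause CSH decomposition into
    breast-cancer vs aggregated non-breast-cancer mortality.  ``adjust`` is
    ``"continuous"`` (age in years) or ``"categorical"`` (three age groups).
    """
    if adjust not in ("continuous", "categorical"):
        raise CompetingRisksError(f"unknown age adjustment {adjust!r}")
    age_cov = "age" if adjust == "continuous" else "age_group"
    df = cohort if "cause4" in getattr(cohort, "columns", []) else classify_cohort(cohort)
    sub = df[(df["stage"] == stage) & df["hr_status"].isin(["positive", "negative"])].copy()
    if len(sub) == 0:
        raise CompetingRisksError(f"empty stratum: stage {stage!r} with known HR status")

    covs = ["hr_status", age_cov]
    out: dict[str, RelativeRisk] = {}

    # (a) all-cause mortality: plain Cox on any death
    allc = sub.copy()
    allc["cause4"] = np.where(allc["event"], "death", None)
    out["all_cause"] = _rr_from_fit(fit_csh_cox(allc, covs, "death"), stage, "all_cause")

    # (b) two-cause CSH: breast cancer vs everything else aggregated
    two = sub.copy()
    two["cause4"] = np.where(
        two["event"], np.where(two["cause4"] == "BC", "BC", "nonBC"), None
    )
    out["bc"] = _rr_from_fit(fit_csh_cox(two, covs, "BC"), stage, "bc")
    out["non_bc"] = _rr_from_fit(fit_csh_cox(two, covs, "nonBC"), stage, "non_bc")
    return out
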