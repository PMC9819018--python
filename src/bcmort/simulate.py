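"""Synthetic registry cohort with known ground truth.

The generator emulates a population-based breast-cancer registry cohort
(diagnoses 2000-2009, ages 15-84, stage I-IV plus missing, hormone-receptor
status known only from 2005 onwards) under a constant cause-specific-hazard
model: within each (stage, HR) stratum the four competing causes of death
(breast cancer, other cancer, cardiovascular, other) act as independent
exponential latent times, realised as a single all-cause exponential draw with
rate Lambda = sum(lambda_k) plus a multinomial cause assignment with weights
lambda_k / Lambda.  Follow-up is administratively truncated at 10 years.

Because hazards are constant, every downstream estimand has a closed form:

    P_k(t)  = (lambda_k / Lambda) * (1 - exp(-Lambda t))      (cumulative mortality)
    S(t)    = exp(-Lambda t)                                  (survival)

and a matching reference-population rate table can be emitted whose rates are
scaled so that the cohort's true standardized mortality ratio for each cause
equals any requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    AGE_MAX,
    AGE_MIN,
    CAUSE4,
    HORIZON,
    STAGES,
    classify_cause,
)

# ---------------------------------------------------------------------------
# default cohort composition (registry-like frequencies)
# ---------------------------------------------------------------------------

#: stage mix of the cohort (registry counts 2257/2478/1080/463/484,
#: normalised over their own sum)
DEFAULT_STAGE_PROBS = {
    stage: n / 6762
    for stage, n in zip(STAGES, (2257, 2478, 1080, 463, 484))
}

#: HR mix among patients diagnosed from 2005 on (2748/547/167 of 3462);
#: earlier diagnoses carry no HR information and are recorded as unknown
DEFAULT_HR_PROBS = {
    "positive": 2748 / 3462,
    "negative": 547 / 3462,
    "unknown": 167 / 3462,
}

#: age at diagnosis: normal(59.1, 14.3) truncated to [15, 84]
DEFAULT_AGE_MEAN = 59.1
DEFAULT_AGE_SD = 14.3

DEFAULT_YEAR_RANGE = (2000, 2009)
DEFAULT_N = 6758

#: 10-year probabilities of death (%) per (stage, HR) stratum used to derive
#: the default constant hazards: order (BC, OtherCancer, CVD, OtherCauses).
#: Magnitudes follow the gradient observed in registry cohorts: breast-cancer
#: mortality rising steeply with stage and for HR-negative tumours,
#: cardiovascular mortality a stable few percent.
DEFAULT_STRATUM_PROBS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("I", "positive"): (1.71, 3.64, 1.42, 3.21),
    ("I", "negative"): (10.42, 4.42, 0.41, 2.71),
    ("II", "positive"): (9.01, 2.04, 3.01, 5.01),
    ("II", "negative"): (14.11, 2.82, 3.86, 2.43),
    ("III", "positive"): (32.99, 2.91, 3.11, 3.82),
    ("III", "negative"): (49.94, 0.94, 3.31, 2.84),
    ("IV", "positive"): (72.61, 12.22, 3.43, 2.76),
    ("IV", "negative"): (86.82, 5.56, 3.85, 1.15),
    ("missing", "positive"): (18.50, 2.60, 3.20, 4.40),
    ("missing", "negative"): (28.00, 2.20, 3.50, 2.60),
}

#: ICD-10 code pools per broad cause, with sampling weights.  The mixes give
#: the cause-of-death structure seen in such cohorts: colon/lung/pancreas/
#: endometrium/ovary among second cancers, ischaemic disease and heart
#: failure among CVD, and a spread over the remaining ICD chapters otherwise.
CODE_POOLS: dict[str, tuple[tuple[str, float], ...]] = {
    "BC": (("C50", 1.0),),
    "OtherCancer": (
        ("C18", 0.14),  # colon
        ("C34", 0.13),  # lung
        ("C25", 0.12),  # pancreas
        ("C22", 0.10),  # liver
        ("C54", 0.10),  # endometrium
        ("C56", 0.10),  # ovary
        ("C16", 0.08),  # stomach
        ("C91", 0.08),  # leukaemia
        ("C80", 0.15),  # unknown primary
    ),
    "CVD": (
        ("I50", 0.25),  # heart failure
        ("I21", 0.20),  # myocardial infarction
        ("I64", 0.20),  # stroke
        ("I25", 0.15),  # chronic ischaemic heart disease
        ("I71", 0.12),  # aortic aneurysm
        ("I10", 0.08),  # hypertensive disease
    ),
    "OtherCauses": (
        ("J44", 0.14),  # COPD
        ("G30", 0.12),  # Alzheimer
        ("E11", 0.10),  # diabetes
        ("K74", 0.09),  # liver cirrhosis
        ("F03", 0.09),  # dementia
        ("N18", 0.08),  # chronic kidney disease
        ("R99", 0.08),  # ill-defined
        ("A41", 0.06),  # sepsis
        ("J18", 0.05),  # pneumonia
        ("X59", 0.04),  # accidental exposure
        ("W19", 0.03),  # fall
        ("D64", 0.03),  # anaemia
        ("M81", 0.03),  # osteoporosis
        ("Q24", 0.01),  # congenital heart malformation
        ("L89", 0.01),  # pressure ulcer
        ("G20", 0.04),  # Parkinson
    ),
}

#: reference-rate table granularity
RATE_AGE_BAND = 5


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


def hazards_from_probabilities(
    probs_pct: Sequence[float], horizon: float = HORIZON
) -> np.ndarray:
    """Invert 10-year cause-specific death probabilities (in %) to constant hazards.

    Under constant hazards, Total(h) = 1 - exp(-Lambda h) and
    P_k(h) = (lambda_k/Lambda) Total(h), so
    Lambda = -log(1 - Total)/h and lambda_k = P_k * Lambda / Total.
    """
    p = np.asarray(probs_pct, dtype=float) / 100.0
    if (p < 0).any() or p.sum() >= 1:
        raise SimulationError(f"invalid 10-year probabilities {probs_pct}")
    total = p.sum()
    if total == 0:
        return np.zeros_like(p)
    lam_total = -np.log1p(-total) / horizon
    return p * lam_total / total


def _default_hazards() -> dict[tuple[str, str], np.ndarray]:
    hz = {k: hazards_from_probabilities(v) for k, v in DEFAULT_STRATUM_PROBS.items()}
    # the observed-unknown stratum behaves as the HR mixture of the cohort
    w_pos = DEFAULT_HR_PROBS["positive"] / (
        DEFAULT_HR_PROBS["positive"] + DEFAULT_HR_PROBS["negative"]
    )
    for stage in STAGES:
        hz[(stage, "unknown")] = w_pos * hz[(stage, "positive")] + (1 - w_pos) * hz[
            (stage, "negative")
        ]
    return hz


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic registry cohort."""

    n_patients: int = DEFAULT_N
    seed: int = 0
    stage_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    hr_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HR_PROBS))
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE
    horizon: float = HORIZON
    #: HR status observed only for diagnoses at/after this year (None: always)
    hr_known_from: int | None = 2005
    hazards: Mapping[tuple[str, str], np.ndarray] = field(default_factory=_default_hazards)
    #: requested true SMR per broad cause for the emitted reference rates
    smr_targets: Mapping[str, float] = field(
        default_factory=lambda: {"OtherCancer": 1.0, "CVD": 1.0, "OtherCauses": 1.0}
    )

    def validate(self) -> None:
        for name, probs in (("stage_probs", self.stage_probs), ("hr_probs", self.hr_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SimulationError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise SimulationError(f"{name} has negative entries")
        for key, lam in self.hazards.items():
            lam = np.asarray(lam, dtype=float)
            if lam.shape != (4,):
                raise SimulationError(f"hazards[{key}] must have 4 entries")
            if (lam < 0).any():
                raise SimulationError(f"hazards[{key}] has negative entries")
        if self.n_patients <= 0:
            raise SimulationError("n_patients must be positive")
        if self.year_range[1] < self.year_range[0]:
            raise SimulationError("invalid year_range")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form estimands of the generating model."""

    hazards: Mapping[tuple[str, str], np.ndarray]
    horizon: float
    true_smr: Mapping[str, float]
    #: person-year-weighted marginal hazard of each broad cause
    marginal_hazard: Mapping[str, float]

    def cumulative_incidence(self, stratum: tuple[str, str], cause: str, t) -> np.ndarray:
        """P_k(t) = (lambda_k/Lambda)(1 - exp(-Lambda t)) for one stratum."""
        lam = np.asarray(self.hazards[stratum], dtype=float)
        total = lam.sum()
        k = CAUSE4.index(cause)
        t = np.asarray(t, dtype=float)
        if total == 0:
            return np.zeros_like(t)
        return (lam[k] / total) * -np.expm1(-total * t)

    def survival(self, stratum: tuple[str, str], t) -> np.ndarray:
        lam_total = float(np.sum(self.hazards[stratum]))
        return np.exp(-lam_total * np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _stratum_weights(config: SimulationConfig) -> dict[tuple[str, str], float]:
    """Expected population share of each (stage, observed-HR) hazard stratum."""
    years = config.year_range[1] - config.year_range[0] + 1
    if config.hr_known_from is None:
        frac_known = 1.0
    else:
        n_known = config.year_range[1] - max(config.hr_known_from, config.year_range[0]) + 1
        frac_known = max(0, min(years, n_known)) / years
    weights: dict[tuple[str, str], float] = {}
    for stage, ps in config.stage_probs.items():
        for hr, ph in config.hr_probs.items():
            w = ps * ph * frac_known
            weights[(stage, hr)] = weights.get((stage, hr), 0.0) + w
        weights[(stage, "unknown")] = weights.get((stage, "unknown"), 0.0) + ps * (1 - frac_known)
    return weights


def _expected_py(lam_total: float, horizon: float) -> float:
    """Expected truncated person-years per subject under total hazard Lambda."""
    if lam_total == 0:
        return horizon
    return -np.expm1(-lam_total * horizon) / lam_total


def _marginal_hazards(config: SimulationConfig) -> dict[str, float]:
    """Person-year-weighted cohort hazard per broad cause.

    With constant hazards, E[deaths of cause k] = sum_strata n w_s lambda_ks E[PY_s]
    and E[person-years] = sum_strata n w_s E[PY_s]; their ratio is the marginal
    cohort rate that a perfectly matched reference population would have.
    """
    weights = _stratum_weights(config)
    num = np.zeros(4)
    den = 0.0
    for stratum, w in weights.items():
        lam = np.asarray(config.hazards[stratum], dtype=float)
        epy = _expected_py(float(lam.sum()), config.horizon)
        num += w * lam * epy
        den += w * epy
    return {c: float(num[i] / den) for i, c in enumerate(CAUSE4)}


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a truncated registry cohort; returns (cohort frame, ground truth).

    Reproducible: a fixed config (including seed) yields an identical frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    stages = rng.choice(list(config.stage_probs), size=n, p=list(config.stage_probs.values()))
    y0, y1 = config.year_range
    years = rng.integers(y0, y1 + 1, size=n)
    a, b = (AGE_MIN - config.age_mean) / config.age_sd, (AGE_MAX - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    ages = np.clip(np.round(ages), AGE_MIN, AGE_MAX).astype(int)
    hr = rng.choice(list(config.hr_probs), size=n, p=list(config.hr_probs.values()))
    if config.hr_known_from is not None:
        hr = np.where(years >= config.hr_known_from, hr, "unknown")

    lam_by_stratum = {k: np.asarray(v, dtype=float) for k, v in config.hazards.items()}
    lam = np.stack([lam_by_stratum[(s, h)] for s, h in zip(stages, hr)])
    lam_total = lam.sum(axis=1)

    # latent all-cause time + multinomial cause split (equivalent to the
    # minimum of independent exponential latent times)
    with np.errstate(divide="ignore"):
        t_all = np.where(
            lam_total > 0, rng.exponential(1.0, size=n) / np.where(lam_total > 0, lam_total, 1.0), np.inf
        )
    u = rng.random(n)
    cum = np.cumsum(lam / np.where(lam_total > 0, lam_total, 1.0)[:, None], axis=1)
    cause_idx = (u[:, None] > cum).sum(axis=1)

    event = t_all <= config.horizon
    follow = np.where(event, t_all, config.horizon)

    # draw ICD-10 codes within the broad cause group
    codes = np.full(n, None, dtype=object)
    u_code = rng.random(n)  # drawn for everyone to keep the stream layout fixed
    for k, cause in enumerate(CAUSE4):
        pool = CODE_POOLS[cause]
        pool_codes = [c for c, _ in pool]
        pool_cum = np.cumsum([w for _, w in pool])
        pool_cum = pool_cum / pool_cum[-1]
        sel = event & (cause_idx == k)
        idx = np.searchsorted(pool_cum, u_code[sel], side="right").clip(0, len(pool_codes) - 1)
        codes[sel] = np.array(pool_codes, dtype=object)[idx]

    cohort = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "age_dx": ages,
            "year_dx": years,
            "stage": stages,
            "hr_status": hr,
            "follow_time": follow,
            "event": event,
            "cause_code": codes,
        }
    )

    truth = GroundTruth(
        hazards={k: v.copy() for k, v in lam_by_stratum.items()},
        horizon=config.horizon,
        true_smr=dict(config.smr_targets),
        marginal_hazard=_marginal_hazards(config),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# reference-population rates
# ---------------------------------------------------------------------------


def _code_group_shares() -> dict[str, dict[str, float]]:
    """Share of each broad cause's deaths falling in each ICD chapter group."""
    shares: dict[str, dict[str, float]] = {}
    for cause, pool in CODE_POOLS.items():
        total = sum(w for _, w in pool)
        for code, w in pool:
            _, chapter = classify_cause(code)
            shares.setdefault(cause, {})
            shares[cause][chapter] = shares[cause].get(chapter, 0.0) + w / total
    return shares


def generate_reference_rates(config: SimulationConfig) -> pd.DataFrame:
    """Emit a reference-population mortality rate table matching the cohort.

    Rates are constant over 5-year age bands and calendar years spanning the
    cohort's Lexis range, and scaled so that the cohort's true SMR for each
    broad cause equals ``config.smr_targets`` (default 1).  Rows are keyed by
    cause label in two granularities: the three non-index broad causes
    (OtherCancer, CVD, OtherCauses) and the ICD-10 chapter groups implied by
    the generator's cause-of-death code pools.  The Tumours chapter rate
    excludes the index disease (breast cancer), matching its use as an SMR
    denominator.
    """
    config.validate()
    marginal = _marginal_hazards(config)
    shares = _code_group_shares()

    cause_rates: dict[str, float] = {}
    for cause in ("OtherCancer", "CVD", "OtherCauses"):
        s = float(config.smr_targets.get(cause, 1.0))
        if s <= 0:
            raise SimulationError(f"smr target for {cause} must be positive")
        cause_rates[cause] = marginal[cause] / s
        for chapter, share in shares[cause].items():
            cause_rates[chapter] = cause_rates.get(chapter, 0.0) + marginal[cause] * share / s

    y0, y1 = config.year_range
    years = range(y0, y1 + int(np.ceil(config.horizon)) + 1)
    age_lo = range(AGE_MIN, AGE_MAX + int(np.ceil(config.horizon)) + 1, RATE_AGE_BAND)
    rows = [
        (cause, lo, lo + RATE_AGE_BAND - 1, year, rate)
        for cause, rate in sorted(cause_rates.items())
        for lo in age_lo
        for year in years
    ]
    return pd.DataFrame(rows, columns=["cause", "age_low", "age_high", "year", "rate"])


def write_rates(rates: pd.DataFrame, path) -> None:
    rates.to_csv(path, index=False)


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["cause", "age_low", "age_high", "year", "rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SimulationError(f"rate table missing columns {missing}")
    return df
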