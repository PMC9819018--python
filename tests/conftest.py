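import warnings

import numpy as np
import pandas as pd
import pytest

import bcmort as b

warnings.filterwarnings("ignore", category=FutureWarning)


def make_cohort_frame(rows) -> pd.DataFrame:
    """Build a cohort frame from (id, age, year, stage, hr, t, cause|None) tuples."""
    return pd.DataFrame(
        [
            {
                "id": r[0],
                "age_dx": r[1],
                "year_dx": r[2],
                "stage": r[3],
                "hr_status": r[4],
                "follow_time": float(r[5]),
                "event": r[6] is not None,
                "cause_code": r[6],
            }
            for r in rows
        ]
    )


@pytest.fixture(scope="session")
def toy5():
    """Five subjects, distinct event times, three causes and one censoring."""
    return make_cohort_frame(
        [
            ("a", 50, 2005, "I", "positive", 1.0, "C50"),
            ("b", 55, 2005, "I", "positive", 2.0, "I21"),
            ("c", 60, 2005, "I", "positive", 3.0, None),
            ("d", 65, 2005, "I", "positive", 4.0, "C50"),
            ("e", 70, 2005, "I", "positive", 5.0, "C34"),
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic cohort shared across tests (n=10,000, seed 7)."""
    cfg = b.SimulationConfig(n_patients=10_000, seed=7)
    cohort, truth = b.generate_cohort(cfg)
    return cfg, cohort, truth


def constant_hazard_cohort(
    lam, n, seed, stage="I", hr="positive", horizon=10.0
) -> pd.DataFrame:
    """Single-stratum cohort with constant cause-specific hazards ``lam``."""
    lam = np.asarray(lam, dtype=float)
    rng = np.random.default_rng(seed)
    total = lam.sum()
    if total == 0:
        t_all = np.full(n, np.inf)
        cause = np.zeros(n, dtype=int)
    else:
        t_all = rng.exponential(1.0 / total, n)
        cause = rng.choice(len(lam), size=n, p=lam / total)
    ev = t_all <= horizon
    ft = np.minimum(t_all, horizon)
    codes = np.array(["C50", "C34", "I21", "J44"], dtype=object)[cause]
    return pd.DataFrame(
        {
            "id": np.arange(n).astype(str),
            "age_dx": rng.integers(35, 80, n),
            "year_dx": 2005,
            "stage": stage,
            "hr_status": hr,
            "follow_time": ft,
            "event": ev,
            "cause_code": np.where(ev, codes, None),
        }
    )
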