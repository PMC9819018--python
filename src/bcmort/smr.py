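"""Bayesian hierarchical standardized mortality ratios.

Model, per cause group c with observed deaths O_c and expected deaths E_c:

    O_c ~ Poisson(mu_c)
    log(mu_c) = log(E_c) + theta_c          (theta_c = log SMR_c)
    theta_c ~ Normal(0, tau)                (tau = 1 / sigma^2, precision)
    sigma ~ Uniform(1, 5)

The Uniform(1, 5) prior on the hierarchical standard deviation — with its
deliberately high lower bound — keeps the posterior proper and well behaved
for causes with few or zero observed deaths, at the price of a very diffuse
prior on the log-SMR.  Two pooling modes exist: ``per_cause_sigma`` fits each
cause independently with its own sigma (the default, matching cause-by-cause
reporting), while ``shared_sigma`` fits all causes jointly with one sigma
(partial pooling as the hierarchical notation reads).

Posteriors are sampled with an adaptive random-walk Metropolis-within-Gibbs
sampler written for this two-level model: theta updates use a Gaussian random
walk whose scale adapts to a ~44% acceptance rate during burn-in; sigma
proposals are reflected back into its prior support.  Reported summaries are
the posterior median SMR, the equal-tailed 95% credible interval, and
P(SMR > 1); period comparisons resample the two posteriors to form the
distribution of SMR_2 / SMR_1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np

from .expected import CauseCount

RHAT_FLAG = 1.05


class SMRModelError(ValueError):
    pass


@dataclass
class SMRModelSpec:
    """Prior bounds, pooling mode and MCMC settings for the SMR model."""

    prior_sd_bounds: tuple[float, float] = (1.0, 5.0)
    pooling_mode: str = "per_cause_sigma"  # or "shared_sigma"
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2000
    thinning: int = 1
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.prior_sd_bounds
        if lo < 0 or hi <= lo:
            raise SMRModelError(f"invalid prior_sd_bounds {self.prior_sd_bounds}")
        if self.pooling_mode not in ("per_cause_sigma", "shared_sigma"):
            raise SMRModelError(f"unknown pooling_mode {self.pooling_mode!r}")
        kept = (self.iterations - self.burn_in) // self.thinning
        if kept < 1000:
            raise SMRModelError("need >= 1000 retained iterations per chain")


@dataclass
class SMRPosterior:
    """Posterior summary of one cause's SMR."""

    cause: str
    cohort_label: str
    samples: np.ndarray  # SMR draws, all chains pooled
    smr_median: float
    cri95: tuple[float, float]
    p_smr: float  # posterior P(SMR > 1)
    rhat: float
    ess: float
    converged: bool
    seed: int

    @classmethod
    def from_draws(cls, cause, cohort_label, theta_draws, seed) -> "SMRPosterior":
        """Summarise (chains, draws) log-SMR samples."""
        theta_draws = np.asarray(theta_draws)
        smr = np.exp(theta_draws)
        pooled = smr.reshape(-1)
        # arviz convention: 2-D arrays are (chain, draw)
        rhat = float(az.rhat(theta_draws.astype(float)))
        ess = float(az.ess(theta_draws.astype(float)))
        converged = bool(rhat <= RHAT_FLAG)
        if not converged:
            warnings.warn(
                f"SMR sampler for {cause!r} did not converge (R-hat {rhat:.3f})", stacklevel=2
            )
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        return cls(
            cause=cause,
            cohort_label=cohort_label,
            samples=pooled,
            smr_median=float(np.median(pooled)),
            cri95=(float(lo), float(hi)),
            p_smr=float(np.mean(pooled > 1.0)),
            rhat=rhat,
            ess=ess,
            converged=converged,
            seed=seed,
        )


@dataclass
class RatioPosterior:
    """Posterior of the between-period ratio SMR_2 / SMR_1 for one cause."""

    cause: str
    samples: np.ndarray
    ratio_median: float
    cri95: tuple[float, float]
    p_ratio: float
    seed: int


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect proposals into [lo, hi] (volume-preserving, symmetric)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def _sample_posterior(
    O: np.ndarray, E: np.ndarray, spec: SMRModelSpec, seed: int
) -> np.ndarray:
    """Adaptive Metropolis-within-Gibbs for (theta_1..theta_C, sigma).

    Returns retained theta draws of shape (chains, kept, C).  All causes in
    O, E share one sigma (call with C=1 per cause for independent fits).
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if (E <= 0).any():
        raise SMRModelError(f"expected deaths must be positive, got {E}")
    if (O < 0).any():
        raise SMRModelError(f"observed deaths must be nonnegative, got {O}")
    rng = np.random.default_rng(seed)
    nch, C = spec.chains, len(O)
    lo, hi = spec.prior_sd_bounds

    # overdispersed starts around the crude log-SMR
    theta0 = np.log((O + 0.5) / E)
    theta = theta0[None, :] + rng.normal(0, 0.5, size=(nch, C))
    sigma = rng.uniform(lo, hi, size=nch)
    s_theta = np.full((nch, C), 0.5)
    s_sigma = np.full(nch, 0.5 * (hi - lo))

    def loglik(th):  # Poisson log-likelihood up to a constant
        return O * th - E * np.exp(th)

    acc_t = np.zeros((nch, C))
    acc_s = np.zeros(nch)
    kept = (spec.iterations - spec.burn_in) // spec.thinning
    out = np.empty((nch, kept, C))
    k = 0
    ADAPT_EVERY = 50
    for it in range(spec.iterations):
        # theta | sigma: independent RW Metropolis per cause
        prop = theta + s_theta * rng.standard_normal((nch, C))
        log_a = (
            loglik(prop)
            - loglik(theta)
            - (prop**2 - theta**2) / (2 * sigma[:, None] ** 2)
        )
        accept = np.log(rng.random((nch, C))) < log_a
        theta = np.where(accept, prop, theta)
        acc_t += accept

        # sigma | theta: RW Metropolis with reflection into the prior support
        prop_s = _reflect(sigma + s_sigma * rng.standard_normal(nch), lo, hi)
        ss = np.sum(theta**2, axis=1)
        log_a_s = (
            -C * np.log(prop_s)
            - ss / (2 * prop_s**2)
            + C * np.log(sigma)
            + ss / (2 * sigma**2)
        )
        accept_s = np.log(rng.random(nch)) < log_a_s
        sigma = np.where(accept_s, prop_s, sigma)
        acc_s += accept_s

        if it < spec.burn_in:
            if (it + 1) % ADAPT_EVERY == 0:
                # cap the scales: beyond these the proposal is effectively an
                # independence sampler and further growth only loses precision
                # in the reflection arithmetic
                s_theta = np.minimum(
                    s_theta * np.exp((acc_t / ADAPT_EVERY - 0.44).clip(-1, 1)), 25.0
                )
                s_sigma = np.minimum(
                    s_sigma * np.exp((acc_s / ADAPT_EVERY - 0.44).clip(-1, 1)), hi - lo
                )
                acc_t[:] = 0.0
                acc_s[:] = 0.0
        elif (it - spec.burn_in) % spec.thinning == 0 and k < kept:
            out[:, k, :] = theta
            k += 1
    return out[:, :k, :]


def fit_smr(counts, spec: SMRModelSpec | None = None) -> dict[str, SMRPosterior]:
    """Fit the hierarchical SMR model; returns one posterior per cause.

    ``counts`` is a :class:`CauseCount` or list thereof.  In
    ``per_cause_sigma`` mode each cause gets its own (theta, sigma) fit; in
    ``shared_sigma`` mode all causes are fitted jointly with one sigma.
    """
    spec = spec or SMRModelSpec()
    spec.validate()
    if isinstance(counts, CauseCount):
        counts = [counts]
    if not counts:
        raise SMRModelError("no counts supplied")

    results: dict[str, SMRPosterior] = {}
    if spec.pooling_mode == "shared_sigma":
        O = np.array([c.observed for c in counts], dtype=float)
        E = np.array([c.expected for c in counts], dtype=float)
        draws = _sample_posterior(O, E, spec, spec.seed)
        for j, c in enumerate(counts):
            results[c.cause] = SMRPosterior.from_draws(
                c.cause, c.cohort_label, draws[:, :, j], spec.seed
            )
    else:
        ss = np.random.SeedSequence(spec.seed).spawn(len(counts))
        for c, sub in zip(counts, ss):
            sub_seed = int(sub.generate_state(1)[0] % (2**31))
            draws = _sample_posterior([c.observed], [c.expected], spec, sub_seed)
            results[c.cause] = SMRPosterior.from_draws(
                c.cause, c.cohort_label, draws[:, :, 0], sub_seed
            )
    return results


# ---------------------------------------------------------------------------
# period comparison and flags
# ---------------------------------------------------------------------------


def smr_ratio(post2: SMRPosterior, post1: SMRPosterior, seed: int = 0) -> RatioPosterior:
    """Posterior of Ratio = SMR_2 / SMR_1 by independent posterior resampling.

    Both sample vectors are resampled with replacement to a common length and
    divided elementwise; the independent resampling breaks any residual
    within-chain ordering so the two cohorts' draws pair at random.
    """
    if post1.cause != post2.cause:
        raise SMRModelError(f"cause mismatch: {post2.cause!r} vs {post1.cause!r}")
    n1, n2 = len(post1.samples), len(post2.samples)
    if min(n1, n2) < 1000:
        raise SMRModelError("need >= 1000 posterior draws in each period")
    n = max(n1, n2)
    rng = np.random.default_rng(seed)
    s2 = rng.choice(post2.samples, size=n, replace=True)
    s1 = rng.choice(post1.samples, size=n, replace=True)
    ratio = s2 / s1
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return RatioPosterior(
        cause=post1.cause,
        samples=ratio,
        ratio_median=float(np.median(ratio)),
        cri95=(float(lo), float(hi)),
        p_ratio=float(np.mean(ratio > 1.0)),
        seed=seed,
    )


def significance_flag(post, threshold: float = 0.95) -> bool:
    """True iff the posterior probability of excess (P > threshold, strict).

    Accepts an :class:`SMRPosterior` (uses p_smr) or :class:`RatioPosterior`
    (uses p_ratio).
    """
    if not 0 < threshold < 1:
        raise SMRModelError(f"threshold must be in (0, 1), got {threshold}")
    p = post.p_smr if isinstance(post, SMRPosterior) else post.p_ratio
    return bool(p > threshold)
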