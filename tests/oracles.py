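"""Independent numerical oracles used by the test suite.

These are deliberately brute-force and share no code with the implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def smr_posterior_quadrature(
    O: int,
    E: float,
    sd_bounds: tuple[float, float] = (1.0, 5.0),
    n_theta: int = 4001,
    n_sigma: int = 201,
    theta_halfwidth: float = 12.0,
):
    """Deterministic 2-D grid quadrature of the single-cause SMR posterior.

    p(theta, sigma | O) ~ Poisson(O | E e^theta) N(theta | 0, sigma^2)
    on sigma in [lo, hi]; marginalises sigma by the trapezoidal rule and
    returns the posterior median of exp(theta), P(exp(theta) > 1) and the
    equal-tailed 95% interval, from the normalised theta grid density.
    """
    lo, hi = sd_bounds
    centre = np.log((O + 0.5) / E)
    theta = np.linspace(centre - theta_halfwidth, centre + theta_halfwidth, n_theta)
    sigma = np.linspace(lo, hi, n_sigma)

    loglik = O * theta - E * np.exp(theta) - gammaln(O + 1)
    logprior = (
        -np.log(sigma)[None, :] - theta[:, None] ** 2 / (2 * sigma[None, :] ** 2)
    )
    logpost = loglik[:, None] + logprior
    logpost -= logpost.max()
    dens_theta = np.trapezoid(np.exp(logpost), sigma, axis=1)
    norm = np.trapezoid(dens_theta, theta)
    dens_theta /= norm

    cdf = np.concatenate([[0.0], np.cumsum((dens_theta[1:] + dens_theta[:-1]) / 2 * np.diff(theta))])
    cdf /= cdf[-1]

    def quantile(q):
        return float(np.interp(q, cdf, theta))

    p_gt1 = float(1.0 - np.interp(0.0, theta, cdf))
    return {
        "smr_median": float(np.exp(quantile(0.5))),
        "cri95": (float(np.exp(quantile(0.025))), float(np.exp(quantile(0.975)))),
        "p_smr": p_gt1,
    }


def cumulative_incidence_enumeration(records, causes):
    """Hand enumeration of the competing-risks estimator on a tiny cohort.

    ``records`` is a list of (time, cause_or_None).  Walks the distinct event
    times, tracking the risk set explicitly, multiplying survival factors and
    accumulating S(t-) d_k / n.  Returns (times, {cause: P_k}, S).
    """
    times = sorted({t for t, c in records if c is not None})
    S = 1.0
    p = {k: 0.0 for k in causes}
    out_t, out_p, out_s = [], [], []
    for t in times:
        n = sum(1 for tt, _ in records if tt >= t)
        d = {k: sum(1 for tt, cc in records if tt == t and cc == k) for k in causes}
        d_all = sum(d.values())
        for k in causes:
            p[k] += S * d[k] / n
        S *= 1 - d_all / n
        out_t.append(t)
        out_p.append(dict(p))
        out_s.append(S)
    return out_t, out_p, out_s


def cox_loglik_1cov(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for a single binary/continuous covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def cox_mle_1cov(times, events, x, grid=(-6, 6), n=20001) -> float:
    """Scalar brute-force grid + golden refinement of the partial likelihood."""
    from scipy.optimize import minimize_scalar

    betas = np.linspace(grid[0], grid[1], n)
    lls = np.array([cox_loglik_1cov(b, times, events, x) for b in betas])
    b0 = betas[np.argmax(lls)]
    res = minimize_scalar(
        lambda b: -cox_loglik_1cov(b, times, events, x),
        bounds=(b0 - 0.01, b0 + 0.01),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
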