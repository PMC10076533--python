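"""Disproportionality statistics for spontaneous-report 2x2 tables.

For every drug–event contingency cell (a, b, c, d) three classical
pharmacovigilance statistics are computed, each with interval bounds:

* **ROR** — reporting odds ratio ``(a*d)/(b*c)`` with a Wald 95% CI on the
  log scale.
* **IC** — information component, a regularised ``log2`` observed/expected
  reporting ratio with exact gamma-posterior credible bounds.
* **EBGM** — the empirical Bayes geometric mean of the posterior reporting
  ratio under the DuMouchel two-component gamma mixture prior (MGPS), with
  the 5th/95th posterior percentiles (EB05 / EBGM95).

*Inverse* signals — pairs reported significantly less often than expected —
are flagged when the relevant upper bound falls below its null value:
ROR upper 95% bound < 1, IC 97.5th percentile < 0, EBGM 95th percentile < 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "MgpsPrior",
    "compute_ror",
    "compute_ic",
    "fit_mgps_prior",
    "compute_ebgm",
    "flag_signals",
]

_Z95 = 1.96  # conventional two-sided 95% Wald multiplier


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the reporting ratio lambda.

    lambda ~ p_mix * Gamma(alpha1, rate=beta1) + (1 - p_mix) * Gamma(alpha2, rate=beta2)
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not 0.0 <= self.p_mix <= 1.0:
            raise ValueError("p_mix must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ROR
# ---------------------------------------------------------------------------

def compute_ror(a, b, c, d, haldane: bool = False):
    """Reporting odds ratio with Wald 95% CI.

    Any zero cell makes the ROR undefined (NaN) unless ``haldane`` adds the
    Haldane–Anscombe +0.5 continuity correction to every cell.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("contingency counts must be non-negative")
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror = np.where(ok, (a * d) / (b * c), np.nan)
        half = _Z95 * np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        lci = np.where(ok, ror * np.exp(-half), np.nan)
        uci = np.where(ok, ror * np.exp(half), np.nan)
    return ror, lci, uci


# ---------------------------------------------------------------------------
# IC
# ---------------------------------------------------------------------------

def compute_ic(a, expected, q_low: float = 0.025, q_high: float = 0.975):
    """Information component with exact gamma-posterior credible bounds.

    The observed count is regularised by +0.5 in both numerator and
    denominator, ``ic = log2((a + 0.5) / (E + 0.5))``; the bounds are log2 of
    the posterior quantiles of ``lambda ~ Gamma(shape=a + 0.5, rate=E + 0.5)``,
    whose mean equals the point estimate's ratio.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = e > 0
        shape = a + 0.5
        rate = e + 0.5
        ic = np.where(ok, np.log2((a + 0.5) / (e + 0.5)), np.nan)
        scale = 1.0 / rate
        lo = np.where(ok, np.log2(stats.gamma.ppf(q_low, shape, scale=scale)), np.nan)
        hi = np.where(ok, np.log2(stats.gamma.ppf(q_high, shape, scale=scale)), np.nan)
    return ic, lo, hi


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

def _mixture_logpmf(a, e, alpha1, beta1, alpha2, beta2, p_mix):
    """Marginal log pmf of counts under the gamma-mixture Poisson model.

    Integrating Poisson(lambda*E) against Gamma(alpha, rate beta) gives a
    negative binomial with size alpha and success prob beta/(beta+E).
    """
    def nb(alpha, beta):
        return (
            special.gammaln(alpha + a)
            - special.gammaln(alpha)
            - special.gammaln(a + 1.0)
            + alpha * np.log(beta / (beta + e))
            + a * np.log(e / (beta + e))
        )

    lp1 = np.log(p_mix) + nb(alpha1, beta1) if p_mix > 0 else np.full_like(a, -np.inf)
    lp2 = (
        np.log1p(-p_mix) + nb(alpha2, beta2)
        if p_mix < 1
        else np.full_like(a, -np.inf)
    )
    return np.logaddexp(lp1, lp2), lp1, lp2


def mgps_loglik(a, e, prior: MgpsPrior) -> float:
    """Total marginal log-likelihood of the cells under ``prior``."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    lp, _, _ = _mixture_logpmf(
        a, e, prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.p_mix
    )
    return float(lp.sum())


def fit_mgps_prior(
    a,
    expected,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    fix_p_mix: float | None = None,
) -> MgpsPrior:
    """Fit the two-gamma mixture prior by marginal maximum likelihood.

    Bounded quasi-Newton (L-BFGS-B) on log-transformed shapes/rates and a
    logit-transformed mixture weight, restarted from ``n_starts`` seeded
    initial points; the best converged optimum is returned with its
    log-likelihood.  ``fix_p_mix`` pins the mixture weight (useful for
    single-component fits).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.size == 0:
        raise ValueError("no cells to fit")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    if np.all(a == 0):
        raise ValueError("degenerate input: every observed count is zero")
    if a.size < 100:
        warnings.warn(
            f"MGPS fit on only {a.size} cells; estimates may be unstable",
            stacklevel=2,
        )

    def unpack(theta):
        la1, lb1, la2, lb2 = theta[:4]
        if fix_p_mix is None:
            p = 1.0 / (1.0 + np.exp(-theta[4]))
        else:
            p = fix_p_mix
        return np.exp(la1), np.exp(lb1), np.exp(la2), np.exp(lb2), p

    def nll(theta):
        a1, b1, a2, b2, p = unpack(theta)
        lp, _, _ = _mixture_logpmf(a, e, a1, b1, a2, b2, p)
        val = -lp.sum()
        return val if np.isfinite(val) else 1e300

    rng = np.random.default_rng(seed)
    ratio = np.clip(a / e, 1e-3, None)
    m = float(np.mean(ratio))
    n_par = 4 if fix_p_mix is not None else 5
    best = None
    for start in range(n_starts):
        if start == 0:
            theta0 = np.array([np.log(0.5), np.log(0.5 / m), np.log(2.0), np.log(2.0 / m), 0.0])
        else:
            theta0 = np.concatenate(
                [rng.normal(0.0, 1.5, size=4), rng.normal(0.0, 1.0, size=1)]
            )
        res = optimize.minimize(
            nll,
            theta0[:n_par],
            method="L-BFGS-B",
            bounds=[(-12, 12)] * 4 + ([(-8, 8)] if n_par == 5 else []),
            options={"ftol": tol, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"MGPS optimisation failed: {best}")
    a1, b1, a2, b2, p = unpack(best.x)
    # canonical order: component 1 has the smaller prior mean (only when both
    # components are free — a pinned weight leaves the other unidentified)
    if fix_p_mix is None and a1 / b1 > a2 / b2:
        a1, b1, a2, b2, p = a2, b2, a1, b1, 1.0 - p
    return MgpsPrior(a1, b1, a2, b2, p, loglik=-float(best.fun))


def _mixture_quantile(q, w1, shape1, rate1, shape2, rate2, iters: int = 200):
    """Vectorised quantile of a two-gamma mixture by bisection.

    The mixture quantile is bracketed by the two component quantiles.
    """
    q1 = stats.gamma.ppf(q, shape1, scale=1.0 / rate1)
    q2 = stats.gamma.ppf(q, shape2, scale=1.0 / rate2)
    lo = np.minimum(q1, q2)
    hi = np.maximum(q1, q2)

    def cdf(x):
        return w1 * stats.gamma.cdf(x, shape1, scale=1.0 / rate1) + (1.0 - w1) * stats.gamma.cdf(
            x, shape2, scale=1.0 / rate2
        )

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = cdf(mid) < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.max(hi - lo) <= 1e-12 * max(1.0, np.max(hi)):
            break
    return 0.5 * (lo + hi)


def compute_ebgm(a, expected, prior: MgpsPrior, q_low: float = 0.05, q_high: float = 0.95):
    """Posterior geometric mean and 5th/95th percentiles under the MGPS prior.

    The posterior is a mixture of Gamma(alpha_i + a, rate beta_i + E) with
    weights updated through the marginal negative-binomial likelihoods;
    ``EBGM = exp(E[log lambda | a])`` using the digamma closed form per
    component; quantiles come from monotone bisection on the mixture CDF.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    _, lp1, lp2 = _mixture_logpmf(
        a, e, prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.p_mix
    )
    # posterior component weight
    w1 = np.exp(lp1 - np.logaddexp(lp1, lp2))
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    mean_log = w1 * (special.digamma(s1) - np.log(r1)) + (1.0 - w1) * (
        special.digamma(s2) - np.log(r2)
    )
    ebgm = np.exp(mean_log)
    eb05 = _mixture_quantile(q_low, w1, s1, r1, s2, r2)
    ebgm95 = _mixture_quantile(q_high, w1, s1, r1, s2, r2)
    return ebgm, eb05, ebgm95


# ---------------------------------------------------------------------------
# signal flagging
# ---------------------------------------------------------------------------

def flag_signals(
    cells: pd.DataFrame,
    methods: tuple[str, ...] = ("ror", "ic", "ebgm"),
    prior: MgpsPrior | None = None,
    haldane: bool = False,
    mgps_seed: int = 0,
) -> pd.DataFrame:
    """Compute the requested statistics for every cell and set inverse flags.

    ``cells`` must carry columns a, b, c, d (and drug/event identifiers,
    which are passed through).  Returns one row per cell with point
    estimates, interval bounds and boolean inverse flags:

    * ``inverse_ror``  iff ror_uci < 1
    * ``inverse_ic``   iff ic975 < 0
    * ``inverse_ebgm`` iff ebgm95 < 1

    Flags are False wherever the statistic is undefined (e.g. a zero cell
    for the ROR).  If ``ebgm`` is requested without a prior, one is fitted
    to the cells first.
    """
    out = cells.copy()
    a = out["a"].to_numpy(float)
    b = out["b"].to_numpy(float)
    c = out["c"].to_numpy(float)
    d = out["d"].to_numpy(float)
    n = a + b + c + d
    expected = (a + b) * (a + c) / n
    out["expected"] = expected

    if "ror" in methods:
        ror, lci, uci = compute_ror(a, b, c, d, haldane=haldane)
        out["ror"], out["ror_lci"], out["ror_uci"] = ror, lci, uci
        out["inverse_ror"] = np.where(np.isnan(uci), False, uci < 1.0)
    if "ic" in methods:
        ic, lo, hi = compute_ic(a, expected)
        out["ic"], out["ic025"], out["ic975"] = ic, lo, hi
        out["inverse_ic"] = np.where(np.isnan(hi), False, hi < 0.0)
    if "ebgm" in methods:
        if prior is None:
            prior = fit_mgps_prior(a[expected > 0], expected[expected > 0], seed=mgps_seed)
        ok = expected > 0
        ebgm = np.full_like(a, np.nan)
        eb05 = np.full_like(a, np.nan)
        ebgm95 = np.full_like(a, np.nan)
        ebgm[ok], eb05[ok], ebgm95[ok] = compute_ebgm(a[ok], expected[ok], prior)
        out["ebgm"], out["eb05"], out["ebgm95"] = ebgm, eb05, ebgm95
        out["inverse_ebgm"] = np.where(np.isnan(ebgm95), False, ebgm95 < 1.0)

    for m in methods:
        col = f"inverse_{m}"
        if col in out:
            logger.info("%s: %d inverse signals of %d cells", m, int(out[col].sum()), len(out))
    return out
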