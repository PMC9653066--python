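"""Linear regressions and the Bayesian mediation (path) model.

The path model links a binary treatment T to an outcome Y through a mediator
M with two Gaussian regressions,

    M = alpha0 + a * T + e1,        e1 ~ N(0, sigma1^2)
    Y = beta0 + b * M + c * T + e2, e2 ~ N(0, sigma2^2)

under Normal(0, 10^2) priors on every coefficient and Inverse-Gamma(0.001,
0.001) priors on the variances.  Because both blocks are conjugate, posterior
draws come from a plain Gibbs sampler.  A pathway is accepted when its 95%
credible interval excludes zero; the indirect (mediated) effect is the
posterior of a * b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "PathModelResult",
    "fit_regression",
    "delta_degree",
    "fit_path_model",
]

PRIOR_COEF_VAR = 100.0
PRIOR_IG_SHAPE = 0.001
PRIOR_IG_SCALE = 0.001


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


@dataclass
class PathModelResult:
    summary: pd.DataFrame  # per pathway: mean, sd, ci_low, ci_high, accepted, rhat
    n_chains: int
    n_iter: int
    burn_in: int
    converged: bool
    draws: dict = field(default_factory=dict, repr=False)

    def accepted(self, pathway: str) -> bool:
        return bool(self.summary.loc[pathway, "accepted"])


def fit_regression(x, y) -> RegressionResult:
    """Ordinary least squares with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )


def delta_degree(classes, signed: bool = False) -> pd.Series:
    """Per-shared-node degree change between two networks.

    Accepts a :class:`~paircomm.network.DegreeClasses` (uses its
    ``degree_pairs``) or a DataFrame with columns degree_a, degree_b.
    Absolute by default; ``signed=True`` returns degree_b - degree_a.
    """
    pairs = getattr(classes, "degree_pairs", classes)
    if len(pairs) == 0:
        raise ValueError("no shared nodes between the networks")
    d = pairs["degree_b"] - pairs["degree_a"]
    out = d if signed else d.abs()
    return out.rename("delta_degree")


def _gibbs_regression(x, y, n_iter, rng):
    """Conjugate Gibbs for y = X beta + e; returns (betas, sigma2) draws."""
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    prior_prec = np.eye(p) / PRIOR_COEF_VAR
    beta = np.zeros(p)
    sigma2 = float(np.var(y)) or 1.0
    betas = np.empty((n_iter, p))
    sigmas = np.empty(n_iter)
    for it in range(n_iter):
        prec = xtx / sigma2 + prior_prec
        cov = np.linalg.inv(prec)
        mean = cov @ (xty / sigma2)
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        resid = y - x @ beta
        shape = PRIOR_IG_SHAPE + n / 2.0
        scale = PRIOR_IG_SCALE + 0.5 * float(resid @ resid)
        sigma2 = scale / rng.gamma(shape)
        betas[it] = beta
        sigmas[it] = sigma2
    return betas, sigmas


def fit_path_model(
    treatment,
    mediator,
    outcome,
    n_chains: int = 4,
    n_iter: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
    standardize: bool = True,
) -> PathModelResult:
    """Gibbs-sampled posterior of the mediation pathways a, b, c and a*b.

    ``treatment`` is binary; variables are z-scored by default so estimates
    are comparable across pathways.  Split-R-hat above 1.1 on any pathway
    flags the result as non-converged (it is still returned).
    """
    t = np.asarray(treatment)
    levels = np.unique(t)  # sorted: the encoding is label-order invariant
    if len(levels) != 2:
        raise ValueError("treatment must have exactly two levels")
    t = (t == levels[1]).astype(float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = t.size
    if n < 6 or m.size != n or y.size != n:
        raise ValueError("need >= 6 complete observations")
    if np.ptp(m) == 0 or np.ptp(y) == 0:
        raise ValueError("mediator and outcome must vary")
    if standardize:
        t = (t - t.mean()) / t.std()
        m = (m - m.mean()) / m.std()
        y = (y - y.mean()) / y.std()
    x1 = np.column_stack([np.ones(n), t])
    x2 = np.column_stack([np.ones(n), m, t])

    keep = n_iter - burn_in
    if keep <= 1:
        raise ValueError("n_iter must exceed burn_in by at least 2")
    chains = {k: np.empty((n_chains, keep)) for k in ("a", "b", "c", "indirect")}
    ss = np.random.SeedSequence(seed)
    for ch, sub in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(sub)
        b1, _ = _gibbs_regression(x1, m, n_iter, rng)
        b2, _ = _gibbs_regression(x2, y, n_iter, rng)
        a_draws = b1[burn_in:, 1]
        b_draws = b2[burn_in:, 1]
        c_draws = b2[burn_in:, 2]
        chains["a"][ch] = a_draws
        chains["b"][ch] = b_draws
        chains["c"][ch] = c_draws
        chains["indirect"][ch] = a_draws * b_draws

    rows = {}
    converged = True
    for name, draws in chains.items():
        flat = draws.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rhat = float(az.rhat(draws)) if n_chains > 1 else np.nan
        if n_chains > 1 and rhat > 1.1:
            converged = False
        rows[name] = {
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "accepted": bool(lo > 0 or hi < 0),
            "rhat": rhat,
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return PathModelResult(
        summary=summary,
        n_chains=n_chains,
        n_iter=n_iter,
        burn_in=burn_in,
        converged=converged,
        draws=chains,
    )
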