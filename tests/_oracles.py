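"""Independent oracles used only by the test suite.

These deliberately re-derive quantities by routes different from the
package implementation: exhaustive enumeration and Monte-Carlo subsampling
for rarefaction, adaptive Gauss-Hermite quadrature for the Poisson mixed
model, and black-box root finding for the effectiveness algebra.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import fsolve, minimize
from scipy.special import gammaln


def rarefaction_enumerate(counts, n: int) -> float:
    """Exhaustive mean richness over all C(N, n) subsets of individuals."""
    individuals = []
    for idx, c in enumerate(counts):
        individuals.extend([idx] * int(c))
    vals = [len(set(sub)) for sub in combinations(individuals, n)]
    return float(np.mean(vals)) if vals else 0.0


def rarefaction_monte_carlo(counts, n: int, n_resamples: int, rng) -> tuple[float, float]:
    """Subsampling estimate of expected richness and its Monte-Carlo SE.

    Each resample draws ``n`` individuals without replacement (via random
    permutation of the individual labels) and counts distinct species.
    """
    individuals = np.repeat(np.arange(len(counts)), np.asarray(counts, dtype=int))
    order = np.argsort(rng.random((n_resamples, individuals.size)), axis=1)[:, :n]
    picked = np.sort(individuals[order], axis=1)
    vals = 1 + np.count_nonzero(np.diff(picked, axis=1), axis=1)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_resamples))


def aghq_loglik(beta, log_sd, y, X, codes, nodes: int = 21) -> float:
    """Poisson GLMM marginal log-likelihood, one grouping factor, AGQ."""
    sd = np.exp(log_sd)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(nodes)
    ll = 0.0
    eta0 = X @ beta
    for g in np.unique(codes):
        m = codes == g
        yg, e0 = y[m], eta0[m]
        u = 0.0
        for _ in range(60):
            mu = np.exp(e0 + u)
            g1 = np.sum(yg - mu) - u / sd**2
            g2 = -np.sum(mu) - 1.0 / sd**2
            step = -g1 / g2
            u += step
            if abs(step) < 1e-13:
                break
        tau = 1.0 / np.sqrt(-g2)
        z = u + tau * gh_x
        f = np.array(
            [np.sum(yg * (e0 + zi) - np.exp(e0 + zi)) - 0.5 * zi**2 / sd**2 for zi in z]
        )
        fmax = f.max()
        val = np.log(np.sum(gh_w * np.exp(f - fmax + 0.5 * gh_x**2))) + fmax + np.log(tau)
        ll += val - 0.5 * np.log(2 * np.pi * sd**2) - np.sum(gammaln(yg + 1))
    return float(ll)


def fit_poisson_aghq(y, X, codes, nodes: int = 21):
    """Maximize the AGQ marginal likelihood over (beta, log sd)."""
    p = X.shape[1]
    b0 = np.zeros(p)
    b0[0] = np.log(max(y.mean(), 0.1))
    x0 = np.concatenate([b0, [np.log(0.5)]])
    res = minimize(
        lambda x: -aghq_loglik(x[:p], x[p], y, X, codes, nodes),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 40000, "maxfev": 40000},
    )
    return res.x[:p], float(np.exp(res.x[p])), float(-res.fun)


def solve_io_rootfind(rho: float, a: float, r: float) -> tuple[float, float]:
    """(i, o) from the two effectiveness equations via black-box fsolve."""

    def eqs(x):
        i, o = x
        return [i - rho * o, a * i + (1.0 - a) * o - (1.0 - r)]

    i, o = fsolve(eqs, [1.0 - r, 1.0 - r], xtol=1e-13)
    return float(i), float(o)
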