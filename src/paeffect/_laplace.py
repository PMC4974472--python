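"""Poisson log-link mixed model fitted by Laplace approximation.

The marginal likelihood of a Poisson GLMM with independent Gaussian random
intercepts (any number of crossed/nested grouping factors, including an
observation-level factor for overdispersion) is approximated by Laplace's
method around the conditional mode of the random effects:

    l(beta, theta) ~= log p(y | beta, u_hat) + log p(u_hat | theta)
                      + (q/2) log 2*pi - 1/2 log det H(u_hat),

with ``H = Z' W Z + D^{-1}`` the negative Hessian of the joint
log-density in ``u``. The conditional mode is found by penalized Newton
iterations (equivalently penalized IRLS); the outer maximization over the
fixed effects and the log standard deviations runs in two stages: a fast
profile stage that optimizes the joint (beta, u) mode over the variance
parameters only, then a joint quasi-Newton polish of the exact Laplace
objective over (beta, theta).

Maximum-likelihood (never REML-like) objectives throughout, so that
likelihood-ratio tests between nested fixed-effect structures are valid.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import gammaln

__all__ = ["PoissonLaplaceGLMM"]

_LOG_SD_MIN = -7.0
_LOG_SD_MAX = 3.0
_SINGULAR_LOG_SD = -5.0


class PoissonLaplaceGLMM:
    """Poisson(log) mixed model with independent random intercepts.

    Parameters
    ----------
    y
        Nonnegative integer counts, length n.
    X
        Fixed-effects design matrix, n x p (including the intercept).
    factors
        Ordered mapping of grouping-factor name to an integer code array of
        length n (codes 0..q_f-1). One random intercept variance per factor.
    """

    def __init__(self, y, X, factors: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or not np.all(self.y == np.floor(self.y)):
            raise ValueError("Poisson responses must be nonnegative integers")
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        if not factors:
            raise ValueError("at least one grouping factor is required")
        self.factor_names = list(factors)
        blocks, sizes = [], []
        for name in self.factor_names:
            codes = np.asarray(factors[name], dtype=np.int64)
            if codes.shape != (self.n,):
                raise ValueError(f"factor {name}: codes must have length n")
            q_f = int(codes.max()) + 1
            blocks.append(
                sp.csr_matrix(
                    (np.ones(self.n), (np.arange(self.n), codes)), shape=(self.n, q_f)
                )
            )
            sizes.append(q_f)
        self.Z = sp.hstack(blocks, format="csr")
        self.Zt = self.Z.T.tocsr()
        self.q = self.Z.shape[1]
        self.sizes = np.array(sizes)
        # Map each random-effect index to its factor.
        self.u_factor = np.repeat(np.arange(len(sizes)), sizes)
        self._ylogfact = float(np.sum(gammaln(self.y + 1)))
        self._u_cache = np.zeros(self.q)

    # -- inner problem ------------------------------------------------------

    def _dinv(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(-2.0 * theta)[self.u_factor]

    def _penalized(self, eta, u, dinv) -> float:
        return float(np.sum(self.y * eta - np.exp(eta)) - 0.5 * np.sum(dinv * u * u))

    def _solve_mode(self, beta, dinv, u0=None, tol=1e-10, max_iter=50):
        """Penalized Newton/IRLS for the conditional mode of u."""
        u = np.zeros(self.q) if u0 is None else u0.copy()
        xb = self.X @ beta
        eta = xb + self.Z @ u
        f = self._penalized(eta, u, dinv)
        lu = None
        for _ in range(max_iter):
            mu = np.exp(eta)
            grad = self.Zt @ (self.y - mu) - dinv * u
            gnorm = np.linalg.norm(grad)
            H = (self.Zt @ sp.diags(mu) @ self.Z + sp.diags(dinv)).tocsc()
            lu = splu(H, permc_spec="MMD_AT_PLUS_A")
            if gnorm < tol * max(1.0, abs(f)):
                break
            step = lu.solve(grad)
            # Backtracking to guarantee ascent of the penalized objective.
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                eta_new = xb + self.Z @ u_new
                f_new = self._penalized(eta_new, u_new, dinv)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            if f_new < f - 1e-8:
                break
            u, eta, f = u_new, eta_new, f_new
        return u, eta, lu

    def _laplace_nll(self, params: np.ndarray) -> float:
        beta = params[: self.p]
        theta = np.clip(params[self.p :], _LOG_SD_MIN, _LOG_SD_MAX)
        dinv = self._dinv(theta)
        u, eta, lu_fact = self._solve_mode(beta, dinv, u0=self._u_cache)
        self._u_cache = u
        mu = np.exp(eta)
        H = (self.Zt @ sp.diags(mu) @ self.Z + sp.diags(dinv)).tocsc()
        lu_fact = splu(H, permc_spec="MMD_AT_PLUS_A")
        logdet_h = float(np.sum(np.log(np.abs(lu_fact.U.diagonal()))))
        logdet_d = float(-np.sum(np.log(dinv)))
        ll = (
            np.sum(self.y * eta - mu)
            - self._ylogfact
            - 0.5 * np.sum(dinv * u * u)
            - 0.5 * (logdet_d + logdet_h)
        )
        return -float(ll)

    # -- profile (joint-mode) stage ----------------------------------------

    def _joint_mode(self, theta, beta0, u0, tol=1e-9, max_iter=80):
        """Newton over the stacked (beta, u) given variance parameters."""
        dinv = self._dinv(theta)
        beta, u = beta0.copy(), u0.copy()
        eta = self.X @ beta + self.Z @ u
        f = self._penalized(eta, u, dinv)
        for _ in range(max_iter):
            mu = np.exp(eta)
            gb = self.X.T @ (self.y - mu)
            gu = self.Zt @ (self.y - mu) - dinv * u
            gnorm = np.linalg.norm(np.concatenate([gb, gu]))
            if gnorm < tol * max(1.0, abs(f)):
                break
            W = sp.diags(mu)
            A = self.X.T @ (W @ self.X)
            B = (self.Zt @ W @ self.X).toarray() if sp.issparse(self.Zt @ W @ self.X) else self.Zt @ (W @ self.X)
            Huu = (self.Zt @ W @ self.Z + sp.diags(dinv)).tocsc()
            lu_fact = splu(Huu, permc_spec="MMD_AT_PLUS_A")
            # Block elimination: solve for beta step via the Schur complement.
            HinvB = lu_fact.solve(B)
            Hinv_gu = lu_fact.solve(gu)
            S = A - B.T @ HinvB
            rhs_b = gb - B.T @ Hinv_gu
            try:
                db = np.linalg.solve(S, rhs_b)
            except np.linalg.LinAlgError:
                db = np.linalg.lstsq(S, rhs_b, rcond=None)[0]
            du = Hinv_gu - HinvB @ db
            t = 1.0
            for _ in range(30):
                bn, un = beta + t * db, u + t * du
                etan = self.X @ bn + self.Z @ un
                fn = self._penalized(etan, un, dinv)
                if fn >= f - 1e-12:
                    break
                t *= 0.5
            if fn < f - 1e-8:
                break
            beta, u, eta, f = bn, un, etan, fn
        return beta, u, eta

    def _profile_nll(self, theta, state):
        beta, u, eta = self._joint_mode(theta, state["beta"], state["u"])
        state["beta"], state["u"] = beta, u
        dinv = self._dinv(theta)
        mu = np.exp(eta)
        H = (self.Zt @ sp.diags(mu) @ self.Z + sp.diags(dinv)).tocsc()
        lu_fact = splu(H, permc_spec="MMD_AT_PLUS_A")
        logdet_h = float(np.sum(np.log(np.abs(lu_fact.U.diagonal()))))
        logdet_d = float(-np.sum(np.log(dinv)))
        ll = (
            np.sum(self.y * eta - mu)
            - self._ylogfact
            - 0.5 * np.sum(dinv * u * u)
            - 0.5 * (logdet_d + logdet_h)
        )
        return -float(ll)

    # -- public fit ---------------------------------------------------------

    def fit(self, start_sd: float = 0.5, gtol: float = 1e-6) -> dict:
        """Two-stage maximum-likelihood fit; returns a plain dict of results."""
        # Starting fixed effects from a Poisson GLM ignoring random effects.
        beta0 = self._glm_start()
        k = len(self.factor_names)
        state = {"beta": beta0, "u": np.zeros(self.q)}
        theta0 = np.full(k, np.log(start_sd))
        prof = minimize(
            self._profile_nll,
            theta0,
            args=(state,),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        x0 = np.concatenate([state["beta"], np.clip(prof.x, _LOG_SD_MIN, _LOG_SD_MAX)])
        self._u_cache = state["u"]
        bounds = [(None, None)] * self.p + [(_LOG_SD_MIN, _LOG_SD_MAX)] * k
        opt = minimize(
            self._laplace_nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-9, "gtol": gtol},
        )
        beta = opt.x[: self.p]
        theta = opt.x[self.p :]
        nll = self._laplace_nll(opt.x)  # refresh u cache at the optimum
        u = self._u_cache
        eta = self.X @ beta + self.Z @ u
        mu = np.exp(eta)
        se, cov = self._fixed_cov(mu, theta)
        sigma2 = {n: float(np.exp(2 * t)) for n, t in zip(self.factor_names, theta)}
        singular = bool(np.any(theta <= _SINGULAR_LOG_SD))
        return {
            "beta": beta,
            "se": se,
            "cov_beta": cov,
            "sigma2": sigma2,
            "loglik": -float(nll),
            "converged": bool(opt.success or opt.status == 1),
            "singular": singular,
            "u": u,
            "mu": mu,
            "n_iter": int(opt.nit),
        }

    def _glm_start(self) -> np.ndarray:
        """Plain Poisson GLM Newton iterations for starting values."""
        beta = np.zeros(self.p)
        beta[0] = np.log(max(self.y.mean(), 1e-3))
        for _ in range(25):
            eta = np.clip(self.X @ beta, -30, 30)
            mu = np.exp(eta)
            g = self.X.T @ (self.y - mu)
            Hb = self.X.T @ (self.X * mu[:, None])
            try:
                step = np.linalg.solve(Hb, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(Hb, g, rcond=None)[0]
            beta = beta + step
            if np.linalg.norm(step) < 1e-10:
                break
        return beta

    def _fixed_cov(self, mu, theta):
        """Wald covariance of beta: Schur complement of the joint Hessian."""
        dinv = self._dinv(np.clip(theta, _LOG_SD_MIN, _LOG_SD_MAX))
        W = sp.diags(mu)
        A = self.X.T @ (self.X * mu[:, None])
        B = (self.Zt @ W) @ self.X
        B = B.toarray() if sp.issparse(B) else np.asarray(B)
        H = (self.Zt @ W @ self.Z + sp.diags(dinv)).tocsc()
        lu_fact = splu(H, permc_spec="MMD_AT_PLUS_A")
        S = A - B.T @ lu_fact.solve(B)
        try:
            cov = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(S)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return se, cov
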