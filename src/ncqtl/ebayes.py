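"""Empirical-Bayes shrinkage estimation of selected genetic effects.

The working model is Y = X beta + Z gamma + eps with X a column of ones
(beta is the population mean mu), one column of Z per selected effect and
eps ~ N(0, sigma^2 I).  Each effect gamma_k carries a normal prior
N(0, sigma_k^2) whose variance in turn has a scaled inverse chi-square
prior Inv-chi2(tau, omega); the default hyperparameters (0, 0) make the
prior minimally informative.  Marginally, Y ~ N(X beta, V) with
V = sum_k Z_k Z_k' sigma_k^2 + I sigma^2.

Estimation is an EM algorithm on the posterior mode of the variance
components:

* E-step:  E(gamma_k)  = sigma_k^2 Z_k' V^-1 (Y - X beta)
           var(gamma_k) = sigma_k^2 - sigma_k^2 Z_k' V^-1 Z_k sigma_k^2
* M-step:  sigma_k^2 = [E(gamma_k' gamma_k) + omega] / (tau + 2 + 1)
           beta      = (X' V^-1 X)^-1 X' V^-1 Y
           sigma^2   = (Y - X beta)' [Y - X beta - sum_k Z_k E(gamma_k)] / n

iterated to convergence.  Shrinkage drives the variance of irrelevant
effects to the floor, at which point their posterior mean is reported as
exactly zero and the effect is treated as excluded from the model.

Linear algebra goes through the Woodbury identity on the q <= a few
hundred selected columns by default, so V (n x n) is never formed; a
direct dense-V solver is available and algebraically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EBayesConfig:
    """Hyperparameters and numerical controls for the EM fit."""

    tau: float = 0.0
    omega: float = 0.0
    tol: float = 1e-6
    max_iter: int = 1000
    var_floor: float = 1e-10
    zero_threshold: float = 1e-6
    solver: str = "auto"  # "auto" | "woodbury" | "direct"


@dataclass
class EBayesFit:
    """Converged state of the empirical-Bayes model."""

    beta: float
    sigma2: float
    gamma: np.ndarray
    gamma_var: np.ndarray
    effect_variances: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    objective_path: np.ndarray
    n_iter: int
    converged: bool
    zero_threshold: float = 1e-6

    @property
    def nonzero(self) -> np.ndarray:
        """Effects retained as non-zero after shrinkage."""
        return np.abs(self.gamma) > self.zero_threshold

    def to_dict(self, descriptors=None, markers=None) -> dict:
        effects = []
        for k in range(len(self.gamma)):
            rec = {"gamma": float(self.gamma[k]),
                   "sigma2_k": float(self.effect_variances[k])}
            if descriptors is not None:
                d = descriptors[k]
                rec["effect"] = d.name(markers) if markers is not None else repr(d)
            effects.append(rec)
        return {"beta": float(self.beta), "sigma2": float(self.sigma2),
                "loglik": float(self.loglik), "converged": bool(self.converged),
                "effects": effects}


class _WoodburySolver:
    """Solves in V = Z D Z' + sigma2 I through the q x q capacitance matrix."""

    def __init__(self, Z: np.ndarray, M: np.ndarray, d: np.ndarray, sigma2: float):
        self.Z, self.M, self.d, self.sigma2 = Z, M, d, sigma2
        A = M + sigma2 * np.diag(1.0 / d)
        try:
            self._cho = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(
                f"covariance V not positive definite (sigma2={sigma2:g}, "
                f"min sigma2_k={d.min():g})") from exc

    def solve(self, v: np.ndarray) -> np.ndarray:
        """V^-1 v."""
        w = self.Z.T @ v
        return (v - self.Z @ linalg.cho_solve(self._cho, w)) / self.sigma2

    def quad_diag(self) -> np.ndarray:
        """diag(Z' V^-1 Z)."""
        S = linalg.cho_solve(self._cho, self.M)
        return (np.diag(self.M) - np.einsum("kj,jk->k", self.M, S)) / self.sigma2

    def logdet(self, n: int) -> float:
        q = len(self.d)
        chol_diag = np.diag(self._cho[0])
        return ((n - q) * np.log(self.sigma2)
                + 2.0 * np.sum(np.log(chol_diag))
                + np.sum(np.log(self.d)))


class _DirectSolver:
    """Reference route: dense n x n factorization of V."""

    def __init__(self, Z: np.ndarray, M: np.ndarray, d: np.ndarray, sigma2: float):
        self.Z, self.d, self.sigma2 = Z, d, sigma2
        n = Z.shape[0]
        V = (Z * d) @ Z.T + sigma2 * np.eye(n)
        try:
            self._cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("covariance V not positive definite") from exc

    def solve(self, v: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self._cho, v)

    def quad_diag(self) -> np.ndarray:
        W = linalg.cho_solve(self._cho, self.Z)
        return np.einsum("ik,ik->k", self.Z, W)

    def logdet(self, n: int) -> float:
        return 2.0 * np.sum(np.log(np.diag(self._cho[0])))


def _make_solver(solver: str, Z, M, d, sigma2):
    if solver == "direct":
        return _DirectSolver(Z, M, d, sigma2)
    if solver in ("auto", "woodbury"):
        return _WoodburySolver(Z, M, d, sigma2)
    raise ValueError(f"unknown solver {solver!r}")


def log_likelihood(y: np.ndarray, Z: np.ndarray, beta: float, sigma2: float,
                   effect_variances: np.ndarray, solver: str = "auto") -> float:
    """Log marginal likelihood: MVN density of y at mean X beta, covariance V."""
    y = np.asarray(y, dtype=float)
    n = y.size
    r = y - beta
    if Z is None or Z.shape[1] == 0:
        quad = float(r @ r) / sigma2
        logdet = n * np.log(sigma2)
    else:
        d = np.asarray(effect_variances, dtype=float)
        s = _make_solver(solver, Z, Z.T @ Z, d, sigma2)
        quad = float(r @ s.solve(r))
        logdet = s.logdet(n)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def log_prior_variances(effect_variances: np.ndarray, tau: float = 0.0,
                        omega: float = 0.0) -> float:
    """Log of the scaled inverse chi-square prior on the variance components.

    log p(sigma_k^2) = -((tau + 2)/2) log sigma_k^2 - omega / (2 sigma_k^2)
    (up to an additive constant), summed over effects.  Together with the
    marginal likelihood this is the objective the EM ascends: shrinking a
    variance component can lower the marginal likelihood while the
    penalized objective still increases.
    """
    d = np.asarray(effect_variances, dtype=float)
    if d.size == 0:
        return 0.0
    return float(np.sum(-(tau + 2.0) / 2.0 * np.log(d) - omega / (2.0 * d)))


def posterior_effects(y: np.ndarray, Z: np.ndarray, beta: float, sigma2: float,
                      effect_variances: np.ndarray, solver: str = "auto"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """One E-step: posterior means and variances of the effects.

    E(gamma_k) = sigma_k^2 Z_k' V^-1 (y - X beta);
    var(gamma_k) = sigma_k^2 - sigma_k^2 Z_k' V^-1 Z_k sigma_k^2.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(effect_variances, dtype=float)
    s = _make_solver(solver, Z, Z.T @ Z, d, sigma2)
    r = y - beta
    gamma = d * (Z.T @ s.solve(r))
    var = d - d**2 * s.quad_diag()
    return gamma, np.maximum(var, 0.0)


class EmpiricalBayesRegression(BaseEstimator, RegressorMixin):
    """Empirical-Bayes shrinkage regression with per-coefficient variances.

    Scikit-learn-style estimator.  ``fit(Z, y)`` runs the EM described in
    the module docstring; the intercept is the only fixed effect.

    Parameters
    ----------
    tau, omega : scaled inverse chi-square hyperparameters of the prior on
        each coefficient variance (default (0, 0)).
    tol : convergence tolerance on the max absolute change over
        (beta, sigma2, all sigma_k^2).
    max_iter : EM iteration cap.
    var_floor : lower bound on each sigma_k^2; a coefficient whose variance
        hits the floor is reported as exactly zero.
    solver : "woodbury" (default via "auto") or "direct" dense-V route.

    Attributes
    ----------
    intercept_ : float            -- beta (population mean).
    coef_ : ndarray (q,)          -- posterior means E(gamma_k).
    coef_var_ : ndarray (q,)      -- posterior variances var(gamma_k).
    effect_variances_ : ndarray   -- converged sigma_k^2.
    sigma2_ : float               -- residual variance.
    loglik_ : float               -- log marginal likelihood at convergence.
    loglik_path_ : ndarray        -- log marginal likelihood per iteration.
    n_iter_ : int, converged_ : bool
    """

    def __init__(self, tau: float = 0.0, omega: float = 0.0, tol: float = 1e-6,
                 max_iter: int = 1000, var_floor: float = 1e-10,
                 zero_threshold: float = 1e-6, solver: str = "auto",
                 track_loglik: bool = True):
        self.tau = tau
        self.omega = omega
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.zero_threshold = zero_threshold
        self.solver = solver
        self.track_loglik = track_loglik

    def fit(self, Z, y):
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if Z.ndim != 2:
            raise ValueError("Z must be 2-dimensional (n x q)")
        n, q = Z.shape
        if n != y.size:
            raise ValueError("Z and y have incompatible shapes")
        if n < 2:
            raise ValueError("need at least 2 observations")
        if not (np.isfinite(Z).all() and np.isfinite(y).all()):
            raise ValueError("Z and y must be finite (no missing values)")

        beta = float(y.mean())
        sigma2 = float(y.var())  # divisor n
        if q == 0:
            ll = log_likelihood(y, None, beta, max(sigma2, 1e-300), np.empty(0))
            self._finish(beta, sigma2, np.empty(0), np.empty(0), np.empty(0),
                         ll, np.array([ll]), np.array([ll]), 0, True)
            return self

        sigma2 = max(sigma2, 1e-12)
        d = np.full(q, sigma2 / q)  # initial sigma_k^2 on the data scale
        gamma = np.zeros(q)
        M = Z.T @ Z
        ones = np.ones(n)
        path = []
        objective = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # E-step at current (beta, sigma2, d)
            solver = _make_solver(self.solver, Z, M, d, sigma2)
            r = y - beta
            gamma = d * (Z.T @ solver.solve(r))
            quad = solver.quad_diag()
            var_g = np.maximum(d - d**2 * quad, 0.0)
            e_gg = gamma**2 + var_g

            # M-step: variance components, then GLS mean, then residual variance
            d_new = np.maximum((e_gg + self.omega) / (self.tau + 2.0 + 1.0),
                               self.var_floor)
            solver_b = _make_solver(self.solver, Z, M, d_new, sigma2)
            viy = solver_b.solve(y)
            vi1 = solver_b.solve(ones)
            beta_new = float(ones @ viy) / float(ones @ vi1)
            r_new = y - beta_new
            sigma2_new = float(r_new @ (r_new - Z @ gamma)) / n
            sigma2_new = max(sigma2_new, 1e-12)

            delta = max(abs(beta_new - beta), abs(sigma2_new - sigma2),
                        float(np.max(np.abs(d_new - d))))
            beta, sigma2, d = beta_new, sigma2_new, d_new
            if self.track_loglik:
                ll_it = log_likelihood(y, Z, beta, sigma2, d, self.solver)
                path.append(ll_it)
                objective.append(ll_it + log_prior_variances(d, self.tau, self.omega))
            if delta < self.tol:
                converged = True
                break

        # final E-step at the converged parameters
        gamma, var_g = posterior_effects(y, Z, beta, sigma2, d, self.solver)
        gamma = np.where(d <= self.var_floor, 0.0, gamma)
        ll = path[-1] if path else log_likelihood(y, Z, beta, sigma2, d, self.solver)
        self._finish(beta, sigma2, gamma, var_g, d, ll, np.asarray(path),
                     np.asarray(objective), it, converged)
        return self

    def _finish(self, beta, sigma2, gamma, var_g, d, ll, path, objective,
                n_iter, converged):
        self.intercept_ = beta
        self.sigma2_ = sigma2
        self.coef_ = gamma
        self.coef_var_ = var_g
        self.effect_variances_ = d
        self.loglik_ = ll
        self.loglik_path_ = path
        self.objective_path_ = objective
        self.n_iter_ = n_iter
        self.converged_ = converged

    def predict(self, Z):
        Z = np.asarray(Z, dtype=float)
        if self.coef_.size == 0:
            return np.full(Z.shape[0], self.intercept_)
        return self.intercept_ + Z @ self.coef_

    def fit_result(self) -> EBayesFit:
        return EBayesFit(self.intercept_, self.sigma2_, self.coef_, self.coef_var_,
                         self.effect_variances_, self.loglik_, self.loglik_path_,
                         self.objective_path_, self.n_iter_, self.converged_,
                         self.zero_threshold)


def fit_empirical_bayes(y, Z, config: EBayesConfig | None = None) -> EBayesFit:
    """Fit the empirical-Bayes model; thin functional wrapper over the estimator."""
    config = config or EBayesConfig()
    est = EmpiricalBayesRegression(
        tau=config.tau, omega=config.omega, tol=config.tol,
        max_iter=config.max_iter, var_floor=config.var_floor,
        zero_threshold=config.zero_threshold, solver=config.solver)
    est.fit(np.asarray(Z, dtype=float), y)
    return est.fit_result()
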