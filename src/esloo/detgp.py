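"""Deterministic GP regression with profiled variance and trend.

A light interpolating GP used for the auxiliary surfaces of the
acquisition machinery (the ES-LOO error surface, the variance-error
surface, and the mean/variance GPs of the many-replicates mode).  The
marginal variance ``sigma^2`` and constant trend ``beta`` are profiled
analytically; lengthscales (and optionally a nugget) are estimated by
multi-start maximum likelihood with analytic gradients.

A lower bound can be placed on the lengthscales; the acquisition code
uses ``theta_floor = -0.5 / log(1e-8)`` to stop the error surface's
correlation lengths collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .kernels import MaternKernel

#: lower bound applied to the ES-LOO surface lengthscales
THETA_FLOOR = -0.5 / np.log(1e-8)


@dataclass
class DeterministicGP:
    """Fitted interpolating GP with constant trend.

    ``nugget`` is the relative jitter on the correlation diagonal; the
    observation noise is ``sigma^2 * nugget``.
    """

    kernel: MaternKernel
    nugget: float
    X: np.ndarray
    y: np.ndarray
    trend: float

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        K = self.kernel.correlation(self.X) + self.nugget * np.eye(n)
        self._cho = linalg.cho_factor(K, lower=True)
        self._alpha = linalg.cho_solve(self._cho, self.y - self.trend)
        self._Kinv = linalg.cho_solve(self._cho, np.eye(n))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def predict(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and (latent, noise-free) variance."""
        points = np.atleast_2d(np.asarray(points, float))
        c = self.kernel.correlation(points, self.X)
        mean = self.trend + c @ self._alpha
        sol = linalg.cho_solve(self._cho, c.T)
        var = self.kernel.variance * np.clip(1.0 - np.sum(c * sol.T, axis=1), 0.0, None)
        return mean, var

    def correlation(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Prior correlation between point sets under the fitted kernel."""
        return self.kernel.correlation(A, B)

    def loo(self) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form leave-one-out mean and latent variance at each
        training point (hyperparameters frozen)."""
        d = np.diag(self._Kinv)
        m_loo = self.y - self._alpha / d
        k_loo = np.clip(self.kernel.variance * (1.0 / d - self.nugget), 0.0, None)
        return m_loo, k_loo


def _neg_ll_and_grad(z, X, y, nu, estimate_nugget, fixed_nugget):
    n, p = X.shape
    theta = np.exp(z[:p])
    g = float(np.exp(z[p])) if estimate_nugget else fixed_nugget
    mk = MaternKernel(1.0, theta, nu)
    C, dC = mk.correlation_with_grad(X)
    K = C + g * np.eye(n)
    try:
        cho = linalg.cho_factor(K, lower=True)
    except linalg.LinAlgError:
        return 1e25, np.zeros_like(z)
    Kinv = linalg.cho_solve(cho, np.eye(n))
    ones = np.ones(n)
    Ki1 = Kinv @ ones
    beta = float((Ki1 @ y) / (Ki1 @ ones))
    e = y - beta
    alpha = Kinv @ e
    qf = float(e @ alpha)
    qf = max(qf, 1e-300)
    ll = -0.5 * n * np.log(qf / n) - np.sum(np.log(np.diag(cho[0]))) - 0.5 * n
    A = 0.5 * (n * np.outer(alpha, alpha) / qf - Kinv)
    grad = np.zeros_like(z)
    for j in range(p):
        grad[j] = np.sum(A * dC[j])
    if estimate_nugget:
        grad[p] = g * np.trace(A)
    return -ll, -grad


def fit_deterministic_gp(
    X: np.ndarray,
    y: np.ndarray,
    nu: float = 2.5,
    theta_floor: float | None = None,
    nugget: float | str = 1e-8,
    n_starts: int = 3,
    seed: int = 0,
    theta_max: float = 10.0,
) -> DeterministicGP:
    """Maximum-likelihood fit of :class:`DeterministicGP`.

    ``nugget`` is either a fixed relative jitter or ``"estimate"``.
    Constant-response data short-circuits to a flat surface.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y sizes disagree")
    lo_theta = theta_floor if theta_floor is not None else 1e-3
    if np.ptp(y) == 0.0:
        # flat data: any kernel interpolates; keep variance tiny
        return DeterministicGP(MaternKernel(1e-12, np.full(p, 1.0), nu),
                               1e-8 if nugget == "estimate" else float(nugget),
                               X, y, trend=float(y[0]))
    estimate_nugget = nugget == "estimate"
    fixed_nugget = 1e-8 if estimate_nugget else float(nugget)
    dim = p + (1 if estimate_nugget else 0)
    lo = np.concatenate([np.full(p, np.log(lo_theta)),
                         [np.log(1e-8)] if estimate_nugget else []])
    hi = np.concatenate([np.full(p, np.log(theta_max)),
                         [np.log(1.0)] if estimate_nugget else []])
    rng = np.random.default_rng(seed)
    base = np.concatenate([np.full(p, np.log(0.5)),
                           [np.log(1e-4)] if estimate_nugget else []])
    best = None
    for s in range(n_starts):
        z0 = base if s == 0 else base + rng.normal(0.0, 0.8, size=dim)
        z0 = np.clip(z0, lo, hi)
        res = optimize.minimize(
            _neg_ll_and_grad, z0, args=(X, y, nu, estimate_nugget, fixed_nugget),
            jac=True, method="L-BFGS-B", bounds=list(zip(lo, hi)),
            options={"maxiter": 100},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x[:p])
    g = float(np.exp(best.x[p])) if estimate_nugget else fixed_nugget
    C = MaternKernel(1.0, theta, nu).correlation(X)
    K = C + g * np.eye(n)
    cho = linalg.cho_factor(K, lower=True)
    Kinv = linalg.cho_solve(cho, np.eye(n))
    ones = np.ones(n)
    Ki1 = Kinv @ ones
    beta = float((Ki1 @ y) / (Ki1 @ ones))
    e = y - beta
    sigma2 = float(max(e @ (Kinv @ e) / n, 1e-12))
    return DeterministicGP(MaternKernel(sigma2, theta, nu), g, X, y, trend=beta)
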