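"""Heteroscedastic Gaussian-process emulation of stochastic simulators.

The simulator output is modelled as ``f(x) = F(x) + v`` with
``v ~ N(0, tau^2(x))``: a smooth mean surface ``F`` plus input-dependent
intrinsic noise.  ``F`` carries a GP prior with Matern kernel
``sigma^2 c(x, x')`` and constant trend ``beta``; the intrinsic variance
is parameterized as ``tau^2(x) = sigma^2 lambda(x)`` with the log latent
variances at the ``n`` unique design points smoothed through a second
(noise) kernel:

    log Lambda_n = C_g (C_g + g R_n^{-1})^{-1} Delta_n,

where ``C_g`` is the noise-kernel correlation matrix at the unique
points, ``g`` a nugget, ``R_n = diag(r_1..r_n)`` the replicate counts and
``Delta_n`` free latent variables estimated by maximum likelihood.

With replicates the full N-run Gaussian likelihood collapses (Woodbury
identities) to quantities of size ``n``::

    Ktilde = C_n + Lambda_n R_n^{-1}
    Q      = sum_i (r_i - 1) s_i^2 / lambda_i + (ybar-b)' Ktilde^{-1} (ybar-b)
    log L  = -N/2 log(2 pi sigma^2)
             - 1/2 sum_i [(r_i - 1) log lambda_i + log r_i]
             - 1/2 log|Ktilde| - Q / (2 sigma^2),

so fitting costs O(n^3) regardless of the replication level N/n.  The
trend ``beta`` and variance ``sigma^2`` are profiled out analytically;
the remaining parameters (mean lengthscales, noise lengthscale, nugget,
latent variables) are optimized by multi-start L-BFGS with analytic
gradients.

Leave-one-out quantities needed by the acquisition criteria are computed
by closed-form downdating of ``Ktilde`` (hyperparameters frozen), never
by refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .design import ReplicatedDesign
from .kernels import MaternKernel

LOG_2PI = float(np.log(2.0 * np.pi))


class InsufficientDataError(ValueError):
    pass


class NumericalError(RuntimeError):
    """Raised when the reduced covariance cannot be factorized."""

    def __init__(self, msg: str, condition_number: float | None = None):
        super().__init__(msg + (f" (cond ~ {condition_number:.3e})" if condition_number else ""))
        self.condition_number = condition_number


@dataclass
class FitSettings:
    """Configuration of the maximum-likelihood fit.

    ``n_starts`` seeded initializations are run and the best final
    likelihood kept.  ``latent_penalty`` adds a unit-variance Gaussian
    prior on the latent variables (with the smoothing covariance), which
    regularizes points carrying a single replicate.
    """

    nu: float = 2.5
    n_starts: int = 5
    seed: int = 0
    max_iter: int = 200
    latent_penalty: bool = True
    loo_variance: str = "total"  # "total" = tau2 + kZ, "process" = kZ only
    theta_bounds: tuple[float, float] = (0.02, 10.0)
    theta_g_bounds: tuple[float, float] = (0.05, 10.0)
    # the nugget is the noise attributed to the latent log-variance
    # observations; the sampling sd of a log sample variance with r
    # replicates is ~sqrt(2/(r-1)), so values near zero are unrealistic
    # at desk-scale replication and would make the smoother (and hence
    # the replicate criterion) blind to replicate counts
    nugget_bounds: tuple[float, float] = (1e-2, 100.0)
    delta_bound: float = 15.0
    jitter: float = 1e-10


@dataclass
class Prediction:
    """Posterior summaries at a set of points.

    ``total_var = intrinsic_var + process_var`` elementwise: the
    predictive variance of a *future simulator run*, combining emulator
    uncertainty about the mean (``process_var``, k_Z) and intrinsic
    simulator noise (``intrinsic_var``, tau^2).
    """

    mean: np.ndarray
    process_var: np.ndarray
    intrinsic_var: np.ndarray

    @property
    def total_var(self) -> np.ndarray:
        return self.process_var + self.intrinsic_var


def _cho(K: np.ndarray):
    try:
        return linalg.cho_factor(K, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "covariance factorization failed", float(np.linalg.cond(K))
        ) from exc


@dataclass
class HetGPModel:
    """A fitted heteroscedastic GP.

    All stored coordinates are unit-cube; ``latent_delta`` holds the raw
    latent variables, ``log_lambda`` their smoothed values at the design
    points (``tau^2(x_i') = sigma^2 exp(log_lambda_i)``).
    """

    mean_kernel: MaternKernel
    noise_kernel: MaternKernel       # correlation form, variance == 1
    nugget: float                    # g in the latent-variance smoother
    latent_delta: np.ndarray
    X: np.ndarray                    # unique design points, (n, p)
    rep_counts: np.ndarray
    ybar: np.ndarray
    s2: np.ndarray                   # NaN where r_i == 1
    trend: float
    loo_variance: str = "total"
    loglik_value: float = np.nan
    # caches (populated by _precompute)
    _log_lambda: np.ndarray = field(default=None, repr=False)
    _W_delta: np.ndarray = field(default=None, repr=False)
    _K_cho: tuple = field(default=None, repr=False)
    _K_inv: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._precompute()

    # -- internal linear algebra --------------------------------------

    def _precompute(self) -> None:
        n = self.X.shape[0]
        r = self.rep_counts.astype(float)
        Cg = self.noise_kernel.correlation(self.X)
        M = Cg + self.nugget * np.diag(1.0 / r)
        self._W_delta = linalg.solve(M, self.latent_delta, assume_a="pos")
        self._log_lambda = Cg @ self._W_delta
        lam = np.exp(self._log_lambda)
        C = self.mean_kernel.correlation(self.X)
        K = C + np.diag(lam / r) + 1e-10 * np.eye(n)
        self._K_cho = _cho(K)
        self._K_inv = linalg.cho_solve(self._K_cho, np.eye(n))
        self._alpha = linalg.cho_solve(self._K_cho, self.ybar - self.trend)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def sigma2(self) -> float:
        return self.mean_kernel.variance

    @property
    def log_lambda(self) -> np.ndarray:
        return self._log_lambda

    def lambda_at(self, points: np.ndarray) -> np.ndarray:
        """Relative intrinsic variance lambda(x), smoothed off-design."""
        points = np.atleast_2d(np.asarray(points, float))
        cg = self.noise_kernel.correlation(points, self.X)
        return np.exp(cg @ self._W_delta)

    def tau2_at(self, points: np.ndarray) -> np.ndarray:
        """Intrinsic variance tau^2(x) = sigma^2 lambda(x)."""
        return self.sigma2 * self.lambda_at(points)

    # -- prediction ----------------------------------------------------

    def predict(self, points: np.ndarray) -> Prediction:
        """Posterior mean / variances at unit-cube points (m, p)."""
        points = np.atleast_2d(np.asarray(points, float))
        c = self.mean_kernel.correlation(points, self.X)
        mean = self.trend + c @ self._alpha
        sol = linalg.cho_solve(self._K_cho, c.T)
        kz = self.sigma2 * np.clip(1.0 - np.sum(c * sol.T, axis=1), 0.0, None)
        tau2 = self.tau2_at(points)
        return Prediction(mean=mean, process_var=kz, intrinsic_var=tau2)

    # -- leave-one-out -------------------------------------------------

    def loo_mean(self) -> tuple[np.ndarray, np.ndarray]:
        """LOO prediction at each unique point with all its replicates removed.

        Hyperparameters (and the latent variances) stay frozen; the
        closed-form downdate of ``Ktilde`` replaces n explicit refits.
        Returns ``(m_loo, k_loo)`` where the variance follows the model's
        ``loo_variance`` convention.
        """
        if self.n < 3:
            raise InsufficientDataError("leave-one-out needs at least 3 unique points")
        Kinv = self._K_inv
        dK = np.diag(Kinv)
        m_loo = self.ybar - self._alpha / dK
        lam = np.exp(self._log_lambda)
        r = self.rep_counts.astype(float)
        # predictive variance of the *noisy* sample mean ybar_i is s2_obs;
        # subtracting its own noise lambda_i/r_i leaves the latent kZ part
        s2_obs = self.sigma2 / dK
        kz_loo = np.clip(s2_obs - self.sigma2 * lam / r, 0.0, None)
        if self.loo_variance == "total":
            k_loo = kz_loo + self.sigma2 * lam
        else:
            k_loo = kz_loo
        return m_loo, k_loo

    def _resmoothed_log_lambda(self, rep_counts: np.ndarray,
                               keep: np.ndarray | None = None) -> np.ndarray:
        """Eq-1.6 smoothing recomputed for modified replicate counts.

        ``keep`` restricts to a subset of unique points (point deletion);
        noise-kernel hyperparameters and latent delta stay frozen.
        """
        X = self.X if keep is None else self.X[keep]
        delta = self.latent_delta if keep is None else self.latent_delta[keep]
        r = rep_counts.astype(float)
        Cg = self.noise_kernel.correlation(X)
        M = Cg + self.nugget * np.diag(1.0 / r)
        return Cg @ linalg.solve(M, delta, assume_a="pos")

    def loo_replicate(self, i: int, j: int) -> tuple[float, float, float]:
        """Delete single replicate j of unique point i (frozen hyperparameters).

        The latent variance is re-smoothed for the reduced replicate
        count ``r_i - 1``.  Returns ``(tau2_loo, m_loo, k_loo)`` at
        ``x_i'``; for ``r_i == 1`` this is deletion of the unique point.
        """
        r = self.rep_counts
        if not (0 <= i < self.n) or not (0 <= j < r[i]):
            raise IndexError(f"replicate index ({i}, {j}) out of range")
        sig2 = self.sigma2
        xi = self.X[i:i + 1]
        if r[i] == 1:
            keep = np.ones(self.n, dtype=bool)
            keep[i] = False
            loglam = self._resmoothed_log_lambda(r[keep], keep=keep)
            lam = np.exp(loglam)
            Xk = self.X[keep]
            C = self.mean_kernel.correlation(Xk)
            K = C + np.diag(lam / r[keep]) + 1e-10 * np.eye(keep.sum())
            cho = _cho(K)
            c = self.mean_kernel.correlation(xi, Xk).ravel()
            m = self.trend + c @ linalg.cho_solve(cho, self.ybar[keep] - self.trend)
            kz = sig2 * max(1.0 - c @ linalg.cho_solve(cho, c), 0.0)
            cg = self.noise_kernel.correlation(xi, Xk).ravel()
            Cgk = self.noise_kernel.correlation(Xk)
            Mk = Cgk + self.nugget * np.diag(1.0 / r[keep].astype(float))
            tau2 = sig2 * float(np.exp(cg @ linalg.solve(Mk, self.latent_delta[keep],
                                                         assume_a="pos")))
        else:
            r_new = r.copy()
            r_new[i] -= 1
            loglam = self._resmoothed_log_lambda(r_new)
            lam = np.exp(loglam)
            tau2 = sig2 * float(lam[i])
            C = self.mean_kernel.correlation(self.X)
            K = C + np.diag(lam / r_new) + 1e-10 * np.eye(self.n)
            cho = _cho(K)
            c = C[i].copy()  # includes the unit self-correlation at i
            m = self.trend + c @ linalg.cho_solve(cho, self.ybar - self.trend)
            kz = sig2 * max(1.0 - c @ linalg.cho_solve(cho, c), 0.0)
        if self.loo_variance == "total":
            k = kz + tau2
        else:
            k = kz
        return float(tau2), float(m), float(k)

    def loo_replicate_with_value(self, i: int, j: int,
                                 design: ReplicatedDesign) -> tuple[float, float, float]:
        """Like :meth:`loo_replicate` but updates the sample mean using the
        actual removed output value ``design.outputs[i][j]``."""
        r = self.rep_counts
        if r[i] == 1:
            return self.loo_replicate(i, j)
        tau2, _, k = self.loo_replicate(i, j)
        r_new = r.copy()
        r_new[i] -= 1
        loglam = self._resmoothed_log_lambda(r_new)
        lam = np.exp(loglam)
        ybar = self.ybar.copy()
        yij = design.outputs[i][j]
        ybar[i] = (r[i] * ybar[i] - yij) / (r[i] - 1)
        C = self.mean_kernel.correlation(self.X)
        K = C + np.diag(lam / r_new) + 1e-10 * np.eye(self.n)
        cho = _cho(K)
        m = self.trend + C[i] @ linalg.cho_solve(cho, ybar - self.trend)
        return tau2, float(m), k

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mean_kernel": self.mean_kernel.to_dict(),
            "noise_kernel": self.noise_kernel.to_dict(),
            "nugget": float(self.nugget),
            "latent_delta": self.latent_delta.tolist(),
            "X": self.X.tolist(),
            "rep_counts": self.rep_counts.tolist(),
            "ybar": self.ybar.tolist(),
            "s2": [None if not np.isfinite(v) else float(v) for v in self.s2],
            "trend": float(self.trend),
            "loo_variance": self.loo_variance,
            "loglik_value": float(self.loglik_value),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "HetGPModel":
        s2 = np.array([np.nan if v is None else v for v in d["s2"]], float)
        return cls(
            mean_kernel=MaternKernel.from_dict(d["mean_kernel"]),
            noise_kernel=MaternKernel.from_dict(d["noise_kernel"]),
            nugget=d["nugget"],
            latent_delta=np.asarray(d["latent_delta"], float),
            X=np.asarray(d["X"], float),
            rep_counts=np.asarray(d["rep_counts"], int),
            ybar=np.asarray(d["ybar"], float),
            s2=s2,
            trend=d["trend"],
            loo_variance=d.get("loo_variance", "total"),
            loglik_value=d.get("loglik_value", np.nan),
        )

    @classmethod
    def from_json(cls, path) -> "HetGPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------


def _design_arrays(design: ReplicatedDesign):
    ybar, s2 = design.sample_stats()
    r = design.rep_counts.astype(float)
    ss = np.where(r > 1, np.nan_to_num(s2) * (r - 1.0), 0.0)  # (r_i-1) s_i^2
    return design.unique_points, r, ybar, ss


def _reduced_loglik_core(C, Cg, g, delta, r, ybar, ss, N, jitter=1e-10):
    """Value + intermediates of the Woodbury-reduced profile log-likelihood."""
    n = r.size
    M = Cg + g * np.diag(1.0 / r)
    M_cho = _cho(M)
    w = linalg.cho_solve(M_cho, delta)       # w = (Cg + g R^-1)^-1 delta
    loglam = Cg @ w
    lam = np.exp(np.clip(loglam, -40.0, 40.0))
    K = C + np.diag(lam / r) + jitter * np.eye(n)
    K_cho = _cho(K)
    Kinv = linalg.cho_solve(K_cho, np.eye(n))
    ones = np.ones(n)
    Ki1 = Kinv @ ones
    beta = float((Ki1 @ ybar) / (Ki1 @ ones))
    e = ybar - beta
    alpha = Kinv @ e
    Q = float(np.sum(ss / lam) + e @ alpha)
    sigma2 = Q / N
    logdetK = 2.0 * np.sum(np.log(np.diag(K_cho[0])))
    ll = (
        -0.5 * N * (LOG_2PI + np.log(sigma2) + 1.0)
        - 0.5 * np.sum((r - 1.0) * loglam + np.log(r))
        - 0.5 * logdetK
    )
    return dict(ll=ll, M_cho=M_cho, w=w, loglam=loglam, lam=lam, K_cho=K_cho,
                Kinv=Kinv, beta=beta, e=e, alpha=alpha, Q=Q, sigma2=sigma2)


def loglik(model: HetGPModel, design: ReplicatedDesign) -> float:
    """Full-data log marginal likelihood through n-sized quantities only.

    Equals the naive N-dimensional Gaussian log-density of all outputs
    (with covariance ``sigma^2 (C_N + Lambda_N)``); the reduction is
    exact, not approximate.
    """
    X, r, ybar, ss = _design_arrays(design)
    if X.shape != model.X.shape or not np.allclose(X, model.X):
        raise ValueError("model and design dimensions do not match")
    N = design.N
    C = model.mean_kernel.correlation(X)
    Cg = model.noise_kernel.correlation(X)
    core = _reduced_loglik_core(C, Cg, model.nugget, model.latent_delta, r, ybar, ss, N)
    # evaluate at the model's own (sigma2, beta) rather than the profiled ones
    lam = core["lam"]
    n = r.size
    K = C + np.diag(lam / r) + 1e-10 * np.eye(n)
    K_cho = _cho(K)
    e = ybar - model.trend
    Q = float(np.sum(ss / lam) + e @ linalg.cho_solve(K_cho, e))
    logdetK = 2.0 * np.sum(np.log(np.diag(K_cho[0])))
    sig2 = model.sigma2
    return float(
        -0.5 * N * (LOG_2PI + np.log(sig2))
        - 0.5 * np.sum((r - 1.0) * core["loglam"] + np.log(r))
        - 0.5 * logdetK
        - 0.5 * Q / sig2
    )


def _objective_and_grad(z, X, r, ybar, ss, N, nu, penalty, jitter):
    """Negative profile log-likelihood and gradient.

    Parameter vector z = [log theta (p), log theta_g, log g, delta (n)].
    """
    n, p = X.shape
    log_theta = z[:p]
    log_theta_g = z[p]
    log_g = z[p + 1]
    delta = z[p + 2:]
    theta = np.exp(log_theta)
    theta_g = np.exp(log_theta_g)
    g = np.exp(log_g)

    mk = MaternKernel(1.0, theta, nu)
    gk = MaternKernel(1.0, np.full(p, theta_g), nu)
    C, dC = mk.correlation_with_grad(X)
    Cg, dCg = gk.correlation_with_grad(X)
    dCg_iso = sum(dCg)  # shared lengthscale: sum of per-dimension grads

    core = _reduced_loglik_core(C, Cg, g, delta, r, ybar, ss, N, jitter)
    ll = core["ll"]
    lam, loglam = core["lam"], core["loglam"]
    Kinv, alpha, sigma2 = core["Kinv"], core["alpha"], core["sigma2"]
    w = core["w"]

    # dll/dC and dll/dloglam (envelope theorem over profiled beta, sigma2)
    A = (np.outer(alpha, alpha) / sigma2 - Kinv) * 0.5
    dll_dlam = (ss / lam**2 + alpha**2 / r) / (2.0 * sigma2) - np.diag(Kinv) / (2.0 * r)
    gamma = lam * dll_dlam - 0.5 * (r - 1.0)

    grad = np.zeros_like(z)
    for j in range(p):
        grad[j] = np.sum(A * dC[j])

    # chain through the smoother: dloglam = (I - Cg W) dCg w - dg Cg W R^-1 w
    CgW = Cg @ linalg.cho_solve(core["M_cho"], np.eye(n))
    left = gamma - CgW.T @ gamma        # (I - Cg W)' gamma
    grad[p] = float(left @ (dCg_iso @ w))
    grad[p + 1] = -g * float(gamma @ (CgW @ (w / r)))
    grad[p + 2:] = CgW.T @ gamma        # d loglam / d delta = Cg W

    if penalty:
        # unit-variance Gaussian prior on delta with covariance Cg + g R^-1
        M_cho = core["M_cho"]
        pen = (-0.5 * float(delta @ w)
               - np.sum(np.log(np.diag(M_cho[0])))
               - 0.5 * n * LOG_2PI)
        ll = ll + pen
        Minv = linalg.cho_solve(M_cho, np.eye(n))
        P = 0.5 * (np.outer(w, w) - Minv)
        grad[p] += np.sum(P * dCg_iso)
        grad[p + 1] += g * float(np.sum((w**2 - np.diag(Minv)) / r)) * 0.5
        grad[p + 2:] += -w

    return -ll, -grad


def _initial_points(X, r, ybar, s2, settings: FitSettings):
    n, p = X.shape
    rng = np.random.default_rng(settings.seed)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled = np.nanmean(s2)
    if not np.isfinite(pooled) or pooled <= 0:
        pooled = max(np.var(ybar) * 0.1, 1e-8)
    sigma2_0 = np.var(ybar) + pooled
    if sigma2_0 <= 0:
        sigma2_0 = 1.0
    d0 = np.log(np.clip(np.nan_to_num(s2, nan=pooled), pooled / 100.0, None) / sigma2_0)
    d0 = np.clip(d0, -10.0, 5.0)
    base = np.concatenate([np.full(p, np.log(0.5)), [np.log(1.0)], [np.log(1.0)], d0])
    starts = [base]
    for _ in range(settings.n_starts - 1):
        pert = base.copy()
        pert[:p + 2] += rng.normal(0.0, 0.7, size=p + 2)
        pert[p + 2:] += rng.normal(0.0, 0.5, size=n)
        starts.append(pert)
    return starts


def fit_hetgp(design: ReplicatedDesign, settings: FitSettings | None = None) -> HetGPModel:
    """Fit the heteroscedastic GP by multi-start maximum likelihood.

    Deterministic given ``settings.seed``.  Requires at least ``p + 2``
    unique points and finite outputs.
    """
    settings = settings or FitSettings()
    X, r, ybar, ss = _design_arrays(design)
    _, s2 = design.sample_stats()
    n, p = X.shape
    if n < p + 2:
        raise InsufficientDataError(f"need at least p + 2 = {p + 2} unique points, got {n}")
    if not np.all([np.all(np.isfinite(o)) for o in design.outputs]):
        raise ValueError("outputs must be finite")
    N = design.N

    lo = np.concatenate([
        np.full(p, np.log(settings.theta_bounds[0])),
        [np.log(settings.theta_g_bounds[0])],
        [np.log(settings.nugget_bounds[0])],
        np.full(n, -settings.delta_bound),
    ])
    hi = np.concatenate([
        np.full(p, np.log(settings.theta_bounds[1])),
        [np.log(settings.theta_g_bounds[1])],
        [np.log(settings.nugget_bounds[1])],
        np.full(n, settings.delta_bound),
    ])
    bounds = list(zip(lo, hi))

    args = (X, r, ybar, ss, N, settings.nu, settings.latent_penalty, settings.jitter)
    best = None
    for z0 in _initial_points(X, r, ybar, s2, settings):
        z0 = np.clip(z0, lo, hi)
        try:
            res = optimize.minimize(
                _objective_and_grad, z0, args=args, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": settings.max_iter},
            )
        except NumericalError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NumericalError("all optimization starts failed")

    z = best.x
    theta = np.exp(z[:p])
    theta_g = np.exp(z[p])
    g = float(np.exp(z[p + 1]))
    delta = z[p + 2:]
    mk = MaternKernel(1.0, theta, settings.nu)
    gk = MaternKernel(1.0, np.full(p, theta_g), settings.nu)
    core = _reduced_loglik_core(mk.correlation(X), gk.correlation(X), g, delta,
                                r, ybar, ss, N, settings.jitter)
    model = HetGPModel(
        mean_kernel=MaternKernel(core["sigma2"], theta, settings.nu),
        noise_kernel=gk,
        nugget=g,
        latent_delta=delta,
        X=X.copy(),
        rep_counts=design.rep_counts.copy(),
        ybar=ybar,
        s2=s2,
        trend=core["beta"],
        loo_variance=settings.loo_variance,
        loglik_value=float(core["ll"]),
    )
    return model
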