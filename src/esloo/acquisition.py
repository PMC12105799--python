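"""ES-LOO acquisition criteria for stochastic sequential design.

Two criteria are computed at each iteration of the design loop:

* ``ESL_m`` — where would a *new* point most improve the mean surface?
  The expected squared leave-one-out error of the heteroscedastic GP is
  computed at every unique design point, standardized by its own spread,

      E_m = E[(Z_-i - ybar_i)^2] / sqrt(Var[(Z_-i - ybar_i)^2]),

  emulated over the whole input space by a deterministic GP on its log
  (the surface ``Z_E``), and maximized through pseudo expected
  improvement: expected improvement over ``max(y_E)`` times a repulsion
  function that vanishes at every design and pseudo point.

* ``ESL_tau`` — which *existing* point most deserves a further
  replicate?  Each replicate is deleted in turn (frozen
  hyperparameters) and the swing of the predicted intrinsic variance
  recorded; a deterministic GP ``Z_e`` fitted to the signed swings gives
  ``ESL_tau(x_i') = m_e(x_i')^2 + k_e(x_i')``, maximized over the
  design points only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import norm, qmc

from .design import DEFAULT_MERGE_TOL, ReplicatedDesign
from .detgp import THETA_FLOOR, DeterministicGP, fit_deterministic_gp
from .hetgp import HetGPModel

SCORE_FLOOR = 1e-12
#: standardized ES-LOO value when the LOO mean is exact: E = v, Var = 2 v^2
ZERO_ERROR_SCORE = 1.0 / np.sqrt(2.0)


def standardized_esloo(v: np.ndarray, err2: np.ndarray) -> np.ndarray:
    """Expected squared LOO error over its own spread.

    With ``v`` the relevant predictive variance and ``err2`` the squared
    LOO mean error, the squared standardized residual is non-central
    chi-square with one degree of freedom, giving

        E   = v + err2
        Var = 2 v^2 + 4 v err2

    and the score ``E / sqrt(Var)``: 1/sqrt(2) at zero error, strictly
    increasing in ``err2`` at fixed ``v``.
    """
    v = np.asarray(v, float)
    err2 = np.asarray(err2, float)
    return (v + err2) / np.sqrt(2.0 * v**2 + 4.0 * v * err2)


def esloo_mean_scores(model: HetGPModel, design: ReplicatedDesign | None = None,
                      deterministic: bool = False) -> np.ndarray:
    """Standardized expected squared LOO error at every unique point.

    With ``deterministic=True`` the sample-mean noise term ``k_Z/r`` is
    dropped (the many-replicates / noise-free pipeline).
    Always strictly positive; the zero-error limit is ``1/sqrt(2)``.
    """
    m_loo, k_loo = model.loo_mean()
    err2 = (m_loo - model.ybar) ** 2
    if deterministic:
        v = k_loo
    else:
        kz = model.predict(model.X).process_var
        v = k_loo + kz / model.rep_counts
    v = np.asarray(v, float)
    tiny = v < 1e-300
    if np.any(tiny):
        warnings.warn("degenerate LOO variance; numerical floor applied")
        v = np.maximum(v, 1e-300)
    return standardized_esloo(v, err2)


def det_esloo_scores(gp: DeterministicGP) -> np.ndarray:
    """Deterministic ES-LOO scores for an interpolating GP (no noise term)."""
    m_loo, k_loo = gp.loo()
    err2 = (m_loo - gp.y) ** 2
    return standardized_esloo(np.maximum(k_loo, 1e-300), err2)


def make_pseudo_points(p: int, design_points: np.ndarray,
                       policy: str = "corners",
                       merge_tol: float = DEFAULT_MERGE_TOL) -> np.ndarray:
    """Boundary pseudo points for the repulsion function.

    ``"corners"`` gives the ``2^p`` unit-cube corners for ``p <= 6`` and
    the ``2p`` face centres beyond that; ``"none"`` disables them.
    Points already in the design are dropped.
    """
    if policy == "none":
        return np.empty((0, p))
    if policy != "corners":
        raise ValueError(f"unknown pseudo-point policy {policy!r}")
    if p <= 6:
        pts = np.array(list(product([0.0, 1.0], repeat=p)))
    else:
        pts = np.vstack([np.eye(p) * 0.0 + 0.5 - 0.5 * np.eye(p),
                         np.eye(p) * 0.0 + 0.5 + 0.5 * np.eye(p)])
    if design_points.size:
        d = cdist(pts, design_points).min(axis=1)
        pts = pts[d > merge_tol]
    return pts


@dataclass
class ESLooSurface:
    """The ES-LOO error surface ``Z_E`` plus its repulsion point set."""

    gp: DeterministicGP
    training_inputs: np.ndarray
    scores: np.ndarray            # raw (positive) ES-LOO values
    log_scores: np.ndarray
    pseudo_points: np.ndarray
    theta_floor: float = THETA_FLOOR

    @property
    def repulsion_points(self) -> np.ndarray:
        if self.pseudo_points.size:
            return np.vstack([self.training_inputs, self.pseudo_points])
        return self.training_inputs

    @property
    def best_score(self) -> float:
        return float(self.log_scores.max())


def fit_esloo_surface(
    inputs: np.ndarray,
    scores: np.ndarray,
    pseudo_policy: str = "corners",
    seed: int = 0,
    n_starts: int = 3,
) -> ESLooSurface:
    """Fit ``Z_E`` to the log ES-LOO scores.

    Scores must be positive (they are clamped at 1e-12 before the log);
    the fitted lengthscales respect the floor ``-0.5/log(1e-8)``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, float))
    scores = np.asarray(scores, float).ravel()
    if np.any(scores <= 0):
        raise ValueError("ES-LOO scores must be strictly positive")
    log_scores = np.log(np.maximum(scores, SCORE_FLOOR))
    gp = fit_deterministic_gp(inputs, log_scores, theta_floor=THETA_FLOOR,
                              nugget=1e-8, n_starts=n_starts, seed=seed)
    pseudo = make_pseudo_points(inputs.shape[1], inputs, pseudo_policy)
    return ESLooSurface(gp=gp, training_inputs=inputs, scores=scores,
                        log_scores=log_scores, pseudo_points=pseudo)


def expected_improvement(surface: ESLooSurface, x: np.ndarray) -> np.ndarray:
    """EI of ``Z_E`` over the current best (log-scale) ES-LOO score.

    Zero wherever the surface variance vanishes.
    """
    x = np.atleast_2d(np.asarray(x, float))
    mu, var = surface.gp.predict(x)
    sd = np.sqrt(var)
    ymax = surface.best_score
    out = np.zeros(x.shape[0])
    ok = sd > 1e-12
    if np.any(ok):
        diff = mu[ok] - ymax
        u = diff / sd[ok]
        out[ok] = diff * norm.cdf(u) + sd[ok] * norm.pdf(u)
    return np.clip(out, 0.0, None)


def repulsion(surface: ESLooSurface, x: np.ndarray,
              extra_points: np.ndarray | None = None) -> np.ndarray:
    """RF(x) = prod_i [1 - Corr(Z_E(x), Z_E(x_i))] over design, pseudo and
    any extra (batch) points; exactly zero at each of them."""
    x = np.atleast_2d(np.asarray(x, float))
    pts = surface.repulsion_points
    if extra_points is not None and np.size(extra_points):
        pts = np.vstack([pts, np.atleast_2d(extra_points)])
    corr = surface.gp.correlation(x, pts)
    return np.prod(1.0 - corr, axis=1)


def pei(surface: ESLooSurface, x: np.ndarray,
        extra_points: np.ndarray | None = None) -> np.ndarray:
    """Pseudo expected improvement: EI times the repulsion function."""
    return expected_improvement(surface, x) * repulsion(surface, x, extra_points)


@dataclass
class ProposedPoint:
    x: np.ndarray
    pei_value: float
    degenerate: bool = False


def propose_new_point(
    surface: ESLooSurface,
    seed: int = 0,
    n_starts: int | None = None,
    n_refine: int = 10,
    extra_points: np.ndarray | None = None,
) -> ProposedPoint:
    """Maximize PEI over the unit cube by seeded multi-start local search.

    A space-filling start set (``100 p`` points by default) is screened,
    the best ``n_refine`` starts polished with L-BFGS-B.  A flat (all
    zero) PEI landscape falls back to the start with maximal surface
    variance and is flagged degenerate.
    """
    p = surface.training_inputs.shape[1]
    n_starts = n_starts or 100 * p
    starts = qmc.LatinHypercube(d=p, seed=seed).random(n_starts)
    vals = pei(surface, starts, extra_points)
    if np.all(vals <= 1e-12):  # numerically flat landscape
        _, var = surface.gp.predict(starts)
        rf = repulsion(surface, starts, extra_points)
        k = int(np.argmax(var * (rf > 0)))
        return ProposedPoint(starts[k], 0.0, degenerate=True)

    def neg(xx: np.ndarray) -> float:
        return -float(pei(surface, xx.reshape(1, -1), extra_points)[0])

    order = np.argsort(vals)[::-1][:n_refine]
    best_x, best_v = starts[order[0]], vals[order[0]]
    for k in order:
        res = minimize(neg, starts[k], method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * p)
        if -res.fun > best_v:
            best_x, best_v = np.clip(res.x, 0.0, 1.0), -res.fun
    return ProposedPoint(best_x, float(best_v), degenerate=False)


@dataclass
class VarianceESLoo:
    """Replicate-deletion LOO diagnostics on the intrinsic variance."""

    per_replicate_errors: list          # |tau2_-ij - tau2_i| per replicate
    signed_deltas: np.ndarray           # per unique point (replicates agree)
    gp: DeterministicGP                 # Z_e on the signed deltas
    scores: np.ndarray                  # ESL_tau at each unique point

    def argmax(self) -> int:
        return int(np.argmax(self.scores))


def esloo_variance_scores(
    model: HetGPModel,
    design: ReplicatedDesign,
    seed: int = 0,
) -> tuple[VarianceESLoo, np.ndarray]:
    """ESL_tau at every unique point and the best replicate candidate.

    The deletion of any replicate at point i moves the re-smoothed
    intrinsic variance by the same amount (replicates are exchangeable
    given frozen hyperparameters), so one deletion per unique point
    suffices; the candidate is the design point with the largest
    ``m_e^2 + k_e``.  No continuous optimization is involved.
    """
    if model.n < 3:
        from .hetgp import InsufficientDataError

        raise InsufficientDataError("variance LOO needs at least 3 unique points")
    n = model.n
    tau2_full = model.sigma2 * np.exp(model.log_lambda)
    deltas = np.empty(n)
    for i in range(n):
        tau2_loo, _, _ = model.loo_replicate(i, 0)
        deltas[i] = tau2_loo - tau2_full[i]
    errors = [np.full(int(r), abs(deltas[i])) for i, r in enumerate(model.rep_counts)]
    gp = fit_deterministic_gp(model.X, deltas, nugget=1e-8, n_starts=3, seed=seed)
    m_e, k_e = gp.predict(model.X)
    scores = m_e**2 + k_e
    out = VarianceESLoo(per_replicate_errors=errors, signed_deltas=deltas,
                        gp=gp, scores=scores)
    return out, model.X[out.argmax()].copy()
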