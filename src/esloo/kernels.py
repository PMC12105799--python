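"""Anisotropic Matern covariance functions.

The kernel uses the scaled (ARD) form: with weighted distance
``d = sqrt(sum_j ((x_j - x'_j)/theta_j)^2)`` the covariance is

    k(x, x') = sigma^2 * 2^(1-nu)/Gamma(nu) * (sqrt(2 nu) d)^nu
               * B_nu(sqrt(2 nu) d),

where ``B_nu`` is the modified Bessel function of the second kind.  The
half-integer smoothness values 1/2, 3/2 and 5/2 use their closed forms
(and support analytic lengthscale gradients); any other positive ``nu``
is evaluated through the Bessel function directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma, kv

_HALF_INTEGER = (0.5, 1.5, 2.5)


def _matern_shape(u: np.ndarray, nu: float) -> np.ndarray:
    """Correlation as a function of u = sqrt(2 nu) * d."""
    if nu == 0.5:
        return np.exp(-u)
    if nu == 1.5:
        return (1.0 + u) * np.exp(-u)
    if nu == 2.5:
        return (1.0 + u + u * u / 3.0) * np.exp(-u)
    out = np.ones_like(u)
    pos = u > 0
    up = u[pos]
    out[pos] = (2 ** (1.0 - nu) / gamma(nu)) * up**nu * kv(nu, up)
    return out


def _matern_shape_du(u: np.ndarray, nu: float) -> np.ndarray:
    """d/du of the correlation shape (half-integer nu only)."""
    if nu == 0.5:
        return -np.exp(-u)
    if nu == 1.5:
        return -u * np.exp(-u)
    if nu == 2.5:
        return -(u / 3.0) * (1.0 + u) * np.exp(-u)
    raise NotImplementedError("analytic derivative only for nu in {1/2, 3/2, 5/2}")


@dataclass
class MaternKernel:
    """Matern kernel with per-dimension lengthscales.

    Parameters
    ----------
    variance : float
        Marginal variance sigma^2; ``k(x, x) = sigma^2``.
    lengthscales : ndarray of shape (p,)
        Correlation lengths theta_j, strictly positive.
    nu : float
        Smoothness; 5/2 by default (twice-differentiable sample paths).
    """

    variance: float
    lengthscales: np.ndarray
    nu: float = 2.5

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be strictly positive")
        if self.variance <= 0:
            raise ValueError("variance must be strictly positive")
        if self.nu <= 0:
            raise ValueError("nu must be strictly positive")

    @property
    def p(self) -> int:
        return self.lengthscales.size

    def _scaled_dist(self, X: np.ndarray, X2: np.ndarray) -> np.ndarray:
        return cdist(X / self.lengthscales, X2 / self.lengthscales)

    def correlation(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        """Correlation matrix between row sets X and X2 (or X with itself)."""
        X = np.atleast_2d(np.asarray(X, float))
        X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, float))
        u = np.sqrt(2.0 * self.nu) * self._scaled_dist(X, X2)
        return _matern_shape(u, self.nu)

    def __call__(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        return self.variance * self.correlation(X, X2)

    def eval(self, x: np.ndarray, x2: np.ndarray) -> float:
        """Scalar covariance k(x, x')."""
        return float(self(np.atleast_2d(x), np.atleast_2d(x2))[0, 0])

    def correlation_with_grad(
        self, X: np.ndarray
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Self-correlation matrix and its derivatives w.r.t. each log-lengthscale.

        Returns ``(C, [dC/dlog(theta_1), ..., dC/dlog(theta_p)])``.
        Half-integer ``nu`` only.
        """
        X = np.atleast_2d(np.asarray(X, float))
        n, p = X.shape
        # per-dimension squared scaled differences
        sq = np.empty((p, n, n))
        for j in range(p):
            dj = (X[:, j:j + 1] - X[:, j:j + 1].T) / self.lengthscales[j]
            sq[j] = dj * dj
        d = np.sqrt(sq.sum(axis=0))
        u = np.sqrt(2.0 * self.nu) * d
        C = _matern_shape(u, self.nu)
        dshape = _matern_shape_du(u, self.nu)
        grads = []
        with np.errstate(invalid="ignore", divide="ignore"):
            inv_d = np.where(d > 0, 1.0 / np.maximum(d, 1e-300), 0.0)
        for j in range(p):
            # d u / d log theta_j = -sqrt(2 nu) * sq_j / d
            du = -np.sqrt(2.0 * self.nu) * sq[j] * inv_d
            grads.append(dshape * du)
        return C, grads

    def to_dict(self) -> dict:
        return {
            "variance": float(self.variance),
            "lengthscales": self.lengthscales.tolist(),
            "nu": float(self.nu),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaternKernel":
        return cls(d["variance"], np.asarray(d["lengthscales"], float), d["nu"])
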