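"""Replicated designs and space-filling initial designs.

A *replicated design* stores runs of a stochastic simulator grouped by
unique input location: ``n`` unique points ``x_i'`` carry ``r_i``
replicate outputs each, for a total of ``N = sum(r_i)`` runs.  The design
is the single source of truth for the sample means and variances

    ybar_i = (1/r_i) sum_j y_ij,
    s2_i   = 1/(r_i - 1) sum_j (y_ij - ybar_i)^2,

which feed both the heteroscedastic GP likelihood and the acquisition
criteria.  All coordinates are stored on the unit cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import qmc

from .domain import InputDomain

DEFAULT_MERGE_TOL = 1e-9


@dataclass
class ReplicatedDesign:
    """Runs of a stochastic simulator grouped by unique input point.

    Attributes
    ----------
    unique_points : ndarray of shape (n, p)
        Distinct input locations in unit-cube coordinates.
    outputs : list of 1-D ndarrays
        ``outputs[i]`` holds the ``r_i`` replicate outputs at point ``i``.
    merge_tol : float
        Euclidean distance below which a new run is treated as a replicate
        of an existing point.
    """

    p: int
    unique_points: np.ndarray = None
    outputs: list = field(default_factory=list)
    merge_tol: float = DEFAULT_MERGE_TOL

    def __post_init__(self) -> None:
        if self.unique_points is None:
            self.unique_points = np.empty((0, self.p), dtype=float)
        else:
            self.unique_points = np.asarray(self.unique_points, dtype=float).reshape(-1, self.p)
        self.outputs = [np.asarray(o, dtype=float).ravel() for o in self.outputs]
        if len(self.outputs) != self.unique_points.shape[0]:
            raise ValueError("one output vector required per unique point")

    # -- bookkeeping ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of unique points."""
        return self.unique_points.shape[0]

    @property
    def rep_counts(self) -> np.ndarray:
        return np.array([len(o) for o in self.outputs], dtype=int)

    @property
    def N(self) -> int:
        """Total number of runs."""
        return int(self.rep_counts.sum()) if self.n else 0

    def copy(self) -> "ReplicatedDesign":
        return ReplicatedDesign(
            p=self.p,
            unique_points=self.unique_points.copy(),
            outputs=[o.copy() for o in self.outputs],
            merge_tol=self.merge_tol,
        )

    def match(self, x: np.ndarray) -> int | None:
        """Index of the unique point within ``merge_tol`` of ``x``, or None."""
        if self.n == 0:
            return None
        d = cdist(np.asarray(x, float).reshape(1, -1), self.unique_points).ravel()
        i = int(np.argmin(d))
        return i if d[i] <= self.merge_tol else None

    def add_run(self, x: np.ndarray, y: float) -> None:
        """Record one simulator run at unit-cube location ``x``.

        Within ``merge_tol`` of an existing point the run becomes a
        replicate; otherwise a new unique point is created.
        """
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.p:
            raise ValueError(f"expected a {self.p}-vector, got shape {x.shape}")
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError("input lies outside the unit cube")
        y = float(y)
        if not np.isfinite(y):
            raise ValueError("output must be finite")
        i = self.match(x)
        if i is None:
            self.unique_points = np.vstack([self.unique_points, x])
            self.outputs.append(np.array([y]))
        else:
            self.outputs[i] = np.append(self.outputs[i], y)

    def sample_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-point sample means and variances.

        Returns ``(ybar, s2)``; ``s2[i]`` is NaN where ``r_i == 1``
        (the unbiased variance is undefined for a single replicate).
        """
        ybar = np.array([o.mean() for o in self.outputs])
        s2 = np.array([o.var(ddof=1) if len(o) > 1 else np.nan for o in self.outputs])
        return ybar, s2

    # -- I/O -----------------------------------------------------------

    def to_frame(self, domain: InputDomain | None = None) -> pd.DataFrame:
        """One row per run: columns ``x1..xp`` (physical if a domain is given) and ``y``."""
        rows = []
        for xi, ys in zip(self.unique_points, self.outputs):
            phys = domain.from_unit(xi) if domain is not None else xi
            for y in ys:
                rows.append(list(phys) + [y])
        cols = [f"x{j + 1}" for j in range(self.p)] + ["y"]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        domain: InputDomain | None = None,
        merge_tol: float = DEFAULT_MERGE_TOL,
    ) -> "ReplicatedDesign":
        xcols = [c for c in df.columns if c != "y"]
        p = len(xcols)
        design = cls(p=p, merge_tol=merge_tol)
        for _, row in df.iterrows():
            x = row[xcols].to_numpy(dtype=float)
            if domain is not None:
                x = domain.to_unit(x)
            design.add_run(x, float(row["y"]))
        return design

    def to_csv(self, path, domain: InputDomain | None = None) -> None:
        self.to_frame(domain).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domain: InputDomain | None = None,
                 merge_tol: float = DEFAULT_MERGE_TOL) -> "ReplicatedDesign":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, domain=domain, merge_tol=merge_tol)


def make_maximin_lhd(
    n_points: int,
    p: int,
    seed: int,
    n_restarts: int = 50,
) -> np.ndarray:
    """Maximin Latin hypercube design on the unit cube.

    Draws ``n_restarts`` random Latin hypercube samples from a seeded
    stream and keeps the one with the largest minimum pairwise distance.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if n_restarts < 1:
        raise ValueError("n_restarts must be positive")
    sampler = qmc.LatinHypercube(d=p, seed=seed)
    best, best_d = None, -np.inf
    for _ in range(n_restarts):
        cand = sampler.random(n_points)
        d = pdist(cand).min()
        if d > best_d:
            best, best_d = cand, d
    return best
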