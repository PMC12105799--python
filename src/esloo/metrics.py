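"""Emulator accuracy metrics against replicated test sets.

NRMSE compares the emulator against test-set sample statistics,
normalized by their observed range:

    NRMSE_m   = RMSE(m*, ybar) / (max ybar - min ybar)
    NRMSE_tau = RMSE(k*, s^2) / (max s^2 - min s^2)

(the variance version compares the *total* predictive variance k* with
the sample variances).  The score rewards calibrated mean and variance
jointly:

    Score = mean_t [ -((m* - ybar)/k*)^2 - log k* ];

higher is better.  The standardization divides by k* itself; a variant
dividing by sqrt(k*) is available via ``standardize="sd"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .benchmarks import StochasticSimulator
from .hetgp import Prediction


@dataclass
class TestSet:
    """Replicated evaluation grid: unit-cube points with sample moments
    over ``rep_count`` draws each."""

    __test__ = False  # not a pytest class despite the name

    points: np.ndarray
    rep_count: int
    sample_means: np.ndarray
    sample_vars: np.ndarray

    def __post_init__(self) -> None:
        if self.rep_count < 2:
            raise ValueError("rep_count must be at least 2 so variances exist")

    def to_frame(self) -> pd.DataFrame:
        p = self.points.shape[1]
        df = pd.DataFrame(self.points, columns=[f"x{j + 1}" for j in range(p)])
        df["ybar"] = self.sample_means
        df["s2"] = self.sample_vars
        df["r"] = self.rep_count
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TestSet":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(points=df[xcols].to_numpy(float),
                   rep_count=int(df["r"].iloc[0]),
                   sample_means=df["ybar"].to_numpy(float),
                   sample_vars=df["s2"].to_numpy(float))


def make_test_set(simulator: StochasticSimulator, n_points: int, reps: int,
                  seed: int = 0) -> TestSet:
    """Latin hypercube test points with ``reps`` replicate draws each."""
    if reps < 2:
        raise ValueError("reps must be at least 2")
    p = simulator.domain.p
    pts = qmc.LatinHypercube(d=p, seed=seed).random(n_points)
    rng = np.random.default_rng(seed + 1)
    draws = np.empty((n_points, reps))
    for i, x in enumerate(pts):
        for j in range(reps):
            draws[i, j] = simulator.sample(x, rng)
    return TestSet(points=pts, rep_count=reps,
                   sample_means=draws.mean(axis=1),
                   sample_vars=draws.var(axis=1, ddof=1))


def nrmse(predictions: Prediction, test: TestSet, target: str = "mean") -> float:
    """Range-normalized RMSE against test-set sample means or variances."""
    if target == "mean":
        pred, obs = predictions.mean, test.sample_means
    elif target == "variance":
        pred, obs = predictions.total_var, test.sample_vars
    else:
        raise ValueError("target must be 'mean' or 'variance'")
    rng_ = float(np.max(obs) - np.min(obs))
    if rng_ == 0.0:
        raise ValueError("zero range in the normalizing statistic")
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / rng_)


def score(predictions: Prediction, test: TestSet, standardize: str = "var") -> float:
    """Log-density-style accuracy score; higher is better.

    ``standardize="var"`` divides the mean error by k* (as printed in
    the defining formula), ``"sd"`` by sqrt(k*).
    """
    k = predictions.total_var
    if np.any(k <= 0):
        raise ValueError("score requires strictly positive predictive variance")
    e = predictions.mean - test.sample_means
    denom = k if standardize == "var" else np.sqrt(k)
    return float(np.mean(-((e / denom) ** 2) - np.log(k)))
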