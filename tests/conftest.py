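import numpy as np
import pytest

from esloo import (
    FitSettings,
    ReplicatedDesign,
    fit_hetgp,
    make_maximin_lhd,
    toy_simulator,
)


def random_design(seed: int, p: int = 2, n: int = 6, max_reps: int = 4,
                  noise: float = 0.3) -> ReplicatedDesign:
    """A small replicated design with smooth mean and mild input-dependent noise."""
    rng = np.random.default_rng(seed)
    design = ReplicatedDesign(p=p)
    X = make_maximin_lhd(n, p, seed=seed + 1)
    for x in X:
        sd = noise * (0.2 + x[0])
        mean = np.sin(3.0 * x[0]) + x[-1] ** 2
        for _ in range(rng.integers(1, max_reps + 1)):
            design.add_run(x, float(rng.normal(mean, sd)))
    return design


def naive_loglik(model, design) -> float:
    """Independent oracle: the N-dimensional Gaussian log-density of all runs."""
    from scipy.stats import multivariate_normal

    rows = np.vstack([np.repeat(design.unique_points[[i]], len(o), axis=0)
                      for i, o in enumerate(design.outputs)])
    y = np.concatenate(design.outputs)
    lam = np.concatenate([np.full(len(o), np.exp(model.log_lambda[i]))
                          for i, o in enumerate(design.outputs)])
    K = model.sigma2 * (model.mean_kernel.correlation(rows) + np.diag(lam))
    return float(multivariate_normal.logpdf(
        y, mean=np.full(design.N, model.trend), cov=K, allow_singular=True))


@pytest.fixture(scope="session")
def toy_design_a10():
    """8 unique points x 4 replicates from the high-noise toy simulator."""
    sim = toy_simulator(a=10.0)
    rng = np.random.default_rng(7)
    design = ReplicatedDesign(p=2)
    for x in make_maximin_lhd(8, 2, seed=5):
        for _ in range(4):
            design.add_run(x, sim.sample(x, rng))
    return design


@pytest.fixture(scope="session")
def toy_model_a10(toy_design_a10):
    return fit_hetgp(toy_design_a10, FitSettings(n_starts=2, seed=1))


@pytest.fixture(scope="session")
def small_fit():
    """A fitted model on a mixed-replication random design, with its design."""
    design = random_design(3, n=7, max_reps=4)
    model = fit_hetgp(design, FitSettings(n_starts=2, seed=2))
    return model, design
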