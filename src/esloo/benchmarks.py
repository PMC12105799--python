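"""Bundled stochastic simulators.

Two desk-scale benchmarks exercise the sequential-design loop:

* a two-dimensional toy simulator with known mean surface

      F(x1, x2) = 4 (x2 + x1^2 + x2^2 + sin(4 pi x1 x2) - 2)

  and linear heteroscedastic noise ``tau(x1, x2) = a (0.25 x1 + 0.75 x2)``
  (``a = 2`` low noise, ``a = 10`` high noise);

* a synthetic chain-binomial stochastic SIR epidemic whose scalar output
  is the basic reproduction number summary

      R0 = N log(S(0)/S(t)) / (N - S(t)).

The epidemic model is a synthetic stand-in: it mimics the interface of
agent-based / compartmental epidemic simulators (up to nine unit-cube
inputs -> one noisy R0 per run) but makes no claim of reproducing any
particular model's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .domain import InputDomain


def toy_mean(x1, x2):
    """Mean response of the 2-D toy simulator."""
    return 4.0 * (x2 + x1**2 + x2**2 + np.sin(4.0 * np.pi * x1 * x2) - 2.0)


def toy_sd(x1, x2, a: float = 2.0):
    """Intrinsic standard deviation of the toy simulator, a*(x1/4 + 3 x2/4)."""
    return a * (0.25 * x1 + 0.75 * x2)


def toy_sample(x, a: float, rng: np.random.Generator) -> float:
    """One noisy draw from the toy simulator at unit-square x."""
    x = np.asarray(x, float).ravel()
    return float(rng.normal(toy_mean(x[0], x[1]), toy_sd(x[0], x[1], a)))


@dataclass
class StochasticSimulator:
    """Callable simulator contract on the unit cube.

    ``sample(x, rng)`` returns one noisy scalar; ``true_mean`` and
    ``true_sd`` are available when known analytically.
    """

    domain: InputDomain
    sample: Callable[[np.ndarray, np.random.Generator], float]
    true_mean: Callable | None = None
    true_sd: Callable | None = None
    name: str = ""


def toy_simulator(a: float = 2.0) -> StochasticSimulator:
    return StochasticSimulator(
        domain=InputDomain.unit(2),
        sample=lambda x, rng: toy_sample(x, a, rng),
        true_mean=lambda x: toy_mean(x[..., 0], x[..., 1]),
        true_sd=lambda x: toy_sd(x[..., 0], x[..., 1], a),
        name=f"toy(a={a})",
    )


def r0_summary(N: int, S0: int, St: int) -> float:
    """Reproduction-number summary N log(S0/St) / (N - St).

    Returns 0 when no epidemic occurred (St == S0); when the susceptible
    pool is exhausted the count is floored at one so the log stays
    finite; St == N (division by zero) returns the log-limit value.
    """
    if St >= S0:
        return 0.0
    St_eff = max(St, 1)
    if N == St:
        return float(np.log(S0 / St_eff))  # limit of the ratio as St -> N
    return float(N * np.log(S0 / St_eff) / (N - St))


@dataclass
class EpidemicConfig:
    """Input mapping of the synthetic chain-binomial SIR simulator.

    Unit-cube inputs map to (in order): per-contact infection
    probability, mean recovery time (days), daily contact rate, initial
    immune fraction, population size; dimensions 6-9 mildly modulate
    isolation, travel mixing, vaccination uptake and contact
    variability.  Use ``p`` <= 9.
    """

    p: int = 5
    n_steps: int = 100
    infect_prob: tuple[float, float] = (0.01, 0.30)
    recovery_time: tuple[float, float] = (2.0, 20.0)
    contact_rate: tuple[float, float] = (1.0, 15.0)
    immune_frac: tuple[float, float] = (0.0, 0.5)
    population: tuple[float, float] = (50.0, 500.0)
    init_infected_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.p <= 9:
            raise ValueError("p must be between 1 and 9")


def _lerp(lohi: tuple[float, float], u: float) -> float:
    return lohi[0] + (lohi[1] - lohi[0]) * u


def epidemic_simulator(x, config: EpidemicConfig, rng: np.random.Generator) -> float:
    """One seeded chain-binomial SIR run; returns the R0 summary.

    Discrete daily steps: each susceptible escapes infection with
    probability ``(1 - beta)^(c I / N)``; infectives recover with
    probability ``1/T``.  The output is heteroscedastic by construction
    (variance depends strongly on the inputs through the epidemic
    threshold and the population size).
    """
    x = np.asarray(x, float).ravel()
    if x.size != config.p:
        raise ValueError(f"expected {config.p} inputs, got {x.size}")
    u = np.clip(x, 0.0, 1.0)
    get = lambda k, default=0.5: u[k] if k < u.size else default

    beta = _lerp(config.infect_prob, get(0))
    T = _lerp(config.recovery_time, get(1, 0.5))
    c = _lerp(config.contact_rate, get(2, 0.5))
    immune = _lerp(config.immune_frac, get(3, 0.0))
    N = int(round(_lerp(config.population, get(4, 0.5))))
    # optional modifiers (dimensions 6..9)
    isolation = get(5, 0.0)          # fraction of contacts avoided when infected
    travel = get(6, 0.5)             # mixing multiplier 0.5..1.5
    vaccinated = 0.3 * get(7, 0.0)   # extra immune fraction
    overdisp = get(8, 0.0)           # day-to-day contact variability

    gamma = 1.0 / T
    n_immune = int(round(min(immune + vaccinated, 0.9) * N))
    n_inf = max(1, int(round(config.init_infected_frac * (N - n_immune))))
    S = N - n_immune - n_inf
    I = n_inf
    S0 = S
    eff_c = c * (1.0 - 0.7 * isolation) * (0.5 + travel)
    for _ in range(config.n_steps):
        if I == 0 or S == 0:
            break
        day_c = eff_c * (1.0 + overdisp * rng.normal()) if overdisp > 0 else eff_c
        day_c = max(day_c, 0.0)
        p_inf = 1.0 - (1.0 - beta) ** (day_c * I / N)
        new_inf = rng.binomial(S, p_inf)
        recov = rng.binomial(I, gamma)
        S -= new_inf
        I += new_inf - recov
    return r0_summary(N, S0, S)


def epidemic_simulator_factory(config: EpidemicConfig | None = None) -> StochasticSimulator:
    config = config or EpidemicConfig()
    return StochasticSimulator(
        domain=InputDomain.unit(config.p),
        sample=lambda x, rng: epidemic_simulator(x, config, rng),
        name=f"epidemic(p={config.p})",
    )


def get_simulator(name: str, **params) -> StochasticSimulator:
    """Simulator registry addressed by name ("toy" or "epidemic")."""
    if name == "toy":
        return toy_simulator(a=params.get("a", 2.0))
    if name == "epidemic":
        cfg = EpidemicConfig(**{k: v for k, v in params.items()
                                if k in EpidemicConfig.__dataclass_fields__})
        return epidemic_simulator_factory(cfg)
    raise KeyError(f"unknown simulator {name!r}")
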