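"""Top-level sequential design loop: new point versus replicate.

Each iteration fits the heteroscedastic GP, proposes one candidate new
point (``x*_m``, by pseudo expected improvement over the ES-LOO error
surface) and one candidate replicate (``x*_tau``, by the intrinsic-
variance LOO criterion), then arbitrates between them with a selection
function ``G``:

    x* = argmax { G(x*_m), c * G(x*_tau) },

where ``c > 0`` encodes a user preference for replication.  Three G's
are provided: predictive variance (sequential maximum entropy), a
fantasy-update IMSPE (negated, so smaller integrated variance wins the
argmax), and an independent uniform draw per candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .acquisition import (
    ESLooSurface,
    ProposedPoint,
    VarianceESLoo,
    det_esloo_scores,
    esloo_mean_scores,
    esloo_variance_scores,
    fit_esloo_surface,
    propose_new_point,
)
from .design import ReplicatedDesign
from .detgp import fit_deterministic_gp
from .hetgp import FitSettings, HetGPModel, fit_hetgp


class ModeNotApplicableError(RuntimeError):
    pass


@dataclass
class SelectionPolicy:
    """How the loop arbitrates and batches.

    ``g_kind`` in {"entropy", "imspe", "random"}; ``replicate_weight``
    is the weight c applied to the replicate candidate's G value;
    ``batch_size`` q adds several runs per iteration; the many-
    replicates mode switches to two deterministic GPs on the sample
    means and log sample variances once every point carries at least
    ``replicate_threshold`` replicates.
    """

    g_kind: str = "entropy"
    replicate_weight: float = 1.0
    batch_size: int = 1
    many_replicates_mode: bool = False
    replicate_threshold: int = 10
    many_run_both: bool = False
    imspe_nodes: int = 256
    batch_replicate_rule: str = "esloo"  # or "fewest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_weight <= 0:
            raise ValueError("replicate_weight must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.g_kind not in ("entropy", "imspe", "random"):
            raise ValueError(f"unknown g_kind {self.g_kind!r}")


@dataclass
class SelectionRecord:
    iteration: int
    chosen_point: np.ndarray
    is_replicate: bool
    g_new: float
    g_rep: float
    candidate_new: np.ndarray
    candidate_rep: np.ndarray
    pei_value: float = np.nan
    esl_tau_value: float = np.nan


def g_entropy(model: HetGPModel, x: np.ndarray) -> float:
    """Sequential maximum-entropy criterion: predictive variance at x in
    correlation form, k*(x)/sigma^2 (intrinsic part included)."""
    pred = model.predict(np.atleast_2d(x))
    return float(pred.total_var[0] / model.sigma2)


def _imspe_nodes(p: int, nodes: int, seed: int = 202406) -> np.ndarray:
    m = int(np.ceil(np.log2(max(nodes, 2))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Sobol balance warning for non-power-of-2
        return qmc.Sobol(d=p, scramble=True, seed=seed).random_base2(m)


def g_imspe(model: HetGPModel, design: ReplicatedDesign, x: np.ndarray,
            nodes: int = 256) -> float:
    """Integrated predictive variance after a fantasy run at x.

    The model is augmented with one hypothetical run at ``x`` (frozen
    hyperparameters; a replicate if ``x`` matches an existing point) and
    ``k*`` is averaged over a fixed seeded Sobol node set.  Smaller is
    better; the caller negates it for the argmax of the selection rule.
    """
    if nodes < 64:
        raise ValueError("at least 64 integration nodes required")
    x = np.asarray(x, float).ravel()
    r = design.rep_counts.astype(float)
    i = design.match(x)
    lam = np.exp(model.log_lambda)
    if i is None:
        Xa = np.vstack([model.X, x])
        lam_a = np.append(lam, model.lambda_at(x.reshape(1, -1))[0])
        r_a = np.append(r, 1.0)
    else:
        Xa = model.X
        lam_a = lam
        r_a = r.copy()
        r_a[i] += 1.0
    from scipy import linalg

    C = model.mean_kernel.correlation(Xa)
    K = C + np.diag(lam_a / r_a) + 1e-10 * np.eye(Xa.shape[0])
    cho = linalg.cho_factor(K, lower=True)
    pts = _imspe_nodes(model.p, nodes)
    c = model.mean_kernel.correlation(pts, Xa)
    sol = linalg.cho_solve(cho, c.T)
    kz = model.sigma2 * np.clip(1.0 - np.sum(c * sol.T, axis=1), 0.0, None)
    tau2 = model.tau2_at(pts)
    return float(np.mean(kz + tau2))


def g_random(rng: np.random.Generator) -> tuple[float, float]:
    """Independent uniform(0,1) draws for the new point and the replicate."""
    return float(rng.uniform()), float(rng.uniform())


def _g_values(model, design, policy, x_new, x_rep, rng):
    if policy.g_kind == "entropy":
        return g_entropy(model, x_new), g_entropy(model, x_rep)
    if policy.g_kind == "imspe":
        return (-g_imspe(model, design, x_new, policy.imspe_nodes),
                -g_imspe(model, design, x_rep, policy.imspe_nodes))
    return g_random(rng)


def select_next(
    model: HetGPModel,
    design: ReplicatedDesign,
    policy: SelectionPolicy,
    proposal: ProposedPoint,
    var_esloo: VarianceESLoo,
    x_rep: np.ndarray,
    rng: np.random.Generator,
    iteration: int = 0,
) -> SelectionRecord:
    """Arbitrate between the candidate new point and candidate replicate.

    The replicate's G is weighted by c; ties go to the new point.
    """
    x_new = proposal.x
    g_new, g_rep = _g_values(model, design, policy, x_new, x_rep, rng)
    is_rep = policy.replicate_weight * g_rep > g_new
    chosen = x_rep if is_rep else x_new
    return SelectionRecord(
        iteration=iteration,
        chosen_point=np.asarray(chosen, float).copy(),
        is_replicate=bool(is_rep),
        g_new=float(g_new),
        g_rep=float(g_rep),
        candidate_new=np.asarray(x_new, float).copy(),
        candidate_rep=np.asarray(x_rep, float).copy(),
        pei_value=proposal.pei_value,
        esl_tau_value=float(var_esloo.scores.max()),
    )


def select_batch(
    model: HetGPModel,
    design: ReplicatedDesign,
    policy: SelectionPolicy,
    surface: ESLooSurface,
    var_esloo: VarianceESLoo,
    rng: np.random.Generator,
    iteration: int = 0,
    acq_seed: int = 0,
) -> list[SelectionRecord]:
    """Batch of q runs: q greedy PEI points (repulsion updated after each
    accepted candidate), q replicate candidates (top ESL_tau, one per
    point, or fewest-replicates), best q of the 2q by weighted G."""
    q = policy.batch_size
    if q == 1:
        prop = propose_new_point(surface, seed=acq_seed)
        x_rep = model.X[var_esloo.argmax()]
        return [select_next(model, design, policy, prop, var_esloo, x_rep, rng,
                            iteration)]
    new_props: list[ProposedPoint] = []
    extra = np.empty((0, model.p))
    for b in range(q):
        prop = propose_new_point(surface, seed=acq_seed + b, extra_points=extra)
        new_props.append(prop)
        extra = np.vstack([extra, prop.x])
    if policy.batch_replicate_rule == "fewest":
        order = np.argsort(design.rep_counts, kind="stable")
    else:
        order = np.argsort(var_esloo.scores)[::-1]
    n_rep = min(q, model.n)
    if n_rep < q:
        warnings.warn(f"only {n_rep} replicate candidates available for batch of {q}")
    rep_idx = order[:n_rep]

    cands = []
    for prop in new_props:
        g, _ = _g_values(model, design, policy, prop.x, prop.x, rng)
        cands.append((g, False, prop.x, prop))
    for i in rep_idx:
        _, g = _g_values(model, design, policy, model.X[i], model.X[i], rng)
        cands.append((policy.replicate_weight * g, True, model.X[i], None))
    # ties go to new points: stable sort with new points first
    cands.sort(key=lambda t: (not t[1],), reverse=False)
    cands.sort(key=lambda t: t[0], reverse=True)
    records = []
    for g, is_rep, x, prop in cands[:q]:
        records.append(SelectionRecord(
            iteration=iteration,
            chosen_point=np.asarray(x, float).copy(),
            is_replicate=is_rep,
            g_new=g if not is_rep else np.nan,
            g_rep=g if is_rep else np.nan,
            candidate_new=new_props[0].x.copy(),
            candidate_rep=model.X[rep_idx[0]].copy(),
            pei_value=prop.pei_value if prop else np.nan,
            esl_tau_value=float(var_esloo.scores.max()),
        ))
    return records


def many_replicates_step(
    design: ReplicatedDesign,
    policy: SelectionPolicy,
    seed: int = 0,
) -> tuple[ProposedPoint, ProposedPoint]:
    """Heavily replicated designs: two deterministic GPs, two PEI points.

    With every point carrying at least ``replicate_threshold``
    replicates, the sample means and log sample variances are trusted
    directly; the deterministic ES-LOO/PEI pipeline runs on each surface
    and returns a mean-targeting and a variance-targeting new point.
    """
    r = design.rep_counts
    if np.any(r < policy.replicate_threshold):
        raise ModeNotApplicableError(
            f"all points need at least {policy.replicate_threshold} replicates")
    ybar, s2 = design.sample_stats()
    X = design.unique_points
    gp_mean = fit_deterministic_gp(X, ybar, nugget=1e-8, seed=seed)
    gp_var = fit_deterministic_gp(X, np.log(np.maximum(s2, 1e-12)),
                                  nugget=1e-8, seed=seed + 1)
    props = []
    for k, gp in enumerate((gp_mean, gp_var)):
        scores = det_esloo_scores(gp)
        surface = fit_esloo_surface(X, scores, seed=seed + 2 + k)
        props.append(propose_new_point(surface, seed=seed + 4 + k))
    return props[0], props[1]


# ---------------------------------------------------------------------
# the sequential loop
# ---------------------------------------------------------------------


@dataclass
class RunHistory:
    """Per-iteration records of one sequential-design run."""

    records: list[SelectionRecord] = field(default_factory=list)
    metrics: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, met in zip(self.records, self.metrics):
            row = {
                "iteration": rec.iteration,
                "is_replicate": rec.is_replicate,
                "g_new": rec.g_new,
                "g_rep": rec.g_rep,
                "pei_value": rec.pei_value,
                "esl_tau_value": rec.esl_tau_value,
            }
            for j, v in enumerate(rec.chosen_point):
                row[f"x{j + 1}"] = v
            row.update(met)
            rows.append(row)
        return pd.DataFrame(rows)


def _derive_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_sequential(
    simulator,
    design: ReplicatedDesign,
    policy: SelectionPolicy,
    n_iterations: int,
    fit_settings: FitSettings | None = None,
    metric_fn=None,
    sim_seed: int = 0,
    start_iteration: int = 0,
    logger=None,
) -> RunHistory:
    """Run the full fit / acquire / select / simulate loop.

    ``simulator`` is called as ``simulator(x_unit, rng)`` and must return
    a finite scalar; the design is modified in place, growing by one run
    (q per batch iteration).  ``metric_fn(model, design)`` may return a
    dict of per-iteration diagnostics.  Fully reproducible: all internal
    seeds are derived from ``policy.seed`` / ``sim_seed`` and the
    iteration index, so an interrupted run can resume at
    ``start_iteration`` with identical behaviour.
    """
    fit_settings = fit_settings or FitSettings()
    history = RunHistory()
    for it in range(start_iteration, start_iteration + n_iterations):
        fs = FitSettings(**{**fit_settings.__dict__,
                            "seed": _derive_seed(fit_settings.seed, it, 1)})
        model = fit_hetgp(design, fs)
        acq_seed = _derive_seed(policy.seed, it, 2)
        rng = np.random.default_rng(_derive_seed(policy.seed, it, 3))
        sim_rng = np.random.default_rng(_derive_seed(sim_seed, it, 4))

        if policy.many_replicates_mode and np.all(
                design.rep_counts >= policy.replicate_threshold):
            prop_m, prop_t = many_replicates_step(design, policy, seed=acq_seed)
            if policy.many_run_both:
                recs = []
                for flag, prop in ((False, prop_m), (True, prop_t)):
                    recs.append(SelectionRecord(
                        iteration=it, chosen_point=prop.x, is_replicate=flag,
                        g_new=np.nan, g_rep=np.nan, candidate_new=prop_m.x,
                        candidate_rep=prop_t.x, pei_value=prop.pei_value))
            else:
                g_new, g_rep = _g_values(model, design, policy,
                                         prop_m.x, prop_t.x, rng)
                is_rep = policy.replicate_weight * g_rep > g_new
                chosen = prop_t if is_rep else prop_m
                recs = [SelectionRecord(
                    iteration=it, chosen_point=chosen.x, is_replicate=bool(is_rep),
                    g_new=float(g_new), g_rep=float(g_rep),
                    candidate_new=prop_m.x, candidate_rep=prop_t.x,
                    pei_value=chosen.pei_value)]
        else:
            scores = esloo_mean_scores(model)
            surface = fit_esloo_surface(model.X, scores, seed=acq_seed)
            var_esloo, x_rep = esloo_variance_scores(model, design, seed=acq_seed)
            if policy.batch_size > 1:
                recs = select_batch(model, design, policy, surface, var_esloo,
                                    rng, iteration=it, acq_seed=acq_seed)
            else:
                prop = propose_new_point(surface, seed=acq_seed)
                recs = [select_next(model, design, policy, prop, var_esloo,
                                    x_rep, rng, iteration=it)]

        for rec in recs:
            try:
                y = float(simulator(rec.chosen_point, sim_rng))
            except Exception as exc:  # simulator failure: skip, design unchanged
                if logger:
                    logger(f"iteration {it}: simulator failed ({exc}); skipped")
                continue
            if not np.isfinite(y):
                if logger:
                    logger(f"iteration {it}: non-finite output; skipped")
                continue
            design.add_run(rec.chosen_point, y)
            met = metric_fn(model, design) if metric_fn else {}
            history.records.append(rec)
            history.metrics.append(met)
            if logger:
                kind = "replicate" if rec.is_replicate else "new point"
                logger(f"iteration {it}: chose {kind} "
                       f"(g_new={rec.g_new:.4g}, g_rep={rec.g_rep:.4g})")
    return history
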