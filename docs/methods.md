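# Methods

## Model

A stochastic simulator is modelled as `f(x) = F(x) + v`,
`v ~ N(0, τ²(x))`, on inputs rescaled to the unit cube `[0,1]^p`. The
mean surface `F` carries a GP prior with constant trend β and Matérn
kernel `σ² c(x, x')` in the scaled (ARD) form: distances are weighted
per dimension by lengthscales θⱼ and passed through the one-dimensional
Matérn radial profile. Smoothness ν defaults to 5/2 (twice-
differentiable surfaces, the common choice for smooth simulator output);
ν ∈ {1/2, 3/2, 5/2} are closed forms with analytic gradients, other
ν are available for kernel evaluation only.

The intrinsic variance is `τ²(x) = σ² λ(x)`. At the n unique design
points the log relative variances are the predictive mean of a
zero-mean GP on free latent variables Δₙ:

    log Λₙ = C_g (C_g + g Rₙ⁻¹)⁻¹ Δₙ,

with `C_g` the (Matérn) correlation matrix of the noise kernel,
`Rₙ = diag(r₁..rₙ)` the replicate counts and `g` a nugget. Off-design,
`log λ(x) = c_g(x, X') (C_g + g Rₙ⁻¹)⁻¹ Δₙ` extends the same predictive
mean continuously, which the predictive equations and the entropy/IMSPE
criteria require. The noise kernel shares one lengthscale across
dimensions: variance surfaces are weakly identified at desk-scale n and
an anisotropic noise kernel mostly adds non-convexity.

### Replicated likelihood

Grouping runs by unique point reduces the N-dimensional Gaussian
likelihood exactly to n-sized quantities (Woodbury identities):

    K̃ₙ  = Cₙ + Λₙ Rₙ⁻¹
    Q    = Σᵢ (rᵢ−1) sᵢ²/λᵢ + (ȳ−β)ᵀ K̃ₙ⁻¹ (ȳ−β)
    logL = −N/2 log(2πσ²) − ½ Σᵢ[(rᵢ−1)log λᵢ + log rᵢ]
           − ½ log|K̃ₙ| − Q/(2σ²).

β (GLS) and σ² (= Q/N) are profiled analytically. The remaining
parameters — log θ (p), log θ_g (1), log g (1), Δₙ (n) — are optimized
by L-BFGS-B with analytic gradients (chain rule through the linear
smoother), from a data-driven start (lengthscales 0.5, Δ from sample
log-variances) plus seeded perturbations; 5 starts by default. The test
suite checks the reduction against the naive N×N Gaussian density and
the gradient against finite differences.

Two regularization choices matter and are deliberate:

* **Latent prior.** The objective adds the log-density of Δₙ under a
  zero-mean Gaussian with covariance `C_g + g Rₙ⁻¹` and unit variance
  (toggleable via `FitSettings.latent_penalty`). Without it, λᵢ at
  singly-replicated points can degenerate (the likelihood of a point
  with no replicate information is maximized by interpolating it
  noise-free). A *profiled* latent variance would be unbounded as Δ→0,
  so the prior variance is fixed at 1 — log-variance latents are O(1)
  quantities.
* **Nugget floor.** `g` is bounded below by 1e-2
  (`FitSettings.nugget_bounds`). `g` represents the observation noise of
  the latent log-variances; the sampling sd of a log sample variance
  with r replicates is ≈ √(2/(r−1)), far above 1e-2 at realistic
  replication. With `g → 0` the smoother reduces to the identity and
  τ² becomes independent of the replicate counts — which would make the
  replicate-selection criterion (below) identically zero.

### Prediction and fast leave-one-out

`m*(x) = β + c(x,X')K̃ₙ⁻¹(ȳ−β)`, `k_Z(x) = σ²(1 − c K̃ₙ⁻¹ cᵀ)`,
`k*(x) = τ²(x) + k_Z(x)`. Deleting all replicates of point i (for the
new-point criterion) uses the standard closed-form downdate via the
diagonal of K̃ₙ⁻¹ — no refitting, hyperparameters frozen. Deleting a
single replicate (for the replicate criterion) re-smooths Λₙ with
`rᵢ → rᵢ−1` (frozen kernel parameters and Δ) and rebuilds K̃ₙ; with
frozen hyperparameters the resulting τ² and variance are exactly
exchangeable across which replicate is deleted, and the predictive mean
additionally depends on the removed value
(`loo_replicate_with_value`). Both are verified against explicit
full-covariance refits.

The LOO variance used in the acquisition includes the intrinsic part
(`k₋ᵢ* = τ²ᵢ + k_{Z,−i}`), consistent with `k* = τ² + k_Z` elsewhere; a
`loo_variance="process"` switch exposes the k_Z-only convention.

## Acquisition

**New point (ESL_m → PEI).** At each unique point the expected squared
LOO error is standardized by its own spread: with
`v = k₋ᵢ* + k_Z(xᵢ')/rᵢ` and `e² = (m₋ᵢ* − ȳᵢ)²`,

    E_m = (v + e²) / sqrt(2v² + 4v e²),

which is 1/√2 at zero error and increasing in the error (the squared
standardized residual is non-central χ²₁). A deterministic GP `Z_E` is
fitted to `log E_m` (scores clamped at 1e-12 first), with lengthscales
floored at `θ_E = −0.5/log(10⁻⁸) ≈ 0.0271` so the error surface cannot
collapse to white noise. Expected improvement over `max(y_E)` is
evaluated on the log scale with the *standard deviation* `s_E = √k_E*`
in the exploration term (the dimensionally consistent standard EI
form), multiplied by the repulsion function over design points plus
pseudo points (the 2^p unit-cube corners for p ≤ 6, 2p face centres
beyond), and maximized by seeded multi-start search: 100·p Latin
hypercube starts screened, the best 10 polished by L-BFGS-B. A
numerically flat PEI landscape (max ≤ 1e-12) falls back to the start
with maximal surface variance and is flagged.

**Replicate (ESL_τ).** For each unique point the deletion swing
`d = τ²₋ᵢ(xᵢ') − τ²(xᵢ')` is computed (one deletion per point suffices —
see exchangeability above; for rᵢ = 1 the point is removed entirely). A
deterministic GP `Z_e` is fitted to the signed swings at the unique
points (per-replicate training pairs would be exact duplicates and are
aggregated by their mean), and `ESL_τ(xᵢ') = m_e² + k_e`. The candidate
replicate is the argmax over *existing* points only; no continuous
search.

**Arbitration (G).** Three options, uniform under one argmax:

* `entropy` — `k*(x)/σ²` in correlation form, intrinsic part included;
* `imspe` — the integrated predictive variance of the model augmented
  by a hypothetical run at x (frozen hyperparameters; a replicate if x
  matches a design point), averaged over a fixed seeded Sobol node set
  (256 nodes by default; 2-D agreement with a 200×200 grid quadrature
  is within 2%). IMSPE is *negated* before the argmax so that smaller
  integrated variance wins; note that the replicate weight c then acts
  on a negative value, so preferences via c are meaningful for the
  positive-valued criteria (entropy, random);
* `random` — one independent uniform draw per candidate.

Ties go to the new point (exploration is the safer early default). The
weight defaults to c = 1.

**Batch mode** selects q new points greedily, adding each accepted
candidate to the repulsion set (so later PEI values can only fall), and
q replicate candidates as the top-q ESL_τ scores with at most one
replicate per point (a fewest-replicates rule is available); the best q
of the 2q candidates by weighted G are run.

**Many-replicates mode** (all rᵢ ≥ 10 by default) trusts the sample
moments: two deterministic GPs are fitted to ȳ and log s², the
deterministic ES-LOO/PEI pipeline (no sample-mean noise term) runs on
each, and either both proposals are executed or G arbitrates, per
policy.

## Benchmarks and metrics

The 2-D toy simulator draws
`N(4(x₂ + x₁² + x₂² + sin(4πx₁x₂) − 2), [a(0.25x₁ + 0.75x₂)]²)`, with
a = 2 (low noise) and a = 10 (high noise) as the study conditions; noise
vanishes at the origin, so the variance surface spans degenerate to
strong noise. The epidemic benchmark is a *synthetic* chain-binomial
SIR model: daily binomial infection/recovery draws, up to nine unit-cube
inputs (per-contact infection probability, recovery time, contact rate,
initial immunity, population size, plus optional isolation/travel/
vaccination/overdispersion modifiers), output
`R0 = N log(S(0)/S(t)) / (N − S(t))` (0 when no epidemic; the
susceptible count is floored at one so the log stays finite, and
`S(t) = N` returns the log-limit value). It reproduces the *interface*
and heteroscedastic character of agent-based epidemic models — output
variance concentrates near the epidemic threshold and at small
populations — not any particular model's values: conclusions from it
are about the design algorithm, not about epidemiology.

Accuracy against a replicated test set (Latin hypercube points, r ≥ 2
replicates) uses the range-normalized RMSE of the predicted mean vs ȳ
and of the total predictive variance k* vs s², and the score
`mean[−((m*−ȳ)/k*)² − log k*]` (higher is better). The score
standardizes by k* itself, as defined; a `standardize="sd"` switch
divides by √k* instead, and cross-implementation comparisons should
avoid the score for that reason.

## Problem sizes and numerical choices

* Experiments in the test suite and acceptance script use the 6-point ×
  4-replicate initial design, 20 sequential iterations, 3 (or 10)
  starting designs and 100 × 50 test sets — desk-scale versions of the
  full protocol (50 iterations, 10 starts, 10000 × 250 test points),
  which remains available through the experiment config.
* merge tolerance 1e-9 (unit-cube Euclidean) decides when an optimizer
  output is an existing point; exact at the boundary by construction.
* lengthscale bounds [0.02, 10] (mean), [0.05, 10] (noise); latent
  bounds |Δᵢ| ≤ 15; covariance jitter 1e-10; log-λ clipped at ±40
  inside the objective.
* All random streams (design, fit, acquisition, simulator) are separate
  and seeded; every loop, experiment and script is bit-reproducible.
* Interrupted experiments resume from per-start checkpoints; per-
  iteration seeds are derived from (base seed, iteration), so a resumed
  run is identical to an uninterrupted one.

## Limitations

* With few design points and strong noise the ML fit can prefer flat
  lengthscales in some dimension (mean-surface variation absorbed into
  τ²); this is the honest likelihood optimum at that sample size and
  resolves as the design grows, but early-iteration NRMSE trajectories
  fluctuate accordingly — more so at a = 10.
* The zero-mean latent GP shrinks log λ toward 0 (τ² toward σ²) where
  replication is scarce.
* The intrinsic-variance estimate carries no posterior uncertainty
  (plug-in Λₙ), so the replicate criterion reacts to replicate-count
  sensitivity, not to full variance uncertainty.
* Hyperrectangular domains and quantitative inputs only; no look-ahead
  over future replication; no asynchronous dispatch.
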