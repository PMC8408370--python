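# blockbps

Blocked and even–odd partitioned bouncy particle samplers for smoothing in
differentiable state-space models.

## The problem

Given a latent process `x_1, …, x_N` on `R^d` with differentiable
transition density `p(x_n | x_{n−1})` and observations
`y_n | x_n ~ p(y_n | x_n)`, *smoothing* is inference of the full
conditional `π(x_{1:N}) = p(x_{1:N} | y_{1:N})`.  Particle-based smoothers
struggle when the spatial dimension `d` grows (weight degeneracy) or the
series is long.  This package implements continuous-time, event-driven
MCMC for the smoothing distribution: the state `x ∈ M_{d,N}` and a
Gaussian velocity `v ∈ M_{d,N}` follow a piecewise-deterministic Markov
process whose events only require gradients of the potential
`U(x) = −log π(x)`.  It is aimed at researchers in computational
statistics and at practitioners with moderately high-dimensional
state-space models (epidemiological panels, multivariate volatility).

## The samplers

A **blocking strategy** covers the index grid `[d] × [N]` with rectangles
`B = i:j × l:m`, possibly overlapping.  With
`φ(k,n) = #{B ∋ (k,n)}`, the position flows as `dx/dt = φ ⋆ v` and each
block carries a Poisson clock with rate

    λ_B(x, v) = ⟨∇_B U(x), v_B⟩_F⁺ ,

whose events reflect the block's velocity in the hyperplane orthogonal to
the block gradient:

    v_B ← v_B − 2 ⟨∇_B U(x), v_B⟩_F / ‖∇_B U(x)‖²_F · ∇_B U(x) .

A homogeneous clock at rate `γ` refreshes the whole velocity from its
standard-normal law.  Overlapping blocks share information along the
series — shared coordinates move `φ` times faster, which is what the flow
correction is for.  One whole-grid block recovers the standard bouncy
particle sampler (`simulate_global_bps`); disjoint temporal blocks give
the local/factor variant (`simulate_local_bps`); the general overlapping
case is `simulate_blocked_bps`.  Event times are simulated by Poisson
thinning against per-block lookahead bounds — exact endpoint bounds for
quadratic potentials, safety-inflated grid bounds otherwise, with hard
errors on any detected bound violation.

The **even–odd / four-clock** variant (`simulate_even_odd_bps`) partitions
the strategy into `K` sub-strategies of pairwise disjoint blocks (2 colours
for a temporal chain, 4 for a spatiotemporal checkerboard) and runs one
clock per colour using the max-type bound
`Λ̄_κ = max_B sup_{s≤θ} λ_B(x + s(φ⋆v), v)`, which grows only
logarithmically in the number of blocks under sub-exponential rate tails.
Disjointness makes the per-event block updates commute — the
order-independence contract of `apply_partition_kernel` is tested at the
bit level.

Built-in models: a linear-Gaussian AR(1) with a kernel autoregressive
matrix (plus exact Kalman/RTS and dense-Gaussian oracles and a posterior
sampler), and a heavy-tailed stochastic volatility model with leverage
(multivariate-t observation noise via Gamma mixing, inference conditional
on the mixing variables).  See `docs/methods.md` for the full model and
algorithm description.

## Worked example

```python
import numpy as np
import blockbps as bb

params = bb.LGSSMParams(d=3, N=200, sigma2=5.0, psi=0.1)
x_true, y = bb.simulate_lgssm(params, seed=0)
model = bb.LinearGaussianSSM(params, y)

strategy = bb.make_temporal_strategy(3, 200, width=20, overlap=10)
config = bb.SamplerConfig(horizon=500.0, theta=0.05, gamma_refresh=1.0, seed=0)
skeleton = bb.simulate_blocked_bps(model, strategy, config, x0=np.zeros((3, 200)))
chain = bb.discretize_trajectory(skeleton, delta=0.1).burn(0.25)

means, covs = bb.kalman_rts_smoother(params, y)
rmse = np.sqrt(np.mean((chain.samples.mean(axis=0) - means) ** 2))
print(f"{len(strategy)} blocks, {skeleton.counters['reflections']} reflections")
print(f"posterior-mean RMSE vs exact smoother: {rmse:.4f}")
print(f"ESS of x^1_100: {bb.ess(chain.coordinate(0, 100)):.0f} from {len(chain)} samples")
```

prints

```
19 blocks, 44256 reflections
posterior-mean RMSE vs exact smoother: 0.0203
ESS of x^1_100: 517 from 3751 samples
```

The simulated 3-dimensional AR(1) series of length 200 is covered by 19
overlapping temporal blocks (width 20, overlap 10).  Running the blocked
sampler for 500 sampler seconds and thinning every 0.1 seconds leaves
3751 samples after a 25% burn-in; their average estimates every smoothing
mean within 0.02 of the exact Kalman/RTS answer (posterior standard
deviations here are ≈ 0.7), and a single coordinate's chain carries about
517 effectively independent samples.

The same workflow is available from the shell:

```bash
blockbps simulate --model lgssm --d 3 --n-steps 200 --seed 0 --out-dir data/
blockbps sample --data data/observations.csv --config config.yaml \
    --sampler even-odd --out-dir run/
blockbps diagnose --chain run/thinned.csv --coordinate 0 100 --out report.json
```

with a YAML config declaring the model block (`name`, `d`, `N`, `sigma2`,
`psi`) and sampler settings (`width`, `overlap`, `horizon`, `theta`,
`delta`, `seed`).

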