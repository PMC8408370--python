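# Methods

## The smoothing problem

A latent process `x_1, …, x_N` on `R^d` evolves through a differentiable
transition density and is observed through a differentiable observation
density.  We collect the state in a `d × N` matrix `x` (rows = spatial
dimensions, columns = time) and target the full smoothing distribution
`π(x) = p(x_{1:N} | y_{1:N})`.  All samplers in this package see the target
only through the potential `U(x) = −log π(x)` (normalisation constants
included, so `U` is exactly the negative log density) and its gradient
`∇U : M_{d,N} → M_{d,N}`.

## Blocked bouncy particle sampler

The sampler is a piecewise-deterministic Markov process on `(x, v)` with
`v` a `d × N` velocity whose stationary law is i.i.d. standard normal.  A
*blocking strategy* is a cover of the index grid `[d] × [N]` by rectangles
`B = i:j × l:m`; blocks may overlap.  The membership count
`φ(k, n) = #{B ∋ (k, n)}` enters the flow: positions follow
`dx/dt = φ ⋆ v` (Hadamard product), so coordinates shared by `φ` blocks move
`φ` times faster — compensating for the fact that they receive events from
`φ` clocks.  Each block carries an inhomogeneous Poisson clock with rate

    λ_B(x, v) = ⟨∇_B U(x), v_B⟩_F⁺ ,

the positive part of the Frobenius inner product between the
block-restricted gradient and the block's velocity submatrix.  At an event
of block `B`, `v_B` is reflected in the hyperplane orthogonal to
`∇_B U(x)`; all other components are untouched.  Reflections preserve
`‖v_B‖_F` and are involutions.  An independent homogeneous clock with rate
`γ` resamples the entire velocity from its standard-normal law; without it
the process can be reducible (on an isotropic Gaussian, for example,
reflections conserve the angular momentum `x ∧ v` exactly — a property the
test suite demonstrates).  One block covering the whole grid recovers the
standard bouncy particle sampler; all-singleton blocks give a process close
to the Zig-Zag sampler with Gaussian velocities.

### Event simulation by thinning

Events are generated by Poisson thinning.  For a lookahead `θ > 0`, each
block receives the worst-case window bound

    λ̄_B = max_{s ∈ [0, θ]} λ_B(x + s(φ⋆v), v) .

For quadratic potentials (the linear-Gaussian model) the directional
derivative is affine in `s`, so the bound is the exact maximum of the two
endpoint values.  Otherwise the maximum over a grid of `bound_grid` points
(default 16) is inflated by a safety factor (default 1.1).  A proposal time
is drawn from the constant sum `Σ_B λ̄_B`, a block is selected with
probability proportional to its bound (unsorted linear scan), and the
reflection is accepted with probability `λ_B(τ)/λ̄_B`.  A true rate found
above its bound raises a hard error — never a silent acceptance — and, for
declared-quadratic models, the acceptance-time rate is cross-checked
against the actual gradient so that a wrongly declared model is detected
rather than silently biased.  In audit mode every recomputed bound is also
checked at eight random interior points of its window.

Bound bookkeeping: windows form a fixed grid of length `θ`.  At expiry all
bounds are recomputed at the advanced position.  After an accepted
reflection in `B`, the recomputed set is every block whose column range,
expanded by the gradient's temporal reach (one column for Markovian
models), meets `B`'s columns.  This is a strict superset of the
rectangle-intersection neighbourhood `N(B)`: the gradient of a temporally
adjacent but non-overlapping block depends on the boundary column whose
velocity just changed, so recomputing `N(B)` alone would leave stale — and
therefore invalid — bounds.  Refreshment invalidates every bound.

The lookahead is tuned so the bounding process fires about once per window
(`tune_theta`, a pilot-run fixed point `θ ← pilot_time / #proposals`).  The
scaling is exactly `θ ∝ 1/rate` only when the window bound is dominated by
the instantaneous rate; when the growth term dominates, the exponent
approaches −1/2.

### Random-number discipline

One counter-based Philox stream per logical purpose (proposal times, block
selection, acceptance, refreshment times, refreshment values, audit),
spawned from a single seed.  Changing the blocking strategy therefore does
not scramble unrelated draws, trajectories are reproducible bit for bit,
and audit mode does not perturb the trajectory.

## Partitioned (even–odd / four-clock) variant

A partition splits the strategy into `K` sub-strategies of pairwise
disjoint blocks: alternating blocks of a temporal strategy (`K = 2`), or a
2×2 checkerboard over the grid cells of a spatiotemporal strategy
(`K = 4`), so that diagonal neighbours never share a colour.  Sub-strategy
`κ` carries the max-type window bound

    Λ̄_κ = max_{B ∈ B̄_κ} max_{s ∈ [0, θ]} λ_B(x + s(φ⋆v), v) ,

which under sub-exponential rate tails `P(λ_B > s) ≤ 2 e^{−2αs}` grows only
logarithmically: `E_π Λ̂_κ ≤ (2e/α) log|B̄_κ|`.  The package measures this
empirically (`max_rate_growth_check`) with exact posterior draws from the
Gaussian model and an `α` fitted to the pooled rate tail.

**Exactness of the event mechanism.**  The partitioned generator's jump
part is a sum over blocks: at any single event time exactly one block
reflects, with intensity `λ_B`.  A seemingly natural implementation — at a
`κ`-event let *every* block of the sub-strategy reflect independently with
probability `λ_B/Λ̄_κ` — reproduces each block's marginal intensity but
correlates reflections that share an event time; expanding the product
kernel shows the realized generator carries an extra second-order term
`Σ_{B<B'} λ_B λ_B' / Λ̄_κ` relative to the sum form.  With interacting
blocks this measurably perturbs the invariant law (on the `d=3, N=50`
Gaussian benchmark: a reproducible +5…11% inflation of singly-covered
coordinates' posterior variances).  The simulator therefore thins the sum
form exactly while keeping the max-type bound and the `K`-clock structure:
sub-strategy `κ` proposes at rate `|B̄_κ| · Λ̄_κ`, one block is drawn
uniformly, and it reflects with probability `λ_B/Λ̄_κ`.  The per-event work
that motivates the partition — one shared gradient evaluation and commuting
reflections of disjoint blocks — is unchanged, and the simultaneous
independent-acceptance kernel remains available as the pure function
`apply_partition_kernel`, whose result is bit-identical under any block
processing order (the parallel-update contract, enforced by test).

## Models

### Linear-Gaussian AR(1) with kernel autoregression

`x_n = A x_{n−1} + η_n`, `y_n = x_n + ε_n`, `η, ε ~ N(0, I_d)`,
`x_1 ~ N(0, I_d)`, and `A_ij = kern(i,j)/(ψ + Σ_l kern(i,l))` with the
squared-exponential kernel `kern(i,j) = exp(−|i−j|²/2σ²)`.  Rows of `A` sum
to less than one, so the process is stable; `σ²` controls spatial coupling
and `ψ` the overall persistence.  The potential is quadratic, enabling
exact endpoint rate bounds.  Exact oracles: a Kalman filter with
Rauch–Tung–Striebel backward pass, an independent dense precision-matrix
solve, and a dense-Cholesky joint posterior sampler.  The prior is placed
directly on the first state (`x_1 ~ N(0, I)`), a convention shared by
model, oracles and simulator.

### Heavy-tailed stochastic volatility with leverage

Log-volatilities follow `x_{n+1} = A x_n + η_n` with `A = diag(α)`;
returns are `y_n = γ_n^{−1/2} Λ_n ε_n` with `Λ_n = diag(exp(x_n/2))` and
`γ_n ~ Gamma(ν/2, ν/2)`, giving multivariate-t observation noise with `ν`
degrees of freedom.  `(η_n, ε_n)` are jointly Gaussian; a negative-definite
cross block `Σ_ρ` produces the leverage effect, feeding the realized return
innovation into the next state's mean through
`Σ_ρ Σ_ε^{−1} Λ_{n−1}^{−1} y^γ_{n−1}`.  Inference conditions on known
`γ_{1:N}` and uses the rescaled observations `y^γ_n = √γ_n · y_n`; an outer
Gibbs step for `γ` can be layered on top by the user but is not part of the
sampler.  The potential includes the state-dependent log-determinants
(`Σ_k x_n^k` per step).  The initial law is the stationary AR(1)
covariance `P₁,ij = Σ_η,ij/(1 − α_i α_j)`, the Lyapunov solution, which
reduces to `(I − AA)^{−1} Σ_η` when all `α_i` are equal (as in the
defaults).  Synthetic-demo defaults: `α_i = 0.9`,
`Σ_η = 0.1(0.3·11ᵀ + 0.7 I)`, `Σ_ε,ij = exp(−|i−j|/2)`, `Σ_ρ = −0.05 I`,
`ν = 10` — persistent, weakly coupled volatilities with mild leverage and
clearly heavy-tailed returns.

## Blocking conventions

External indices are 1-based inclusive (`i:j × l:m`), converted once to
0-based half-open slices.  Builders advance block starts by
`stride = width − overlap` per axis.  If aligned blocks fall short of the
boundary, the final block ends exactly at the boundary: at full width
(shifted start) when the axis overlaps, and truncated when the overlap is
zero — a full-width shifted block would overlap its predecessor and destroy
the disjointness that defines the factor/local sampler.  Block order is
row-major (spatial outer, temporal inner), which fixes the parity used by
the partition builders.  An end-anchored row or column whose offset from
the previous start is below the stride can intersect the same-parity cell
two steps back; `four_clock_partition` detects this and reports the
offending pair instead of returning an invalid partition.
`min_partition_size` combines a clique lower bound (the maximum of `φ`;
axis-aligned rectangles have the Helly property, so pairwise-intersecting
blocks share a grid point), a greedy colouring, and exhaustive backtracking
for at most 20 blocks; the result flags whether it is exact.

## Diagnostics

Trajectories are piecewise linear, so thinning on a `Δ`-grid (default 0.1
sampler seconds) is exact interpolation.  Default burn-in fraction is 25%.
Mean squared jumping distance is the average squared successive difference
of one coordinate after burn-in; under the block-augmented flow a doubly
covered coordinate moves twice as fast and its MSJD approaches four times
that of a singly covered one.  ESS uses the initial-positive-sequence
truncation of the autocorrelation sum, clipped to `(0, n]`, with a
batch-means estimator as a cross-check; constant chains report 0 with a
warning.  For comparing chain moments against exact oracles the test suite
uses overlapping-batch-means standard errors (batch length 1000 thinned
samples) with the squared SEs smoothed over a 9-column temporal window —
for these non-reversible samplers the autocorrelation of squared
coordinates can oscillate, which defeats initial-sequence truncation.

## Numerical and statistical choices

- Tie-breaking of simultaneous clocks (probability zero): refreshment,
  then proposal, then bound expiry; the horizon ends the trajectory.
- A zero block gradient at a proposed reflection is treated as rate zero
  (the acceptance probability is already zero); the explicit reflection
  operator raises on a zero gradient, since the involution is undefined.
- Bound tolerance for violation detection: relative `1e−9` plus `1e−12`
  absolute, covering floating-point drift between the affine rate
  prediction and the recomputed gradient.
- Refreshment rate default `γ = 0.1` events per sampler second.  For
  stationarity validation runs the suite uses `γ = 1`, comparable to the
  bounce-event scale: at `γ = 0.1` the velocity decorrelates two orders of
  magnitude slower than the bounce clock on the benchmark target, the
  dynamics become near-periodic, and second-moment Monte-Carlo error
  estimation is ill-conditioned (oscillatory, long-memory ACFs).
- Sampler validation scales: the oracle-comparison battery runs each
  sampler for 5000 sampler seconds on the `d=3, N=50` benchmark; the
  jumping-distance comparison uses `N=400` for 300 sampler seconds,
  averaged over five seeds.

## What the synthetic generators do and do not cover

The AR(1) generator produces exactly the Gaussian model the exact oracles
solve, so sampler/oracle agreement there validates the event machinery,
not model realism.  The SV generator produces heavy tails, volatility
clustering and leverage, but with known mixing variables, diagonal
homogeneous persistence and stationary parameters; real return panels add
parameter uncertainty, missing data and non-stationarity that are out of
scope (the package performs state inference only, never parameter
estimation).  Passing tests demonstrate correctness of the samplers on
differentiable targets of this structure, not forecasting performance on
market data.

## Known limitations

- Grid-estimated bounds for non-quadratic targets are heuristic; the
  safety factor trades rejected proposals against the (hard-failing) risk
  of an undetected rate excursion between grid points.
- The even–odd implementation executes sequentially; the order-independence
  contract makes per-block parallelism possible but no multi-process
  executor is included.
- Per-coordinate comparison of chain moments against an oracle at a fixed
  number of standard errors is an extreme-value test: with hundreds of
  coordinates the worst z-score of an exact sampler regularly exceeds 3.
  Aggregate error bounds are the robust alternative used throughout the
  per-module tests.
- `min_partition_size` is exact only up to 20 blocks unless the greedy
  colouring meets the clique bound.
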