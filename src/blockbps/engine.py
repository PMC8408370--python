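"""Event-driven core of the blocked bouncy particle sampler.

The sampler is a piecewise-deterministic Markov process on (x, v) in
M_{d,N} x M_{d,N}.  Positions follow the block-augmented linear flow
t -> x + t (phi * v) (Hadamard product: coordinates shared by several blocks
move proportionally faster); each block B carries an inhomogeneous Poisson
clock with rate lambda_B(x, v) = <grad_B U(x), v_B>_F^+ whose events reflect
the block's velocity submatrix in the hyperplane orthogonal to the block
gradient; a homogeneous clock with rate gamma refreshes the full velocity
from its standard-normal stationary law.  Event times are simulated by
Poisson thinning against piecewise-constant lookahead bounds recomputed
every ``theta`` sampler seconds.

For quadratic potentials the directional derivative is affine along the
flow, so the worst-case lookahead bound is the exact maximum over the window
endpoints; otherwise bounds are grid-estimated and inflated by a safety
factor, and any detected violation of a bound raises
:class:`~blockbps.errors.BoundViolationError` rather than biasing the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .blocking import BlockingStrategy, compute_phi
from .errors import (
    BoundViolationError,
    DegenerateReflectionError,
    ParameterError,
    ShapeError,
)
from .models import PotentialModel, as_state_matrix

__all__ = [
    "SamplerConfig",
    "TrajectorySkeleton",
    "RateBound",
    "block_rate",
    "reflect_block",
    "refresh_velocity",
    "rate_bound_on_window",
    "simulate_blocked_bps",
    "simulate_thinned_event_times",
    "tune_theta",
]

_REL_TOL = 1e-9  # slack when auditing true rate against its bound


@dataclass(frozen=True)
class SamplerConfig:
    """Run configuration shared by all samplers.

    gamma_refresh : velocity refreshment rate (events per sampler second).
    theta         : lookahead window length for rate bounds.
    horizon       : total sampler time T.
    seed          : master seed; every random stream derives from it.
    bound_safety  : multiplicative inflation of grid-estimated bounds;
                    ``None`` selects 1.0 for quadratic potentials (exact
                    endpoint bounds) and 1.1 otherwise.
    bound_grid    : evaluation points per lookahead window for non-quadratic
                    bounds.
    audit         : if True, every recomputed bound is additionally checked
                    against the true rate at 8 random interior points of its
                    window (test mode).
    """

    horizon: float
    gamma_refresh: float = 0.1
    theta: float = 0.1
    seed: int = 0
    bound_safety: float | None = None
    bound_grid: int = 16
    audit: bool = False

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ParameterError("horizon must be positive")
        if self.theta <= 0:
            raise ParameterError("theta must be positive")
        if self.gamma_refresh < 0:
            raise ParameterError("gamma_refresh must be >= 0")
        if self.bound_safety is not None and self.bound_safety < 1:
            raise ParameterError("bound_safety must be >= 1")
        if self.bound_grid < 2:
            raise ParameterError("bound_grid must be >= 2")


class _Streams:
    """One counter-based generator per logical purpose, so that changing the
    blocking strategy does not scramble unrelated random draws."""

    NAMES = ("proposal", "selection", "acceptance", "refresh_time",
             "refresh_value", "audit")

    def __init__(self, seed: int):
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(self.NAMES))
        for name, child in zip(self.NAMES, children):
            setattr(self, name, np.random.Generator(np.random.Philox(child)))


# event kind codes in the event log
EVENT_CODES = {0: "reflection", 1: "refreshment", 2: "bound-expiry",
               3: "proposal-rejected", 4: "partition-reflection"}


@dataclass
class TrajectorySkeleton:
    """Piecewise-linear trajectory in compact event form.

    Between velocity changes the position follows
    ``x(t) = x(t_prev) + (t - t_prev) * (phi * v)`` exactly.  Velocity
    changes are stored as deltas (reflections touch one block's submatrix;
    refreshments replace v); :meth:`segments` replays the exact path.
    """

    x0: np.ndarray
    v0: np.ndarray
    phi: np.ndarray
    horizon: float
    block_slices: tuple
    velocity_events: list = field(default_factory=list)
    log_times: list = field(default_factory=list)
    log_codes: list = field(default_factory=list)
    log_blocks: list = field(default_factory=list)
    counters: dict = field(default_factory=dict)
    final_x: np.ndarray | None = None
    final_v: np.ndarray | None = None

    # -- recording -----------------------------------------------------
    def log(self, t: float, code: int, block: int = -1) -> None:
        self.log_times.append(t)
        self.log_codes.append(code)
        self.log_blocks.append(block)

    def add_reflection(self, t: float, block: int, new_vB: np.ndarray) -> None:
        self.velocity_events.append((t, "reflect", block, new_vB))
        self.log(t, 0, block)

    def add_multi_reflection(self, t: float, updates: list) -> None:
        self.velocity_events.append((t, "multi", -1, updates))
        for b, _ in updates:
            self.log(t, 4, b)

    def add_refreshment(self, t: float, new_v: np.ndarray) -> None:
        self.velocity_events.append((t, "refresh", -1, new_v))
        self.log(t, 1)

    # -- replay --------------------------------------------------------
    def segments(self) -> Iterator[tuple[float, float, np.ndarray, np.ndarray]]:
        """Yield (t_start, t_end, x_at_start, velocity) for every linear piece.

        ``x_at_start`` is a live buffer; callers must copy if they keep it.
        """
        x = self.x0.astype(float).copy()
        v = self.v0.astype(float).copy()
        u = self.phi * v
        t = 0.0
        for te, kind, block, payload in self.velocity_events:
            yield t, te, x, u
            x += (te - t) * u
            t = te
            if kind == "reflect":
                sl = self.block_slices[block]
                v[sl] = payload
                u[sl] = self.phi[sl] * payload
            elif kind == "multi":
                for b, vB in payload:
                    sl = self.block_slices[b]
                    v[sl] = vB
                    u[sl] = self.phi[sl] * vB
            else:  # refresh
                v = payload.copy()
                u = self.phi * v
        yield t, self.horizon, x, u

    def final_position(self) -> np.ndarray:
        """Position at the horizon recomputed by exact replay."""
        for t0, t1, x, u in self.segments():
            pass
        return x + (t1 - t0) * u

    @property
    def n_events(self) -> int:
        return len(self.log_times)

    def event_log_frame(self):
        """Event log as a pandas DataFrame (time, kind, block)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time": np.asarray(self.log_times),
                "kind": [EVENT_CODES[c] for c in self.log_codes],
                "block": np.asarray(self.log_blocks, dtype=int),
            }
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def block_rate(
    model: PotentialModel,
    strategy: BlockingStrategy,
    x: np.ndarray,
    v: np.ndarray,
    block_index: int,
) -> float:
    """lambda_B(x, v) = <grad_B U(x), v_B>_F clipped at zero."""
    sl = strategy.blocks[block_index].slices
    g = model.grad(x)[sl]
    return max(float(np.vdot(g, v[sl])), 0.0)


def reflect_block(
    model: PotentialModel,
    strategy: BlockingStrategy,
    x: np.ndarray,
    v: np.ndarray,
    block_index: int,
) -> np.ndarray:
    """Reflect v_B in the hyperplane orthogonal to the block gradient.

    Only the block's submatrix changes; its Frobenius norm is preserved and
    the operation is an involution.  A vanishing block gradient makes the
    reflection undefined and raises :class:`DegenerateReflectionError`.
    """
    sl = strategy.blocks[block_index].slices
    g = model.grad(x)[sl]
    n2 = float(np.vdot(g, g))
    if n2 == 0.0:
        raise DegenerateReflectionError(
            f"zero gradient on block {block_index}; reflection undefined"
        )
    v_new = np.array(v, dtype=float, copy=True)
    v_new[sl] = v[sl] - (2.0 * float(np.vdot(g, v[sl])) / n2) * g
    return v_new


def refresh_velocity(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a fresh velocity with i.i.d. standard normal components."""
    return rng.standard_normal(np.shape(v))


@dataclass(frozen=True)
class RateBound:
    """Constant upper bound for one block's rate over a lookahead window."""

    block_index: int
    value: float
    valid_until: float


def _window_bound_quadratic(a: float, c: float, h: float) -> float:
    # rate along the flow is (a + s c)^+, affine in s: endpoint max is exact
    return max(a, a + h * c, 0.0)


def rate_bound_on_window(
    model: PotentialModel,
    strategy: BlockingStrategy,
    x: np.ndarray,
    v: np.ndarray,
    block_index: int,
    theta: float,
    *,
    bound_grid: int = 16,
    bound_safety: float | None = None,
    phi: np.ndarray | None = None,
) -> RateBound:
    """Worst-case lookahead bound max_{s in [0, theta]} lambda_B(x + s u, v).

    Exact (endpoint max) for quadratic potentials; otherwise the maximum over
    ``bound_grid`` equispaced points inflated by ``bound_safety``.
    """
    if phi is None:
        phi = compute_phi(strategy).astype(float)
    u = phi * np.asarray(v, dtype=float)
    sl = strategy.blocks[block_index].slices
    vB = np.asarray(v, dtype=float)[sl]
    if model.quadratic:
        a = float(np.vdot(model.grad(x)[sl], vB))
        c = float(np.vdot(model.grad_linear(u)[sl], vB))
        value = _window_bound_quadratic(a, c, theta)
    else:
        safety = 1.1 if bound_safety is None else bound_safety
        best = 0.0
        for s in np.linspace(0.0, theta, bound_grid):
            g = model.grad(x + s * u)[sl]
            best = max(best, float(np.vdot(g, vB)))
        value = safety * best
    return RateBound(block_index=block_index, value=value, valid_until=theta)


def invalidation_sets(
    strategy: BlockingStrategy, temporal_reach: int
) -> list[tuple[int, ...]]:
    """For each block B, the blocks whose rate bounds a reflection in B
    invalidates.

    A reflection changes velocities only inside B, but the gradient of
    another block depends on columns up to ``temporal_reach`` beyond its own
    temporal range (and, through dense spatial coupling, on every row of
    those columns).  The set therefore contains every block whose expanded
    column range meets B's columns — a superset of the rectangle-intersection
    neighbourhood N(B), which by itself would leave the bounds of temporally
    adjacent but non-overlapping blocks stale.
    """
    cols = [(b.col_start, b.col_stop) for b in strategy.blocks]
    out = []
    for l, m in cols:
        members = tuple(
            i
            for i, (l2, m2) in enumerate(cols)
            if l2 - temporal_reach <= m and l <= m2 + temporal_reach
        )
        out.append(members)
    return out


def simulate_thinned_event_times(
    rate_fn: Callable[[float], float],
    bound: float,
    horizon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thinning primitive: accepted event times of an inhomogeneous Poisson
    process with rate ``rate_fn`` dominated by the constant ``bound``.

    Proposals arrive at rate ``bound``; each is accepted with probability
    rate/bound.  A rate exceeding the bound raises
    :class:`BoundViolationError` (never silently accepted).
    """
    if bound <= 0:
        raise ParameterError("bound must be positive")
    t = 0.0
    out = []
    while True:
        t += rng.exponential(1.0 / bound)
        if t >= horizon:
            break
        lam = rate_fn(t)
        if lam > bound * (1.0 + _REL_TOL):
            raise BoundViolationError(
                f"rate {lam} exceeds thinning bound {bound} at t={t}"
            )
        if rng.random() * bound < lam:
            out.append(t)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# bound bookkeeping shared by the blocked and even-odd engines
# ---------------------------------------------------------------------------


class _BoundTable:
    """Per-block lookahead bounds with lazy position advancement.

    The position buffer ``x`` is the state at time ``t_base``; the current
    position is x + (t - t_base) u.  For quadratic models each block stores
    the affine coefficients (a, c) of its directional derivative so that
    true rates at proposal times are O(1).
    """

    def __init__(self, model, strategy, phi, config, streams):
        self.model = model
        self.strategy = strategy
        self.phi = phi
        self.config = config
        self.streams = streams
        self.quad = model.quadratic
        self.safety = (
            config.bound_safety
            if config.bound_safety is not None
            else (1.0 if self.quad else 1.1)
        )
        self.slices = tuple(b.slices for b in strategy.blocks)
        nb = len(strategy)
        self.a = np.zeros(nb)
        self.c = np.zeros(nb)
        self.t_ref = np.zeros(nb)
        self.bounds = np.zeros(nb)
        self.n_bound_recomputes = 0

    # position handling ------------------------------------------------
    def init_state(self, x0, v):
        self.x = np.array(x0, dtype=float, copy=True)
        self.t_base = 0.0
        self.v = v
        self.u = self.phi * v

    def advance_to(self, t: float) -> None:
        if t > self.t_base:
            self.x += (t - self.t_base) * self.u
            self.t_base = t

    def position_at(self, t: float) -> np.ndarray:
        return self.x + (t - self.t_base) * self.u

    def set_velocity(self, v: np.ndarray) -> None:
        self.v = v
        self.u = self.phi * v

    def update_block_velocity(self, block: int, new_vB: np.ndarray) -> None:
        sl = self.slices[block]
        self.v[sl] = new_vB
        self.u[sl] = self.phi[sl] * new_vB

    # bounds -----------------------------------------------------------
    def recompute(self, idxs: Sequence[int], now: float, win_end: float) -> None:
        """Recompute bounds for ``idxs`` valid on [now, win_end]."""
        self.advance_to(now)
        h = max(win_end - now, 0.0)
        g0 = self.model.grad(self.x)
        if self.quad:
            gu = self.model.grad_linear(self.u)
            for b in idxs:
                sl = self.slices[b]
                vB = self.v[sl]
                a = float(np.vdot(g0[sl], vB))
                c = float(np.vdot(gu[sl], vB))
                self.a[b] = a
                self.c[b] = c
                self.t_ref[b] = now
                self.bounds[b] = _window_bound_quadratic(a, c, h)
            if self.config.audit and h > 0:
                self._audit(idxs, now, h)
        else:
            grid = np.linspace(0.0, h, self.config.bound_grid)
            best = np.zeros(len(idxs))
            for s in grid:
                g = g0 if s == 0.0 else self.model.grad(self.x + s * self.u)
                for j, b in enumerate(idxs):
                    sl = self.slices[b]
                    val = float(np.vdot(g[sl], self.v[sl]))
                    if val > best[j]:
                        best[j] = val
            for j, b in enumerate(idxs):
                self.t_ref[b] = now
                self.bounds[b] = self.safety * max(best[j], 0.0)
            if self.config.audit and h > 0:
                self._audit(idxs, now, h)
        self.n_bound_recomputes += len(idxs)

    def _audit(self, idxs, now, h) -> None:
        for s in self.streams.audit.random(8) * h:
            g = self.model.grad(self.x + s * self.u)
            for b in idxs:
                sl = self.slices[b]
                lam = max(float(np.vdot(g[sl], self.v[sl])), 0.0)
                if lam > self.bounds[b] * (1.0 + _REL_TOL) + 1e-12:
                    raise BoundViolationError(
                        f"audit: rate {lam} of block {b} exceeds its bound "
                        f"{self.bounds[b]} at t={now + s}"
                    )

    def true_rate(self, b: int, t: float) -> float:
        if self.quad:
            return max(self.a[b] + (t - self.t_ref[b]) * self.c[b], 0.0)
        g = self.model.grad(self.position_at(t))
        sl = self.slices[b]
        return max(float(np.vdot(g[sl], self.v[sl])), 0.0)

    def check_bound(self, b: int, lam: float, t: float) -> None:
        if lam > self.bounds[b] * (1.0 + _REL_TOL) + 1e-12:
            raise BoundViolationError(
                f"true rate {lam} of block {b} exceeds its bound "
                f"{self.bounds[b]} (window starting {self.t_ref[b]}) at t={t}"
            )

    def block_gradient(self, b: int, t: float) -> np.ndarray:
        return self.model.grad(self.position_at(t))[self.slices[b]]


# ---------------------------------------------------------------------------
# the blocked sampler
# ---------------------------------------------------------------------------


def _prepare_run(model, strategy, config, x0, v0):
    if strategy.d != model.d or strategy.N != model.N:
        raise ShapeError(
            f"strategy grid {strategy.d} x {strategy.N} does not match model "
            f"{model.d} x {model.N}"
        )
    x0 = as_state_matrix(x0, model.d, model.N)
    streams = _Streams(config.seed)
    phi = compute_phi(strategy).astype(float)
    if v0 is None:
        v = streams.refresh_value.standard_normal((model.d, model.N))
    else:
        v = as_state_matrix(v0, model.d, model.N).copy()
    return x0, v, phi, streams


def simulate_blocked_bps(
    model: PotentialModel,
    strategy: BlockingStrategy,
    config: SamplerConfig,
    x0: np.ndarray,
    v0: np.ndarray | None = None,
) -> TrajectorySkeleton:
    """Run the blocked bouncy particle sampler until the horizon.

    Events are generated by thinning against per-block lookahead bounds: a
    proposal time is drawn from the sum bound, a block is selected with
    probability proportional to its bound, and the reflection is accepted
    with probability true-rate / bound.  Accepted reflections invalidate the
    bounds of dependent blocks only; expired windows are recomputed at the
    advanced position; refreshments resample the full velocity and
    invalidate every bound.  Deterministic given ``config.seed``.
    """
    x0, v, phi, streams = _prepare_run(model, strategy, config, x0, v0)
    nb = len(strategy)
    all_blocks = tuple(range(nb))
    invalid = invalidation_sets(strategy, model.grad_temporal_reach)
    table = _BoundTable(model, strategy, phi, config, streams)
    table.init_state(x0, v)

    skel = TrajectorySkeleton(
        x0=x0.copy(), v0=v.copy(), phi=phi, horizon=config.horizon,
        block_slices=table.slices,
    )
    counters = {
        "proposals": 0, "reflections": 0, "refreshments": 0,
        "windows": 0, "bound_recomputes": 0,
    }

    T = config.horizon
    theta = config.theta
    gamma = config.gamma_refresh
    t = 0.0
    next_refresh = (
        streams.refresh_time.exponential(1.0 / gamma) if gamma > 0 else np.inf
    )
    table.recompute(all_blocks, 0.0, theta)
    counters["windows"] += 1
    win_end = theta

    while True:
        total = float(table.bounds.sum())
        tau_prop = (
            t + streams.proposal.exponential(1.0 / total) if total > 0 else np.inf
        )
        # event ordering at ties: horizon, then refresh < proposal < expiry
        t_next = min(next_refresh, tau_prop, win_end, T)
        if t_next >= T:
            break
        if next_refresh == t_next:
            t = next_refresh
            new_v = streams.refresh_value.standard_normal(v.shape)
            table.advance_to(t)
            table.set_velocity(new_v)
            v = new_v
            skel.add_refreshment(t, new_v.copy())
            counters["refreshments"] += 1
            table.recompute(all_blocks, t, win_end)
            next_refresh = t + streams.refresh_time.exponential(1.0 / gamma)
        elif tau_prop == t_next:
            t = tau_prop
            counters["proposals"] += 1
            if nb > 1:
                r = streams.selection.random() * total
                b = int(np.searchsorted(np.cumsum(table.bounds), r))
                b = min(b, nb - 1)
            else:
                b = 0
            lam = table.true_rate(b, t)
            table.check_bound(b, lam, t)
            u_acc = streams.acceptance.random()
            if table.bounds[b] > 0 and u_acc * table.bounds[b] < lam:
                table.advance_to(t)
                g = table.block_gradient(b, t)
                sl = table.slices[b]
                # cross-check the bound against the actual gradient (catches
                # models whose declared quadratic structure is wrong)
                table.check_bound(b, float(np.vdot(g, v[sl])), t)
                n2 = float(np.vdot(g, g))
                if n2 > 0.0:
                    new_vB = v[sl] - (2.0 * float(np.vdot(g, v[sl])) / n2) * g
                    table.update_block_velocity(b, new_vB)
                    skel.add_reflection(t, b, new_vB.copy())
                    counters["reflections"] += 1
                    table.recompute(invalid[b], t, win_end)
                # zero block gradient: the rate was 0, treat as no event
            else:
                skel.log(t, 3, b)
        else:  # bound expiry
            t = win_end
            win_end = t + theta
            table.recompute(all_blocks, t, win_end)
            counters["windows"] += 1

    table.advance_to(T)
    counters["bound_recomputes"] = table.n_bound_recomputes
    skel.counters = counters
    skel.final_x = table.x.copy()
    skel.final_v = v.copy()
    return skel


def tune_theta(
    model: PotentialModel,
    strategy: BlockingStrategy,
    config: SamplerConfig,
    pilot_time: float,
    x0: np.ndarray | None = None,
    n_iter: int = 3,
) -> float:
    """Choose the lookahead so the bounding process fires about once per
    window (pilot-run fixed point of theta = 1 / proposal rate).

    Used as a default only; callers may override theta directly.
    """
    if pilot_time <= 0:
        raise ParameterError("pilot_time must be positive")
    if x0 is None:
        x0 = np.zeros((model.d, model.N))
    theta = config.theta
    for _ in range(n_iter):
        cfg = replace(config, horizon=pilot_time, theta=theta)
        skel = simulate_blocked_bps(model, strategy, cfg, x0)
        n_prop = skel.counters["proposals"]
        if n_prop == 0:
            warnings.warn(
                "pilot run generated no proposal events; keeping the "
                "configured theta",
                RuntimeWarning,
            )
            return config.theta
        theta = pilot_time / n_prop
    return theta
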