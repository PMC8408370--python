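"""Independent reference implementations used as test oracles.

These deliberately avoid the package's engine internals: the single-block
sampler below is a direct transcription of the bouncy-particle recipe for a
quadratic potential, and the no-leverage stochastic-volatility potential is
coded from the factorized density, term by term.
"""

from __future__ import annotations

import math

import numpy as np

from blockbps.engine import _Streams


def reference_single_block_bps(model, config, x0, v0):
    """Plain single-block BPS for a quadratic potential.

    Mirrors the engine's random-stream discipline (one generator per
    purpose, identical draw order) so that trajectories can be compared
    event for event under the same seed.  Returns (event list, final x)
    with events as (time, kind) tuples, kind in {"reflect", "refresh"}.
    """
    streams = _Streams(config.seed)
    x = np.array(x0, dtype=float)
    v = np.array(v0, dtype=float)
    T, theta, gamma = config.horizon, config.theta, config.gamma_refresh
    t = 0.0
    next_refresh = (
        streams.refresh_time.exponential(1.0 / gamma) if gamma > 0 else np.inf
    )
    events = []

    def affine_coeffs():
        a = float(np.vdot(model.grad(x), v))
        c = float(np.vdot(model.grad_linear(v), v))
        return a, c

    a, c = affine_coeffs()
    t_ref = 0.0
    win_end = theta
    bound = max(a, a + (win_end - t_ref) * c, 0.0)

    while True:
        tau = t + streams.proposal.exponential(1.0 / bound) if bound > 0 else np.inf
        t_next = min(next_refresh, tau, win_end, T)
        if t_next >= T:
            break
        if next_refresh == t_next:
            t = next_refresh
            x = x + (t - t_ref) * v
            v = streams.refresh_value.standard_normal(v.shape)
            events.append((t, "refresh"))
            a, c = affine_coeffs()
            t_ref = t
            bound = max(a, a + (win_end - t_ref) * c, 0.0)
            next_refresh = t + streams.refresh_time.exponential(1.0 / gamma)
        elif tau == t_next:
            t = tau
            lam = max(a + (t - t_ref) * c, 0.0)
            u_acc = streams.acceptance.random()
            if bound > 0 and u_acc * bound < lam:
                x = x + (t - t_ref) * v
                g = model.grad(x)
                n2 = float(np.vdot(g, g))
                v = v - (2.0 * float(np.vdot(g, v)) / n2) * g
                events.append((t, "reflect"))
                a, c = affine_coeffs()
                t_ref = t
                bound = max(a, a + (win_end - t_ref) * c, 0.0)
        else:
            t = win_end
            x = x + (t - t_ref) * v
            win_end = t + theta
            a, c = affine_coeffs()
            t_ref = t
            bound = max(a, a + (win_end - t_ref) * c, 0.0)

    x = x + (T - t_ref) * v
    return events, x


def no_leverage_sv_potential(params, data, x):
    """SV potential for Sigma_rho = 0, written from the factorized density:
    independent AR(1) transitions plus scaled-Gaussian observations."""
    d, N = params.d, params.N
    alpha = params.alpha
    Se = params.Sigma_eps
    Sh = params.Sigma_eta
    Se_inv = np.linalg.inv(Se)
    Sh_inv = np.linalg.inv(Sh)
    P1 = Sh / (1.0 - alpha[:, None] * alpha[None, :])
    out = 0.0
    # initial state
    out += 0.5 * float(x[:, 0] @ np.linalg.solve(P1, x[:, 0]))
    out += 0.5 * (math.log(np.linalg.det(P1)) + d * math.log(2 * math.pi))
    # transitions
    for n in range(1, N):
        r = x[:, n] - alpha * x[:, n - 1]
        out += 0.5 * float(r @ Sh_inv @ r)
        out += 0.5 * (math.log(np.linalg.det(Sh)) + d * math.log(2 * math.pi))
    # observations of y^gamma with covariance Lambda Sigma_eps Lambda
    for n in range(N):
        lam = np.exp(0.5 * x[:, n])
        z = data.y_gamma[:, n] / lam
        out += 0.5 * float(z @ Se_inv @ z)
        out += 0.5 * (
            math.log(np.linalg.det(Se)) + float(x[:, n].sum()) + d * math.log(2 * math.pi)
        )
    return out


def brute_force_phi(strategy):
    """Per-coordinate membership scan, one grid point at a time."""
    phi = np.zeros((strategy.d, strategy.N), dtype=int)
    for k in range(1, strategy.d + 1):
        for n in range(1, strategy.N + 1):
            phi[k - 1, n - 1] = sum(b.contains(k, n) for b in strategy.blocks)
    return phi


def naive_block_rate(model, strategy, x, v, block_index):
    """Entrywise double-loop rate computation."""
    b = strategy.blocks[block_index]
    g = model.grad(x)
    total = 0.0
    for a_ in range(b.row_start - 1, b.row_stop):
        for c_ in range(b.col_start - 1, b.col_stop):
            total += g[a_, c_] * v[a_, c_]
    return max(total, 0.0)
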