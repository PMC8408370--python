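import math
import warnings

import numpy as np
import pytest

import blockbps as bb
from blockbps.engine import invalidation_sets
from blockbps.errors import (
    BoundViolationError,
    DegenerateReflectionError,
    ParameterError,
)

from _reference import naive_block_rate, reference_single_block_bps
from conftest import obm_se


class ZeroGradientModel(bb.PotentialModel):
    """Constant potential: flat target, no reflections ever."""

    quadratic = True

    def __init__(self, d, N):
        self.d, self.N = d, N

    def potential(self, x):
        return 0.0

    def grad(self, x):
        return np.zeros((self.d, self.N))

    def grad_linear(self, w):
        return np.zeros((self.d, self.N))


class ScaledModel(bb.PotentialModel):
    """c * U for an underlying model; rates scale by c."""

    def __init__(self, base, c):
        self.base, self.c = base, c
        self.d, self.N = base.d, base.N
        self.quadratic = base.quadratic

    def potential(self, x):
        return self.c * self.base.potential(x)

    def grad(self, x):
        return self.c * self.base.grad(x)

    def grad_linear(self, w):
        return self.c * self.base.grad_linear(w)


class LyingQuadraticModel(bb.PotentialModel):
    """Declares a quadratic rate evolution but its gradient is not affine:
    the engine's endpoint bounds are wrong, which must be detected."""

    quadratic = True

    def __init__(self, inner):
        self.inner = inner
        self.d, self.N = inner.d, inner.N

    def potential(self, x):
        return self.inner.potential(x)

    def grad(self, x):
        return self.inner.grad(x)

    def grad_linear(self, w):
        return np.zeros((self.d, self.N))  # pretends rates are constant


class TestBlockRate:
    def test_matches_naive_loop(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.standard_normal((2, 20))
            v = rng.standard_normal((2, 20))
            for b in range(len(strat)):
                got = bb.block_rate(lgssm_2x20.model, strat, x, v, b)
                assert got == pytest.approx(
                    naive_block_rate(lgssm_2x20.model, strat, x, v, b),
                    abs=1e-12,
                )

    def test_descent_direction_has_zero_rate(self, lgssm_2x20):
        strat = bb.trivial_strategy(2, 20)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 20))
        v = -lgssm_2x20.model.grad(x)
        assert bb.block_rate(lgssm_2x20.model, strat, x, v, 0) == 0.0

    def test_isotropic_quadratic_rate_is_squared_norm(self):
        # U = ||x||_F^2 / 2 realized as d=2, N=1 prior-only with y = x scale:
        class Iso(bb.PotentialModel):
            quadratic = True
            d, N = 2, 3

            def potential(self, x):
                return 0.5 * float((x * x).sum())

            def grad(self, x):
                return x

            def grad_linear(self, w):
                return w

        strat = bb.trivial_strategy(2, 3)
        rng = np.random.default_rng(2)
        v = rng.standard_normal((2, 3))
        rate = bb.block_rate(Iso(), strat, v.copy(), v, 0)
        assert rate == pytest.approx(float((v * v).sum()), rel=1e-12)


class TestReflection:
    def test_parallel_velocity_flips(self, lgssm_2x20):
        strat = bb.trivial_strategy(2, 20)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 20))
        g = lgssm_2x20.model.grad(x)
        v = 1.7 * g
        out = bb.reflect_block(lgssm_2x20.model, strat, x, v, 0)
        assert np.allclose(out, -v, atol=1e-12)

    def test_orthogonal_velocity_unchanged(self, lgssm_2x20):
        strat = bb.trivial_strategy(2, 20)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 20))
        g = lgssm_2x20.model.grad(x)
        v = rng.standard_normal((2, 20))
        v -= g * float(np.vdot(g, v) / np.vdot(g, g))
        out = bb.reflect_block(lgssm_2x20.model, strat, x, v, 0)
        assert np.allclose(out, v, atol=1e-10)

    def test_inner_product_negated_norm_kept_involution(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        rng = np.random.default_rng(5)
        model = lgssm_2x20.model
        for _ in range(50):
            x = rng.standard_normal((2, 20))
            v = rng.standard_normal((2, 20))
            b = int(rng.integers(len(strat)))
            sl = strat.blocks[b].slices
            g = model.grad(x)[sl]
            out = bb.reflect_block(model, strat, x, v, b)
            # untouched outside the block
            mask = np.ones((2, 20), dtype=bool)
            mask[sl] = False
            assert np.array_equal(out[mask], v[mask])
            assert float(np.vdot(g, out[sl])) == pytest.approx(
                -float(np.vdot(g, v[sl])), rel=1e-9, abs=1e-9
            )
            assert np.linalg.norm(out[sl]) == pytest.approx(
                np.linalg.norm(v[sl]), abs=1e-10
            )
            twice = bb.reflect_block(model, strat, x, out, b)
            assert np.abs(twice - v).max() < 1e-10

    def test_zero_gradient_raises(self):
        model = ZeroGradientModel(2, 4)
        strat = bb.trivial_strategy(2, 4)
        with pytest.raises(DegenerateReflectionError):
            bb.reflect_block(model, strat, np.zeros((2, 4)), np.ones((2, 4)), 0)


class TestRefreshVelocity:
    def test_moments_and_independence(self):
        rng = np.random.default_rng(6)
        v = bb.refresh_velocity(np.zeros((2, 50_000)), rng)
        flat = v.ravel()
        n = flat.size
        assert abs(flat.mean()) < 3 / math.sqrt(n)
        assert abs(flat.var() - 1) < 3 * math.sqrt(2 / n)
        corr = np.corrcoef(v[0], v[1])[0, 1]
        assert abs(corr) < 3 / math.sqrt(v.shape[1])

    def test_seeded_reproducibility(self):
        a = bb.refresh_velocity(np.zeros((3, 4)), np.random.default_rng(9))
        b = bb.refresh_velocity(np.zeros((3, 4)), np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestRateBounds:
    def test_quadratic_endpoint_bound_matches_dense_scan(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        rng = np.random.default_rng(7)
        phi = bb.compute_phi(strat).astype(float)
        model = lgssm_2x20.model
        for trial in range(5):
            x = rng.standard_normal((2, 20))
            v = rng.standard_normal((2, 20))
            u = phi * v
            theta = 0.7
            for b in range(len(strat)):
                rb = bb.rate_bound_on_window(model, strat, x, v, b, theta, phi=phi)
                sl = strat.blocks[b].slices
                grid = np.linspace(0, theta, 10_000)
                vals = [
                    float(np.vdot(model.grad(x + s * u)[sl], v[sl])) for s in grid
                ]
                dense = max(0.0, max(vals))
                assert rb.value >= dense - 1e-9
                assert rb.value == pytest.approx(dense, rel=1e-6, abs=1e-9)

    def test_zero_velocity_gives_zero_bound(self, lgssm_2x20):
        strat = bb.trivial_strategy(2, 20)
        x = np.zeros((2, 20))
        rb = bb.rate_bound_on_window(lgssm_2x20.model, strat, x, x, 0, 0.5)
        assert rb.value == 0.0

    def test_sv_grid_bound_dominates_random_audit(self):
        params = bb.default_sv_params(2, 10)
        _, data = bb.simulate_sv(params, 0)
        model = bb.StochasticVolatilitySSM(params, data)
        strat = bb.make_temporal_strategy(2, 10, 5, 2)
        phi = bb.compute_phi(strat).astype(float)
        rng = np.random.default_rng(8)
        x = 0.3 * rng.standard_normal((2, 10))
        v = rng.standard_normal((2, 10))
        u = phi * v
        theta = 0.2
        for b in range(len(strat)):
            rb = bb.rate_bound_on_window(
                model, strat, x, v, b, theta, bound_safety=1.1, phi=phi
            )
            sl = strat.blocks[b].slices
            for s in rng.random(1000) * theta:
                lam = max(float(np.vdot(model.grad(x + s * u)[sl], v[sl])), 0.0)
                assert lam <= rb.value + 1e-9


class TestBlockedSampler:
    def test_single_gaussian_moment_check(self):
        # d=1, N=1 with y=0: posterior N(0, 1/2)
        p = bb.LGSSMParams(d=1, N=1, sigma2=1.0, psi=0.5)
        model = bb.LinearGaussianSSM(p, np.zeros((1, 1)))
        cfg = bb.SamplerConfig(horizon=5000.0, theta=0.5, gamma_refresh=1.0, seed=0)
        skel = bb.simulate_global_bps(model, cfg, np.zeros((1, 1)))
        s = bb.discretize_trajectory(skel, 0.1).burn(0.1).samples[:, 0, 0]
        se_m = obm_se(s, 500)
        se_v = obm_se((s - s.mean()) ** 2, 500)
        assert abs(s.mean()) < 3 * se_m
        assert abs(s.var(ddof=1) - 0.5) < 3 * se_v

    def test_matches_independent_reference_implementation(self):
        p = bb.LGSSMParams(d=2, N=6, sigma2=5.0, psi=0.1)
        rng = np.random.default_rng(10)
        y = rng.standard_normal((2, 6))
        model = bb.LinearGaussianSSM(p, y)
        cfg = bb.SamplerConfig(horizon=50.0, theta=0.2, gamma_refresh=0.5, seed=3)
        x0 = rng.standard_normal((2, 6))
        v0 = rng.standard_normal((2, 6))
        skel = bb.simulate_global_bps(model, cfg, x0, v0)
        ref_events, ref_x = reference_single_block_bps(model, cfg, x0, v0)
        got = [(t, k) for t, k, _, _ in skel.velocity_events]
        assert len(got) == len(ref_events)
        for (t1, k1), (t2, k2) in zip(got, ref_events):
            assert k1 == {"reflect": "reflect", "refresh": "refresh"}[k2]
            assert t1 == pytest.approx(t2, abs=1e-12)
        assert np.abs(skel.final_x - ref_x).max() < 1e-10

    def test_zigzag_limit_targets_correct_marginals(self):
        # all blocks of size one: componentwise velocity flips
        p = bb.LGSSMParams(d=2, N=1, sigma2=1.0, psi=0.5)
        y = np.array([[0.8], [-0.4]])
        model = bb.LinearGaussianSSM(p, y)
        blocks = tuple(bb.Block(k, k, 1, 1) for k in (1, 2))
        strat = bb.BlockingStrategy(d=2, N=1, blocks=blocks)
        cfg = bb.SamplerConfig(horizon=3000.0, theta=0.5, gamma_refresh=0.5, seed=1)
        skel = bb.simulate_blocked_bps(model, strat, cfg, np.zeros((2, 1)))
        c = bb.discretize_trajectory(skel, 0.1).burn(0.1)
        for k in range(2):
            s = c.samples[:, k, 0]
            assert abs(s.mean() - y[k, 0] / 2) < 3 * obm_se(s, 500)
            sq = (s - s.mean()) ** 2
            assert abs(s.var(ddof=1) - 0.5) < 3.5 * obm_se(sq, 500)

    def test_trajectory_replay_consistency(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        cfg = bb.SamplerConfig(horizon=100.0, theta=0.1, seed=4)
        skel = bb.simulate_blocked_bps(lgssm_2x20.model, strat, cfg, np.zeros((2, 20)))
        assert skel.counters["reflections"] > 50
        assert np.abs(skel.final_position() - skel.final_x).max() < 1e-9

    def test_speed_preserved_at_every_reflection(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        cfg = bb.SamplerConfig(horizon=50.0, theta=0.1, seed=5)
        skel = bb.simulate_blocked_bps(lgssm_2x20.model, strat, cfg, np.zeros((2, 20)))
        v = skel.v0.copy()
        slices = skel.block_slices
        n_checked = 0
        for t, kind, block, payload in skel.velocity_events:
            if kind == "reflect":
                before = np.linalg.norm(v[slices[block]])
                after = np.linalg.norm(payload)
                assert after == pytest.approx(before, abs=1e-10)
                v[slices[block]] = payload
                n_checked += 1
            elif kind == "refresh":
                v = payload.copy()
        assert n_checked > 20

    def test_phi_speedup_of_shared_coordinates(self):
        # flat potential, no refreshment: pure deterministic flow x0 + T phi*v
        model = ZeroGradientModel(1, 30)
        strat = bb.make_temporal_strategy(1, 30, 10, 5)
        phi = bb.compute_phi(strat).astype(float)
        cfg = bb.SamplerConfig(horizon=7.0, theta=0.5, gamma_refresh=0.0, seed=0)
        v0 = np.ones((1, 30))
        skel = bb.simulate_blocked_bps(model, strat, cfg, np.zeros((1, 30)), v0)
        assert np.allclose(skel.final_x, 7.0 * phi, atol=1e-12)
        assert skel.counters["reflections"] == 0
        # phi=2 coordinates travel exactly twice as far per unit time
        assert skel.final_x[0, 12] == pytest.approx(2 * skel.final_x[0, 2])

    def test_bound_violation_is_a_hard_error(self):
        p = bb.LGSSMParams(d=2, N=10, sigma2=5.0, psi=0.1)
        rng = np.random.default_rng(11)
        y = rng.standard_normal((2, 10))
        model = LyingQuadraticModel(bb.LinearGaussianSSM(p, y))
        strat = bb.make_temporal_strategy(2, 10, 5, 2)
        cfg = bb.SamplerConfig(horizon=200.0, theta=0.5, seed=0)
        with pytest.raises(BoundViolationError):
            bb.simulate_blocked_bps(model, strat, cfg, np.zeros((2, 10)))

    def test_stationarity_on_spatiotemporal_strategy(self, lgssm_3x50):
        strat = bb.make_spatiotemporal_strategy(3, 50, 2, 20, 1, 10)
        cfg = bb.SamplerConfig(horizon=1500.0, theta=0.05, gamma_refresh=1.0, seed=0)
        skel = bb.simulate_blocked_bps(lgssm_3x50.model, strat, cfg, np.zeros((3, 50)))
        c = bb.discretize_trajectory(skel, 0.1).burn(0.25)
        err = np.abs(c.samples.mean(axis=0) - lgssm_3x50.means)
        # robust aggregate check: posterior sds are ~0.7, MC error ~0.02
        assert err.mean() < 0.05
        assert err.max() < 0.2
        rel_var = (
            c.samples.var(axis=0, ddof=1) - lgssm_3x50.marginal_var
        ) / lgssm_3x50.marginal_var
        assert abs(rel_var.mean()) < 0.05
        assert np.abs(rel_var).max() < 0.35

    def test_audit_mode_runs_clean_on_sv_model(self):
        params = bb.default_sv_params(2, 15)
        _, data = bb.simulate_sv(params, 5)
        model = bb.StochasticVolatilitySSM(params, data)
        strat = bb.make_temporal_strategy(2, 15, 6, 3)
        cfg = bb.SamplerConfig(
            horizon=30.0, theta=0.05, seed=0, bound_safety=1.3, audit=True
        )
        skel = bb.simulate_blocked_bps(model, strat, cfg, np.zeros((2, 15)))
        assert skel.counters["reflections"] > 0

    def test_deterministic_given_seed(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        cfg = bb.SamplerConfig(horizon=20.0, theta=0.1, seed=7)
        a = bb.simulate_blocked_bps(lgssm_2x20.model, strat, cfg, np.zeros((2, 20)))
        b = bb.simulate_blocked_bps(lgssm_2x20.model, strat, cfg, np.zeros((2, 20)))
        assert a.log_times == b.log_times
        assert np.array_equal(a.final_x, b.final_x)


class TestInvalidationSets:
    def test_contains_neighbourhood_and_column_reach_rule(self):
        strat = bb.make_temporal_strategy(2, 100, 20, 10)
        sets = invalidation_sets(strat, temporal_reach=1)
        cols = [(blk.col_start, blk.col_stop) for blk in strat.blocks]
        for b in range(len(strat)):
            # every rectangle-intersection neighbour is invalidated ...
            assert set(sets[b]) >= set(bb.neighbors(strat, b))
            # ... plus exactly the blocks within one column of gradient reach
            expected = {
                i for i, (l, m) in enumerate(cols)
                if l - 1 <= cols[b][1] and cols[b][0] <= m + 1
            }
            assert set(sets[b]) == expected

    def test_zero_overlap_includes_adjacent_blocks(self):
        strat = bb.make_temporal_strategy(2, 100, 20, 0)
        sets = invalidation_sets(strat, temporal_reach=1)
        assert set(sets[2]) == {1, 2, 3}
        assert set(sets[0]) == {0, 1}


class TestThinningPrimitive:
    def test_event_count_near_expectation(self):
        rng = np.random.default_rng(12)
        times = bb.simulate_thinned_event_times(lambda t: 2.0, 4.0, 1000.0, rng)
        assert abs(len(times) - 2000) < 4 * math.sqrt(2000)

    def test_rate_above_bound_raises(self):
        rng = np.random.default_rng(13)
        with pytest.raises(BoundViolationError):
            bb.simulate_thinned_event_times(lambda t: 5.0, 4.0, 100.0, rng)


class TestTuneTheta:
    def test_scale_equivariance(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        cfg = bb.SamplerConfig(horizon=1.0, theta=0.1, seed=0)
        t1 = bb.tune_theta(lgssm_2x20.model, strat, cfg, pilot_time=60.0)
        t2 = bb.tune_theta(ScaledModel(lgssm_2x20.model, 4.0), strat, cfg,
                           pilot_time=60.0)
        # scaling U by c scales every rate by c; the one-event-per-window
        # fixed point then shrinks theta by a factor between 1/c (window
        # bound dominated by the instantaneous rate) and 1/sqrt(c) (bound
        # dominated by the growth of the rate along the lookahead)
        assert t2 < t1
        assert 1 / 4 * 0.8 < t2 / t1 < 0.55

    def test_tuned_theta_yields_about_one_event_per_window(self, lgssm_2x20):
        strat = bb.make_temporal_strategy(2, 20, 8, 4)
        cfg = bb.SamplerConfig(horizon=1.0, theta=0.1, seed=0)
        theta = bb.tune_theta(lgssm_2x20.model, strat, cfg, pilot_time=100.0)
        run_cfg = bb.SamplerConfig(horizon=200.0, theta=theta, seed=1)
        skel = bb.simulate_blocked_bps(
            lgssm_2x20.model, strat, run_cfg, np.zeros((2, 20))
        )
        per_window = skel.counters["proposals"] / (200.0 / theta)
        assert 0.5 < per_window < 2.0

    def test_flat_potential_warns_and_keeps_default(self):
        model = ZeroGradientModel(2, 10)
        strat = bb.make_temporal_strategy(2, 10, 5, 0)
        cfg = bb.SamplerConfig(horizon=1.0, theta=0.25, gamma_refresh=0.0, seed=0)
        with pytest.warns(RuntimeWarning):
            theta = bb.tune_theta(model, strat, cfg, pilot_time=5.0)
        assert theta == 0.25

    def test_invalid_pilot_time(self, lgssm_2x20):
        strat = bb.trivial_strategy(2, 20)
        cfg = bb.SamplerConfig(horizon=1.0, theta=0.1, seed=0)
        with pytest.raises(ParameterError):
            bb.tune_theta(lgssm_2x20.model, strat, cfg, pilot_time=0.0)
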