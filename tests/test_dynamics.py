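import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimeranet import LayeredNetwork
from chimeranet.dynamics import (
    FHNParameters,
    InstabilityError,
    SystemState,
    coupling_matrix,
    derivatives,
    integrate,
    random_initial_conditions,
)


def two_node_net():
    """One node per layer, a single inter-link."""
    z = np.zeros((1, 1), dtype=np.int8)
    return LayeredNetwork(z, z.copy(), np.ones((1, 1), dtype=np.int8))


class TestCouplingMatrix:
    def test_identity_at_zero(self):
        assert np.allclose(coupling_matrix(0.0), np.eye(2))

    def test_quarter_rotation(self):
        assert np.allclose(
            coupling_matrix(np.pi / 2), [[0, 1], [-1, 0]], atol=1e-15
        )

    def test_near_quarter_rotation_values(self):
        d = coupling_matrix(np.pi / 2 - 0.1)
        assert d[0, 0] == pytest.approx(0.09983, abs=1e-5)
        assert d[0, 1] == pytest.approx(0.99500, abs=1e-5)
        assert d[1, 0] == pytest.approx(-0.99500, abs=1e-5)
        assert d[1, 1] == pytest.approx(0.09983, abs=1e-5)

    @settings(deadline=None)
    @given(st.floats(-10, 10, allow_nan=False))
    def test_rotation_properties(self, alpha):
        d = coupling_matrix(alpha)
        assert np.allclose(d @ coupling_matrix(-alpha), np.eye(2), atol=1e-12)
        assert np.linalg.det(d) == pytest.approx(1.0)


class TestParameters:
    def test_alpha_normalized(self):
        p = FHNParameters(alpha=3 * np.pi)
        assert p.alpha == pytest.approx(np.pi)
        p = FHNParameters(alpha=-np.pi / 2 + 4 * np.pi)
        assert p.alpha == pytest.approx(-np.pi / 2)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            FHNParameters(epsilon=0.0)
        with pytest.raises(ValueError):
            FHNParameters(lambda_in=-1.0)


class TestDerivatives:
    def test_uncoupled_node_at_origin(self, single_node_net):
        state = SystemState(np.zeros(2), np.zeros(2))
        du, dv = derivatives(state, FHNParameters(a=0.5), single_node_net)
        assert np.allclose(du, 0.0)
        assert np.allclose(dv, 0.5)

    def test_identical_states_cancel_coupling(self, two_rings):
        n = two_rings.n_total
        state = SystemState(np.full(n, 0.7), np.full(n, -0.2))
        strong = FHNParameters(alpha=1.0, lambda_in=2.0, lambda_out=3.0)
        uncoupled = FHNParameters()
        du1, dv1 = derivatives(state, strong, two_rings)
        du0, dv0 = derivatives(state, uncoupled, two_rings)
        assert np.allclose(du1, du0)
        assert np.allclose(dv1, dv0)

    def test_two_node_hand_expansion(self):
        net = two_node_net()
        params = FHNParameters(
            epsilon=0.05, a=0.5, alpha=0.0, lambda_in=0.0, lambda_out=1.0
        )
        state = SystemState(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        du, dv = derivatives(state, params, net)
        assert du[0] == pytest.approx((1 - 1 / 3 - 0 + (0 - 1)) / 0.05)  # -20/3
        assert dv[0] == pytest.approx(1.5)
        assert du[1] == pytest.approx((0 - 0 - 0 + (1 - 0)) / 0.05)  # 20
        assert dv[1] == pytest.approx(0.5)

    def test_matches_naive_loop_transcription(self, modular_net):
        # independent oracle: per-node loops written directly from the
        # coupled equations, no shared code with the vectorized RHS
        rng = np.random.default_rng(0)
        net = modular_net
        n_a, n = net.n_a, net.n_total
        u = rng.uniform(-2, 2, n)
        v = rng.uniform(-2, 2, n)
        p = FHNParameters(
            epsilon=0.05, a=0.5, alpha=np.pi / 2 - 0.1,
            lambda_in=0.6, lambda_out=0.5,
        )
        c, s = math.cos(p.alpha), math.sin(p.alpha)
        du_ref = np.empty(n)
        dv_ref = np.empty(n)
        adj_ab = net.adj_ab
        for i in range(n):
            in_layer_a = i < n_a
            if in_layer_a:
                intra = np.flatnonzero(net.adj_a[i])
                inter = n_a + np.flatnonzero(adj_ab[i])
            else:
                intra = n_a + np.flatnonzero(net.adj_b[i - n_a])
                inter = np.flatnonzero(adj_ab[:, i - n_a])
            cu = cv = 0.0
            if len(intra):
                cu += p.lambda_in * np.mean(c * (u[intra] - u[i]) + s * (v[intra] - v[i]))
                cv += p.lambda_in * np.mean(-s * (u[intra] - u[i]) + c * (v[intra] - v[i]))
            if len(inter):
                cu += p.lambda_out * np.mean(c * (u[inter] - u[i]) + s * (v[inter] - v[i]))
                cv += p.lambda_out * np.mean(-s * (u[inter] - u[i]) + c * (v[inter] - v[i]))
            du_ref[i] = (u[i] - u[i] ** 3 / 3 - v[i] + cu) / p.epsilon
            dv_ref[i] = u[i] + p.a + cv
        du, dv = derivatives(SystemState(u, v), p, net)
        assert np.allclose(du, du_ref, atol=1e-10)
        assert np.allclose(dv, dv_ref, atol=1e-10)

    def test_size_mismatch_rejected(self, two_rings):
        with pytest.raises(ValueError):
            derivatives(
                SystemState(np.zeros(3), np.zeros(3)),
                FHNParameters(),
                two_rings,
            )


class TestIntegration:
    def test_synchronized_manifold_invariance(self, two_rings):
        n = two_rings.n_total
        state = SystemState(np.full(n, 0.3), np.full(n, -0.1))
        params = FHNParameters(alpha=np.pi / 2 - 0.1, lambda_in=1.0, lambda_out=1.8)
        traj = integrate(state, params, two_rings, t_end=50.0, dt=0.01, sample_stride=20)
        spread = traj.u.max(axis=1) - traj.u.min(axis=1)
        assert spread.max() < 1e-9

    def test_zero_coupling_matches_isolated_orbit(self, two_rings, single_node_net):
        # each node of an uncoupled network follows the isolated trajectory
        n = two_rings.n_total
        u0, v0 = 0.5, -0.3
        state = SystemState(np.full(n, u0), np.full(n, v0))
        params = FHNParameters(lambda_in=0.0, lambda_out=0.0)
        traj = integrate(state, params, two_rings, 20.0, 0.01, 50)
        lone = SystemState(np.full(2, u0), np.full(2, v0))
        ref = integrate(lone, params, single_node_net, 20.0, 0.01, 50)
        assert np.allclose(traj.u, np.tile(ref.u[:, :1], n), atol=1e-10)

    def test_oscillatory_vs_excitable(self, single_node_net):
        # |a| < 1: sustained firing; |a| > 1: quiescent after the transient
        from chimeranet.observables import count_firings

        ic = SystemState(np.array([0.1, 0.1]), np.array([0.0, 0.0]))
        for a, expect_firing in ((0.5, True), (1.5, False)):
            traj = integrate(
                ic, FHNParameters(a=a), single_node_net, 200.0, 0.01, 10
            )
            post = traj.u[traj.times > 50.0]
            m = count_firings(post)
            assert (m > 0).all() == expect_firing

    def test_step_halving_convergence(self, two_rings):
        state = random_initial_conditions(two_rings, seed=8)
        params = FHNParameters(alpha=0.5, lambda_in=0.3, lambda_out=0.2)
        t1 = integrate(state, params, two_rings, 10.0, 0.01, 100)
        t2 = integrate(state, params, two_rings, 10.0, 0.005, 200)
        assert np.allclose(t1.times, t2.times)
        rms = np.sqrt(np.mean((t1.u - t2.u) ** 2))
        assert rms < 1e-4

    def test_single_oscillator_period_stable_under_refinement(self, single_node_net):
        # period extracted from upward crossings agrees to 0.1% between dt and dt/2
        def period(dt):
            ic = SystemState(np.array([0.0, 0.0]), np.array([0.5, 0.5]))
            traj = integrate(ic, FHNParameters(), single_node_net, 120.0, dt, 1)
            u = traj.u[traj.times > 40.0, 0]
            t = traj.times[traj.times > 40.0]
            crossings = t[1:][(u[:-1] < 0) & (u[1:] >= 0)]
            return np.diff(crossings).mean()

        p1, p2 = period(0.01), period(0.005)
        assert abs(p1 - p2) / p2 < 1e-3

    def test_overflow_guard_raises_with_step(self, single_node_net):
        huge = SystemState(np.array([900.0, 0.0]), np.zeros(2))
        with pytest.raises(InstabilityError) as exc:
            integrate(huge, FHNParameters(), single_node_net, 1.0, 0.01, 1)
        assert exc.value.step >= 1

    def test_final_step_always_sampled(self, single_node_net):
        ic = SystemState(np.zeros(2), np.zeros(2))
        traj = integrate(ic, FHNParameters(), single_node_net, 1.0, 0.01, 7)
        assert traj.times[-1] == pytest.approx(1.0)


class TestInitialConditions:
    def test_determinism_and_range(self, two_rings):
        s1 = random_initial_conditions(two_rings, seed=3)
        s2 = random_initial_conditions(two_rings, seed=3)
        assert np.array_equal(s1.u, s2.u) and np.array_equal(s1.v, s2.v)
        assert (np.abs(s1.u) <= 2).all() and (np.abs(s1.v) <= 2).all()

    def test_different_seeds_differ(self, two_rings):
        s1 = random_initial_conditions(two_rings, seed=3)
        s2 = random_initial_conditions(two_rings, seed=4)
        assert not np.array_equal(s1.u, s2.u)
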