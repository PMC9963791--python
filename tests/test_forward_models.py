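"""Differentiable solvers: closed forms, conservation, gradients."""

import numpy as np
import pytest

from neurocalib import autodiff as ad
from neurocalib.exceptions import (
    ConfigurationError,
    NumericalInstabilityError,
)
from neurocalib.forward_models import (
    HWNetwork,
    HWParams,
    SIRParams,
    StateTrajectory,
    hw_balance_residual,
    hw_flows,
    hw_segment,
    hw_steady_state,
    integrate_hw,
    integrate_sir,
    sir_drift,
    sir_segment,
)


class TestSIRDrift:
    def test_disease_free_equilibrium(self):
        assert sir_drift((1.0, 0.0, 0.0), SIRParams(0.5, 10.0)) == (0.0, 0.0, 0.0)

    def test_mass_conservation_of_drift(self, rng):
        for _ in range(20):
            s, i = rng.uniform(0, 1, 2) / 2
            d = sir_drift((s, i, 1 - s - i), SIRParams(*rng.uniform(0.1, 2, 2)))
            assert sum(d) == pytest.approx(0.0, abs=1e-14)

    def test_invalid_tau(self):
        with pytest.raises(ConfigurationError):
            SIRParams(beta=0.1, tau=0.0)


class TestIntegrateSIR:
    def test_pure_decay_matches_exponential(self):
        # beta = 0, sigma = 0: dI/dt = -I/tau exactly
        tau, i0 = 8.0, 0.4
        traj = integrate_sir(SIRParams(0.0, tau, 0.0), (0.5, i0, 0.1),
                             n_steps=400, dt=0.01)
        expected = i0 * np.exp(-traj.times / tau)
        np.testing.assert_allclose(traj.states[:, 1], expected, rtol=1e-4)
        # everything lost from I arrives in R
        assert traj.states[-1, 2] == pytest.approx(0.1 + i0 - expected[-1], rel=1e-4)

    def test_pathwise_conservation_with_noise(self):
        rng = np.random.default_rng(7)
        traj = integrate_sir(SIRParams(0.3, 14.0, 0.1), (0.99, 0.01, 0.0),
                             n_steps=1000, dt=0.1, rng=rng)
        total = traj.states.sum(axis=1)
        assert np.max(np.abs(total - 1.0)) < 1e-10

    def test_instability_error_names_step(self):
        with pytest.raises(NumericalInstabilityError) as err:
            # absurd rate at dt=1 explodes to overflow -> non-finite
            integrate_sir(SIRParams(1e8, 14.0, 0.0), (0.5, 0.5, 0.0), n_steps=500)
        assert err.value.step is not None

    def test_invalid_dt(self):
        with pytest.raises(ConfigurationError):
            integrate_sir(SIRParams(0.1, 5.0), (1, 0, 0), 10, dt=0.0)


class TestHWFlows:
    def test_two_destination_symmetry(self):
        net = HWNetwork([4.0], [[1.0, 1.0]], [1.0, 1.0])
        T, D = hw_flows(np.array([1.0, 1.0]), net, alpha=1.0, beta=1.0)
        np.testing.assert_allclose(T, [[2.0, 2.0]])
        np.testing.assert_allclose(D, [2.0, 2.0])

    def test_beta_zero_collapses_cost_kernel(self, small_hw_network, rng):
        net = small_hw_network
        W = rng.uniform(0.5, 2.0, net.n_destinations)
        alpha = 1.3
        _, D = hw_flows(W, net, alpha=alpha, beta=0.0)
        expected = W**alpha / (W**alpha).sum() * net.origin_sizes.sum()
        np.testing.assert_allclose(D, expected)

    def test_origin_demand_fully_distributed(self, small_hw_network, rng):
        net = small_hw_network
        W = rng.uniform(0.2, 3.0, net.n_destinations)
        T, D = hw_flows(W, net, alpha=0.8, beta=2.5)
        np.testing.assert_allclose(T.sum(axis=1), net.origin_sizes)
        assert D.sum() == pytest.approx(net.origin_sizes.sum())
        assert np.all(D >= 0)

    def test_zero_cost_entries_carry_no_flow(self):
        net = HWNetwork([1.0, 1.0], [[0.0, 1.0], [1.0, 1.0]], [1.0, 1.0])
        T, _ = hw_flows(np.array([1.0, 1.0]), net, alpha=1.0, beta=2.0)
        assert T[0, 0] == 0.0
        assert T[0, 1] == pytest.approx(1.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ConfigurationError):
            HWNetwork([1.0], [[0.0, 0.0]], [1.0, 1.0])


class TestIntegrateHW:
    def test_single_zone_logistic_convergence(self):
        # one destination, c column of ones: D = sum(O), W* = sum(O)/kappa
        net = HWNetwork([1.0, 2.0, 0.5], [[1.0]] * 3, [0.2])
        p = HWParams(alpha=1.1, beta=0.7, kappa=2.0)
        traj = integrate_hw(p, net, n_steps=4000, dt=0.01)
        assert traj.states[-1, 0] == pytest.approx(3.5 / 2.0, rel=1e-6)

    def test_steady_state_matches_w_equals_d_over_kappa(self, small_hw_network):
        p = HWParams(alpha=0.9, beta=3.0, kappa=1.5)
        W = hw_steady_state(p, small_hw_network)
        assert hw_balance_residual(W, small_hw_network, p) < 1e-6

    def test_epsilon_does_not_move_steady_state(self, small_hw_network):
        states = [
            hw_steady_state(
                HWParams(alpha=0.9, beta=3.0, kappa=1.5, epsilon=eps),
                small_hw_network,
            )
            for eps in (0.5, 1.0, 2.0)
        ]
        np.testing.assert_allclose(states[0], states[1], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(states[1], states[2], rtol=1e-6, atol=1e-9)

    def test_scale_covariance_of_kappa(self, small_hw_network):
        # multiplying all O and W by s leaves alpha, beta structure and
        # rescales nothing in kappa units: W* scales by s at fixed kappa
        s = 3.7
        p = HWParams(alpha=0.9, beta=3.0, kappa=1.5)
        W1 = hw_steady_state(p, small_hw_network)
        scaled = HWNetwork(
            small_hw_network.origin_sizes * s,
            small_hw_network.cost_matrix,
            small_hw_network.initial_sizes * s,
        )
        W2 = hw_steady_state(p, scaled)
        np.testing.assert_allclose(W2, W1 * s, rtol=1e-6, atol=1e-9)

    def test_noiseless_sigma_required_for_steady_state(self, small_hw_network):
        with pytest.raises(ConfigurationError):
            hw_steady_state(HWParams(1.0, 1.0, 1.0, sigma=0.5), small_hw_network)

    def test_trajectory_stays_positive_under_noise(self, small_hw_network):
        rng = np.random.default_rng(3)
        traj = integrate_hw(HWParams(1.2, 4.0, 2.0, sigma=0.8),
                            small_hw_network, 2000, dt=0.01, rng=rng)
        assert np.all(traj.states > 0)


class TestStateTrajectory:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ConfigurationError):
            StateTrajectory([0.0, 0.0, 1.0], np.zeros((3, 2)))

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            StateTrajectory([0.0, 1.0], np.zeros((3, 2)))


class TestGradientsThroughSolvers:
    """Autodiff through both integrators against finite differences."""

    def test_sir_loss_gradient(self):
        obs = integrate_sir(SIRParams(0.25, 12.0, 0.0), (0.97, 0.03, 0.0),
                            n_steps=15).states[1:]

        def loss(beta, tau):
            states = sir_segment((0.97, 0.03, 0.0), SIRParams(beta, tau, 0.0), 15)
            pred = (ad.stack([ad.stack(s) for s in states])
                    if isinstance(beta, ad.Tensor) else np.asarray(states))
            return ((pred - obs) ** 2).sum() / 15

        b = ad.Tensor(0.3, requires_grad=True)
        t = ad.Tensor(10.0, requires_grad=True)
        loss(b, t).backward()
        for leaf, name in ((b, "beta"), (t, "tau")):
            x0 = float(leaf.data)
            h = 1e-6 * max(1.0, abs(x0))
            args = {"beta": 0.3, "tau": 10.0}
            hi = dict(args); hi[name] = x0 + h
            lo = dict(args); lo[name] = x0 - h
            fd = (float(loss(**hi)) - float(loss(**lo))) / (2 * h)
            assert float(leaf.grad) == pytest.approx(fd, rel=1e-4)

    def test_hw_loss_gradient(self, small_hw_network):
        net = small_hw_network
        obs = hw_steady_state(HWParams(1.2, 4.0, 2.0), net)

        def loss(alpha, beta, kappa):
            p = HWParams(alpha, beta, kappa)
            Ws = hw_segment(net.initial_sizes, net, p, 8, dt=0.05)
            pred = ad.stack(Ws) if isinstance(alpha, ad.Tensor) else np.asarray(
                [np.asarray(w) for w in Ws])
            return ((pred - obs) ** 2).sum() / 8

        leaves = {n: ad.Tensor(v, requires_grad=True)
                  for n, v in (("alpha", 1.1), ("beta", 3.5), ("kappa", 1.8))}
        loss(**leaves).backward()
        base = {"alpha": 1.1, "beta": 3.5, "kappa": 1.8}
        for name, leaf in leaves.items():
            h = 1e-6 * max(1.0, base[name])
            hi = dict(base); hi[name] += h
            lo = dict(base); lo[name] -= h
            fd = (float(loss(**hi)) - float(loss(**lo))) / (2 * h)
            assert float(leaf.grad) == pytest.approx(fd, rel=1e-4)

    def test_sir_noise_amplitude_gradient_with_fixed_increments(self):
        rng = np.random.default_rng(11)
        inc = rng.standard_normal(10)
        obs = np.linspace(0.9, 0.6, 10)

        def loss(sigma):
            states = sir_segment((0.9, 0.1, 0.0), SIRParams(0.2, 10.0, sigma),
                                 10, increments=inc)
            tot = 0.0
            for k, s in enumerate(states):
                tot = tot + (s[0] - obs[k]) ** 2
            return tot

        s = ad.Tensor(0.15, requires_grad=True)
        loss(s).backward()
        h = 1e-6
        fd = (float(loss(0.15 + h)) - float(loss(0.15 - h))) / (2 * h)
        assert float(s.grad) == pytest.approx(fd, rel=1e-4)
        assert fd != 0.0
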