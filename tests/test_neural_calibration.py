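"""Network, initialization, batching and training-loop behavior."""

import numpy as np
import pytest
from scipy import stats

from neurocalib import autodiff as ad
from neurocalib.exceptions import ConfigurationError
from neurocalib.forward_models import SIRParams, integrate_sir
from neurocalib.neural_calibration import (
    CalibrationNet,
    NetConfig,
    TrainConfig,
    batch_loss,
    make_batches,
    run_multi_init,
    samples_frame,
    train_single,
)
from neurocalib.problems import SIRProblem
from neurocalib import density as de


def sir_net_config(**kw):
    defaults = dict(
        input_dim=3,
        param_names=("beta", "tau", "sigma"),
        prior_ranges=((0.0, 1.0), (1.0, 30.0), (0.0, 1.0)),
    )
    defaults.update(kw)
    return NetConfig(**defaults)


class TestBatchLoss:
    def test_identical_prediction_is_zero(self):
        obs = np.ones((4, 3))
        assert batch_loss(ad.Tensor(obs), obs).item() == 0.0

    def test_hand_evaluated_single_residual(self):
        pred = ad.Tensor([[0.1, -0.1, 0.0]])
        assert batch_loss(pred, np.zeros((1, 3))).item() == pytest.approx(0.02)

    def test_quadratic_homogeneity(self, rng):
        obs = rng.uniform(size=(5, 3))
        pred = obs + rng.normal(size=(5, 3)) * 0.1
        j1 = batch_loss(ad.Tensor(pred), obs).item()
        j2 = batch_loss(ad.Tensor(obs + 2 * (pred - obs)), obs).item()
        assert j2 == pytest.approx(4 * j1)

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigurationError):
            batch_loss(ad.Tensor(np.zeros((0, 3))), np.zeros((0, 3)))


class TestBatchLayout:
    def test_unit_series_yields_self_consistency_batch(self):
        assert make_batches(1, 90) == [(0, 1)]

    def test_trailing_remainder_dropped(self):
        # 101 frames = 100 transitions: one full batch of 90, tail dropped
        assert make_batches(101, 90) == [(0, 90)]

    def test_exact_multiple_covers_everything(self):
        assert make_batches(7, 2) == [(0, 2), (2, 2), (4, 2)]

    def test_short_series_used_whole(self):
        assert make_batches(4, 90) == [(0, 3)]


class TestNetwork:
    def test_output_nonnegative_under_modulus(self, rng):
        net = CalibrationNet(sir_net_config(), rng)
        for _ in range(50):
            out = net.forward(rng.normal(size=3))
            assert np.all(out.data >= 0)

    def test_zero_weights_give_zero_output(self, rng):
        net = CalibrationNet(sir_net_config(), rng)
        for p in net.parameters:
            p.data[:] = 0.0
        np.testing.assert_allclose(net.forward(np.ones(3)).data, 0.0)

    def test_dimension_mismatch_raises(self, rng):
        net = CalibrationNet(sir_net_config(), rng)
        with pytest.raises(ConfigurationError):
            net.forward(np.ones(5))

    def test_output_scales_default_to_prior_upper_bounds(self):
        cfg = sir_net_config()
        assert cfg.output_scales == (1.0, 30.0, 1.0)

    def test_unreachable_prior_rejected(self):
        with pytest.raises(ConfigurationError):
            sir_net_config(prior_ranges=((-2.0, -1.0), (1.0, 2.0), (0.0, 1.0)))


class TestUniformPriorInitialization:
    def test_initial_outputs_uniform_over_prior_box(self):
        """KS distance to the uniform law below 0.1 per coordinate."""
        cfg = sir_net_config()
        x0 = np.array([0.99, 0.01, 0.0])
        draws = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            net = CalibrationNet(cfg, rng)
            net.calibrate_initial_output(x0, rng)
            draws.append(net.forward(x0).data)
        draws = np.asarray(draws)
        for j, (lo, hi) in enumerate(cfg.prior_ranges):
            u = (draws[:, j] - lo) / (hi - lo)
            assert 0 <= u.min() and u.max() <= 1
            ks = stats.kstest(u, "uniform").statistic
            assert ks < 0.1

    def test_degenerate_range_pins_initial_output(self, rng):
        cfg = sir_net_config(prior_ranges=((0.5, 0.5), (7.0, 7.0), (0.2, 0.2)))
        net = CalibrationNet(cfg, rng)
        net.calibrate_initial_output(np.ones(3), rng)
        np.testing.assert_allclose(net.forward(np.ones(3)).data,
                                   [0.5, 7.0, 0.2], atol=1e-12)


def make_problem(n_steps=40, beta=0.3, tau=10.0):
    traj = integrate_sir(SIRParams(beta, tau, 0.0), (0.97, 0.03, 0.0), n_steps)
    return SIRProblem(traj)


class TestTraining:
    def test_loss_descends_on_noiseless_data(self):
        problem = make_problem()
        run = train_single(problem, problem.default_net_config(),
                           TrainConfig(epochs=40, batch_size=40, seed=2))
        trace = run.loss_trace
        assert np.median(trace[-10:]) < np.median(trace[:10])

    def test_one_sample_per_optimizer_step(self):
        problem = make_problem(n_steps=40)
        cfg = TrainConfig(epochs=5, batch_size=10, seed=0)
        run = train_single(problem, problem.default_net_config(), cfg)
        assert len(run.samples) == 5 * 4  # 40 transitions / 10 per batch

    def test_multi_init_pools_with_provenance_and_determinism(self):
        problem = make_problem(n_steps=30)
        cfg = TrainConfig(epochs=3, batch_size=30, n_initializations=3, seed=5)
        runs_a = run_multi_init(problem, problem.default_net_config(), cfg)
        runs_b = run_multi_init(problem, problem.default_net_config(), cfg)
        df_a, df_b = samples_frame(runs_a), samples_frame(runs_b)
        assert sorted(df_a["init_id"].unique()) == [0, 1, 2]
        assert df_a.equals(df_b)

    def test_single_init_pool_equals_run(self):
        problem = make_problem(n_steps=30)
        cfg = TrainConfig(epochs=3, batch_size=30, n_initializations=1, seed=5)
        runs = run_multi_init(problem, problem.default_net_config(), cfg)
        assert len(runs) == 1
        assert len(samples_frame(runs)) == len(runs[0].samples)

    def test_batch_isolation(self):
        """Perturbing frames outside a batch leaves its proposal unchanged."""
        problem_a = make_problem(n_steps=40)
        states = problem_a.data.states.copy()
        states[35:] += 0.1  # tampers only with the second batch's frames
        from neurocalib.forward_models import StateTrajectory
        problem_b = SIRProblem(StateTrajectory(problem_a.data.times, states))
        cfg = TrainConfig(epochs=1, batch_size=20, seed=3)
        run_a = train_single(problem_a, problem_a.default_net_config(), cfg)
        run_b = train_single(problem_b, problem_b.default_net_config(), cfg)
        # first optimizer step happens before any second-batch data is read
        np.testing.assert_allclose(run_a.samples[0].lambda_hat,
                                   run_b.samples[0].lambda_hat)

    def test_learned_noise_sigma_receives_gradient(self):
        problem = make_problem(n_steps=20)
        assert problem.param_names == ("beta", "tau", "sigma")
        cfg = problem.default_net_config()
        rng = np.random.default_rng(0)
        net = CalibrationNet(cfg, rng)
        net.calibrate_initial_output(problem.frame(0), rng)
        lam = net.forward(problem.frame(0))
        pred = problem.simulate_batch(lam, 0, 20, rng)
        J = batch_loss(pred, problem.batch_targets(0, 20))
        J.backward()
        grads = [np.abs(p.grad).sum() for p in net.parameters]
        assert all(g > 0 for g in grads)

    def test_fixed_noise_drops_sigma_from_parameters(self):
        traj = integrate_sir(SIRParams(0.3, 10.0, 0.0), (0.97, 0.03, 0.0), 20)
        problem = SIRProblem(traj, solver_noise=0.0)
        assert problem.param_names == ("beta", "tau")


class TestSelfConsistentRecovery:
    def test_parameters_recovered_from_solver_generated_data(self):
        """Mismatch-free recovery: beta within 5%, tau within 15%."""
        true_beta, true_tau = 0.3, 14.0
        traj = integrate_sir(SIRParams(true_beta, true_tau, 0.0),
                             (1 - 1 / 300, 1 / 300, 0.0), 100)
        problem = SIRProblem(traj)
        cfg = TrainConfig(epochs=70, batch_size=90, n_initializations=4, seed=3)
        runs = run_multi_init(problem, problem.default_net_config(), cfg)
        df = samples_frame(runs)
        mle = {}
        for p in ("beta", "tau"):
            md = de.marginal(df[p].to_numpy(), losses=df["loss"].to_numpy(),
                             parameter_name=p)
            mle[p] = de.summarize(md)["mle"]
        assert abs(mle["beta"] - true_beta) / true_beta < 0.05
        assert abs(mle["tau"] - true_tau) / true_tau < 0.15
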