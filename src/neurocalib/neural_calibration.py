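"""Training a neural network through a differentiable solver.

The calibration loop is the heart of the package.  A small network
``u_theta`` reads ``q`` consecutive observed frames (throughout this
package ``q = 1``) and emits a parameter proposal ``lambda_hat``.  The
proposal is handed to the differentiable forward model, which is
teacher-forced: each batch's predicted segment starts from the true
observed state at the batch's first index and is integrated for ``B``
steps.  The batch-averaged squared error

.. math::

    J = \\frac{1}{B} \\sum_{j} \\lVert \\hat\\varphi_j - \\varphi_j \\rVert^2

is backpropagated through the solver into the network weights and one
Adam step is taken.  Every optimizer step contributes one
``(lambda_hat, J)`` pair to the sample pool; over many epochs and many
random initializations these pairs trace out the loss potential from
which :mod:`neurocalib.density` estimates posterior marginals.

Positivity of the proposals is guaranteed by the absolute-value
activation on the output layer; per-parameter output scales map the
unit-range activations onto physically sensible prior ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from . import autodiff as ad
from .exceptions import ConfigurationError, NumericalInstabilityError
from .forward_models import StateTrajectory

_ACTIVATIONS: dict[str, Callable[[ad.Tensor], ad.Tensor]] = {
    "abs": lambda x: x.abs(),
    "identity": lambda x: x,
    "relu": lambda x: x.clip_min(0.0),
}


@dataclass
class NetConfig:
    """Architecture and prior specification of the calibration network.

    ``prior_ranges`` are per-parameter intervals; the network is
    initialized so that its first proposal on the training input is a
    uniform draw from this box, which realizes a uniform prior over the
    sampled region.  ``output_scales`` default to the upper ends of the
    prior ranges so that unit-scale activations reach the whole box.
    """

    input_dim: int
    param_names: tuple[str, ...]
    prior_ranges: tuple[tuple[float, float], ...]
    hidden_layers: tuple[int, ...] = (20,)
    activation: str = "abs"
    final_activation: str = "abs"
    output_scales: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        p = len(self.param_names)
        if len(self.prior_ranges) != p:
            raise ConfigurationError("one prior range per parameter required")
        for lo, hi in self.prior_ranges:
            if hi < lo:
                raise ConfigurationError("prior range upper bound below lower bound")
            if self.final_activation == "abs" and hi < 0:
                raise ConfigurationError(
                    "prior range unreachable under the positivity activation"
                )
        if self.output_scales is None:
            self.output_scales = tuple(
                hi if hi > 0 else 1.0 for _, hi in self.prior_ranges
            )
        if len(self.output_scales) != p or any(s <= 0 for s in self.output_scales):
            raise ConfigurationError("output_scales must be p positive reals")
        for name in (self.activation, self.final_activation):
            if name not in _ACTIVATIONS:
                raise ConfigurationError(f"unknown activation {name!r}")

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass
class TrainConfig:
    """Optimization settings for one calibration experiment."""

    epochs: int = 70
    batch_size: int = 90
    optimizer: str = "adam"
    learning_rate: float = 0.002
    n_initializations: int = 20
    solver_noise: float | str = 0.0   # fixed amplitude, or "learned"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if isinstance(self.solver_noise, str) and self.solver_noise != "learned":
            raise ConfigurationError("solver_noise must be a number or 'learned'")


@dataclass
class ParameterSample:
    """One (lambda_hat, J) point visited during training."""

    lambda_hat: np.ndarray
    loss: float
    init_id: int
    epoch: int
    batch_index: int


@dataclass
class CalibrationRun:
    """The full training record of a single network initialization."""

    net_config: NetConfig
    train_config: TrainConfig
    samples: list[ParameterSample]
    final_lambda: np.ndarray
    loss_trace: np.ndarray

    @property
    def init_id(self) -> int:
        return self.samples[0].init_id if self.samples else -1


class CalibrationNet:
    """Shallow fully connected network with per-parameter output scaling."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.act = _ACTIVATIONS[cfg.activation]
        self.final_act = _ACTIVATIONS[cfg.final_activation]
        self.scales = np.asarray(cfg.output_scales, dtype=float)
        dims = [cfg.input_dim, *cfg.hidden_layers, cfg.n_params]
        self.weights: list[ad.Tensor] = []
        self.biases: list[ad.Tensor] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((fan_out, fan_in)) / np.sqrt(fan_in)
            b = rng.standard_normal(fan_out) * 0.1
            self.weights.append(ad.Tensor(w, requires_grad=True))
            self.biases.append(ad.Tensor(b, requires_grad=True))

    @property
    def parameters(self) -> list[ad.Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, frames: np.ndarray) -> ad.Tensor:
        """Map observed frame(s) to a nonnegative parameter proposal."""
        x = np.asarray(frames, dtype=float).ravel()
        if x.shape[0] != self.cfg.input_dim:
            raise ConfigurationError(
                f"input has dimension {x.shape[0]}, expected {self.cfg.input_dim}"
            )
        h: ad.Tensor | np.ndarray = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = w @ h + b
            h = self.final_act(z) if i == last else self.act(z)
        return h * self.scales

    def calibrate_initial_output(self, reference_input: np.ndarray,
                                 rng: np.random.Generator) -> None:
        """Make the initial proposal a uniform draw from the prior box.

        The network weights stay randomly initialized; only the output
        bias is shifted so that the pre-activation output on the
        reference input equals a uniform draw divided by the output
        scales.  Over repeated initializations the distribution of
        initial proposals is then exactly uniform over ``prior_ranges``.
        """
        lo = np.array([r[0] for r in self.cfg.prior_ranges])
        hi = np.array([r[1] for r in self.cfg.prior_ranges])
        target = rng.uniform(lo, hi)
        x = np.asarray(reference_input, dtype=float).ravel()
        h: np.ndarray = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = w.data @ h + b.data
            h = _ACTIVATIONS[self.cfg.activation](ad.Tensor(z)).data
        pre = self.weights[-1].data @ h
        self.biases[-1].data = target / self.scales - pre


class Adam:
    """Standard Adam optimizer over a list of leaf tensors."""

    def __init__(self, params: Sequence[ad.Tensor], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def batch_loss(pred: ad.Tensor, obs: np.ndarray) -> ad.Tensor:
    """Batch-averaged squared error ``(1/B) sum_j ||phi_hat_j - phi_j||^2``."""
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 0:
        raise ConfigurationError("empty batch")
    diff = pred - obs
    return (diff * diff).sum() / obs.shape[0]


def make_batches(n_frames: int, batch_size: int) -> list[tuple[int, int]]:
    """Teacher-forced batch layout over a trajectory of ``n_frames`` frames.

    Returns ``(start_index, n_steps)`` pairs covering the frame
    transitions ``start -> start + n_steps`` in consecutive
    non-overlapping segments.  A trailing remainder shorter than the
    batch size is dropped (with a 100-frame series and batch size 90
    this gives exactly one optimizer step per epoch); if the whole
    series is shorter than one batch, a single short batch covers it.
    A single-frame (steady state) trajectory yields one
    self-consistency batch of one step whose target is the frame
    itself.
    """
    if n_frames == 1:
        return [(0, 1)]
    n_trans = n_frames - 1
    if n_trans <= batch_size:
        return [(0, n_trans)]
    batches = []
    k = 0
    while k + batch_size <= n_trans:
        batches.append((k, batch_size))
        k += batch_size
    return batches


class CalibrationProblem:
    """Couples an observed trajectory to a differentiable forward model.

    Subclasses provide :meth:`simulate_batch`, which integrates the
    model for ``n_steps`` starting from the observed state at ``start``
    using a tensor-valued parameter proposal, and
    :meth:`batch_targets`, the observed states the prediction is scored
    against.
    """

    data: StateTrajectory
    param_names: tuple[str, ...]

    @property
    def state_dim(self) -> int:
        return self.data.states.shape[1]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def frame(self, k: int) -> np.ndarray:
        return self.data.states[k]

    def batch_targets(self, start: int, n_steps: int) -> np.ndarray:
        if self.n_frames == 1:
            return self.data.states[[0]]
        return self.data.states[start + 1: start + 1 + n_steps]

    def batches(self, batch_size: int) -> list[tuple[int, int]]:
        return make_batches(self.n_frames, batch_size)

    def simulate_batch(self, lam: ad.Tensor, start: int, n_steps: int,
                       rng: np.random.Generator) -> ad.Tensor:
        raise NotImplementedError

    def effective_lambda(self, lam_data: np.ndarray) -> np.ndarray:
        """The parameter values the solver actually evaluated.

        Problems that saturate extreme proposals before integration
        override this so that recorded (lambda, J) samples place the
        loss at the coordinates where it was computed.
        """
        return lam_data

    def default_net_config(self, seed: int = 0) -> NetConfig:
        raise NotImplementedError


def train_single(problem: CalibrationProblem, net_cfg: NetConfig,
                 train_cfg: TrainConfig, init_id: int = 0,
                 seed: int | None = None) -> CalibrationRun:
    """Train one initialization; returns its full sample record.

    Raises :class:`NumericalInstabilityError` carrying the offending
    proposal if the loss becomes non-finite.
    """
    seed = train_cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    net = CalibrationNet(net_cfg, rng)
    net.calibrate_initial_output(problem.frame(0), rng)
    opt = Adam(net.parameters, lr=train_cfg.learning_rate)
    batches = problem.batches(train_cfg.batch_size)
    samples: list[ParameterSample] = []
    lam_data = None
    for epoch in range(train_cfg.epochs):
        for b_idx, (start, n_steps) in enumerate(batches):
            lam = net.forward(problem.frame(start))
            pred = problem.simulate_batch(lam, start, n_steps, rng)
            J = batch_loss(pred, problem.batch_targets(start, n_steps))
            loss_val = J.item()
            lam_data = problem.effective_lambda(lam.data.copy())
            if not np.isfinite(loss_val):
                raise NumericalInstabilityError(
                    f"non-finite loss in epoch {epoch}, batch {b_idx}",
                    lambda_hat=lam_data,
                )
            opt.zero_grad()
            J.backward()
            opt.step()
            samples.append(ParameterSample(lam_data, loss_val, init_id, epoch, b_idx))
        if epoch % 10 == 0:
            logger.debug("init %d epoch %d: loss %.3e", init_id, epoch,
                         samples[-1].loss)
    return CalibrationRun(
        net_cfg, train_cfg, samples,
        final_lambda=lam_data,
        loss_trace=np.array([s.loss for s in samples]),
    )


def run_multi_init(problem: CalibrationProblem, net_cfg: NetConfig,
                   train_cfg: TrainConfig) -> list[CalibrationRun]:
    """Independent trainings from distinct seeds, pooled for density estimation.

    Each initialization derives its own seed from the master training
    seed, so runs are independent, reproducible and order-insensitive.
    A failing initialization is recorded and skipped; only if every
    initialization fails is an error raised.
    """
    child_seeds = np.random.SeedSequence(train_cfg.seed).generate_state(
        train_cfg.n_initializations
    ) % (2**31 - 1)
    runs: list[CalibrationRun] = []
    failures: list[tuple[int, Exception]] = []
    for init_id in range(train_cfg.n_initializations):
        try:
            runs.append(
                train_single(problem, net_cfg, train_cfg, init_id=init_id,
                             seed=int(child_seeds[init_id]))
            )
            logger.info("initialization %d/%d done: final loss %.3e",
                        init_id + 1, train_cfg.n_initializations,
                        runs[-1].loss_trace[-1])
        except NumericalInstabilityError as err:  # pragma: no cover - rare
            logger.warning("initialization %d failed: %s", init_id, err)
            failures.append((init_id, err))
    if not runs:
        raise RuntimeError(
            f"all {train_cfg.n_initializations} initializations failed: "
            f"{failures[0][1]}"
        )
    return runs


def samples_frame(runs: Sequence[CalibrationRun]) -> pd.DataFrame:
    """Flat table of all visited samples: init_id, epoch, batch, lambdas, loss."""
    if not runs:
        raise ValueError("no calibration runs given")
    names = runs[0].net_config.param_names
    records = []
    for run in runs:
        for s in run.samples:
            rec = {"init_id": s.init_id, "epoch": s.epoch, "batch": s.batch_index}
            rec.update({n: v for n, v in zip(names, s.lambda_hat)})
            rec["loss"] = s.loss
            records.append(rec)
    return pd.DataFrame.from_records(records)
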