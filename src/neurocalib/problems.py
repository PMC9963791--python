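"""Concrete calibration problems for the two shipped forward models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .exceptions import ConfigurationError
from .forward_models import (
    HWNetwork,
    HWParams,
    SIRParams,
    StateTrajectory,
    hw_segment,
    sir_heun_step,
    sir_segment,
)
from .neural_calibration import CalibrationProblem, NetConfig

#: default uniform prior boxes; wide enough to cover the physically
#: plausible range of each parameter while keeping the solver stable
SIR_PRIOR = (("beta", (0.0, 1.0)), ("tau", (1.0, 30.0)), ("sigma", (0.0, 1.0)))
HW_PRIOR = (("alpha", (0.0, 2.5)), ("beta", (0.0, 8.0)), ("kappa", (0.0, 10.0)))


def _leaky_clamp_np(x, lo: float | None, hi: float | None,
                    slope: float = 0.05) -> np.ndarray:
    """Numpy mirror of :func:`_leaky_clamp` for reporting effective values."""
    x = np.asarray(x, dtype=float)
    if hi is not None:
        x = np.minimum(x, hi) + np.maximum(x - hi, 0.0) * slope
    if lo is not None:
        x = np.maximum(x, lo) + np.minimum(x - lo, 0.0) * slope
    return x


def _leaky_clamp(x, lo: float | None, hi: float | None,
                 slope: float = 0.05) -> ad.Tensor:
    """Saturate a value outside ``[lo, hi]`` with a small leak.

    Identity inside the band.  Outside, the value grows only at
    ``slope``, which keeps the solver out of overflow territory while
    preserving a restoring gradient — a hard clamp would zero the
    gradient and strand any initialization that momentum carries past
    the bound.
    """
    x = ad.as_tensor(x)
    if hi is not None:
        x = x.clip_max(hi) + (x - hi).clip_min(0.0) * slope
    if lo is not None:
        x = x.clip_min(lo) + (x - lo).clip_max(0.0) * slope
    return x


@dataclass
class SIRProblem(CalibrationProblem):
    """Calibrate (beta, tau, sigma) of the SIR density SDE to a time series.

    ``solver_noise="learned"`` (the default) makes the noise amplitude a
    network output: the solver is driven by fixed Wiener increments
    drawn per batch and the gradient flows through the amplitude.  A
    fixed numeric ``solver_noise`` drops sigma from the calibrated
    parameters.  The recovery time is floored at 1 inside the solver:
    below that the relaxation rate ``1/tau`` leaves the stability
    region of the unit-step scheme and training excursions explode.
    """

    data: StateTrajectory
    dt: float = 1.0
    solver_noise: float | str = "learned"

    def __post_init__(self):
        if self.data.states.shape[1] != 3:
            raise ConfigurationError("SIR data must have (S, I, R) columns")
        self.param_names = (
            ("beta", "tau", "sigma")
            if self.solver_noise == "learned"
            else ("beta", "tau")
        )

    def simulate_batch(self, lam, start, n_steps, rng):
        # clamp proposals to twice the prior box before they enter the
        # solver: a transient excursion to large beta or sigma compounds
        # over ~90 unit steps into overflow, killing the whole
        # initialization.  Samples record these effective values.
        beta = _leaky_clamp(lam[0], None, 2.0)
        tau = _leaky_clamp(lam[1], 1.0, None)
        increments = None
        if self.solver_noise == "learned":
            sigma = _leaky_clamp(lam[2], None, 2.0)
            increments = rng.standard_normal(n_steps) * np.sqrt(self.dt)
        elif self.solver_noise > 0:
            sigma = float(self.solver_noise)
            increments = rng.standard_normal(n_steps) * np.sqrt(self.dt)
        else:
            sigma = 0.0
        params = SIRParams(beta=beta, tau=tau, sigma=sigma)
        # integrate with a hard state clamp far outside the simplex: the
        # drift is quadratic in the state, so extreme proposals double-
        # exponentiate within a few unit steps; inside [-5, 5] the
        # dynamics are untouched, and the pre-rail steps keep carrying
        # gradient signal that pulls proposals back
        if increments is None:
            increments = np.zeros(n_steps)
        state = tuple(self.frame(start))
        out = []
        for k in range(n_steps):
            state = sir_heun_step(state, params, self.dt, float(increments[k]))
            state = tuple(
                ad.as_tensor(x).clip_min(-5.0).clip_max(5.0) for x in state
            )
            out.append(state)
        return ad.stack([ad.stack(s) for s in out])

    def effective_lambda(self, lam_data: np.ndarray) -> np.ndarray:
        out = lam_data.copy()
        out[0] = _leaky_clamp_np(out[0], None, 2.0)
        out[1] = _leaky_clamp_np(out[1], 1.0, None)
        if self.solver_noise == "learned":
            out[2] = _leaky_clamp_np(out[2], None, 2.0)
        return out

    def default_net_config(self, seed: int = 0) -> NetConfig:
        prior = dict(SIR_PRIOR)
        return NetConfig(
            input_dim=3,
            param_names=self.param_names,
            prior_ranges=tuple(prior[n] for n in self.param_names),
            seed=seed,
        )


@dataclass
class HWProblem(CalibrationProblem):
    """Calibrate (alpha, beta, kappa) of the Harris-Wilson SDE.

    The solver runs noiselessly by default, which makes no assumption
    about the noise present in the data.  Two scoring modes exist:

    * ``"stationary"`` (default): every frame is treated as an
      observation of the stationary regime.  The solver runs
      ``steady_horizon`` steps from the observed state and every
      visited state is compared against it, so parameters under which
      the state is not stationary accumulate drift over the whole
      horizon.  This covers both the single converged steady state
      and noisy replicate observations of it.
    * ``"transitions"``: for genuine time-series data the solver flows
      each frame forward by one frame interval (``frame_dt``, inferred
      from the time stamps) and the arrival state is compared with the
      next frame.

    In both modes the horizon matters: a single-``dt`` residual is
    quadratically small in ``dt``, and the resulting loss landscape is
    so flat that the optimizer's own step noise washes out the basin
    structure of the potential.  ``epsilon`` is not calibrated: it
    does not affect the steady state.
    """

    network: HWNetwork
    data: StateTrajectory
    dt: float = 0.1
    epsilon: float = 1.0
    solver_noise: float = 0.0
    steady_horizon: int = 5
    mode: str = "stationary"
    frame_dt: float | None = None     # frame spacing; inferred from times
    param_names: tuple[str, ...] = ("alpha", "beta", "kappa")

    def __post_init__(self):
        if self.data.states.shape[1] != self.network.n_destinations:
            raise ConfigurationError(
                "data frames must have one column per destination zone"
            )
        if self.mode not in ("stationary", "transitions"):
            raise ConfigurationError(f"unknown scoring mode {self.mode!r}")
        if self.mode == "transitions" and self.n_frames < 2:
            raise ConfigurationError("transition scoring needs >= 2 frames")
        if self.frame_dt is None:
            self.frame_dt = (
                float(np.diff(self.data.times).mean()) if self.n_frames > 1 else 0.0
            )

    @property
    def _flow_steps(self) -> int:
        return max(1, round(self.frame_dt / self.dt))

    def batches(self, batch_size):
        if self.mode == "stationary":
            return [(k, self.steady_horizon) for k in range(self.n_frames)]
        return [(k, 1) for k in range(self.n_frames - 1)]

    def batch_targets(self, start, n_steps):
        if self.mode == "stationary":
            return np.tile(self.data.states[start], (self.steady_horizon, 1))
        return self.data.states[[start + 1]]

    def simulate_batch(self, lam, start, n_steps, rng):
        # clamp to twice the prior box: large alpha raises zone sizes to
        # overflowing powers during excursions ("danger zone" guard)
        params = HWParams(
            alpha=_leaky_clamp(lam[0], None, 5.0),
            beta=_leaky_clamp(lam[1], None, 16.0),
            kappa=_leaky_clamp(lam[2], 1e-6, 20.0),
            epsilon=self.epsilon,
            sigma=float(self.solver_noise),
        )
        solver_steps = (
            self.steady_horizon if self.mode == "stationary" else self._flow_steps
        )
        increments = None
        if self.solver_noise > 0:
            increments = rng.standard_normal(
                (solver_steps, self.network.n_destinations)
            ) * np.sqrt(self.dt)
        Ws = hw_segment(np.maximum(self.frame(start), 1e-8), self.network,
                        params, solver_steps, self.dt, increments)
        if self.mode == "stationary":
            return ad.stack(Ws)
        return ad.stack(Ws[-1:])    # only the arrival state is observed

    def effective_lambda(self, lam_data: np.ndarray) -> np.ndarray:
        out = lam_data.copy()
        out[0] = _leaky_clamp_np(out[0], None, 5.0)
        out[1] = _leaky_clamp_np(out[1], None, 16.0)
        out[2] = _leaky_clamp_np(out[2], 1e-6, 20.0)
        return out

    def default_net_config(self, seed: int = 0) -> NetConfig:
        # kappa is the only dimensionful parameter (cost per unit floor
        # space); its natural unit is Sum O / Sum W, the value any
        # steady state pins it to.  Scaling the prior by that unit keeps
        # initial proposals within the dynamically sane range whatever
        # units the user's tables are in.
        kappa_unit = float(
            self.network.origin_sizes.sum() / self.data.states.mean(axis=0).sum()
        )
        prior = dict(HW_PRIOR)
        prior["kappa"] = (0.0, 2.0 * kappa_unit)
        return NetConfig(
            input_dim=self.network.n_destinations,
            param_names=self.param_names,
            prior_ranges=tuple(prior[n] for n in self.param_names),
            seed=seed,
        )
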