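"""Synthetic data and diagnostics for the Harris-Wilson system.

The generator emulates a polycentric spatial-interaction setting:
destination zones (retail centers) and origin zones (demand sources)
are scattered around a handful of well-separated town centers,
pairwise Euclidean distances are turned into convenience weights by
the exponential cost kernel ``c_ij = exp(-d_ij / sup d)``, and zone
sizes/demands are drawn uniformly.  The multi-town geometry matters:
with every zone in one undifferentiated cluster the size preference
(``alpha > 1``) drives the market to a monopoly, whose steady state
carries no information about the parameters.  Separated towns keep
one retail center per town alive, which yields interior inequality
*and* enough independent steady-state balance equations to pin
``(alpha, beta)`` down to the model's discrete solution set.
Noiseless datasets are single converged steady states; noisy datasets
are late-time frames of the stochastic dynamics.  Every dataset is
screened by the inequality statistic

.. math::

    \\nu = \\frac{\\max_j W_j - \\min_j W_j}{\\sum_k W_k} \\in [0, 1],

because the parameters are unlearnable at the boundary: at ``nu = 1``
(monopoly) any ``(alpha, beta)`` solves the steady state, and at
``nu = 0`` (perfect equality) ``alpha`` is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .forward_models import (
    HWNetwork,
    HWParams,
    StateTrajectory,
    hw_steady_state,
    integrate_hw,
)


@dataclass
class DistanceMatrix:
    """Pairwise nonnegative distances with their sup scale."""

    distances: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ConfigurationError("distances must be nonnegative")

    @property
    def scale(self) -> float:
        """The time/length scale ``sup_ij d_ij`` used by the cost kernel."""
        return float(self.distances.max())


def cost_kernel(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Convenience weights ``c_ij = exp(-d_ij / sup d)``.

    The exponent is unitless, so rescaling all distances leaves the
    kernel unchanged; weights lie in ``(0, 1]`` and decrease strictly
    with distance.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(d)
    if d.scale <= 0:
        raise ConfigurationError("distance scale sup_ij d_ij must be positive")
    return np.exp(-d.distances / d.scale)


def nu_statistic(W: np.ndarray) -> float:
    """Inequality of the destination sizes: ``(max W - min W) / sum W``."""
    W = np.asarray(W, dtype=float)
    total = W.sum()
    if total <= 0:
        raise ConfigurationError("zone sizes must have positive total")
    return float((W.max() - W.min()) / total)


@dataclass
class SyntheticHWSpec:
    """Recipe for one synthetic Harris-Wilson dataset.

    Defaults: 50 origin and 8 destination zones spread around 4 town
    centers near the corners of the unit square (Gaussian scatter of
    SD ``town_radius`` around each center, destinations dealt to towns
    round-robin, origins assigned uniformly at random), demands and
    initial sizes i.i.d. uniform on [0.1, 1], the exponential cost
    kernel on Euclidean distances, and true parameters
    ``(alpha, beta, kappa) = (1.2, 4, 2)``.  With ``sigma = 0`` the
    dataset is the single converged steady state (``n_frames = 1``);
    with noise it is ``n_frames = 4`` replicate observations of the
    steady state, each perturbed by centered Gaussian measurement
    noise of SD ``sigma`` (clipped to stay positive).
    """

    n_origins: int = 50
    n_destinations: int = 8
    town_centers: tuple[tuple[float, float], ...] = (
        (0.1, 0.1), (0.9, 0.1), (0.1, 0.9), (0.9, 0.9)
    )
    town_radius: float = 0.05
    min_surviving_zones: int = 4
    origin_size_range: tuple[float, float] = (0.1, 1.0)
    initial_size_range: tuple[float, float] = (0.1, 1.0)
    true_params: HWParams = field(
        default_factory=lambda: HWParams(alpha=1.2, beta=4.0, kappa=2.0)
    )
    sigma: float = 0.0
    n_frames: int | None = None       # defaults to 1 (noiseless) or 4 (noisy)
    dt: float = 0.01
    cost_matrix: np.ndarray | None = None   # user-supplied override
    seed: int = 0

    def __post_init__(self):
        if self.n_origins < 1 or self.n_destinations < 1:
            raise ConfigurationError("need at least one origin and destination")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be nonnegative")
        if self.n_frames is None:
            self.n_frames = 1 if self.sigma == 0 else 4
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.sigma == 0 and self.n_frames != 1:
            raise ConfigurationError("noiseless data is a single steady frame")


def _build_network(spec: SyntheticHWSpec, rng: np.random.Generator) -> HWNetwork:
    if spec.cost_matrix is not None:
        cost = np.asarray(spec.cost_matrix, dtype=float)
    else:
        centers = np.asarray(spec.town_centers, dtype=float)
        town_of_dest = np.arange(spec.n_destinations) % len(centers)
        town_of_orig = rng.integers(len(centers), size=spec.n_origins)
        dests = centers[town_of_dest] + rng.normal(
            0, spec.town_radius, (spec.n_destinations, 2))
        origins = centers[town_of_orig] + rng.normal(
            0, spec.town_radius, (spec.n_origins, 2))
        d = np.linalg.norm(origins[:, None, :] - dests[None, :, :], axis=-1)
        cost = cost_kernel(DistanceMatrix(d))
    O = rng.uniform(*spec.origin_size_range, spec.n_origins)
    W0 = rng.uniform(*spec.initial_size_range, spec.n_destinations)
    return HWNetwork(O, cost, W0)


def generate(
    spec: SyntheticHWSpec, max_tries: int = 100
) -> tuple[HWNetwork, StateTrajectory, HWParams]:
    """Draw a network and simulate its observation frames.

    Datasets whose steady state falls outside ``0 < nu < 1`` are
    rejected and regenerated from a fresh derived seed (monopolized or
    perfectly equal markets carry no information on alpha and beta).
    Steady-state frames from extinct zones are floored at a tiny
    positive size so downstream solvers stay in the positive domain.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(max_tries) % (2**31 - 1)
    params = HWParams(
        alpha=spec.true_params.alpha,
        beta=spec.true_params.beta,
        kappa=spec.true_params.kappa,
        epsilon=spec.true_params.epsilon,
        sigma=spec.sigma,
    )
    noiseless = HWParams(params.alpha, params.beta, params.kappa,
                         params.epsilon, 0.0)
    for attempt in range(max_tries):
        rng = np.random.default_rng(int(seeds[attempt]))
        network = _build_network(spec, rng)
        W = hw_steady_state(noiseless, network, dt=spec.dt)
        nu = nu_statistic(W)
        # strict interior check: a numerically monopolized market (one
        # zone holding essentially all mass) is as unlearnable as nu = 1
        if not 1e-6 < nu < 1 - 1e-6:
            continue
        # identifiability check: k surviving zones supply k - 1
        # independent balance constraints on (alpha, beta); with fewer
        # than min_surviving_zones the nontrivial solution is exactly
        # determined at best and its valley too shallow to resolve
        if int((W > 1e-6 * W.max()).sum()) < spec.min_surviving_zones:
            continue
        if spec.sigma == 0:
            frames = np.maximum(W, 1e-8)[None, :]
        else:
            noise = rng.standard_normal((spec.n_frames, len(W)))
            frames = np.maximum(W[None, :] + spec.sigma * noise, 1e-8)
        times = np.arange(float(len(frames)))
        return network, StateTrajectory(times, frames, "harris-wilson"), params
    raise ConfigurationError(
        f"no dataset with 0 < nu < 1 found in {max_tries} tries; "
        "the requested parameter regime may be degenerate"
    )


def nu_phase_diagram(
    alphas: np.ndarray, betas: np.ndarray, spec: SyntheticHWSpec
) -> np.ndarray:
    """Steady-state inequality over a grid of (alpha, beta) values.

    Returns a ``len(alphas) x len(betas)`` surface.  High size
    preference with weak distance sensitivity drives the market toward
    monopoly (``nu -> 1``); the opposite corner supports many equal
    zones (``nu -> 0``).
    """
    alphas, betas = np.asarray(alphas), np.asarray(betas)
    if alphas.size == 0 or betas.size == 0:
        raise ConfigurationError("parameter grids must be nonempty")
    rng = np.random.default_rng(spec.seed)
    network = _build_network(spec, rng)
    surface = np.empty((len(alphas), len(betas)))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            p = HWParams(alpha=float(a), beta=float(b),
                         kappa=spec.true_params.kappa)
            W = hw_steady_state(p, network, dt=spec.dt)
            surface[i, j] = nu_statistic(W)
    return surface


def calibration_mspe(
    fitted: HWParams,
    network: HWNetwork,
    observed: np.ndarray,
    n_runs: int = 1000,
    rng: np.random.Generator | None = None,
    n_steps: int = 10_000,
    dt: float = 0.01,
) -> tuple[float, float]:
    """Expected squared prediction error of a calibrated model.

    Runs the (noisy) solver ``n_runs`` times with the fitted
    parameters, compares each run's final state with the observed
    steady state, and returns the mean and SD over runs of the mean
    squared error, thereby accounting for the random noise involved in
    the predictions.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    observed = np.asarray(observed, dtype=float)
    if fitted.sigma == 0:
        # deterministic: every run converges to the same steady state
        W = hw_steady_state(fitted, network, dt=dt)
        return float(np.mean((W - observed) ** 2)), 0.0
    errors = np.empty(n_runs)
    for r in range(n_runs):
        traj = integrate_hw(fitted, network, n_steps, dt=dt, rng=rng)
        errors[r] = float(np.mean((traj.states[-1] - observed) ** 2))
    return float(errors.mean()), float(errors.std())
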