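"""Differentiable Stratonovich integrators for the two calibrated systems.

Two forward models are provided:

* the compartmental SIR density SDE

  .. math::

      dS = -\\beta S I\\,dt - \\sigma I \\circ dW,\\qquad
      dI = (\\beta S - \\tau^{-1}) I\\,dt + \\sigma I \\circ dW,\\qquad
      dR = \\tau^{-1} I\\,dt,

  where the same Wiener increment appears with opposite signs in the S
  and I equations, so that S + I + R is conserved pathwise;

* the Harris-Wilson model of demand flow on a complete bipartite
  network: N origin zones with fixed demands ``O_i`` send flows

  .. math::

      T_{ij} = \\frac{W_j^\\alpha c_{ij}^\\beta}
                     {\\sum_k W_k^\\alpha c_{ik}^\\beta} O_i

  to M destination zones whose sizes follow the coupled logistic SDEs
  ``dW_j = eps * W_j (D_j - kappa W_j) dt + sigma W_j o dB_j`` with
  ``D_j = sum_i T_ij``.

Both systems are discretized with a Heun (predictor-corrector) scheme,
the standard strongly convergent method for Stratonovich SDEs.  Every
step is written in the generic arithmetic shared by numpy arrays and
:class:`~neurocalib.autodiff.Tensor`, so the same code path yields
plain trajectories during data generation and gradient-carrying
trajectories during training; noise increments are pre-drawn numpy
arrays and therefore constants under differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .exceptions import ConfigurationError, ConvergenceError, NumericalInstabilityError

#: lower floor applied to Harris-Wilson zone sizes after each step; keeps
#: training excursions out of the log-domain singularity at W = 0
W_FLOOR = 1e-8


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, ad.Tensor) for x in xs)


def _clip_min(x, floor: float):
    if isinstance(x, ad.Tensor):
        return x.clip_min(floor)
    return np.maximum(x, floor)


@dataclass
class SIRParams:
    """SIR SDE parameters: transmission rate, recovery time, noise amplitude."""

    beta: float
    tau: float
    sigma: float = 0.0

    def __post_init__(self):
        if not isinstance(self.beta, ad.Tensor) and self.beta < 0:
            raise ConfigurationError("beta must be nonnegative")
        if not isinstance(self.tau, ad.Tensor) and self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if not isinstance(self.sigma, ad.Tensor) and self.sigma < 0:
            raise ConfigurationError("sigma must be nonnegative")


@dataclass
class HWParams:
    """Harris-Wilson parameters.

    ``alpha`` is the consumers' preference for destination size,
    ``beta`` their preference for convenient travel, ``kappa`` the cost
    per unit floor space, ``epsilon`` the responsiveness of zones to
    excess demand (it sets the convergence rate but not the steady
    state) and ``sigma`` the multiplicative noise amplitude.
    """

    alpha: float
    beta: float
    kappa: float
    epsilon: float = 1.0
    sigma: float = 0.0

    def __post_init__(self):
        if not isinstance(self.kappa, ad.Tensor) and self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if not isinstance(self.sigma, ad.Tensor) and self.sigma < 0:
            raise ConfigurationError("sigma must be nonnegative")


@dataclass
class HWNetwork:
    """Bipartite origin->destination network with a nonnegative cost matrix."""

    origin_sizes: np.ndarray      # (N,) positive
    cost_matrix: np.ndarray       # (N, M) nonnegative, no all-zero row
    initial_sizes: np.ndarray     # (M,) positive

    def __post_init__(self):
        self.origin_sizes = np.asarray(self.origin_sizes, dtype=float)
        self.cost_matrix = np.asarray(self.cost_matrix, dtype=float)
        self.initial_sizes = np.asarray(self.initial_sizes, dtype=float)
        if np.any(self.origin_sizes <= 0):
            raise ConfigurationError("all origin sizes must be positive")
        if np.any(self.cost_matrix < 0):
            raise ConfigurationError("cost matrix must be nonnegative")
        if np.any(self.cost_matrix.sum(axis=1) == 0):
            raise ConfigurationError("cost matrix has an all-zero row: "
                                     "an origin zone reaches no destination")
        if np.any(self.initial_sizes <= 0):
            raise ConfigurationError("all initial destination sizes must be positive")

    @property
    def n_origins(self) -> int:
        return self.cost_matrix.shape[0]

    @property
    def n_destinations(self) -> int:
        return self.cost_matrix.shape[1]


@dataclass
class StateTrajectory:
    """An observed or predicted time series of state vectors."""

    times: np.ndarray
    states: np.ndarray            # (L, state_dim)
    model_tag: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if len(self.times) != len(self.states):
            raise ConfigurationError("times and states must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ----------------------------------------------------------------------
# SIR density SDE
# ----------------------------------------------------------------------

def sir_drift(state, params: SIRParams):
    """Deterministic rates (dS, dI, dR) per unit time; they sum to zero."""
    S, I, R = state
    beta, tau = params.beta, params.tau
    inc = beta * S * I
    rec = I / tau
    return (-inc, inc - rec, rec)


def _sir_diffusion(state, sigma):
    """Noise coefficients of the shared Wiener increment: (-sigma*I, sigma*I, 0)."""
    _, I, _ = state
    g = sigma * I
    return (-g, g, 0.0)


def sir_heun_step(state, params: SIRParams, dt: float, dW: float):
    """One Stratonovich Heun step of the SIR SDE.

    ``state`` is a tuple (S, I, R) of scalars (floats or tensors); the
    Wiener increment ``dW`` is a plain number, shared by the S and I
    noise terms so that the step conserves S + I + R exactly.
    """
    f0 = sir_drift(state, params)
    g0 = _sir_diffusion(state, params.sigma)
    pred = tuple(x + fx * dt + gx * dW for x, fx, gx in zip(state, f0, g0))
    f1 = sir_drift(pred, params)
    g1 = _sir_diffusion(pred, params.sigma)
    return tuple(
        x + 0.5 * (fa + fb) * dt + 0.5 * (ga + gb) * dW
        for x, fa, fb, ga, gb in zip(state, f0, f1, g0, g1)
    )


def sir_segment(init, params: SIRParams, n_steps: int, dt: float = 1.0,
                increments: np.ndarray | None = None):
    """Iterate :func:`sir_heun_step`, returning the list of visited states.

    ``increments`` are pre-drawn Wiener increments (length ``n_steps``);
    when omitted the dynamics are noiseless.  Works identically on
    float and tensor states/parameters.
    """
    if increments is None:
        increments = np.zeros(n_steps)
    state = tuple(init)
    out = []
    for k in range(n_steps):
        state = sir_heun_step(state, params, dt, float(increments[k]))
        out.append(state)
    return out


def integrate_sir(params: SIRParams, init, n_steps: int, dt: float = 1.0,
                  rng: np.random.Generator | None = None) -> StateTrajectory:
    """Integrate the SIR SDE from ``init`` on the simplex.

    With ``rng`` given and ``sigma > 0``, Wiener increments
    ``dW ~ N(0, dt)`` drive the shared noise term; otherwise the
    noiseless drift is integrated.  Raises
    :class:`NumericalInstabilityError` naming the offending step if the
    state leaves the finite range.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    inc = None
    if rng is not None and float(getattr(params.sigma, "data", params.sigma)) > 0:
        inc = rng.standard_normal(n_steps) * np.sqrt(dt)
    states = [tuple(float(x) for x in init)]
    state = states[0]
    for k in range(n_steps):
        dW = 0.0 if inc is None else float(inc[k])
        state = sir_heun_step(state, params, dt, dW)
        if not all(np.isfinite(x) for x in state):
            raise NumericalInstabilityError(
                f"SIR integration became non-finite at step {k + 1}", step=k + 1
            )
        states.append(state)
    times = np.arange(n_steps + 1) * dt
    return StateTrajectory(times, np.asarray(states), model_tag="sir")


# ----------------------------------------------------------------------
# Harris-Wilson network SDE
# ----------------------------------------------------------------------

def _cost_power(cost: np.ndarray, beta):
    """``cost ** beta`` elementwise, with 0 ** beta taken as 0.

    Zero-cost entries mark unreachable routes and contribute no flow;
    strictly positive matrices (e.g. the exponential cost kernel) never
    hit this branch.
    """
    if _is_tensor(beta):
        mask = cost > 0
        if mask.all():
            return ad.power(cost, beta)
        safe = np.where(mask, cost, 1.0)
        return ad.power(safe, beta) * mask.astype(float)
    with np.errstate(divide="ignore"):
        out = np.where(cost > 0, cost, 1.0) ** beta
    return np.where(cost > 0, out, 0.0)


def hw_flows(W, network: HWNetwork, alpha, beta):
    """Origin->destination flows ``T_ij`` and cumulative demands ``D_j``.

    Each origin distributes its entire demand ``O_i`` across
    destinations in proportion to ``W_j^alpha c_ij^beta``, so row sums
    of T equal ``O_i`` and total demand is conserved.
    """
    c_pow = _cost_power(network.cost_matrix, beta)
    if _is_tensor(W, alpha, beta):
        w_pow = ad.power(ad.as_tensor(W).clip_min(W_FLOOR), alpha)
        attract = c_pow * w_pow.reshape(1, -1)
    else:
        attract = c_pow * np.asarray(W, dtype=float) ** alpha
    row = attract.sum(axis=1, keepdims=True)
    row_data = row.data if isinstance(row, ad.Tensor) else row
    if np.any(row_data == 0):
        raise ConfigurationError(
            "degenerate cost row: an origin zone has zero total attractiveness"
        )
    T = attract / row * network.origin_sizes[:, None]
    D = T.sum(axis=0)
    return T, D


def hw_drift(W, network: HWNetwork, params: HWParams):
    """Net growth rates ``eps * W_j * (D_j - kappa W_j)`` per unit time."""
    _, D = hw_flows(W, network, params.alpha, params.beta)
    return params.epsilon * W * (D - params.kappa * W)


def hw_heun_step(W, network: HWNetwork, params: HWParams, dt: float, dB):
    """One Stratonovich Heun step of the zone-size SDE with positivity floor."""
    f0 = hw_drift(W, network, params)
    g0 = params.sigma * W
    pred = _clip_min(W + f0 * dt + g0 * dB, W_FLOOR)
    f1 = hw_drift(pred, network, params)
    g1 = params.sigma * pred
    new = W + 0.5 * (f0 + f1) * dt + 0.5 * (g0 + g1) * dB
    return _clip_min(new, W_FLOOR)


def hw_segment(W0, network: HWNetwork, params: HWParams, n_steps: int,
               dt: float = 0.01, increments: np.ndarray | None = None):
    """Iterate :func:`hw_heun_step`; generic over floats and tensors."""
    if increments is None:
        increments = np.zeros((n_steps, network.n_destinations))
    W = W0
    out = []
    for k in range(n_steps):
        W = hw_heun_step(W, network, params, dt, increments[k])
        out.append(W)
    return out


def integrate_hw(params: HWParams, network: HWNetwork, n_steps: int,
                 dt: float = 0.01, rng: np.random.Generator | None = None,
                 W0: np.ndarray | None = None) -> StateTrajectory:
    """Integrate the Harris-Wilson SDE from the network's initial sizes."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    W = np.asarray(network.initial_sizes if W0 is None else W0, dtype=float)
    inc = None
    if rng is not None and params.sigma > 0:
        inc = rng.standard_normal((n_steps, len(W))) * np.sqrt(dt)
    states = [W.copy()]
    for k in range(n_steps):
        dB = 0.0 if inc is None else inc[k]
        W = hw_heun_step(W, network, params, dt, dB)
        if not np.all(np.isfinite(W)):
            raise NumericalInstabilityError(
                f"Harris-Wilson integration became non-finite at step {k + 1}",
                step=k + 1,
            )
        states.append(W.copy())
    times = np.arange(n_steps + 1) * dt
    return StateTrajectory(times, np.asarray(states), model_tag="harris-wilson")


def hw_steady_state(params: HWParams, network: HWNetwork, tol: float = 1e-8,
                    dt: float = 0.01, max_steps: int = 100_000) -> np.ndarray:
    """Noiseless steady state ``W* = D(W*) / kappa`` of the zone sizes.

    Integrates the deterministic dynamics until the drift magnitude
    ``sup_j |eps W_j (D_j - kappa W_j)|`` is moderate, then polishes the
    fixed point with the self-consistency iteration ``W <- D(W)/kappa``.
    The two-stage scheme matters when ``alpha > 1``: zones that lose the
    competition for demand decay only algebraically under the dynamics
    (``dW ~ -kappa W^2`` once their demand collapses), while the Picard
    map sends them to zero superlinearly and converges exponentially on
    the surviving zones.  The returned state satisfies
    ``sup_j |dW_j| < tol``; extinct zones are reported as exactly 0.
    The steady state is independent of ``epsilon``, which only sets the
    convergence rate of the dynamics.
    """
    if params.sigma != 0:
        raise ConfigurationError(
            "hw_steady_state requires sigma = 0; use integrate_hw with a "
            "late-time window for the noisy dynamics"
        )
    W = network.initial_sizes.copy()
    coarse = max(np.sqrt(tol), 1e-5)
    resid = np.inf
    for k in range(max_steps):
        f = hw_drift(W, network, params)
        resid = float(np.max(np.abs(f)))
        if resid < coarse:
            break
        W = hw_heun_step(W, network, params, dt, 0.0)
        if not np.all(np.isfinite(W)):
            raise NumericalInstabilityError(
                f"steady-state iteration became non-finite at step {k + 1}",
                step=k + 1,
            )
    for _ in range(10_000):
        _, D = hw_flows(np.maximum(W, 1e-300), network, params.alpha, params.beta)
        W_new = np.asarray(D) / params.kappa
        if float(np.max(np.abs(W_new - W))) < 1e-15:
            W = W_new
            break
        W = W_new
    f = hw_drift(np.maximum(W, 1e-300), network, params)
    resid = float(np.max(np.abs(f)))
    if resid >= tol:
        raise ConvergenceError(
            f"steady state not reached (sup_j |dW_j| = {resid:.3e})",
            residual=resid,
        )
    return W


def hw_balance_residual(W: np.ndarray, network: HWNetwork,
                        params: HWParams) -> float:
    """Max relative violation of the steady-state balance ``D_j = kappa W_j``.

    Evaluated over surviving zones only: zones extinct at the steady
    state (size below ``1e-6`` of the largest, which also covers the
    tiny positivity floor written into stored datasets) satisfy the
    balance in the limit sense ``D_j -> 0`` and carry no relative
    scale.
    """
    W = np.asarray(W, dtype=float)
    alive = W > 1e-6 * W.max()
    _, D = hw_flows(np.maximum(W, 1e-300), network, params.alpha, params.beta)
    D = np.asarray(D)
    return float(np.max(
        np.abs(D[alive] - params.kappa * W[alive]) / (params.kappa * W[alive])
    ))
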