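"""Posterior marginals from the loss potential.

Every optimizer step during calibration visits a point
``(lambda_hat, J)`` of the loss potential.  Interpreting the potential
as a negative log-density (with the uniform prior realized by the
initialization scheme), a posterior weight ``w ~ exp(-J)`` is attached
to every visited sample and one-dimensional marginals are estimated by
a weighted Gaussian kernel density on a regular grid.  Summaries follow
the same conventions throughout: the maximum-likelihood estimate is the
grid argmax, expectations and standard deviations are trapezoidal
quadratures, and peak widths are measured at half height with linear
interpolation between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ConfigurationError, DegenerateSampleError


class AmbiguousMLEError(ValueError):
    """The density has several equally high maxima."""

    def __init__(self, message: str, locations: np.ndarray):
        super().__init__(message)
        self.locations = locations


class NoPeakError(ValueError):
    """No local maximum clears the prominence threshold."""


@dataclass
class MarginalDensity:
    """A gridded, normalized one-dimensional posterior marginal."""

    parameter_name: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)

    @property
    def normalization(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class PeakSummary:
    """Half-height widths of the detected density peaks."""

    peak_locations: np.ndarray
    widths: np.ndarray

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.widths))

    @property
    def width_sd(self) -> float:
        # population SD: exactly 0 for a single peak
        return float(np.std(self.widths))

    @property
    def n_peaks(self) -> int:
        return len(self.widths)


def posterior_weights(losses: np.ndarray) -> np.ndarray:
    """Normalized weights ``w_t ~ exp(-J_t)`` over the visited samples.

    The losses are shifted by their minimum before exponentiation;
    the weight ratio is unchanged and overflow is avoided.  Samples
    with non-finite loss receive weight zero.
    """
    J = np.asarray(losses, dtype=float)
    if J.size == 0:
        raise DegenerateSampleError("no samples given")
    finite = np.isfinite(J)
    if not finite.any():
        raise DegenerateSampleError("all sample losses are non-finite")
    w = np.zeros_like(J)
    w[finite] = np.exp(-(J[finite] - J[finite].min()))
    return w / w.sum()


def box_restricted_weights(samples, losses: np.ndarray,
                           prior_ranges) -> np.ndarray:
    """Posterior weights with the uniform-box prior applied.

    The loss potential is exponentiated against the prior under which
    training started; with a uniform prior over a box, any visited
    proposal outside the box carries zero prior mass, however small
    its loss.  ``samples`` is a mapping (e.g. a DataFrame) holding one
    column per parameter; ``prior_ranges`` maps parameter names to
    ``(lo, hi)``.  The box test is joint: a sample outside the box in
    any coordinate is excluded entirely.
    """
    w = posterior_weights(losses)
    mask = np.ones(len(w), dtype=bool)
    for name, (lo, hi) in dict(prior_ranges).items():
        vals = np.asarray(samples[name], dtype=float)
        mask &= (vals >= lo) & (vals <= hi)
    w = w * mask
    total = w.sum()
    if total == 0:
        raise DegenerateSampleError(
            "no sample with finite loss lies inside the prior box"
        )
    return w / total


def scott_bandwidth(values: np.ndarray, weights: np.ndarray) -> float:
    """Scott's rule on a weighted sample, using the effective sample size."""
    mean = np.average(values, weights=weights)
    var = np.average((values - mean) ** 2, weights=weights)
    n_eff = 1.0 / np.sum(weights**2)
    return float(np.sqrt(var) * n_eff ** (-1 / 5))


def marginal(
    values: np.ndarray,
    losses: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    parameter_name: str = "lambda",
    grid_size: int = 500,
    bandwidth: float | None = None,
) -> MarginalDensity:
    """Weighted Gaussian-kernel marginal of one parameter coordinate.

    ``losses`` are converted to :func:`posterior_weights`; alternatively
    precomputed ``weights`` may be passed directly.  The grid spans the
    sampled range extended by three bandwidths on both sides and the
    result integrates to one.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        if losses is None:
            raise ConfigurationError("either losses or weights must be given")
        weights = posterior_weights(losses)
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    if np.unique(values[weights > 0]).size < 2:
        raise ConfigurationError(
            "need at least two distinct sampled values to estimate a density"
        )
    if bandwidth is None:
        bandwidth = scott_bandwidth(values, weights)
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    grid = np.linspace(values.min() - 3 * bandwidth,
                       values.max() + 3 * bandwidth, grid_size)
    dens = np.zeros_like(grid)
    norm = 1.0 / (np.sqrt(2 * np.pi) * bandwidth)
    # chunk over samples to bound the (n_samples x grid) intermediate
    for a in range(0, len(values), 20_000):
        v = values[a: a + 20_000, None]
        w = weights[a: a + 20_000, None]
        dens += (w * np.exp(-0.5 * ((grid[None, :] - v) / bandwidth) ** 2)).sum(axis=0)
    dens *= norm
    total = np.trapezoid(dens, grid)
    return MarginalDensity(parameter_name, grid, dens / total, float(bandwidth))


def summarize(density: MarginalDensity) -> dict:
    """MLE (grid argmax), expectation and SD (trapezoidal quadrature)."""
    d, x = density.density, density.grid
    top = d.max()
    argmaxes = x[d >= top * (1 - 1e-12)]
    if len(argmaxes) > 1:
        raise AmbiguousMLEError(
            f"{len(argmaxes)} equally high maxima", locations=argmaxes
        )
    mean = float(np.trapezoid(x * d, x))
    var = float(np.trapezoid((x - mean) ** 2 * d, x))
    return {
        "parameter": density.parameter_name,
        "mle": float(argmaxes[0]),
        "expectation": mean,
        "sd": float(np.sqrt(max(var, 0.0))),
    }


def _half_height_crossing(x: np.ndarray, d: np.ndarray, peak: int,
                          half: float, direction: int) -> float:
    """Linearly interpolated abscissa where the density falls to ``half``."""
    i = peak
    while 0 <= i + direction < len(d) and d[i + direction] >= half:
        i += direction
    j = i + direction
    if j < 0 or j >= len(d):
        return x[i]  # shoulder runs off the grid; clip at the edge
    # interpolate between grid points i and j
    frac = (d[i] - half) / (d[i] - d[j])
    return float(x[i] + frac * (x[j] - x[i]))


def peak_widths(density: MarginalDensity,
                prominence: float | None = None) -> PeakSummary:
    """Half-height widths of all peaks above the prominence threshold.

    The default prominence is 5% of the global density maximum.  A
    single detected peak yields a width SD of exactly zero.
    """
    d, x = density.density, density.grid
    if prominence is None:
        prominence = 0.05 * d.max()
    peaks, _ = find_peaks(d, prominence=prominence)
    # a mode at the grid edge has no left/right neighbor for find_peaks
    top = int(d.argmax())
    if top in (0, len(d) - 1) and top not in peaks and d[top] >= prominence:
        peaks = np.sort(np.append(peaks, top))
    if len(peaks) == 0:
        raise NoPeakError("no peak above the prominence threshold")
    locs, widths = [], []
    for p in peaks:
        half = d[p] / 2
        left = _half_height_crossing(x, d, p, half, -1)
        right = _half_height_crossing(x, d, p, half, +1)
        locs.append(x[p])
        widths.append(right - left)
    return PeakSummary(np.asarray(locs), np.asarray(widths))
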