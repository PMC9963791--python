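"""Plotting helpers for marginals, loss potentials and epidemic fits."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_marginal(md, true_value: float | None = None, ax=None):
    """One posterior marginal; optional dotted line at the true value."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(md.grid, md.density, lw=1.5)
    ax.fill_between(md.grid, md.density, alpha=0.25)
    if true_value is not None:
        ax.axvline(true_value, color="crimson", ls=":", lw=1)
    ax.set_xlabel(md.parameter_name)
    ax.set_ylabel("density")
    return ax


def plot_loss_scatter(samples, x: str, y: str, ax=None):
    """Visited (x, y) proposals colored by the negative log loss."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    J = np.maximum(samples["loss"].to_numpy(), 1e-300)
    sc = ax.scatter(samples[x], samples[y], c=-np.log(J), s=2, cmap="viridis")
    plt.colorbar(sc, ax=ax, label="-log J")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax


def plot_sir_fit(densities, ensemble, ax=None):
    """Observed epidemic curves with the calibrated ensemble's mean and band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"S": "tab:green", "I": "tab:red", "R": "tab:olive"}
    obs = densities.states()
    for i, name in enumerate(("S", "I", "R")):
        ax.plot(densities.times, obs[:, i], color=colors[name], lw=1,
                label=f"{name} (observed)")
        ax.plot(ensemble["times"], ensemble["mean"][:, i], color=colors[name],
                ls="--", lw=1)
        ax.fill_between(
            ensemble["times"],
            ensemble["mean"][:, i] - ensemble["sd"][:, i],
            ensemble["mean"][:, i] + ensemble["sd"][:, i],
            color=colors[name], alpha=0.2,
        )
    ax.set_xlabel("t")
    ax.set_ylabel("population fraction")
    ax.legend(fontsize=7)
    return ax
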