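"""Figures: filter shapes, space-time plots, and experiment summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import ExperimentResult
from .filters import make_gabor, make_gaussian, sample_tm, sample_tw, sigma_nl
from .params import ModelParams
from .stimuli import StimulusSequence

__all__ = ["plot_filters", "xt_plot", "plot_result"]


def plot_filters(params: ModelParams | None = None):
    """Overview of the sensor's elements: T_m, T_w, m, w and sigma."""
    params = params or ModelParams()
    fig, axes = plt.subplots(1, 5, figsize=(16, 3))
    tm, tw = sample_tm(params), sample_tw(params)
    axes[0].plot(tm.delays_ms, tm.taps, "o-")
    axes[0].axhline(0, lw=0.5, color="gray")
    axes[0].set(title="$T_m$ (bandpass)", xlabel="delay (ms)")
    axes[1].plot(tw.delays_ms, tw.taps, "o-")
    axes[1].set(title="$T_w$ (lowpass)", xlabel="delay (ms)")
    m, w = make_gaussian(params), make_gabor(params)
    axes[2].imshow(m.weights, cmap="gray")
    axes[2].set(title="m (Gaussian)")
    lim = np.abs(w.weights).max()
    axes[3].imshow(w.weights, cmap="RdBu_r", vmin=-lim, vmax=lim)
    axes[3].set(title="w (odd Gabor)")
    z = np.linspace(-1, 1, 501)
    axes[4].plot(z, sigma_nl(z, params))
    axes[4].set(title=r"$\sigma(z)$", xlabel="luminance difference")
    fig.tight_layout()
    return fig


def xt_plot(seq: StimulusSequence, row: int | None = None):
    """Space-time (x-t) plot of one stimulus row; motion shows as slant."""
    row = seq.frames.shape[1] // 2 if row is None else row
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [0, seq.frames.shape[2] * seq.deg_per_px, seq.duration_s, 0]
    ax.imshow(seq.frames[:, row, :], cmap="gray", aspect="auto", extent=extent)
    ax.set(xlabel="space (deg)", ylabel="time (s)")
    return fig


def plot_result(result: ExperimentResult):
    """Render an ExperimentResult: bars, a curve, or a heat map as fits."""
    if result.responses.ndim == 2:
        return _plot_map(result)
    grid_name = next(iter(result.variable_grid))
    grid = result.variable_grid[grid_name]
    if isinstance(grid, (list, tuple)) or getattr(grid, "dtype", None) == object:
        return _plot_bars(result, grid_name)
    return _plot_curve(result, grid_name)


def _plot_bars(result, grid_name):
    labels = list(result.variable_grid[grid_name])
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    colors = ["tab:blue" if v >= 0 else "tab:red" for v in result.responses]
    ax.bar(labels, result.responses, yerr=result.dispersion, color=colors, capsize=4)
    ax.axhline(0, color="k", lw=0.8)
    ax.set(ylabel="MS-INRF response", title=result.name)
    fig.tight_layout()
    return fig


def _plot_curve(result, grid_name):
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(result.variable_grid[grid_name], dtype=float)
    ax.errorbar(x, result.responses, yerr=result.dispersion, fmt="o-", capsize=3)
    if "unmasked_response" in result.extras:
        ax.axhline(result.extras["unmasked_response"], color="tab:orange",
                   label="signal alone")
        ax.legend()
    ax.set(xlabel=grid_name, ylabel="MS-INRF response", title=result.name)
    fig.tight_layout()
    return fig


def _plot_map(result):
    names = list(result.variable_grid)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    g0 = np.asarray(result.variable_grid[names[0]], dtype=float)
    g1 = np.asarray(result.variable_grid[names[1]], dtype=float)
    im = ax.pcolormesh(g1, g0, result.responses, shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="MS-INRF response")
    ax.set(xlabel=names[1], ylabel=names[0], title=result.name)
    fig.tight_layout()
    return fig
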