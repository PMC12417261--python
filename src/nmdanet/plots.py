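"""Figure helpers: rasters with population activity, error traces,
psychometric curves with bootstrap error bars, sweep heatmaps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import weibull  # noqa: E402

__all__ = ["plot_raster_activity", "plot_error_traces", "plot_psychometric",
           "plot_sweep_heatmap"]


def plot_raster_activity(result, trial=0, pops=("EA", "EB"), max_neurons=100, ax=None):
    """Spike raster of the selective populations over the binned activity."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5)) \
        if ax is None else (None, ax)
    t, n = result.spikes_of(trial)
    sl = {p: s for p, s in zip(result.pop_names,
                               _slices(result.pop_names, result.pop_sizes))}
    y0 = 0
    for p in pops:
        s = sl[p]
        m = (n >= s.start) & (n < min(s.stop, s.start + max_neurons))
        ax1.plot(t[m], n[m] - s.start + y0, ".", ms=1, label=p)
        y0 += min(s.stop - s.start, max_neurons)
    ax1.set_ylabel("neuron")
    ax1.legend(loc="upper right", fontsize=8)
    bins = (np.arange(result.pop_rates.shape[1]) + 0.5) * result.rate_bin
    for p in pops:
        ax2.plot(bins, result.pop_rates[trial, :, result.pop_names.index(p)], label=p)
    ax2.set_xlabel("time (ms)")
    ax2.set_ylabel("rate (spikes/s)")
    return fig


def _slices(names, sizes):
    o = 0
    for s in sizes:
        yield slice(o, o + s)
        o += s


def plot_error_traces(err, ax=None):
    """Current and voltage error traces from an error experiment."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5)) \
        if ax is None else (None, ax)
    ax1.plot(err.times, err.i_error, lw=0.8)
    ax1.set_ylabel("I_NMDA error (pA)")
    ax2.plot(err.times, err.v_error, lw=0.8)
    ax2.set_ylabel("V error (mV)")
    ax2.set_xlabel("time (ms)")
    return fig


def plot_psychometric(table, fit=None, ax=None):
    """Proportion correct vs coherence with bootstrap error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    c = table["coherence"].to_numpy(dtype=float)
    p = table["p_correct"].to_numpy(dtype=float)
    yerr = np.vstack([p - table["ci_low"], table["ci_high"] - p])
    ax.errorbar(c, p, yerr=yerr, fmt="o", capsize=3)
    if fit is not None:
        cc = np.geomspace(max(c.min(), 0.5), c.max(), 200)
        ax.plot(cc, weibull(cc, fit.alpha, fit.beta), "k-", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("coherence c' (%)")
    ax.set_ylabel("P(correct)")
    ax.set_ylim(0, 1.05)
    return ax.figure


def plot_sweep_heatmap(table, value="E_SA_minus_SB", ax=None):
    """Heatmap of a sweep statistic over the connectivity grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    piv = table.pivot(index="eps_inhibitory", columns="eps_selective", values=value)
    im = ax.imshow(piv.to_numpy(), origin="lower", aspect="auto",
                   extent=[piv.columns.min(), piv.columns.max(),
                           piv.index.min(), piv.index.max()])
    ax.figure.colorbar(im, ax=ax, label=value)
    ax.set_xlabel("intra-selective connectivity")
    ax.set_ylabel("inhibitory-selective connectivity")
    return ax.figure
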