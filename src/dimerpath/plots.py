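"""Diagnostic plots for path-sampling runs."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_tp_accounting", "plot_committor_validation"]


def plot_tp_accounting(n_generated: np.ndarray, n_expected: np.ndarray,
                       path=None):
    """Cumulative generated vs expected TP counts and their difference.

    A flattening difference curve indicates the committor model has become
    calibrated: it predicts as many transition paths as are being generated.
    """
    fig, ax = plt.subplots(figsize=(5, 3.4))
    steps = np.arange(1, len(n_generated) + 1)
    ax.plot(steps, n_generated, label=r"$N_\mathrm{generated}$")
    ax.plot(steps, n_expected, label=r"$N_\mathrm{expected}$")
    ax.plot(steps, n_generated - n_expected, label="difference")
    ax.set_xlabel("MC step")
    ax.set_ylabel("cumulative TP count")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_committor_validation(sampled, predicted, ci_low=None, ci_high=None,
                              path=None):
    """Predicted vs sampled committor scatter with the identity diagonal."""
    sampled = np.asarray(sampled, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    if ci_low is not None and ci_high is not None:
        yerr = np.vstack([sampled - np.asarray(ci_low),
                          np.asarray(ci_high) - sampled])
        ax.errorbar(predicted, sampled, yerr=yerr, fmt="o", ms=4, capsize=2)
    else:
        ax.plot(predicted, sampled, "o", ms=4)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel(r"predicted $p_B$")
    ax.set_ylabel(r"sampled $p_B$")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
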