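"""Diagnostic figures: rate-vs-baseline scatter and the anchored trajectory."""

from __future__ import annotations

import numpy as np

from .trajectory import ControlAgingModel, PremotorEstimate


def plot_rate_scatter(ax, rate_samples, rate_function=None, show_outliers=True):
    """Annual change against baseline SBR with the fitted RCS curve.

    Flagged outliers are hidden when ``show_outliers`` is False but are
    always part of the fit.
    """
    xs = np.array([s.baseline_sbr for s in rate_samples])
    ys = np.array([s.annual_change for s in rate_samples])
    flags = np.array([s.outlier_flag for s in rate_samples])
    keep = np.ones_like(flags, bool) if show_outliers else ~flags
    ax.scatter(xs[keep], ys[keep], s=12, alpha=0.5, color="tab:gray",
               label="putamina")
    if rate_function is not None:
        grid = np.linspace(xs.min(), xs.max(), 200)
        ax.plot(grid, rate_function(grid), color="tab:red", lw=2, label="RCS fit")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("baseline putaminal SBR")
    ax.set_ylabel("annual change (SBR/year)")
    ax.legend(frameon=False)
    return ax


def plot_trajectory(ax, estimate: PremotorEstimate, age_axis: bool = True):
    """Estimated SBR trajectory with the control aging line and onset marks."""
    traj = estimate.trajectory
    x = traj.ages if age_axis else traj.times
    ax.plot(x, traj.values, color="tab:blue", lw=2, label="PD-state trajectory")
    cm: ControlAgingModel = estimate.control_model
    if age_axis:
        ax.plot(x, cm(traj.ages), color="tab:green", lw=1.5, ls="--",
                label="control aging line")
        ax.axvline(estimate.onset_age, color="tab:orange", lw=1,
                   label="degeneration onset")
        ax.axvline(estimate.motor_onset_age, color="tab:red", lw=1,
                   label="motor onset")
        ax.set_xlabel("age (years)")
    else:
        ax.set_xlabel("disease duration (years)")
    ax.set_ylabel("putaminal SBR")
    ax.legend(frameon=False, fontsize=8)
    return ax
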