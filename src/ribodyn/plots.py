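"""Figure rendering: trajectory panels, asymptotic overlays, scan curves.

All functions are side-effect-free on the numeric results: they consume
already-computed trajectories/solutions and only write image files.
"""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core_models import Trajectory
from .nonlinear_asymptotics import PiecewiseSolution

__all__ = ["trajectory_panels", "overlay_figure", "scan_figure"]

_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _check_traj(traj: Trajectory) -> None:
    if len(traj.times) < 2:
        raise ValueError("trajectory is empty; nothing to plot")


def trajectory_panels(traj: Trajectory, path: str) -> str:
    """Four panels: species and fluxes, each on log and linear time."""
    _check_traj(traj)
    fig, axes = plt.subplots(2, 2, figsize=(11, 7))
    t = traj.times
    pos = t > 0
    for ax, log in zip(axes[0], (True, False)):
        for j, name in enumerate(traj.species):
            ax.plot(t[pos] if log else t, traj.states[pos, j] if log else
                    traj.states[:, j], label=name.lstrip("c_").lstrip("c"))
        if log:
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_ylim(bottom=1e-4)
        ax.set_xlabel("time (model units)")
        ax.set_ylabel("concentration")
        ax.legend(fontsize=7)
    for ax, log in zip(axes[1], (True, False)):
        for j in range(traj.fluxes.shape[1]):
            ax.plot(t[pos] if log else t, traj.fluxes[pos, j] if log else
                    traj.fluxes[:, j], label=f"w{j + 1}")
        if log:
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_ylim(bottom=1e-6)
        ax.set_xlabel("time (model units)")
        ax.set_ylabel("reaction flux")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def overlay_figure(
    solution: PiecewiseSolution, traj: Trajectory, path: str
) -> str:
    """Numeric (markers) vs staged-analytic (lines) species, log-log axes.

    Vertical dashed guides mark the estimated transition times.
    """
    _check_traj(traj)
    fig, ax = plt.subplots(figsize=(8, 5.5))
    t = traj.times[traj.times > 0]
    approx = solution.evaluate(t)
    for j, name in enumerate(traj.species):
        color = _COLORS[j % len(_COLORS)]
        ax.plot(t[::12], traj.states[traj.times > 0][::12, j], "o",
                ms=3.2, color=color, alpha=0.6)
        ax.plot(t, approx[:, j], "-", color=color, lw=1.3,
                label=name.lstrip("c_").lstrip("c"))
    for guide in (
        solution.transitions.t_dprime,
        solution.transitions.t_tprime,
    ):
        if np.isfinite(guide):
            ax.axvline(guide, ls="--", color="k", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_ylim(bottom=1e-4)
    ax.set_xlabel("time (model units)")
    ax.set_ylabel("concentration")
    ax.set_title(f"numeric (markers) vs staged solution ({solution.route})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def scan_figure(scans: Iterable, path: str) -> str:
    """Steady rate and relaxation time vs inhibition factor (log-log)."""
    scans = list(scans)
    if not scans:
        raise ValueError("no scans to plot")
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.2))
    for scan in scans:
        label = f"{scan.setting}/{scan.mechanism}"
        ax1.plot(scan.factors, scan.steady_rates, "-o", ms=3, label=label)
        ax2.plot(scan.factors, scan.relaxation_times, "-o", ms=3, label=label)
    for ax, ylabel in ((ax1, "steady protein synthesis rate"),
                       (ax2, "relaxation time")):
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.invert_xaxis()
        ax.set_xlabel("inhibition factor")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
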