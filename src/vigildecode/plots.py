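"""Figure rendering from serialized results (never recomputes analysis).

Two figure families mirror the standard presentation of this analysis:
an array of temporal-generalization matrices over state pairs with
significance dots, and disc-interpolated scalp topographies of the
forward-model patterns at selected latencies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

from .forward_model import TopographyMap

__all__ = ["plot_grid", "plot_topography", "plot_tgm"]


def plot_tgm(ax, scores, train_times, test_times, mask=None, vlim=(0.4, 0.6)):
    im = ax.imshow(
        scores, origin="lower", aspect="auto", cmap="RdBu_r",
        vmin=vlim[0], vmax=vlim[1],
        extent=[test_times[0], test_times[-1], train_times[0], train_times[-1]],
    )
    if mask is not None and mask.any():
        ii, jj = np.nonzero(mask)
        ax.plot(test_times[jj], train_times[ii], "k.", ms=2)
    ax.axhline(0, color="k", lw=0.4)
    ax.axvline(0, color="k", lw=0.4)
    return im


def plot_grid(grid, contrast: str, path) -> Path:
    """Array of group-mean TGMs (train state = row, test state = column)
    with BH-significant cells dotted."""
    states = grid.states
    n = len(states)
    fig, axes = plt.subplots(n, n, figsize=(2.2 * n, 2.2 * n), squeeze=False)
    im = None
    for i, a in enumerate(states):
        for j, b in enumerate(states):
            res = grid.entries[(a, b, contrast)]
            im = plot_tgm(
                axes[i][j], res.group_mean.scores, res.group_mean.train_times,
                res.group_mean.test_times, mask=res.stat.mask,
            )
            if i == 0:
                axes[i][j].set_title(f"test {b}", fontsize=9)
            if j == 0:
                axes[i][j].set_ylabel(f"train {a}", fontsize=9)
    fig.suptitle(f"{contrast}: cross-generalization accuracy")
    fig.colorbar(im, ax=[ax for row in axes for ax in row], shrink=0.5,
                 label="accuracy")
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_topography(
    topo: TopographyMap, path, times: Optional[Sequence[float]] = None
) -> Path:
    """Interpolated scalp maps of the activation pattern at selected
    latencies (default: five evenly spaced times)."""
    if times is None:
        times = np.linspace(topo.times[0], topo.times[-1], 5)
    pos = topo.layout.positions
    grid_x, grid_y = np.mgrid[-1:1:101j, -1:1:101j]
    outside = grid_x**2 + grid_y**2 > 1.0
    vmax = np.abs(topo.patterns).max() or 1.0
    fig, axes = plt.subplots(1, len(times), figsize=(2.0 * len(times), 2.4),
                             squeeze=False)
    for ax, t in zip(axes[0], times):
        k = int(np.argmin(np.abs(topo.times - t)))
        vals = griddata(pos, topo.patterns[:, k], (grid_x, grid_y),
                        method="cubic")
        vals[outside] = np.nan
        ax.imshow(vals.T, origin="lower", extent=[-1, 1, -1, 1],
                  cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1))
        ax.plot(pos[:, 0], pos[:, 1], "k.", ms=1)
        ax.set_title(f"{topo.times[k]:.2f} s", fontsize=9)
        ax.set_axis_off()
    fig.suptitle(f"{topo.contrast or ''} {topo.state} pattern ({topo.units})")
    path = Path(path)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path
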