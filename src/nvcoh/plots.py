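"""Display helpers: coherence maps, z-maps with cluster contours,
band-averaged group trajectories."""

from __future__ import annotations

import numpy as np

from .cluster import ClusterTestResult
from .wtc import CoherenceMap


def plot_coherence_map(cmap: CoherenceMap, ax=None, show_coi: bool = True,
                       vmin: float = 0.0, vmax: float = 1.0):
    """Time x period heat map of R2 (red = strong coupling), COI hatched."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(cmap.time_h, cmap.periods_min,
                         np.ma.masked_invalid(cmap.r2),
                         cmap="jet", vmin=vmin, vmax=vmax, shading="nearest")
    if show_coi:
        ax.plot(cmap.time_h, cmap.coi_min, "w--", lw=1)
    ax.set_yscale("log")
    ax.set_ylim(cmap.periods_min[0], cmap.periods_min[-1])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("period (min)")
    ax.figure.colorbar(mesh, ax=ax, label=r"$R^2$")
    return ax


def plot_cluster_zmap(result: ClusterTestResult, ax=None):
    """Z-statistic map with black contours around significant clusters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.time_h if result.time_h is not None else np.arange(result.z_map.shape[1])
    p = (result.periods_min if result.periods_min is not None
         else np.arange(result.z_map.shape[0]))
    lim = np.nanmax(np.abs(result.z_map))
    mesh = ax.pcolormesh(t, p, np.ma.masked_invalid(result.z_map),
                         cmap="RdBu_r", vmin=-lim, vmax=lim, shading="nearest")
    if result.significant_mask.any():
        ax.contour(t, p, result.significant_mask.astype(float), levels=[0.5],
                   colors="k", linewidths=1.5)
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("period (min)")
    ax.figure.colorbar(mesh, ax=ax, label="Z")
    return ax


def plot_group_trajectories(df, ax=None):
    """Group mean +- SEM of the band-averaged coherence over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"A": "tab:blue", "B": "tab:red"}
    names = {"A": "non-TH", "B": "TH"}
    for g, sub in df.groupby("group"):
        agg = sub.groupby("time_h")["nvc"].agg(["mean", "sem"])
        ax.plot(agg.index, agg["mean"], color=colors.get(g, None),
                label=names.get(g, g))
        ax.fill_between(agg.index, agg["mean"] - agg["sem"],
                        agg["mean"] + agg["sem"],
                        color=colors.get(g, None), alpha=0.3)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("band-mean $R^2$")
    ax.legend()
    return ax
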