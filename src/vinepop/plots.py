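"""Diagnostic plots: marginal density overlays and contour overlays.

Matplotlib is imported lazily so headless library use never touches a GUI
backend; pass a filename to save, or receive the figure for further styling.
"""

from __future__ import annotations

import numpy as np

from .evaluate import _kde2d, _modelling_scale, density_contour
from .table import CovariateTable


def _get_plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_marginal_densities(obs: CovariateTable, sims: list[CovariateTable], path=None, max_cols=4):
    """Observed density curve (orange) with simulated replicates (grey)."""
    plt = _get_plt()
    cont = obs.continuous
    ncol = min(max_cols, len(cont))
    nrow = int(np.ceil(len(cont) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for k, name in enumerate(cont):
        ax = axes[k // ncol][k % ncol]
        for sim in sims:
            v = np.asarray(sim.values(name), float)
            v = v[~np.isnan(v)]
            if v.size > 1:
                xs, ys = _density_curve(v)
                ax.plot(xs, ys, color="0.6", lw=0.8, alpha=0.7)
        v = np.asarray(obs.values(name), float)
        v = v[~np.isnan(v)]
        xs, ys = _density_curve(v)
        ax.plot(xs, ys, color="tab:orange", lw=1.6)
        ax.set_title(name, fontsize=9)
    for k in range(len(cont), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _density_curve(v, points=200):
    from scipy.stats import gaussian_kde

    xs = np.linspace(v.min(), v.max(), points)
    return xs, gaussian_kde(v)(xs)


def plot_contour_overlay(obs: CovariateTable, sim: CovariateTable, x: str, y: str,
                         mass: float = 0.95, path=None):
    """95% HDR contours of observed (orange, dashed) vs simulated (grey)."""
    plt = _get_plt()
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    for table, color, ls in ((sim, "0.4", "-"), (obs, "tab:orange", "--")):
        xv = _modelling_scale(table, x)
        yv = _modelling_scale(table, y)
        ok = ~(np.isnan(xv) | np.isnan(yv))
        c = density_contour(xv[ok], yv[ok], mass=mass, x_name=x, y_name=y)
        geoms = c.region.geoms if c.region.geom_type == "MultiPolygon" else [c.region]
        for g in geoms:
            xs, ys = g.exterior.xy
            ax.plot(xs, ys, color=color, ls=ls, lw=1.4)
    ax.set_xlabel(f"log {x}" if obs.spec(x).log_scale else x)
    ax.set_ylabel(f"log {y}" if obs.spec(y).log_scale else y)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
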