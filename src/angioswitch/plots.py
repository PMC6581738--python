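"""Optional matplotlib renders of the analysis outputs (cosmetic only)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_hysteresis", "plot_matrix_pair", "plot_cusp"]


def _axes():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_hysteresis(result, path):
    """Winning-cell DLL4 vs VEGF for the up and down sweep legs."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.v_up, result.dll4_up, "-o", ms=2.5, label="VEGF up")
    ax.plot(result.v_down, result.dll4_down, "-o", ms=2.5, label="VEGF down")
    ax.axhline(result.tip_threshold, color="grey", lw=0.8, ls="--")
    for v, lbl in ((result.switch_on_vegf, "on"),
                   (result.switch_off_vegf, "off")):
        if v is not None:
            ax.axvline(v, color="k", lw=0.6, ls=":")
    ax.set_xlabel("VEGF (model units)")
    ax.set_ylabel("winning-cell DLL4 (c.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_matrix_pair(matrix_off, matrix_on, path):
    """Side-by-side patterning-time heatmaps (feedback off / on)."""
    plt = _axes()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    vmax = np.nanmax([np.nanmax(matrix_off.times), np.nanmax(matrix_on.times)])
    for ax, m, title in ((axes[0], matrix_off, "feedback off"),
                         (axes[1], matrix_on, "feedback on")):
        img = np.where(m.resolved, m.times, np.nan)
        h = ax.pcolormesh(m.v_grid, m.v_grid, img.T, shading="nearest",
                          vmin=0, vmax=vmax, cmap="viridis")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title(title)
        ax.set_xlabel("V_A (c.u.)")
    axes[0].set_ylabel("V_B (c.u.)")
    fig.colorbar(h, ax=axes, label="patterning time")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cusp(cusp, path):
    """Bistable region in the (VEGF, feedback-production) plane."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    fb = np.where(cusp.fb_grid > 0, cusp.fb_grid, np.nan)
    ax.pcolormesh(cusp.v_grid, np.arange(cusp.fb_grid.size),
                  cusp.bistable.astype(float), shading="nearest",
                  cmap="Greens")
    ax.set_yticks(np.arange(cusp.fb_grid.size)[::4])
    ax.set_yticklabels([f"{v:g}" for v in cusp.fb_grid[::4]])
    ax.set_xlabel("VEGF (model units)")
    ax.set_ylabel("feedback production fb_prod")
    ax.set_title("bistable region")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
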