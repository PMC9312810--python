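"""Rendering of landscapes, step vectors, contact planes and timelines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_landscape", "plot_profile", "plot_step_vectors",
           "plot_pande_rokhsar", "plot_ss_timeline"]


def _save(fig, path):
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig


def plot_landscape(grid, path=None, out=None):
    """Contour map of DeltaF with the reaction path overlaid (if given).

    Empty bins are displayed capped at max occupied DeltaF + RT.
    """
    dF = grid.deltaF.copy()
    cap = dF[np.isfinite(dF)].max() + (grid.RT or 1.0)
    dF[~np.isfinite(dF)] = cap
    xs = np.linspace(*grid.bounds[0], grid.n_bins[0] + 1)
    ys = np.linspace(*grid.bounds[1], grid.n_bins[1] + 1)
    xc = (xs[:-1] + xs[1:]) / 2
    yc = (ys[:-1] + ys[1:]) / 2
    fig, ax = plt.subplots(figsize=(5, 4))
    cf = ax.contourf(xc, yc, dF.T, levels=15, cmap="viridis")
    fig.colorbar(cf, ax=ax, label=r"$\Delta F$ (kcal/mol)")
    if path is not None:
        pts = np.array([grid.bin_center(b) for b in path.bin_sequence])
        ax.plot(pts[:, 0], pts[:, 1], "r-", lw=1.5, label="reaction path")
        ax.legend(loc="best")
    ax.set_xlabel("RMSD-space axis 1 (A)")
    ax.set_ylabel("RMSD-space axis 2 (A)")
    return _save(fig, out)


def plot_profile(path, out=None):
    """1D free-energy profile along the reaction coordinate."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(path.arc_length, path.profile, "-o", ms=2)
    ax.axhline(path.profile.max(), ls="--", color="grey", lw=0.8)
    ax.set_xlabel("reaction coordinate arc length (A)")
    ax.set_ylabel(r"$\Delta F$ (kcal/mol)")
    return _save(fig, out)


def plot_step_vectors(steps, exit=None, out=None):
    """2D projection of step-vector terminals; exit frame highlighted."""
    t = steps.terminals
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(t[:, 0], t[:, 1], "-", lw=0.3, color="steelblue", alpha=0.7)
    ax.scatter(t[:, 0], t[:, 1], s=2, c=np.arange(len(t)), cmap="plasma")
    if exit is not None and exit.found:
        ax.scatter(*t[exit.exit_frame, :2], s=60, c="red", zorder=5,
                   label=f"exit frame {exit.exit_frame}")
        ax.legend(loc="best")
    ax.set_xlabel("RMSD-space axis 1 (A)")
    ax.set_ylabel("RMSD-space axis 2 (A)")
    return _save(fig, out)


def plot_pande_rokhsar(series, classes=None, out=None):
    """Native vs total contact counts per frame, coloured by class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if classes is None:
        ax.scatter(series.total, series.Q, s=4)
    else:
        for cls, color in (("native", "tab:green"),
                           ("molten_globule", "tab:orange"),
                           ("unfolded", "tab:red")):
            sel = np.asarray(classes) == cls
            ax.scatter(series.total[sel], series.Q[sel], s=4, c=color, label=cls)
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("total contacts")
    ax.set_ylabel("native contacts")
    return _save(fig, out)


def plot_ss_timeline(ss, frame_interval=1.0, out=None):
    """Secondary-structure raster: residues x time, H/E/C coloured."""
    code = np.zeros(ss.labels.shape, dtype=int)
    code[ss.labels == "H"] = 1
    code[ss.labels == "E"] = 2
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(code.T, aspect="auto", origin="lower", cmap="viridis",
                   extent=[0, code.shape[0] * frame_interval, 0, code.shape[1]])
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("residue")
    fig.colorbar(im, ax=ax, ticks=[0, 1, 2], label="C / H / E")
    return _save(fig, out)
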