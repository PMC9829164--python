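"""Figure export: spatiotemporal voltage maps, CL-stacked panels and the
category map of a parameter sweep.

Colour key for categories: control green, no excitation gray, AP
prolongation blue, AP alternans yellow, EAD events red; numeric failures
black, missing runs white.
"""

from __future__ import annotations

from typing import Dict, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .sweep import SweepResult
from .tissue import SimulationResult

CATEGORY_COLORS: Dict[str, str] = {
    "control": "#2ca02c",          # green
    "no_excitation": "#7f7f7f",    # gray
    "ap_prolongation": "#1f77b4",  # blue
    "ap_alternans": "#ffdf00",     # yellow
    "ead": "#d62728",              # red
    "numeric_failure": "#000000",
    "missing": "#ffffff",
}

_CATEGORY_ORDER = ("control", "no_excitation", "ap_prolongation",
                   "ap_alternans", "ead", "numeric_failure", "missing")


def render_voltage_map(result: SimulationResult, path=None, ax=None,
                       cmap: str = "turbo"):
    """Cells x time colour map of membrane potential (strand convention:
    Purkinje end at the top)."""
    own = ax is None
    if own:
        fig, ax = plt.subplots(figsize=(8, 3))
    extent = [result.times[0], result.times[-1], result.n_cells, 0]
    im = ax.imshow(result.v, aspect="auto", extent=extent, cmap=cmap,
                   vmin=-90, vmax=40)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell")
    if own:
        plt.colorbar(im, ax=ax, label="V (mV)")
        if path is not None:
            plt.savefig(path, dpi=110, bbox_inches="tight")
            plt.close()
            return None
        return ax.figure
    return im


def render_stacked_maps(results: Sequence[SimulationResult], path=None):
    """One panel per run, ordered by cycle length, shortest CL on top."""
    ordered = sorted(results, key=lambda r: r.protocol.cl)
    n = len(ordered)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.2 * n), squeeze=False)
    for ax, res in zip(axes[:, 0], ordered):
        render_voltage_map(res, ax=ax)
        ax.set_ylabel(f"CL {res.protocol.cl:.0f}", fontsize=7)
        ax.set_xlabel("")
        ax.tick_params(labelsize=6)
    axes[-1, 0].set_xlabel("time (ms)")
    if path is not None:
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def render_category_map(sweep: SweepResult, path=None):
    """Per-CL panels of the (S_Kr block x S_CaL block) category grid."""
    grid = sweep.grid
    by_key = {(r.s_kr_block, r.s_cal_block, r.cl): r.category
              for r in sweep.records}
    idx = {c: i for i, c in enumerate(_CATEGORY_ORDER)}
    cmap = ListedColormap([CATEGORY_COLORS[c] for c in _CATEGORY_ORDER])
    n_cl = len(grid.cls)
    ncols = min(4, n_cl)
    nrows = int(np.ceil(n_cl / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.8 * nrows),
                             squeeze=False)
    for k, cl in enumerate(grid.cls):
        ax = axes[k // ncols, k % ncols]
        mat = np.full((len(grid.s_kr_levels), len(grid.s_cal_levels)),
                      idx["missing"], dtype=float)
        for i, kr in enumerate(grid.s_kr_levels):
            for j, cal in enumerate(grid.s_cal_levels):
                cat = by_key.get((kr, cal, cl))
                if cat is not None:
                    mat[i, j] = idx.get(cat, idx["missing"])
        ax.imshow(mat, cmap=cmap, vmin=-0.5, vmax=len(_CATEGORY_ORDER) - 0.5,
                  origin="lower", aspect="auto")
        ax.set_xticks(range(len(grid.s_cal_levels)),
                      [f"{v:g}" for v in grid.s_cal_levels], fontsize=6)
        ax.set_yticks(range(len(grid.s_kr_levels)),
                      [f"{v:g}" for v in grid.s_kr_levels], fontsize=6)
        ax.set_xlabel("S_CaL block", fontsize=7)
        ax.set_ylabel("S_Kr block", fontsize=7)
        ax.set_title(f"CL = {cl:.0f} ms", fontsize=8)
    for k in range(n_cl, nrows * ncols):
        axes[k // ncols, k % ncols].axis("off")
    handles = [plt.Rectangle((0, 0), 1, 1, color=CATEGORY_COLORS[c])
               for c in _CATEGORY_ORDER[:5]]
    fig.legend(handles, _CATEGORY_ORDER[:5], loc="lower center", ncol=5,
               fontsize=7)
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return None
    return fig
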