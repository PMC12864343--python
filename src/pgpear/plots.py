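"""Optional matplotlib renderings of EAR curves and sweep heatmaps."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .ear import EarResult, SweepResult

__all__ = ["plot_ear_curves", "plot_sweep_heatmap"]


def plot_ear_curves(results: Iterable[EarResult], ax=None):
    """Line plot of rEAR vs expression fraction, one line per drug.

    The dashed diagonal marks a perfectly linear expression-activity
    relationship (rEAR_x% = x%).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    lo, hi = np.inf, -np.inf
    for res in results:
        ax.plot(res.fractions, res.rear, marker="o", label=res.drug)
        lo = min(lo, min(res.fractions))
        hi = max(hi, max(res.fractions))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="linear EAR")
    ax.set_xlabel("P-gp expression (% of reference)")
    ax.set_ylabel("rEAR (%)")
    ax.legend(fontsize=8)
    return ax


def plot_sweep_heatmap(sweep: SweepResult, value_col: str | None = None):
    """Heatmap grid of rEAR_50% over (k_e, k_off), faceted by dose and P-gp.

    The colour scale is anchored at 50% (linear, red) and 100%
    (non-linear, green).
    """
    import matplotlib.pyplot as plt

    frame = sweep.frame
    if value_col is None:
        value_col = [c for c in frame.columns if c.startswith("rEAR_")][0]
    doses = sorted(frame["dose_um"].unique())
    pgps = sorted(frame["pgp_um"].unique())
    fig, axes = plt.subplots(
        len(doses), len(pgps),
        figsize=(3 * len(pgps), 2.5 * len(doses)),
        squeeze=False,
    )
    for i, dose in enumerate(doses):
        for j, pgp in enumerate(pgps):
            ax = axes[i][j]
            sub = frame[(frame["dose_um"] == dose) & (frame["pgp_um"] == pgp)]
            pivot = sub.pivot_table(
                index="k_off_per_s", columns="k_e_per_s", values=value_col
            ).sort_index(ascending=True)
            mesh = ax.pcolormesh(
                pivot.columns, pivot.index, pivot.values,
                cmap="RdYlGn", vmin=50, vmax=100, shading="nearest",
            )
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_title(f"dose {dose:g} uM, P-gp {pgp:g} uM", fontsize=8)
            if i == len(doses) - 1:
                ax.set_xlabel("k_e (1/s)")
            if j == 0:
                ax.set_ylabel("k_off (1/s)")
    fig.colorbar(mesh, ax=axes, label="rEAR_50% (%)", shrink=0.8)
    return fig
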