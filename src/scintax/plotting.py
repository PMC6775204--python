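"""Diagnostic plots: field activation heat maps with centroid overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt

from .scenarios import SimulationResult

__all__ = ["field_heatmap"]


def field_heatmap(result: SimulationResult, field_id: str, ax=None):
    """Field activation over time (brighter = more activation) with the
    centroid (dynamic target) and tract-variable trajectories overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    u = result.field_activation[field_id]
    extent = [result.times[0], result.times[-1], 0.0, 1.0]
    ax.imshow(u.T, origin="lower", aspect="auto", extent=extent, cmap="magma")
    ax.plot(result.times, result.targets[field_id], color="lime", lw=1.2,
            label="dynamic target (centroid)")
    ax.plot(result.times, result.tract[field_id], color="cyan", lw=1.2, ls="--",
            label="tract variable")
    for ep in result.epochs:
        ax.axvline(ep.start, color="w", lw=0.5, alpha=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"{field_id} parameter x")
    ax.legend(loc="upper right", fontsize=7)
    return ax
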