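"""Minimal PNG exports: flux heatmaps and labelled trace plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .detect import InflectionLabels
from .flux_io import FluxTrace
from .speckle_contrast import (
    DEFAULT_CONTRAST_FLOOR,
    DEFAULT_WINDOW,
    SpeckleStack,
    flux_from_contrast,
    spatial_contrast,
)

__all__ = ["save_flux_heatmap", "save_trace_plot"]


def save_flux_heatmap(stack: SpeckleStack, path: str | Path,
                      window_size: int = DEFAULT_WINDOW,
                      contrast_floor: float = DEFAULT_CONTRAST_FLOOR,
                      frame: int = 0) -> Path:
    """Render one frame's flux map as a pseudo-colour PNG."""
    cmap = spatial_contrast(stack, window_size)[frame]
    fmap = flux_from_contrast(cmap, contrast_floor)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(np.where(fmap.valid_mask, fmap.values, np.nan), cmap="inferno")
    fig.colorbar(im, ax=ax, label="flux (arbitrary units)")
    ax.set_title(f"flux map, frame {frame}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_trace_plot(trace: FluxTrace, path: str | Path,
                    labels: InflectionLabels | None = None) -> Path:
    """Plot a flux trace, marking accepted highs/lows and rejected extrema."""
    fig, ax = plt.subplots(figsize=(8, 3))
    t = trace.times_s
    ax.plot(t, trace.values, lw=0.8, color="0.3")
    if labels is not None:
        ax.plot(t[labels.highs], trace.values[labels.highs], "o", ms=4,
                color="tab:green", label="diastolic high")
        ax.plot(t[labels.lows], trace.values[labels.lows], "o", ms=4,
                color="tab:blue", label="systolic low")
        if labels.rejected.size:
            ax.plot(t[labels.rejected], trace.values[labels.rejected], "o", ms=4,
                    mfc="white", mec="0.5", label="rejected")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("flux (a.u.)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
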