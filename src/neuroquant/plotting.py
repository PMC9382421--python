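"""Basic raster and synchrony-heatmap export (PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import WellRecording
from .synchrony import PairResult


def raster_plot(recording: WellRecording, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(8, 3))
    for i, eid in enumerate(recording.electrode_ids):
        t = recording.spike_trains[eid]
        ax.vlines(t, i + 0.6, i + 1.4, lw=0.5, color="k")
    ax.set_yticks(range(1, len(recording.electrode_ids) + 1))
    ax.set_yticklabels(recording.electrode_ids)
    ax.set_xlabel("time (s)")
    ax.set_title(recording.well_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def correlation_heatmap(results: list[PairResult], electrode_ids, path: str | Path) -> Path:
    """9x9 heatmap of pairwise r, electrodes in E1..E9 order."""
    ids = list(electrode_ids)
    n = len(ids)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for res in results:
        if np.isnan(res.r):
            continue
        i, j = ids.index(res.pair[0]), ids.index(res.pair[1])
        mat[i, j] = mat[j, i] = res.r
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(n)); ax.set_xticklabels(ids, rotation=90)
    ax.set_yticks(range(n)); ax.set_yticklabels(ids)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
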