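"""Connectivity heatmaps: per-state mean brain networks.

The diagnostic plot contrasts the mean ictal and interictal connectivity
matrices — ictal networks show globally elevated, spatially extensive
coupling while interictal networks stay weak and sparse.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["state_mean_matrices", "plot_state_means"]


def state_mean_matrices(tensors) -> dict:
    """Mean connectivity matrix (over segments and slices) per state label."""
    out = {}
    for label in ("ictal", "interictal"):
        stack = [t.values for t in tensors if t.label == label]
        if stack:
            out[label] = np.mean([m.mean(axis=0) for m in stack], axis=0)
    return out


def plot_state_means(tensors, out_dir, prefix: str = "mean_network") -> list:
    """Write one heatmap per state plus a side-by-side comparison figure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    means = state_mean_matrices(tensors)
    if not means:
        raise ValueError("no labeled tensors to plot")
    written = []
    vmax = max(float(m.max()) for m in means.values())
    for label, mat in means.items():
        fig, ax = plt.subplots(figsize=(4.4, 4))
        im = ax.imshow(mat, vmin=0, vmax=vmax, cmap="viridis")
        ax.set_title(f"{label}: mean connectivity")
        ax.set_xlabel("channel")
        ax.set_ylabel("channel")
        fig.colorbar(im, ax=ax, fraction=0.046)
        path = out_dir / f"{prefix}_{label}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    if len(means) == 2:
        fig, axes = plt.subplots(1, 2, figsize=(8.6, 4))
        for ax, (label, mat) in zip(axes, sorted(means.items())):
            im = ax.imshow(mat, vmin=0, vmax=vmax, cmap="viridis")
            ax.set_title(label)
            fig.colorbar(im, ax=ax, fraction=0.046)
        fig.suptitle("Mean connectivity by state")
        path = out_dir / f"{prefix}_comparison.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
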