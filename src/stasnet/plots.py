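"""Figure-style exports: landscapes and patch-effect scatter (reporting only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .topology import GridGeometry


def plot_landscape(
    landscape: np.ndarray, geometry: GridGeometry, out_path: str | Path, title: str = ""
) -> None:
    """Heatmap of a per-neuron landscape (in-degree or sequence counts)."""
    img = np.asarray(landscape).reshape(geometry.nrows, geometry.nrows)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(img, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax)
    ax.set_xlabel("x (grid points)")
    ax.set_ylabel("y (grid points)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_effect_scatter(
    patch_effects: np.ndarray,
    control_effects: np.ndarray,
    out_path: str | Path,
) -> None:
    """Patch vs non-spatial modulation effects on (delta count, delta duration).

    Patch effects are drawn as points; the non-spatial control as a Gaussian
    kernel density contour, mirroring the usual presentation of network-wide
    modulation effects.
    """
    patch_effects = np.asarray(patch_effects, dtype=float)
    control_effects = np.asarray(control_effects, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(patch_effects[:, 0], patch_effects[:, 1], c="tab:orange", label="patch")
    if control_effects.shape[0] >= 3:
        try:
            kde = gaussian_kde(control_effects.T)
            lo = control_effects.min(axis=0) - 1.0
            hi = control_effects.max(axis=0) + 1.0
            gx, gy = np.meshgrid(
                np.linspace(lo[0], hi[0], 60), np.linspace(lo[1], hi[1], 60)
            )
            dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
            ax.contour(gx, gy, dens, levels=4, colors="gray")
        except np.linalg.LinAlgError:
            ax.scatter(
                control_effects[:, 0], control_effects[:, 1], c="gray", label="control"
            )
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(r"$\Delta$ sequence count")
    ax.set_ylabel(r"$\Delta$ mean duration (ms)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
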