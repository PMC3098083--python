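"""Basic diagnostic plots: similarity heat map, spy plot, entropy curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .matrices import LabeledSquareMatrix, spy_filter

__all__ = ["plot_heatmap", "plot_spy", "plot_entropy_curve"]


def plot_heatmap(m: LabeledSquareMatrix, path, cmap: str = "RdBu_r") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.values, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=m.kind)
    ax.set_title(f"pairwise {m.kind} matrix (N={m.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spy(m: LabeledSquareMatrix, threshold: float, path) -> None:
    """Spy plot of the entries that survive zeroing values above ``threshold``."""
    filtered = spy_filter(m, threshold)
    fig, ax = plt.subplots(figsize=(5, 5))
    off = ~np.eye(m.n, dtype=bool)
    shown = (filtered.values != 0) & off
    ax.spy(shown, markersize=3)
    ax.set_title(f"entries <= {threshold:g} (N={m.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_entropy_curve(hierarchy, n_items: int, selected_theta: float, path) -> None:
    """Cluster entropy S(theta) over the threshold sweep, plateau marked."""
    thetas = [h[0] for h in hierarchy]
    entropies = [h[2] for h in hierarchy]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(thetas, entropies, where="post")
    ax.axvline(selected_theta, color="red", linestyle="--", label=f"selected theta={selected_theta:.3f}")
    ax.axhline(np.log(n_items), color="grey", linestyle=":", label="ln N (all singletons)")
    ax.set_xlabel("mutual-information threshold theta (nats)")
    ax.set_ylabel("cluster entropy S(theta) (nats)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
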