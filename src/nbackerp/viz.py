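"""Minimal rendering helpers: ERP traces and scalp topographies to image files.

These are conveniences for inspecting pipeline output; all quantitative
results flow through the CSV/TSV tables, never through figures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .erp import Evoked
from .montage import Montage


def _flat_positions(montage: Montage, labels) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere electrode positions."""
    pos = montage.position_matrix(labels)
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def plot_topography(values, montage: Montage, path, labels=None, title: str = ""):
    """Render per-channel values (e.g. a window-mean map) on the scalp layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(labels or montage.scalp_labels)
    xy = _flat_positions(montage, labels)
    values = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = np.abs(values).max() or 1.0
    sc = ax.scatter(xy[:, 1], -xy[:, 0], c=values, s=160, cmap="RdBu_r",
                    vmin=-lim, vmax=lim, edgecolors="k", linewidths=0.4)
    for (x, y), lab in zip(xy, labels):
        ax.annotate(lab, (y, -x), fontsize=5, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7, label="µV")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def plot_erp(evokeds: dict[str, Evoked], channel: str, path,
             window_ms=(300.0, 700.0), title: str = ""):
    """Overlay condition-averaged traces at one channel, marking the window."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, ev in evokeds.items():
        ax.plot(ev.times_ms, ev.channel(channel), label=f"{name} (n={ev.n_trials})")
    for edge in window_ms:
        ax.axvline(edge, color="gray", ls=":", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(title or channel)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
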