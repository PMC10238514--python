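"""Overlay figures: landmarks colored by importance/heat on a face render."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def overlay_landmarks(
    image: np.ndarray,
    coords: np.ndarray,
    values01: np.ndarray,
    path: str | Path,
    threshold: float = 0.5,
    title: str | None = None,
) -> None:
    """Save a PNG: render with landmarks red above threshold, blue below.

    ``values01`` are per-landmark relative scores in [0, 1]; red depth
    tracks the score above the threshold, matching the convention that a
    landmark is highlighted when its relative importance reaches 0.5.
    """
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1 if image.max() <= 1 else 255)
    hot = values01 >= threshold
    ax.scatter(coords[~hot, 0], coords[~hot, 1], c="tab:blue", s=14)
    if hot.any():
        ax.scatter(coords[hot, 0], coords[hot, 1], c=values01[hot],
                   cmap="Reds", vmin=threshold, vmax=1.0, s=22)
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_heatmap(heatmap: np.ndarray, path: str | Path) -> None:
    """8-bit PNG view of a [0, 1] scalar heat field."""
    from PIL import Image

    Image.fromarray((np.clip(heatmap, 0, 1) * 255).astype(np.uint8)).save(path)
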