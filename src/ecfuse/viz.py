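"""Optional heatmap export of feature-map channels (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_feature_map(
    tensor: np.ndarray,
    path: str | Path,
    channel_axis: int = 2,
    titles: list[str] | None = None,
    cmap: str = "viridis",
) -> None:
    """Save a grid of per-channel heatmaps of a 3-D feature tensor as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tensor = np.moveaxis(np.asarray(tensor), channel_axis, 0)
    n = tensor.shape[0]
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.0 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for i in range(len(axes)):
        if i < n:
            axes[i].imshow(tensor[i], cmap=cmap, aspect="auto")
            if titles and i < len(titles):
                axes[i].set_title(titles[i], fontsize=7)
        axes[i].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
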