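"""Class-averaged connectivity visualization."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

#: Color-scale ranges per measure.
_RANGES = {"pcc": (-1.0, 1.0), "plv": (0.0, 1.0), "wcc": (0.0, 1.0), "te": (0.0, None)}


def class_mean_matrices(features: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    """Mean connectivity matrix per class; errors on an empty class."""
    features = np.asarray(features)
    labels = np.asarray(labels)
    out = {}
    for cls in (0, 1):
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls} has zero samples")
        out[cls] = features[mask].mean(axis=0)
    return out


def visualize_class_means(features: np.ndarray, labels: np.ndarray, out_dir: str | Path,
                          measure: str = "plv", ch_names: list[str] | None = None) -> dict[int, Path]:
    """Render per-class mean matrices as heatmaps; write matching CSVs.

    Axes are labelled with the electrode order used to build the
    features.  Returns the written PNG paths per class.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    means = class_mean_matrices(features, labels)
    vmin, vmax = _RANGES.get(measure, (None, None))
    paths = {}
    for cls, mat in means.items():
        name = {0: "low", 1: "high"}[cls]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat, vmin=vmin, vmax=vmax, cmap="viridis")
        ax.set_title(f"mean {measure.upper()} — {name} class")
        if ch_names is not None and len(ch_names) <= 40:
            ax.set_xticks(range(len(ch_names)), ch_names, rotation=90, fontsize=5)
            ax.set_yticks(range(len(ch_names)), ch_names, fontsize=5)
        fig.colorbar(im, ax=ax)
        png = out_dir / f"mean_{measure}_{name}.png"
        fig.savefig(png, dpi=150, bbox_inches="tight")
        plt.close(fig)
        np.savetxt(out_dir / f"mean_{measure}_{name}.csv", mat, delimiter=",")
        paths[cls] = png
    return paths
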