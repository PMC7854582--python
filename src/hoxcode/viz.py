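"""Heatmap rendering for score and validation matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["render_heatmap", "cluster_order"]

_EXTENSIONS = {".png", ".pdf", ".svg"}


def cluster_order(matrix: pd.DataFrame, axis: int = 0) -> list:
    """Leaf order from average-linkage clustering on Euclidean distance.

    Missing values are imputed with the matrix mean for the distance
    computation only.  Returns the reordered row (axis=0) or column
    (axis=1) labels.
    """
    data = matrix.to_numpy(dtype=float)
    if axis == 1:
        data = data.T
    labels = matrix.index if axis == 0 else matrix.columns
    if data.shape[0] < 3:
        return list(labels)
    fill = np.nanmean(data) if np.isnan(data).any() else None
    if fill is not None:
        data = np.where(np.isnan(data), fill, data)
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
    return [labels[i] for i in hierarchy.leaves_list(link)]


def render_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    order: str = "fixed",
    title: str | None = None,
) -> Path:
    """Render a matrix as a heatmap image (PNG/PDF/SVG by extension).

    Correlation-scaled matrices (all finite values within [-1, 1]) get a
    diverging color map symmetric about 0 spanning [-1, 1]; missing cells
    are drawn in grey.  ``order="cluster"`` reorders rows and columns by
    average-linkage hierarchical clustering; ``"fixed"`` keeps the input
    order.
    """
    if matrix is None or matrix.size == 0:
        raise ValueError("cannot render an empty matrix")
    if order not in {"fixed", "cluster"}:
        raise ValueError(f"unknown ordering {order!r}")
    path = Path(path)
    if path.suffix.lower() not in _EXTENSIONS:
        raise ValueError(
            f"unknown image extension {path.suffix!r}; use one of {sorted(_EXTENSIONS)}"
        )
    if order == "cluster":
        matrix = matrix.loc[cluster_order(matrix, 0), cluster_order(matrix, 1)]

    values = matrix.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    correlation_like = finite.size > 0 and (np.abs(finite) <= 1.0).all()
    if correlation_like:
        cmap = plt.get_cmap("RdBu_r").copy()
        vmin, vmax = -1.0, 1.0
    else:
        cmap = plt.get_cmap("viridis").copy()
        vmin, vmax = (finite.min(), finite.max()) if finite.size else (0, 1)
    cmap.set_bad("#bbbbbb")

    h = max(2.5, 0.22 * matrix.shape[0] + 1.2)
    w = max(3.0, 0.22 * matrix.shape[1] + 1.8)
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(np.ma.masked_invalid(values), cmap=cmap, vmin=vmin, vmax=vmax,
                   aspect="auto", interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.7, label="Pearson r" if correlation_like else "value")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata=_stable_metadata(path.suffix.lower()))
    plt.close(fig)
    return path


def _stable_metadata(suffix: str) -> dict | None:
    """Strip timestamps so identical inputs give identical bytes."""
    if suffix == ".png":
        return {"Software": "hoxcode"}
    if suffix == ".pdf":
        return {"CreationDate": None}
    if suffix == ".svg":
        return {"Date": None}
    return None
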