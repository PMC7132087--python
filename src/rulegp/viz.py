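"""Class-separability diagnostics: 3-D PCA projection, class-framed
heatmap matrix, and a silhouette separability score.

The diagnostic workflow standardizes the data to mean 0 / variance 1,
projects it to three principal components for a scatter view, and lays
the standardized matrix out as attributes x patterns with the pattern
columns grouped contiguously by class, so each class appears as a
framed block whose color structure reveals how separable the classes
are.  Well-separated, compact classes predict classifiers with few
rules and small rule intersections; interlinked classes predict more
rules, larger intersections, and lower accuracy.  The silhouette score
turns that visual judgment into a number in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .data import Dataset

__all__ = ["Projection3D", "HeatmapMatrix", "pca3", "heatmap_matrix",
           "separability_summary", "render_heatmap", "render_scatter3d"]


@dataclass
class Projection3D:
    """Top-3 principal-component coordinates of a standardized dataset."""

    coords: np.ndarray                # n x 3
    explained_variance_fraction: np.ndarray  # length 3, non-increasing
    loadings: np.ndarray              # d x 3, orthonormal columns


@dataclass
class HeatmapMatrix:
    """Attributes-by-patterns value matrix with class-framed columns.

    ``values[i, j]`` is attribute ``i`` of the ``j``-th pattern after
    grouping the pattern columns contiguously by class (classes in
    declared order, original order kept within a class).
    ``class_boundaries[c]`` is the first column index *after* class
    ``c``'s block; ``value_range`` gives (min, midpoint, max) anchors
    for a color scale.
    """

    values: np.ndarray
    class_boundaries: list[int]
    class_labels: list
    value_range: tuple[float, float, float]
    column_order: np.ndarray  # original pattern index of each column


def pca3(data: Dataset) -> Projection3D:
    """Project standardized data onto its top three principal components.

    Sign convention: each component is flipped, if necessary, so its
    largest-magnitude loading is positive — making the projection
    deterministic across runs and SVD backends.
    """
    if not data.standardized:
        raise ValueError("pca3 requires standardized data")
    if data.d < 3:
        raise ValueError(f"pca3 needs d >= 3 attributes, got d={data.d}")
    pca = PCA(n_components=3, svd_solver="full")
    coords = pca.fit_transform(data.X)
    loadings = pca.components_.T.copy()  # d x 3
    for c in range(3):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            coords[:, c] *= -1.0
    return Projection3D(
        coords=coords,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=loadings)


def heatmap_matrix(data: Dataset) -> HeatmapMatrix:
    """Lay the standardized matrix out as attributes x patterns, columns
    grouped contiguously by class."""
    if not data.standardized:
        raise ValueError("heatmap_matrix requires standardized data")
    order = np.concatenate([
        np.flatnonzero(data.class_mask(cls)) for cls in data.class_labels])
    values = data.X[order].T  # d x n
    boundaries = list(np.cumsum(
        [data.class_size(cls) for cls in data.class_labels]).astype(int))
    vmin, vmax = float(values.min()), float(values.max())
    return HeatmapMatrix(
        values=values,
        class_boundaries=boundaries,
        class_labels=list(data.class_labels),
        value_range=(vmin, (vmin + vmax) / 2.0, vmax),
        column_order=order)


def separability_summary(data: Dataset) -> dict:
    """Silhouette-based class-separability score in [-1, 1].

    Mean silhouette with Euclidean distance in standardized space;
    higher means tighter, better-separated classes.  Classes with a
    single pattern are skipped with a warning.  Returns a dict with
    ``overall`` and ``per_class`` entries.
    """
    sizes = {cls: data.class_size(cls) for cls in data.class_labels}
    usable = [cls for cls, size in sizes.items() if size >= 2]
    skipped = [cls for cls in data.class_labels if cls not in usable]
    if skipped:
        warnings.warn(
            f"classes {skipped!r} have a single pattern and are skipped "
            "in the separability summary")
    if len(usable) < 2:
        raise ValueError("separability needs >= 2 classes with >= 2 patterns")
    keep = np.asarray([label in usable for label in data.y])
    X = data.X[keep]
    y = np.asarray([str(label) for label in data.y[keep]])
    sil = silhouette_samples(X, y, metric="euclidean")
    per_class = {cls: float(sil[y == str(cls)].mean()) for cls in usable}
    return {"overall": float(sil.mean()), "per_class": per_class}


# --------------------------------------------------------------------------
# Optional matplotlib renderings.  The tested artifact is the matrix and
# its anchors; colors are cosmetic.
# --------------------------------------------------------------------------

def render_heatmap(hm: HeatmapMatrix, path) -> None:
    """Write a PNG heatmap with class blocks framed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(hm.values, aspect="auto", cmap="RdYlGn_r",
                   vmin=hm.value_range[0], vmax=hm.value_range[2])
    start = 0
    for cls, end in zip(hm.class_labels, hm.class_boundaries):
        ax.axvline(end - 0.5, color="black", linewidth=1.5)
        ax.text((start + end) / 2, -1.0, f"class {cls}", ha="center")
        start = end
    ax.set_xlabel("patterns (grouped by class)")
    ax.set_ylabel("attributes")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_scatter3d(proj: Projection3D, labels, path) -> None:
    """Write a PNG 3-D scatter of the PCA coordinates, one color per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    labels = np.asarray(labels, dtype=object)
    for cls in dict.fromkeys(labels):
        mask = labels == cls
        ax.scatter(proj.coords[mask, 0], proj.coords[mask, 1],
                   proj.coords[mask, 2], label=f"class {cls}", s=12)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
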