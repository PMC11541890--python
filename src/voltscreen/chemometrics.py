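"""Unsupervised chemometrics on voltammogram matrices: PCA and HCA.

Rows of the feature matrix are samples (analyte x replicate); columns are the
current values of the preprocessed anodic sweep followed by the cathodic
sweep on their common cropped grids.  PCA is a column-mean-centred
eigen-decomposition (no scaling by default, since traces are already
normalized), with component signs fixed so each loading's largest-magnitude
entry is positive.  HCA is agglomerative clustering (Ward on Euclidean
distances by default); dendrogram heights are also expressed on a
``100 * (1 - d/d_max)`` similarity scale, and the cluster count can be chosen
automatically at the largest gap between successive merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .simulate import Voltammogram

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "HCAResult",
    "build_matrix",
    "run_pca",
    "run_hca",
    "cut_by_gap",
    "cut_at",
    "plot_scores",
    "plot_dendrogram",
]

_LINKAGES = ("ward", "single", "complete", "average", "centroid", "median", "weighted")
_METRICS = ("euclidean", "cityblock", "cosine", "correlation", "chebyshev")


@dataclass
class FeatureMatrix:
    """Samples-by-potentials matrix of preprocessed currents."""

    data: pd.DataFrame  # index: row labels; columns: ("anodic"|"cathodic", E)
    anodic_grid: np.ndarray
    cathodic_grid: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def row_labels(self) -> list:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, n_components)
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    row_labels: list

    def reconstruct(self) -> np.ndarray:
        """Back-project scores to the original feature space."""
        return self.scores @ self.loadings + self.column_means


@dataclass
class HCAResult:
    merge_tree: np.ndarray  # scipy linkage matrix, (n-1, 4)
    linkage: str
    metric: str
    row_labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.merge_tree[:, 2]

    @property
    def similarity(self) -> np.ndarray:
        """Merge heights rescaled to 100 * (1 - d/d_max)."""
        d_max = self.heights.max()
        return 100.0 * (1.0 - self.heights / d_max)


def build_matrix(
    traces: list[tuple[Voltammogram, Voltammogram, object]],
) -> FeatureMatrix:
    """Stack preprocessed (anodic, cathodic, label) trace pairs into a matrix.

    All pairs must share identical grids (same crop windows); rows keep the
    input order, columns are the anodic grid followed by the cathodic grid.
    """
    if not traces:
        raise ValueError("need at least one trace pair")
    a0, c0, _ = traces[0]
    rows, labels = [], []
    for anodic, cathodic, label in traces:
        if anodic.potentials.shape != a0.potentials.shape or not np.allclose(
            anodic.potentials, a0.potentials
        ):
            raise ValueError("anodic grids differ between samples (mismatched crops)")
        if cathodic.potentials.shape != c0.potentials.shape or not np.allclose(
            cathodic.potentials, c0.potentials
        ):
            raise ValueError("cathodic grids differ between samples (mismatched crops)")
        rows.append(np.concatenate([anodic.currents, cathodic.currents]))
        labels.append(label)
    columns = pd.MultiIndex.from_tuples(
        [("anodic", float(e)) for e in a0.potentials]
        + [("cathodic", float(e)) for e in c0.potentials],
        names=["scan", "potential_V"],
    )
    frame = pd.DataFrame(np.vstack(rows), index=labels, columns=columns)
    return FeatureMatrix(frame, a0.potentials.copy(), c0.potentials.copy())


def run_pca(m: FeatureMatrix, n_components: int = 2, scale: bool = False) -> PCAResult:
    """Centred (optionally autoscaled) PCA of the feature matrix.

    Deterministic up to component sign; signs are fixed so that each
    loading's largest-magnitude entry is positive.
    """
    x = m.values.astype(float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least two rows")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}"
        )
    means = x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - means) / sd + means  # centring handled by sklearn below

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_
    # sign convention: largest-|.| entry of each loading positive
    flips = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    flips[flips == 0] = 1.0
    loadings = loadings * flips[:, None]
    scores = scores * flips[None, :]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_,
        column_means=model.mean_,
        row_labels=m.row_labels,
    )


def run_hca(
    m: FeatureMatrix, linkage_method: str = "ward", metric: str = "euclidean"
) -> HCAResult:
    """Agglomerative hierarchical clustering of the feature matrix rows."""
    if linkage_method not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage_method!r}; choose from {_LINKAGES}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if len(m) < 2:
        raise ValueError("HCA needs at least two rows")
    distances = pdist(m.values, metric=metric)
    tree = linkage(distances, method=linkage_method)
    return HCAResult(
        merge_tree=tree, linkage=linkage_method, metric=metric, row_labels=m.row_labels
    )


def cut_by_gap(h: HCAResult) -> np.ndarray:
    """Cut the dendrogram at the largest gap between successive merge heights.

    With ``n`` rows there are ``n-1`` merges; a cut between merges ``i`` and
    ``i+1`` (0-based, heights ascending) leaves ``n - i - 1`` clusters.  The
    gap above the final merge (to the tree top) is not a candidate, so the
    result always has at least two clusters.
    """
    heights = h.heights
    n = len(h.row_labels)
    if n < 2:
        raise ValueError("cannot cut a tree with fewer than two leaves")
    if len(heights) == 1:
        return cut_at(h, 2)
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))
    return cut_at(h, n - i - 1)


def cut_at(h: HCAResult, n_clusters: int) -> np.ndarray:
    """Flat partition with a fixed number of clusters (labels per row)."""
    return fcluster(h.merge_tree, t=n_clusters, criterion="maxclust")


def plot_scores(result: PCAResult, path: str, components: tuple[int, int] = (0, 1)):
    """Score plot of two principal components, annotated with row labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.scores[:, i], result.scores[:, j], s=18)
    for label, x, y in zip(result.row_labels, result.scores[:, i], result.scores[:, j]):
        ax.annotate(str(label), (x, y), fontsize=6, alpha=0.7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC{i + 1} ({100 * evr[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({100 * evr[j]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(h: HCAResult, path: str):
    """Dendrogram on the 100*(1 - d/d_max) similarity axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(h.merge_tree, labels=[str(l) for l in h.row_labels], ax=ax,
               leaf_font_size=6)
    d_max = h.heights.max()
    ticks = ax.get_yticks()
    ax.set_yticks(ticks)
    ax.set_yticklabels([f"{100 * (1 - t / d_max):.0f}" for t in ticks])
    ax.set_ylabel("similarity (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
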