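"""Hierarchical clustering of spectra and signature matching.

Samples (or catalogue signatures) are rows of a spectrum matrix; pairwise
dissimilarity is cosine distance (1 - cosine similarity), and agglomeration
uses WPGMA ("weighted") linkage by default, with Ward available behind a
flag. Leaf order is a deterministic smaller-subtree-first traversal: it
affects display only, never the merges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "cosine_similarity",
    "Dendrogram",
    "hierarchical_cluster",
    "match_signatures",
    "load_signature_catalog",
]

LINKAGES = ("weighted", "ward")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (|u| |v|); zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass(frozen=True)
class Dendrogram:
    """Merge table (scipy linkage format) with labelled leaves."""

    merges: np.ndarray  # (n-1, 4): child, child, height, leaf count
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        """Deterministic display order: smaller subtree first, then lower
        node id."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        for k in range(len(self.merges)):
            sizes[n + k] = int(self.merges[k, 3])

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right = (int(x) for x in self.merges[node - n, :2])
            first, second = sorted(
                (left, right), key=lambda c: (sizes[c], c)
            )
            return walk(first) + walk(second)

        return [self.labels[i] for i in walk(2 * n - 2)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment at the ``n_clusters``-cluster cut."""
        flat = hierarchy.fcluster(
            self.merges, t=n_clusters, criterion="maxclust"
        )
        return dict(zip(self.labels, (int(x) for x in flat)))

    def to_newick(self) -> str:
        """Newick string; branch lengths from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for k in range(len(self.merges)):
            height[n + k] = float(self.merges[k, 2])

        def node(i: int, parent_h: float) -> str:
            bl = max(parent_h - height[i], 0.0)
            if i < n:
                return f"{self.labels[i]}:{bl:.6g}"
            left, right = (int(x) for x in self.merges[i - n, :2])
            return f"({node(left, height[i])},{node(right, height[i])}):{bl:.6g}"

        root = 2 * n - 2
        left, right = (int(x) for x in self.merges[root - n, :2])
        h = height[root]
        return f"({node(left, h)},{node(right, h)});"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges,
            columns=["child_a", "child_b", "height", "n_leaves"],
        )


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    linkage: str = "weighted",
) -> Dendrogram:
    """Agglomerative clustering of spectrum rows under cosine distance.

    ``linkage`` is ``"weighted"`` (WPGMA, the default) or ``"ward"``.
    Deterministic: identical input matrices give identical merge tables.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if labels is None:
        labels = [f"row{i}" for i in range(matrix.shape[0])]
    if (np.linalg.norm(matrix, axis=1) == 0).any():
        raise ValueError("zero rows have no cosine distance")
    dist = np.clip(pdist(matrix, metric="cosine"), 0.0, None)
    merges = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(merges=merges, labels=tuple(labels))


def match_signatures(
    spectrum: np.ndarray, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Rank catalogue signatures by cosine similarity to a spectrum.

    ``catalog`` columns are signatures, rows the 96 class labels in the
    same order as the query spectrum. Ties keep catalogue column order
    (stable sort).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if len(spectrum) != catalog.shape[0]:
        raise ValueError(
            f"query has {len(spectrum)} classes, catalogue rows "
            f"{catalog.shape[0]}"
        )
    sims = [
        cosine_similarity(spectrum, catalog[col].to_numpy())
        for col in catalog.columns
    ]
    out = pd.DataFrame({"signature": catalog.columns, "similarity": sims})
    return out.sort_values(
        "similarity", ascending=False, kind="stable"
    ).reset_index(drop=True)


def load_signature_catalog(
    path, class_labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Read a signature catalogue TSV (96 labelled rows x signatures)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if class_labels is not None:
        missing = set(class_labels) - set(df.index)
        if missing:
            raise ValueError(
                f"catalogue is missing {len(missing)} class labels "
                f"(e.g. {sorted(missing)[:3]})"
            )
        df = df.loc[list(class_labels)]
    return df
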