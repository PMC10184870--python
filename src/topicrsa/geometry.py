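"""Representational (dis)similarity matrices and hierarchical clustering.

An RDM here is always ``1 - Pearson r`` between item feature vectors:
symmetric, zero diagonal, entries in [0, 2].  RDMs are compared by Pearson
correlation of their vectorised upper triangles — the standard second-order
similarity used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

SYM_TOL = 1e-10  # absolute tolerance for symmetry / zero-diagonal checks

__all__ = [
    "RDM",
    "Dendrogram",
    "build_rdm",
    "vectorize_rdm",
    "unvectorize_rdm",
    "compare_rdms",
    "ward_dendrogram",
    "cut_clusters",
    "silhouette_scores",
    "read_rdm",
    "write_rdm",
]


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix (1 - Pearson r)."""

    matrix: np.ndarray
    item_ids: list = field(default_factory=list)
    source_model: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if np.abs(m - m.T).max() > SYM_TOL:
            raise ValueError("RDM is not symmetric")
        if np.abs(np.diag(m)).max() > SYM_TOL:
            raise ValueError("RDM diagonal is not zero")
        if m.min() < -SYM_TOL or m.max() > 2 + 1e-8:
            raise ValueError("RDM entries must lie in [0, 2]")
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        self.matrix = m
        if not self.item_ids:
            self.item_ids = list(range(m.shape[0]))
        if len(self.item_ids) != m.shape[0]:
            raise ValueError("item_ids length mismatch")

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Dendrogram:
    """Ward merge sequence in scipy linkage form (n_items - 1 merges)."""

    linkage_matrix: np.ndarray
    n_items: int

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        if Z.shape != (self.n_items - 1, 4):
            raise ValueError("linkage matrix must have n_items - 1 rows")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        self.linkage_matrix = Z

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick export with merge heights as branch lengths."""
        labels = labels or [str(i) for i in range(self.n_items)]
        Z = self.linkage_matrix
        height = {i: 0.0 for i in range(self.n_items)}
        node = {i: labels[i] for i in range(self.n_items)}
        for k, (a, b, h, _) in enumerate(Z):
            a, b = int(a), int(b)
            nid = self.n_items + k
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[nid] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[nid] = h
        return node[self.n_items + len(Z) - 1] + ";"


def _check_features(features) -> tuple[np.ndarray, list, str]:
    """Accept a SentenceFeatures-like object or a bare matrix."""
    if hasattr(features, "matrix"):
        return (
            np.asarray(features.matrix, dtype=float),
            list(getattr(features, "sentence_ids", [])),
            getattr(features, "model_name", ""),
        )
    return np.asarray(features, dtype=float), [], ""


def build_rdm(features) -> RDM:
    """1 - Pearson correlation between every pair of feature rows."""
    X, ids, name = _check_features(features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to build an RDM")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        which = ids[bad[0]] if ids else int(bad[0])
        raise ValueError(f"zero-variance feature row for item {which!r}")
    r = np.corrcoef(X)
    m = 1.0 - np.clip(r, -1.0, 1.0)
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return RDM(m, ids, name)


def vectorize_rdm(rdm: RDM | np.ndarray) -> np.ndarray:
    """Upper triangle excluding the diagonal, row-major; length n(n-1)/2."""
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if np.abs(m - m.T).max() > SYM_TOL:
        raise ValueError("matrix is not symmetric within tolerance")
    out = squareform(m, checks=False)
    return out


def unvectorize_rdm(vec: np.ndarray) -> np.ndarray:
    """Re-assemble a square zero-diagonal matrix from its upper triangle."""
    return squareform(np.asarray(vec, dtype=float), checks=False)


def compare_rdms(a: RDM | np.ndarray, b: RDM | np.ndarray) -> float:
    """Pearson correlation of the two vectorised upper triangles."""
    va, vb = vectorize_rdm(a), vectorize_rdm(b)
    if va.shape != vb.shape:
        raise ValueError("RDMs have different sizes")
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("constant vectorized RDM: correlation undefined")
    # elementwise product then sum: exactly symmetric in the arguments
    return float(np.sum(va * vb) / (na * nb))


def ward_dendrogram(features, metric: str = "euclidean") -> Dendrogram:
    """Ward agglomerative clustering of feature rows.

    Default is Euclidean distance on the raw feature vectors (Ward's validity
    condition).  ``metric="rdm"`` clusters on correlation-distance derived
    from the features instead.
    """
    X, _, _ = _check_features(features)
    if metric == "euclidean":
        Z = linkage(X, method="ward")
    elif metric == "rdm":
        d = vectorize_rdm(build_rdm(X))
        Z = linkage(d, method="ward")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return Dendrogram(Z, X.shape[0])


def cut_clusters(d: Dendrogram, k: int) -> np.ndarray:
    """Cut a dendrogram into exactly k clusters; labels are 0-based."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > d.n_items:
        raise ValueError("k exceeds number of items")
    return fcluster(d.linkage_matrix, t=k, criterion="maxclust") - 1


def silhouette_scores(features, labels) -> np.ndarray:
    """Per-item silhouette (b - a)/max(a, b) on Euclidean distances.

    Members of singleton clusters score 0 by convention.
    """
    X, _, _ = _check_features(features)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return silhouette_samples(X, labels, metric="euclidean")


def write_rdm(rdm: RDM, path) -> None:
    """Tab-separated square matrix with item-id header row and column."""
    ids = [str(i) for i in rdm.item_ids]
    lines = ["\t" + "\t".join(ids)]
    for i, row in enumerate(rdm.matrix):
        lines.append(ids[i] + "\t" + "\t".join(f"{x:.10g}" for x in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_rdm(path, source_model: str = "") -> RDM:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    ids = lines[0].split("\t")[1:]
    rows = [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
    return RDM(np.array(rows), ids, source_model)
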