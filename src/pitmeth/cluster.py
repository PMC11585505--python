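"""Top-variable-CpG selection, hierarchical clustering, and PCA.

Unsupervised structure discovery on the methylome: the top-k most variable
CpGs are clustered by complete linkage on Pearson correlation distance
(d = 1 - r), embedded by PCA, and the agreement between a dendrogram cut and
external labels is scored with the adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .preprocess import BetaMatrix, validate_sample_sheet

logger = logging.getLogger("pitmeth")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]
    method: str = "complete"
    metric: str = "pearson"

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick export; branch length = parent merge height - node height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass
class PCAResult:
    """Sample coordinates on ordered principal components."""

    coordinates: pd.DataFrame          # samples x components
    variance_explained: np.ndarray     # percentages, non-increasing


def select_top_variable(beta: BetaMatrix, k: int = 5000) -> BetaMatrix:
    """Retain the k probes with the highest across-sample variance.

    Ties are broken by the current (manifest) row order via a stable sort,
    so selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = len(beta.probes)
    if k >= n:
        if k > n:
            logger.warning("k=%d exceeds probe count %d; keeping all probes", k, n)
        return beta.subset_probes(beta.probes)
    var = beta.values.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[:k]
    keep = beta.probes[np.sort(order)]  # preserve manifest order in output
    return beta.subset_probes(keep)


def pearson_distance_matrix(beta: BetaMatrix) -> pd.DataFrame:
    """Pairwise sample distance d(i, j) = 1 - Pearson r of the profiles."""
    x = beta.values.to_numpy(float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = beta.samples[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} has zero variance across selected probes")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=beta.samples, columns=beta.samples)


def cluster_samples(beta: BetaMatrix) -> Dendrogram:
    """Complete-linkage agglomeration on Pearson correlation distance."""
    if len(beta.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    d = pearson_distance_matrix(beta)
    z = hierarchy.linkage(squareform(d.to_numpy(), checks=False), method="complete")
    return Dendrogram(linkage=z, labels=list(beta.samples))


def pca_embed(beta: BetaMatrix, n_components: int = 3) -> PCAResult:
    """SVD of the probe-centred matrix; variance explained per component."""
    x = beta.values.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncated", n_components, rank)
        n_components = rank
    var_pct = (s ** 2) / (s ** 2).sum() * 100.0
    coords = (vt[:n_components].T * s[:n_components])
    frame = pd.DataFrame(
        coords,
        index=beta.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PCAResult(coordinates=frame, variance_explained=var_pct[:n_components])


def separation_score(
    dendrogram: Dendrogram,
    sheet: pd.DataFrame,
    label_field: str = "group",
    k_cut: int = 2,
) -> float:
    """Adjusted Rand index between a k-cluster dendrogram cut and labels.

    ARI = 1 means the cut reproduces the labelling exactly (e.g. complete
    separation of aggressive/metastatic from benign tumours); 0 is chance.
    """
    if k_cut < 2:
        raise ValueError("k_cut must be at least 2")
    sheet = validate_sample_sheet(sheet).set_index("sample")
    if label_field not in sheet.columns:
        raise ValueError(f"label field {label_field!r} missing from sample sheet")
    labels = sheet.loc[dendrogram.labels, label_field].to_numpy()
    clusters = dendrogram.cut(k_cut)
    return float(adjusted_rand_score(labels, clusters))
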