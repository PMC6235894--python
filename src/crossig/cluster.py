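"""Unsupervised co-clustering of pooled mouse+human samples on signature
genes, with the two resulting clusters labeled by the mouse anchors.

Distance is 1 - centered Pearson correlation between sample profiles, with
average linkage — the Cluster/TreeView convention for expression heatmaps.
The cluster containing the majority of perturbed mouse samples is labeled
``ASS_present``. ``CorrelationCluster`` exposes the clusterer in
scikit-learn style; ``hier_cluster`` adds the anchor labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .bccp import ASS_ABSENT, ASS_PRESENT
from .io import ExpressionMatrix
from .signature import PERTURBED

logger = logging.getLogger("crossig")


def _correlation_linkage(X: np.ndarray) -> np.ndarray:
    """Average-linkage tree on 1 - centered Pearson distance between rows."""
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    d = pdist(X, metric="correlation")
    d = np.clip(d, 0.0, 2.0)  # guard fp noise below 0
    return hierarchy.linkage(d, method="average")


class CorrelationCluster(BaseEstimator, ClusterMixin):
    """Agglomerative clustering with correlation distance, average linkage.

    ``fit(X)`` clusters rows (samples x features). Fitted attributes:
    ``labels_`` (cluster ids 0..k-1 renumbered by first appearance),
    ``linkage_`` (scipy linkage matrix), ``leaf_order_`` (deterministic leaf
    ordering: lower-height subtree first, ties by input order).
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValueError("fewer samples than clusters")
        Z = _correlation_linkage(X)
        raw = hierarchy.fcluster(Z, t=self.n_clusters, criterion="maxclust")
        # renumber by first appearance for determinism
        remap: dict[int, int] = {}
        labels = np.empty(len(raw), dtype=int)
        for i, r in enumerate(raw):
            if r not in remap:
                remap[r] = len(remap)
            labels[i] = remap[r]
        self.labels_ = labels
        self.linkage_ = Z
        self.leaf_order_ = _leaf_order(Z)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _leaf_order(Z: np.ndarray) -> list[int]:
    """Leaf order with the tighter (lower merge height) subtree first.

    Children at equal height keep input order (left child is the one formed
    or listed first).
    """
    n = Z.shape[0] + 1
    heights = np.concatenate([np.zeros(n), Z[:, 2]])

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        if heights[b] < heights[a]:
            a, b = b, a
        return walk(a) + walk(b)

    return walk(2 * n - 2)


@dataclass
class ClusterAssignment:
    """Two-cluster sample assignment anchored by the mouse samples."""

    assignment: pd.Series  # sample_id -> 1 or 2
    anchor_label: dict[int, str]  # cluster -> ASS_present / ASS_absent
    linkage: np.ndarray
    leaf_order: list[str]

    def call_for(self, sample_id: str) -> str:
        return self.anchor_label[int(self.assignment[sample_id])]

    @property
    def calls(self) -> pd.Series:
        return self.assignment.map(lambda k: self.anchor_label[int(k)]).rename("call")


def hier_cluster(
    m: ExpressionMatrix,
    signature_genes: list[str],
    mouse_labels: pd.Series,
    k: int = 2,
) -> ClusterAssignment:
    """Cluster samples of a pooled matrix restricted to signature genes.

    ``mouse_labels`` maps mouse sample IDs to perturbed/control; the cluster
    holding the majority of perturbed mouse samples becomes ``ASS_present``.
    An exact 50/50 split of the perturbed anchors is a hard error (the
    anchoring is then meaningless and needs manual review).
    """
    sub = m.subset_genes(signature_genes)
    if sub.values.shape[0] == 0:
        raise ValueError("no signature gene present in pooled matrix")
    model = CorrelationCluster(n_clusters=k).fit(sub.values.T.to_numpy())
    assignment = pd.Series(
        model.labels_ + 1, index=sub.values.columns, name="cluster"
    )
    perturbed = [
        s for s, lab in mouse_labels.items() if lab == PERTURBED and s in assignment
    ]
    if not perturbed:
        raise ValueError("no perturbed mouse anchor present in matrix")
    counts = assignment.loc[perturbed].value_counts()
    c1 = int(counts.get(1, 0))
    c2 = int(counts.get(2, 0))
    if c1 == c2:
        raise ValueError(
            "perturbed mouse anchors split evenly between clusters; "
            "anchor labeling is ambiguous — review the clustering manually"
        )
    present = 1 if c1 > c2 else 2
    anchor_label = {present: ASS_PRESENT, 3 - present: ASS_ABSENT}
    leaf_order = [sub.values.columns[i] for i in model.leaf_order_]
    logger.info(
        "hier_cluster: %d samples, clusters sizes %s, present=%d",
        len(assignment),
        assignment.value_counts().to_dict(),
        present,
    )
    return ClusterAssignment(
        assignment=assignment,
        anchor_label=anchor_label,
        linkage=model.linkage_,
        leaf_order=leaf_order,
    )


def heatmap_order(
    m: ExpressionMatrix, assignment: ClusterAssignment
) -> dict:
    """Row/column permutation for a heatmap: columns by the sample dendrogram
    leaf order, rows by a gene dendrogram (same metric/linkage). Values are
    untouched; the color scale is symmetric about 0 on the log2 scale.
    """
    cols = [c for c in assignment.leaf_order if c in m.values.columns]
    X = m.values.to_numpy()
    if m.values.shape[0] >= 3:
        gene_model = CorrelationCluster(n_clusters=2).fit(X)
        rows = [m.values.index[i] for i in gene_model.leaf_order_]
    else:
        rows = m.values.index.tolist()
    ordered = m.values.loc[rows, cols]
    vmax = float(np.abs(ordered.to_numpy()).max()) if ordered.size else 1.0
    return {
        "matrix": ordered,
        "row_order": rows,
        "col_order": cols,
        "color_scale": {"vmin": -vmax, "vmax": vmax, "center": 0.0, "scale": "log2"},
    }
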