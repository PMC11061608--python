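"""Signature-restricted hierarchical clustering, reference-anchored cluster
labelling, and the batch-principal-component gene-selection workaround.

The batch workaround formalises a manual step: when two merged cohorts are
clustered jointly, one principal component is typically dominated by the data
source rather than biology. PCs whose scores separate the sources (rank test
p below alpha with a large effect) are excluded, and clustering genes are
taken as the union of the top-loading genes of the retained PCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.decomposition import PCA

from .io import AnnotationTable, GeneSignature, MergedMatrix, ValidationError
from .integrate import zscore_genes

_LINKAGES = ("ward", "average", "complete", "single")


@dataclass
class ClusterModel:
    """Linkage tree over samples plus a flat cut at k clusters.

    Samples are ordered lexicographically before the tree is built, which
    makes the output invariant to the input column order.
    """

    linkage: np.ndarray
    samples: list[str]
    assignment: pd.Series  # sample -> cluster id (1..k)
    params: dict

    @property
    def k(self) -> int:
        return int(self.params["k"])

    def members_of(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    def to_newick(self) -> str:
        """Plain newick-style text export of the dendrogram (heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ClusterLabels:
    anchor_cluster: int
    anchor_class: str
    labels: pd.Series  # sample -> anchor_class or "cluster_<id>"


@dataclass
class BatchPCReport:
    """Per-PC source-association screen and the resulting gene selection."""

    per_pc: pd.DataFrame  # pc, variance_fraction, statistic, p_value, effect, excluded
    retained: list[int]
    excluded: list[int]
    selected_genes: list[str]
    params: dict


def _restrict_to_signature(m: MergedMatrix, signature: GeneSignature) -> MergedMatrix:
    present = [g for g in m.gene_ids if g in signature.members]
    coverage = len(present) / len(signature)
    if coverage < 0.5:
        raise ValidationError(
            f"only {coverage:.0%} of signature {signature.name!r} genes present (< 50%)"
        )
    if coverage < 0.8:
        warnings.warn(
            f"only {coverage:.0%} of signature {signature.name!r} genes present"
        )
    return MergedMatrix(values=m.values.loc[present], sample_meta=m.sample_meta)


def hcluster_signature(
    m: MergedMatrix,
    signature: GeneSignature,
    k: int,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> ClusterModel:
    """Cluster samples on the signature-restricted, gene-z-scored matrix and
    cut the tree into k flat clusters."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_samples:
        raise ValidationError(f"k={k} exceeds number of samples ({m.n_samples})")
    sub = _restrict_to_signature(m, signature)
    z = zscore_genes(sub)
    if z.n_genes < 2:
        raise ValidationError("fewer than 2 usable signature genes after z-scoring")
    order = sorted(z.sample_ids)
    X = z.values[order].T.to_numpy()
    if linkage == "ward":
        L = hierarchy.linkage(X, method="ward")
    else:
        L = hierarchy.linkage(pdist(X, metric=distance), method=linkage)
    flat = hierarchy.fcluster(L, t=k, criterion="maxclust")
    assignment = pd.Series(flat, index=order, name="cluster")
    params = {
        "distance": distance,
        "linkage": linkage,
        "k": k,
        "signature": signature.name,
        "n_genes_used": z.n_genes,
    }
    return ClusterModel(linkage=L, samples=order, assignment=assignment, params=params)


def label_clusters(
    model: ClusterModel, annotations: AnnotationTable, anchor_class: str
) -> ClusterLabels:
    """Label the cluster holding the majority of ``anchor_class`` reference
    samples with that class; plurality with a warning if no strict majority."""
    ann = annotations.table
    if "reference_class" not in ann.columns:
        raise ValidationError("annotations lack a reference_class column")
    anchors = [
        s
        for s in ann.index[ann["reference_class"] == anchor_class]
        if s in model.assignment.index
    ]
    if not anchors:
        raise ValidationError(f"no clustered sample annotated {anchor_class!r}")
    counts = model.assignment.loc[anchors].value_counts().sort_index()
    top = counts.idxmax()
    if counts.max() * 2 <= len(anchors):
        warnings.warn(
            f"no cluster holds a strict majority of {anchor_class!r} samples; "
            f"labelling plurality cluster {top}"
        )
    labels = model.assignment.map(
        lambda c: anchor_class if c == top else f"cluster_{c}"
    )
    labels.name = "label"
    return ClusterLabels(anchor_cluster=int(top), anchor_class=anchor_class, labels=labels)


def _source_association(scores: np.ndarray, sources: pd.Series) -> tuple[float, float, float]:
    """(statistic, p, effect) of PC scores vs source labels.

    Two sources: two-sided rank-sum (Mann-Whitney) with rank-biserial effect
    |1 - 2U/(n1 n2)|. More sources: Kruskal-Wallis with epsilon-squared
    H/(n-1) as the effect size.
    """
    levels = sorted(sources.unique())
    groups = [scores[(sources == lvl).to_numpy()] for lvl in levels]
    if len(levels) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        n1, n2 = len(groups[0]), len(groups[1])
        effect = abs(1.0 - 2.0 * res.statistic / (n1 * n2))
        return float(res.statistic), float(res.pvalue), float(effect)
    res = stats.kruskal(*groups)
    n = len(scores)
    effect = float(res.statistic) / (n - 1)
    return float(res.statistic), float(res.pvalue), float(effect)


def batch_aware_gene_selection(
    m: MergedMatrix,
    n_pcs: int = 4,
    n_top: int = 50,
    assoc_alpha: float = 0.05,
    effect_floor: float = 0.5,
    exclude_pcs: Sequence[int] | None = None,
) -> BatchPCReport:
    """Screen the first ``n_pcs`` principal components for source association
    and select the union of the ``n_top`` highest-|loading| genes of every
    retained PC.

    ``exclude_pcs`` (1-based PC indices) overrides the statistical rule so a
    known source-driven PC can be dropped verbatim.
    """
    sources = m.sources()
    if sources.nunique() < 2:
        raise ValidationError("batch-aware selection needs >= 2 source cohorts")
    if m.n_samples < n_pcs + 1:
        raise ValidationError(f"need at least {n_pcs + 1} samples for {n_pcs} PCs")
    z = zscore_genes(m)
    X = z.values.T.to_numpy()  # samples x genes
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    rows = []
    auto_excluded: list[int] = []
    for i in range(n_pcs):
        statistic, p, effect = _source_association(scores[:, i], sources)
        if exclude_pcs is not None:
            flag = (i + 1) in set(exclude_pcs)
        else:
            flag = p < assoc_alpha and effect >= effect_floor
        if flag:
            auto_excluded.append(i + 1)
        rows.append(
            {
                "pc": i + 1,
                "variance_fraction": float(pca.explained_variance_ratio_[i]),
                "statistic": statistic,
                "p_value": p,
                "effect": effect,
                "excluded": flag,
            }
        )
    per_pc = pd.DataFrame(rows)
    retained = [i + 1 for i in range(n_pcs) if (i + 1) not in auto_excluded]
    if not retained:
        raise ValidationError(
            "every screened PC is source-associated; pass exclude_pcs explicitly "
            "to override the automatic rule"
        )
    genes = z.values.index.to_numpy()
    selected: list[str] = []
    for pc in retained:
        loadings = np.abs(pca.components_[pc - 1])
        top = genes[np.argsort(-loadings, kind="stable")[:n_top]]
        for g in top:
            if g not in selected:
                selected.append(g)
    params = {
        "n_pcs": n_pcs,
        "n_top": n_top,
        "assoc_alpha": assoc_alpha,
        "effect_floor": effect_floor,
        "manual_exclude": list(exclude_pcs) if exclude_pcs is not None else None,
    }
    return BatchPCReport(
        per_pc=per_pc,
        retained=retained,
        excluded=auto_excluded,
        selected_genes=selected,
        params=params,
    )
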