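"""Iterative derivation of the tumor-invasiveness expression signature.

The procedure alternates unsupervised hierarchical clustering of samples
with differential expression between the two resulting clusters, starting
from the most-varying genes, until neither the cluster memberships nor the
differentially expressed gene set changes. The two fixed-point clusters are
then labeled invasive / non-invasive from the predominant histology, and
the signature splits into pro-invasive (up in the invasive cluster) and
indolence (up in the non-invasive cluster) gene lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .stats import DEResult, differential_expression

logger = logging.getLogger(__name__)

__all__ = [
    "AGGRESSIVE_HISTOLOGIES",
    "LEPIDIC_HISTOLOGIES",
    "ClusterAssignment",
    "SignatureSet",
    "select_top_variance_genes",
    "hierarchical_cluster",
    "derive_signature",
    "label_groups",
]

#: Aggressive (invasive) histological subtypes: acinar, papillary,
#: micropapillary, solid.
AGGRESSIVE_HISTOLOGIES = frozenset({"AC", "PAP", "MP", "SOL"})
#: Non-/less-invasive subtypes: adenocarcinoma in situ, minimally invasive
#: adenocarcinoma, lepidic-predominant.
LEPIDIC_HISTOLOGIES = frozenset({"AIS", "MIA", "LPA"})


@dataclass
class ClusterAssignment:
    """A two-group partition of samples from hierarchical clustering."""

    labels: pd.Series  # sample -> {1, 2}
    linkage_method: str
    metric: str
    genes: list[str]

    def partition(self) -> frozenset[frozenset[str]]:
        """The unordered bipartition (invariant to label swap)."""
        return frozenset(
            frozenset(self.labels.index[self.labels == g]) for g in (1, 2)
        )

    def group(self, g: int) -> list[str]:
        return list(self.labels.index[self.labels == g])


@dataclass
class SignatureSet:
    """Fixed-point invasiveness signature.

    ``pro_invasive`` genes are up-regulated in the invasive cluster and
    ``indolence`` genes in the non-invasive cluster. When no histology was
    supplied for orientation, cluster 1 plays the invasive role and
    ``oriented`` is False.
    """

    pro_invasive: list[str]
    indolence: list[str]
    assignment: ClusterAssignment
    iterations: int
    converged: bool = True
    invasive_cluster: int = 1
    oriented: bool = False
    de_result: DEResult | None = None

    @property
    def genes(self) -> list[str]:
        return self.pro_invasive + self.indolence

    def invasive_samples(self) -> list[str]:
        return self.assignment.group(self.invasive_cluster)

    def class_labels(self) -> pd.Series:
        """Binary labels: 1 = invasive cluster, 0 = non-invasive cluster."""
        return (self.assignment.labels == self.invasive_cluster).astype(int)


def select_top_variance_genes(expr: pd.DataFrame, n: int = 1000,
                              var_min: float = 1.0) -> list[str]:
    """Top-``n`` genes by descending variance, keeping only variance > var_min."""
    var = expr.var(axis=1, ddof=1)
    var = var[var > var_min].sort_values(ascending=False, kind="stable")
    if var.empty:
        raise ValueError(f"no gene has variance > {var_min}")
    if len(var) < n:
        warnings.warn(f"only {len(var)} genes pass variance > {var_min} "
                      f"(requested {n})")
    return list(var.index[:n])


def _pairwise_distance(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        # 1 - Pearson correlation between samples across genes
        return pdist(x, metric="correlation")
    if metric == "euclidean":
        return pdist(x, metric="euclidean")
    raise ValueError(f"unknown metric: {metric}")


def hierarchical_cluster(expr: pd.DataFrame, genes, k: int = 2,
                         method: str = "complete",
                         metric: str = "correlation",
                         standardize: bool = False) -> ClusterAssignment:
    """Agglomerative clustering of samples on the given genes, cut at k groups.

    Distance between samples defaults to 1 - Pearson correlation across the
    selected genes; complete linkage matches the published dendrograms.
    If the k=2 cut leaves a singleton group, singletons are reassigned to
    the nearer of the two largest clusters of a deeper cut (warning logged).
    """
    genes = [g for g in genes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster on")
    if k > expr.shape[1]:
        raise ValueError("k exceeds the number of samples")
    sub = expr.loc[genes]
    if standardize:
        sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    x = sub.to_numpy(float).T  # samples x genes
    d = _pairwise_distance(x, metric)
    z = linkage(d, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")

    counts = np.bincount(labels)[1:]
    if k == 2 and counts.min() == 1 and len(labels) > 2:
        warnings.warn("k=2 cut produced a singleton group; reassigning "
                      "singletons to the nearest major cluster")
        labels = _rescue_singletons(d, z, len(labels))

    ser = pd.Series(labels, index=expr.columns, name="cluster")
    return ClusterAssignment(labels=ser, linkage_method=method,
                             metric=metric, genes=genes)


def _rescue_singletons(d: np.ndarray, z: np.ndarray, n: int) -> np.ndarray:
    """Cut deeper until two clusters of size >= 2 exist, then assign every
    sample to the nearer (average-distance) of the two largest clusters."""
    from scipy.spatial.distance import squareform

    dm = squareform(d)
    for kk in range(3, n + 1):
        labels = fcluster(z, t=kk, criterion="maxclust")
        sizes = pd.Series(labels).value_counts()
        big = sizes[sizes >= 2]
        if len(big) >= 2:
            top2 = list(big.index[:2])
            members = {g: np.flatnonzero(labels == g) for g in top2}
            out = np.empty(n, dtype=int)
            for i in range(n):
                mean_d = [dm[i, members[g]].mean() if i not in members[g]
                          else dm[i, members[g]].sum() / max(len(members[g]) - 1, 1)
                          for g in top2]
                out[i] = 1 + int(np.argmin(mean_d))
            return out
    return fcluster(z, t=2, criterion="maxclust")


def derive_signature(expr: pd.DataFrame, max_iter: int = 20,
                     n_top: int = 1000, var_min: float = 1.0,
                     fc_thresh: float = 1.5, fdr_thresh: float = 0.01,
                     method: str = "complete", metric: str = "correlation",
                     histology: pd.Series | None = None,
                     exclude_genes=None) -> SignatureSet:
    """Iterate clustering and differential expression to a fixed point.

    Starts from the top-variance genes, clusters the samples into two
    groups, recomputes the differentially expressed genes between them, and
    repeats until both the gene set and the (unordered) sample bipartition
    stop changing. ``exclude_genes`` removes a gene set (e.g. a
    proliferation signature) from every candidate gene list, supporting
    confound-robustness checks.

    If ``histology`` is given the clusters are oriented by
    :func:`label_groups`; otherwise cluster 1 is reported as invasive and
    ``oriented`` is False.
    """
    if expr.shape[1] < 6:
        raise ValueError("need at least 6 samples")
    exclude = set(exclude_genes or ())

    genes = [g for g in select_top_variance_genes(expr, n=n_top, var_min=var_min)
             if g not in exclude]
    if not genes:
        raise ValueError("gene selection exhausted by exclusions")

    assignment = None
    de = None
    prev_partition = None
    prev_genes: set[str] | None = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        assignment = hierarchical_cluster(expr, genes, k=2,
                                          method=method, metric=metric)
        de = differential_expression(expr, assignment.labels.to_numpy(),
                                     fc_thresh=fc_thresh,
                                     fdr_thresh=fdr_thresh)
        new_genes = [g for g in de.genes if g not in exclude]
        if not new_genes:
            raise ValueError("no separating signal: DEG set became empty")
        part = assignment.partition()
        if prev_partition == part and prev_genes == set(new_genes):
            converged = True
            break
        prev_partition, prev_genes = part, set(new_genes)
        genes = new_genes
    if not converged:
        warnings.warn(f"signature iteration did not converge in {max_iter} "
                      "rounds; returning last state")

    # direction is computed with cluster labels 1 < 2, so "up" = up in cluster 2
    up_in_2 = [g for g in de.up if g not in exclude]
    up_in_1 = [g for g in de.down if g not in exclude]

    invasive_cluster, oriented = 1, False
    if histology is not None:
        invasive_cluster = label_groups(assignment, histology)["invasive_group"]
        oriented = True
    pro = up_in_1 if invasive_cluster == 1 else up_in_2
    ind = up_in_2 if invasive_cluster == 1 else up_in_1
    return SignatureSet(pro_invasive=pro, indolence=ind,
                        assignment=assignment, iterations=iterations,
                        converged=converged,
                        invasive_cluster=invasive_cluster,
                        oriented=oriented, de_result=de)


def label_groups(assignment: ClusterAssignment,
                 histology: pd.Series) -> dict:
    """Call the cluster dominated by aggressive histologies "invasive".

    ``histology`` holds per-sample subtype codes (AIS/MIA/LPA vs
    AC/PAP/MP/SOL). The cluster with the higher fraction of aggressive
    subtypes is the invasive group; an exact tie is an error.
    """
    histology = pd.Series(histology)
    missing = [s for s in assignment.labels.index if s not in histology.index]
    if missing:
        raise ValueError(f"histology missing for samples: {missing[:5]}")
    fracs = {}
    for g in (1, 2):
        members = assignment.group(g)
        h = histology.loc[members]
        fracs[g] = float(h.isin(AGGRESSIVE_HISTOLOGIES).mean())
    if fracs[1] == fracs[2]:
        raise ValueError("ambiguous labeling: equal aggressive-histology "
                         "fractions in both clusters")
    invasive = 1 if fracs[1] > fracs[2] else 2
    return {"invasive_group": invasive,
            "non_invasive_group": 3 - invasive,
            "aggressive_fraction": fracs}
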