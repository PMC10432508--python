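"""Haplotype clustering and sweep-phenotype association within peak windows.

Within a window of interest, pairwise genetic distance between phased
haplotypes is D_xy = (number of differing sites) / (sites in window).
Agglomerative clustering (complete linkage, so every within-cluster pair
sits within the cut height) is cut at D_xy = 0.001, grouping
near-identical haplotypes that descend from a recent sweep.  Clusters
larger than 20 haplotypes are tested for phenotype association with a
binomial-logit GLM on the per-sample haplotype dose (0/1/2 copies), and
the SNPs distinguishing a cluster are found by a one-sided Fisher exact
test of allele counts on- versus off-cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._glm import logistic_lrt

CUT_HEIGHT = 0.001
MIN_CLUSTER = 20         # strict: clusters must be larger than this
ENRICH_ALPHA = 0.001


def pairwise_dxy(hap: np.ndarray) -> np.ndarray:
    """Pairwise D_xy between haplotype rows (proportion of differing sites)."""
    hap = np.asarray(hap, dtype=np.int8)
    if hap.shape[1] == 0:
        raise ValueError("empty window")
    h = hap.astype(np.float64)
    # Hamming distance for 0/1 data via inner products
    ones = h @ h.T
    zeros = (1 - h) @ (1 - h).T
    diff = hap.shape[1] - ones - zeros
    np.fill_diagonal(diff, 0.0)
    return diff / hap.shape[1]


def cut_clusters(dxy: np.ndarray, height: float = CUT_HEIGHT,
                 linkage: str = "complete") -> np.ndarray:
    """Agglomerative clustering cut at a fixed height (non-strict, <=).

    Returns integer cluster labels per haplotype; singleton clusters are
    allowed.
    """
    n = dxy.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    condensed = squareform(dxy, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return hierarchy.fcluster(Z, t=height, criterion="distance") - 1


def haplotype_dose(labels: np.ndarray, cluster: int) -> np.ndarray:
    """Per-sample copies (0/1/2) of a haplotype cluster.

    Haplotype rows 2i and 2i+1 belong to sample i.
    """
    member = (labels == cluster).astype(int)
    return member[0::2] + member[1::2]


@dataclass
class ClusterAssociation:
    cluster: int
    size: int
    p_value: float | None
    direction: int                      # sign of slope; 0 when untestable
    tested: bool
    flagged_no_variance: bool = False


def cluster_association_glm(dose: np.ndarray, phenotypes: np.ndarray
                            ) -> tuple[float | None, int, bool]:
    """Binomial-logit GLM of phenotype on haplotype dose.

    Returns (likelihood-ratio p, direction sign, no-variance flag).  A
    dose vector with no variance cannot be tested.
    """
    dose = np.asarray(dose)
    if np.ptp(dose) == 0:
        return None, 0, True
    p, b, _ = logistic_lrt(dose[None, :], phenotypes)
    return float(p[0]), int(np.sign(b[0])), False


@dataclass
class EnrichedSNP:
    index: int
    position: int
    p_value: float
    freq_on: float
    freq_off: float
    annotation: str | None = None


def cluster_snp_enrichment(hap: np.ndarray, labels: np.ndarray, cluster: int,
                           positions: Sequence[int] | None = None,
                           annotations: Sequence[str | None] | None = None,
                           alpha: float = ENRICH_ALPHA) -> list[EnrichedSNP]:
    """SNPs significantly more frequent on a cluster than off it.

    One-sided Fisher exact test per site on the 2x2 table of alt-allele
    counts among cluster vs non-cluster haplotypes; sites with p < alpha
    and higher on-cluster frequency are reported.
    """
    on = labels == cluster
    off = ~on
    if not on.any() or not off.any():
        raise ValueError("cluster and complement must both be non-empty")
    n_on, n_off = int(on.sum()), int(off.sum())
    alt_on = hap[on].sum(axis=0)
    alt_off = hap[off].sum(axis=0)
    out = []
    for j in range(hap.shape[1]):
        a, c = int(alt_on[j]), int(alt_off[j])
        f_on, f_off = a / n_on, c / n_off
        if f_on <= f_off:
            continue
        _, p = stats.fisher_exact([[a, n_on - a], [c, n_off - c]],
                                  alternative="greater")
        if p < alpha:
            out.append(EnrichedSNP(
                index=j,
                position=int(positions[j]) if positions is not None else j,
                p_value=float(p), freq_on=f_on, freq_off=f_off,
                annotation=(annotations[j] if annotations is not None
                            else None)))
    return out


def dendrogram_newick(dxy: np.ndarray,
                      leaf_names: Sequence[str] | None = None,
                      linkage: str = "complete") -> str:
    """Newick string for the clustering dendrogram of a window.

    Branch lengths are differences in merge height, so leaf-to-root path
    lengths equal the cophenetic height of the root.
    """
    n = dxy.shape[0]
    if leaf_names is None:
        leaf_names = [f"h{i}" for i in range(n)]
    if n == 1:
        return f"{leaf_names[0]};"
    Z = hierarchy.linkage(squareform(dxy, checks=False), method=linkage)
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height):
        length = max(parent_height - (0.0 if node.is_leaf()
                                      else node.dist), 0.0)
        if node.is_leaf():
            length = parent_height
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


@dataclass
class HaplotypeClusterSet:
    """Clustering result for one window, with per-cluster association."""

    dxy: np.ndarray
    labels: np.ndarray
    associations: list[ClusterAssociation]
    cut_height: float = CUT_HEIGHT

    def cluster_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


def analyse_window(hap: np.ndarray, phenotypes: np.ndarray,
                   cut_height: float = CUT_HEIGHT,
                   min_cluster: int = MIN_CLUSTER,
                   linkage: str = "complete") -> HaplotypeClusterSet:
    """Cluster one window's haplotypes and test large clusters.

    ``phenotypes`` is per sample (half the haplotype count).  Only
    clusters strictly larger than ``min_cluster`` haplotypes are tested.
    """
    dxy = pairwise_dxy(hap)
    labels = cut_clusters(dxy, cut_height, linkage)
    associations = []
    for cl, size in sorted(
            zip(*np.unique(labels, return_counts=True)),
            key=lambda t: -t[1]):
        if size > min_cluster:
            dose = haplotype_dose(labels, cl)
            p, direction, flagged = cluster_association_glm(dose, phenotypes)
            associations.append(ClusterAssociation(
                int(cl), int(size), p, direction, tested=not flagged,
                flagged_no_variance=flagged))
        else:
            associations.append(ClusterAssociation(
                int(cl), int(size), None, 0, tested=False))
    return HaplotypeClusterSet(dxy, labels, associations, cut_height)
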