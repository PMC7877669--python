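"""Node statistics and greedy cluster extraction.

For node m with neighbor set N_m: degree d_m = |N_m|, clustering
coefficient gamma_m = |E(N_m)| / (d_m (d_m - 1)/2) (defined as 0 for
d_m <= 1).  gamma_m * d_m is roughly the average degree among m's
neighbors, so the score s_m = d_m + gamma_m * d_m prefers centers whose
clusters are both large and densely interconnected.

Clusters are extracted greedily: pick the unassigned node with maximal
s_m (ties to the lowest node index), take it plus all its neighbors in
the full graph as a cluster, mark the members assigned, repeat.  Clusters
below the minimum size are discarded but still consume their center, so
their members stay available to later clusters.  The procedure is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import Network

__all__ = ["NodeStats", "Cluster", "ClusterSet", "node_stats", "find_clusters",
           "write_clusters"]


@dataclass
class NodeStats:
    """Per-node degree, clustering coefficient, and selection score."""

    gene_ids: list[str]
    degree: np.ndarray     # int
    gamma: np.ndarray      # in [0, 1]
    score: np.ndarray      # d + gamma * d


@dataclass
class Cluster:
    center: int
    members: np.ndarray    # node indices, includes the center

    @property
    def size(self) -> int:
        return self.members.size


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    min_size: int
    gene_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)


def node_stats(net: Network) -> NodeStats:
    """Degree and clustering coefficient of every node."""
    adj = net.adjacency()
    adj_bool = adj.astype(bool)
    degree = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
    gamma = np.zeros(net.n_nodes)
    for m in range(net.n_nodes):
        d = degree[m]
        if d <= 1:
            continue
        nbrs = adj.indices[adj.indptr[m]:adj.indptr[m + 1]]
        links = adj_bool[nbrs][:, nbrs].nnz // 2
        gamma[m] = links / (d * (d - 1) / 2)
    return NodeStats(
        gene_ids=list(net.gene_ids),
        degree=degree,
        gamma=gamma,
        score=degree + gamma * degree,
    )


def find_clusters(net: Network, min_size: int = 30) -> ClusterSet:
    """Greedy extraction of dense clusters around high-score centers.

    Scores and neighborhoods are those of the full graph and are not
    recomputed as nodes get assigned.  Members may overlap across
    clusters (a node can neighbor two centers); centers never repeat.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    stats = node_stats(net)
    adj = net.adjacency()
    nbr = [adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
           for i in range(net.n_nodes)]
    assigned = np.zeros(net.n_nodes, dtype=bool)
    clusters: list[Cluster] = []
    while not assigned.all():
        cand = np.nonzero(~assigned)[0]
        # argmax of score with ties to the lowest index (argmax returns the
        # first maximum, and cand is sorted)
        center = int(cand[np.argmax(stats.score[cand])])
        members = np.unique(np.append(nbr[center], center))
        if members.size >= min_size:
            clusters.append(Cluster(center=center, members=members))
            assigned[members] = True
        assigned[center] = True  # undersized: only the center is consumed
    return ClusterSet(clusters=clusters, min_size=min_size,
                      gene_ids=list(net.gene_ids))


def write_clusters(cs: ClusterSet, net: Network, path) -> None:
    """Cluster TSV: cluster_id, center_gene, member_gene, degree, gamma."""
    stats = node_stats(net)
    with open(path, "w") as fh:
        fh.write("cluster_id\tcenter_gene\tmember_gene\tdegree\tgamma\n")
        for cid, cl in enumerate(cs, start=1):
            center_gene = cs.gene_ids[cl.center]
            for m in cl.members:
                fh.write(
                    f"{cid}\t{center_gene}\t{cs.gene_ids[m]}\t"
                    f"{stats.degree[m]}\t{stats.gamma[m]:.6f}\n"
                )
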