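"""K-mer-sharing read graph and repeat clustering of a pooled read set.

Reads from the same repeat family share many k-mers even at a few percent
sequence divergence, while single-copy reads at very low genome coverage
rarely overlap at all. Building a graph whose edges connect read pairs
sharing at least ``min_shared_kmers`` canonical k-mers and taking connected
components therefore groups reads into putative repeat families. This is a
deliberately transparent, deterministic emulation of graph-based repeat
clustering: components of a thresholded k-mer-overlap graph rather than a
hierarchical community agglomeration, so every result can be re-derived by
brute force on small pools.

With the defaults (k = 13, 20 shared k-mers on 140-bp reads) an edge
requires roughly a 32-bp exact-overlap equivalent and tolerates on the
order of 8-10% pairwise divergence over a full-length overlap — the
emulation of a ~90% read-joining identity criterion.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .readprep import PooledReads
from .seqs import canonical_kmers

DEFAULT_K = 13
DEFAULT_MIN_SHARED = 20
DEFAULT_MIN_CLUSTER_READS = 2
DEFAULT_MIN_FRACTION = 0.0001


@dataclass
class ClusterTable:
    """Per-cluster x per-individual counts and genome-proportion estimates.

    ``table`` has one row per retained cluster: ``cluster_id`` (rank by
    total size, 1 = largest over *all* clusters, so filtered ids may be
    non-contiguous), a ``count_<individual>`` and ``pct_<individual>``
    column per individual (the percent of that individual's sampled reads,
    the genome-proportion proxy), ``total`` and ``fraction_of_pool``.
    ``clustered_fraction`` counts all clustered reads, retained or not.
    """

    table: pd.DataFrame
    clustered_fraction: float
    members: dict[int, list[str]] = field(default_factory=dict)
    tag_map: dict = field(default_factory=dict)

    def counts(self, cluster_id: int, sex: str) -> list[int]:
        row = self.table.set_index("cluster_id").loc[cluster_id]
        return [
            int(row[f"count_{ind}"])
            for ind, tag in self.tag_map.items()
            if tag.sex == sex
        ]

    def n_sampled(self, sex: str) -> list[int]:
        return [tag.n_reads for tag in self.tag_map.values() if tag.sex == sex]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_read_graph(
    pool: PooledReads,
    k: int = DEFAULT_K,
    min_shared_kmers: int = DEFAULT_MIN_SHARED,
) -> nx.Graph:
    """Graph over read indices; edge weight = shared canonical k-mer count.

    K-mers are canonicalized (lexicographic minimum of k-mer and reverse
    complement) so the graph is strand-independent; k-mers containing N are
    skipped. An edge exists iff the two reads' canonical k-mer sets share
    at least ``min_shared_kmers`` elements.
    """
    if min_shared_kmers < 1:
        raise ValueError("min_shared_kmers must be >= 1")
    read_len = min((len(seq) for _, seq in pool.reads), default=None)
    if read_len is not None and k >= read_len:
        raise ValueError(f"k ({k}) must be smaller than the read length ({read_len})")

    graph = nx.Graph()
    graph.add_nodes_from(range(len(pool.reads)))

    # inverted index: k-mer -> reads containing it; each distinct shared
    # k-mer contributes exactly 1 to a pair, so the accumulated counts are
    # exact set-intersection sizes.
    index: dict[str, list[int]] = defaultdict(list)
    for i, (_, seq) in enumerate(pool.reads):
        for kmer in canonical_kmers(seq, k):
            index[kmer].append(i)

    shared: dict[tuple[int, int], int] = defaultdict(int)
    for reads_with in index.values():
        m = len(reads_with)
        if m < 2:
            continue
        for a in range(m):
            ia = reads_with[a]
            for b in range(a + 1, m):
                shared[(ia, reads_with[b])] += 1

    for (i, j), w in shared.items():
        if w >= min_shared_kmers:
            graph.add_edge(i, j, weight=w)
    return graph


def cluster_reads(
    graph: nx.Graph, min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS
) -> list[list[int]]:
    """Connected components with >= ``min_cluster_reads`` members.

    Sorted by size descending; ties broken by smallest member read index.
    Components below the size floor (singletons by default) are the
    'unclustered' remainder and are not returned.
    """
    comps = [
        sorted(c) for c in nx.connected_components(graph) if len(c) >= min_cluster_reads
    ]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def tabulate_clusters(
    clusters: list[list[int]],
    pool: PooledReads,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ClusterTable:
    """Per-cluster, per-individual counts with a pool-fraction floor.

    Clusters are ranked by total size over the full cluster list (1 =
    largest), then only those holding at least ``min_fraction`` of the pool
    are retained — the low-abundance filter applied before enrichment
    testing. ``clustered_fraction`` still counts every clustered read.
    """
    seen: set[int] = set()
    for c in clusters:
        for i in c:
            if i in seen:
                raise ValueError(f"read index {i} appears in more than one cluster")
            seen.add(i)

    n_pool = len(pool.reads)
    clustered = sum(len(c) for c in clusters)
    inds = list(pool.tag_map)

    rows = []
    members: dict[int, list[str]] = {}
    ranked = sorted(
        enumerate(clusters), key=lambda t: (-len(clusters[t[0]]), clusters[t[0]][0])
    ) if clusters else []
    for rank, (_, cluster) in enumerate(ranked, start=1):
        frac = len(cluster) / n_pool if n_pool else 0.0
        if frac < min_fraction:
            continue
        counts = {ind: 0 for ind in inds}
        ids = []
        for i in cluster:
            rid = pool.reads[i][0]
            counts[pool.individual_of(rid)] += 1
            ids.append(rid)
        row: dict = {"cluster_id": rank}
        for ind in inds:
            row[f"count_{ind}"] = counts[ind]
        row["total"] = len(cluster)
        row["fraction_of_pool"] = frac
        for ind in inds:
            row[f"pct_{ind}"] = counts[ind] / pool.tag_map[ind].n_reads * 100.0
        rows.append(row)
        members[rank] = ids

    columns = (
        ["cluster_id"]
        + [f"count_{ind}" for ind in inds]
        + ["total", "fraction_of_pool"]
        + [f"pct_{ind}" for ind in inds]
    )
    table = pd.DataFrame(rows, columns=columns)
    return ClusterTable(
        table=table,
        clustered_fraction=clustered / n_pool if n_pool else 0.0,
        members=members,
        tag_map=dict(pool.tag_map),
    )
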