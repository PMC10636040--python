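"""Bottom-up agglomerative clustering of read 5' positions with average
linkage, and TSS-cluster summaries.

The distance between clusters A and B is the mean pairwise absolute distance

    L(A, B) = (1 / (n_A * n_B)) * sum_i sum_j |x_Ai - x_Bj|

and agglomeration proceeds from singletons, always merging the pair with the
smallest linkage, until the smallest inter-cluster linkage reaches the cutoff
(default 100 bp): two clusters at or above the cutoff are never merged.
Clustering operates on UMI-deduplicated read starts, so each surviving
(cell barcode, UMI) pair contributes one position sample.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .filters import FilterConfig, has_unencoded_g
from .io_models import GeneModel, Read1Record

_TIE_RTOL = 1e-9


@dataclass
class TSSCluster:
    """A candidate TSS region with per-position UMI counts and features."""

    gene_id: str
    chrom: str
    strand: str
    position_counts: dict[int, int]
    summit_pos: int = field(init=False)
    summit_count: int = field(init=False)
    total_umi: int = field(init=False)
    std_dev: float = 0.0
    unencoded_g_frac: float = 0.0
    prob_true: float | None = None
    name: str | None = None
    is_novel: bool = False
    feature_class: str | None = None

    def __post_init__(self):
        if not self.position_counts:
            raise ValueError("empty cluster")
        self.total_umi = sum(self.position_counts.values())
        best = max(self.position_counts.values())
        candidates = sorted(p for p, c in self.position_counts.items() if c == best)
        # summit tie-break: the 5'-most position in transcription direction
        self.summit_pos = candidates[0] if self.strand == "+" else candidates[-1]
        self.summit_count = best

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.position_counts), max(self.position_counts))


def average_linkage(a, b) -> float:
    """Mean pairwise absolute distance between two position multisets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("average_linkage requires non-empty clusters")
    return float(np.abs(a[:, None] - b[None, :]).mean())


def cluster_read_starts(positions, linkage_cutoff: float = 100.0) -> list[list[int]]:
    """Agglomerate a position multiset into clusters.

    Duplicate positions are collapsed to weighted points internally (the
    average linkage of multisets equals the count-weighted linkage of their
    supports), and cluster linkages are maintained with the Lance-Williams
    update for weighted average linkage. Ties in the minimal linkage are
    broken toward the pair with the smaller leftmost coordinate. Returns
    position multisets sorted by leftmost member; together they partition
    the input.
    """
    positions = sorted(positions)
    if not positions:
        return []
    counts = Counter(positions)
    uniq = np.array(sorted(counts), dtype=float)
    sizes = np.array([counts[u] for u in sorted(counts)], dtype=float)
    k = len(uniq)
    if k == 1:
        return [positions]
    dist = np.abs(uniq[:, None] - uniq[None, :])
    np.fill_diagonal(dist, np.inf)
    active = np.ones(k, dtype=bool)
    leftmost = uniq.copy()
    members: list[list[int]] = [[int(u)] * counts[u] for u in sorted(counts)]

    while active.sum() > 1:
        sub = np.where(active)[0]
        m = dist[np.ix_(sub, sub)]
        mval = m.min()
        if mval >= linkage_cutoff:
            break
        tie = np.argwhere(m <= mval * (1 + _TIE_RTOL) + 1e-12)
        pairs = [(sub[i], sub[j]) for i, j in tie if i < j]
        i, j = min(pairs, key=lambda p: (min(leftmost[p[0]], leftmost[p[1]]),
                                         max(leftmost[p[0]], leftmost[p[1]])))
        ni, nj = sizes[i], sizes[j]
        dist[i, :] = (ni * dist[i, :] + nj * dist[j, :]) / (ni + nj)
        dist[:, i] = dist[i, :]
        dist[i, i] = np.inf
        sizes[i] = ni + nj
        leftmost[i] = min(leftmost[i], leftmost[j])
        members[i] = sorted(members[i] + members[j])
        active[j] = False
        dist[j, :] = np.inf
        dist[:, j] = np.inf

    out = [members[i] for i in np.where(active)[0]]
    out.sort(key=lambda c: c[0])
    return out


def dedup_umis(reads: list[Read1Record]) -> list[Read1Record]:
    """One record per (cell barcode, UMI): the first in coordinate order."""
    seen: dict[tuple[str, str], Read1Record] = {}
    for r in sorted(reads, key=lambda r: (r.five_prime_pos, r.cell_barcode, r.umi)):
        seen.setdefault((r.cell_barcode, r.umi), r)
    return list(seen.values())


def summarize_cluster(members: list[Read1Record], gene: GeneModel,
                      cfg: FilterConfig | None = None) -> TSSCluster:
    """Summarize UMI-deduplicated member reads into a :class:`TSSCluster`.

    The standard deviation is the sample standard deviation (ddof=1) of the
    position multiset, treating each UMI as one sample; single-UMI clusters
    get 0. ``unencoded_g_frac`` is the fraction of member reads whose leading
    soft clip marks an unencoded G.
    """
    if not members:
        raise ValueError("empty member list")
    positions = [r.five_prime_pos for r in members]
    counts = dict(sorted(Counter(positions).items()))
    if len(positions) > 1:
        std = float(np.std(positions, ddof=1))
    else:
        std = 0.0
    g_frac = sum(has_unencoded_g(r, cfg) for r in members) / len(members)
    cl = TSSCluster(gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                    position_counts=counts)
    cl.std_dev = std
    cl.unencoded_g_frac = g_frac
    return cl


def apply_umi_filter(clusters: list[TSSCluster], min_umi: int = 50) -> list[TSSCluster]:
    """Keep clusters with at least ``min_umi`` total UMIs."""
    return [c for c in clusters if c.total_umi >= min_umi]


def apply_distance_filter(clusters: list[TSSCluster], min_dist: int = 300) -> list[TSSCluster]:
    """Greedy summit-distance control within a gene: walking clusters in
    descending UMI count, keep one iff its summit is at least ``min_dist``
    from every already-kept summit."""
    kept: list[TSSCluster] = []
    for c in sorted(clusters, key=lambda c: (-c.total_umi, c.summit_pos)):
        if all(abs(c.summit_pos - k.summit_pos) >= min_dist for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.summit_pos)
    return kept
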