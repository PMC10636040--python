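"""Agglomerative clustering of read starts and cluster summaries, checked
against a brute-force oracle that recomputes every linkage from the raw
positions."""
import numpy as np
import pytest

from captss.clustering import (apply_distance_filter, apply_umi_filter,
                               average_linkage, cluster_read_starts,
                               dedup_umis, summarize_cluster, TSSCluster)
from captss.io_models import GeneModel

from conftest import make_read

GENE = GeneModel("G", "chr1", "+", 0, 10**6)


def oracle_agglomerate(positions, cutoff=100.0):
    """Reference implementation: keeps explicit member lists and evaluates
    every inter-cluster linkage directly from the raw member positions (mean
    pairwise |x - y|, no recurrence), with the same leftmost tie-break as
    the production code. Only the minimum search uses a matrix."""
    clusters = [[p] for p in sorted(positions)]
    k = len(clusters)
    if k == 0:
        return []
    # for singletons the definition reduces to |x - y| exactly
    pos0 = np.array([c[0] for c in clusters], dtype=float)
    dist = np.abs(pos0[:, None] - pos0[None, :])
    np.fill_diagonal(dist, np.inf)
    alive = list(range(k))
    while len(alive) > 1:
        sub = dist[np.ix_(alive, alive)]
        m = sub.min()
        if m >= cutoff:
            break
        ties = np.argwhere(sub <= m * (1 + 1e-9) + 1e-12)
        pairs = [(alive[i], alive[j]) for i, j in ties if i < j]
        i, j = min(pairs, key=lambda p: (min(clusters[p[0]][0], clusters[p[1]][0]),
                                         max(clusters[p[0]][0], clusters[p[1]][0])))
        clusters[i] = sorted(clusters[i] + clusters[j])
        alive.remove(j)
        for o in alive:
            if o != i:
                d = average_linkage(clusters[i], clusters[o])
                dist[i, o] = dist[o, i] = d
    return sorted((clusters[i] for i in alive), key=lambda c: c[0])


@pytest.mark.parametrize("a,b,expected", [
    ([100, 102], [110], 9.0),
    ([50], [50], 0.0),
    ([0], [100], 100.0),
])
def test_average_linkage_values(a, b, expected):
    assert average_linkage(a, b) == pytest.approx(expected)


def test_average_linkage_rejects_empty():
    with pytest.raises(ValueError):
        average_linkage([], [1])


@pytest.mark.parametrize("positions,expected", [
    ([100, 101, 102, 500, 501], [[100, 101, 102], [500, 501]]),
    ([0, 99], [[0, 99]]),        # linkage 99 < 100: merged
    ([0, 100], [[0], [100]]),    # linkage at the cutoff: never merged
    ([], []),
    ([42], [[42]]),
])
def test_clustering_known_cases(positions, expected):
    assert cluster_read_starts(positions) == expected


def test_clustering_matches_oracle_on_random_instances(rng):
    """The Lance-Williams implementation equals brute-force agglomeration on
    random multisets, including duplicated positions."""
    for _ in range(200):
        n = int(rng.integers(2, 200))
        span = int(rng.integers(50, 2000))
        positions = rng.integers(0, span, size=n).tolist()
        fast = cluster_read_starts(positions)
        slow = oracle_agglomerate(positions)
        assert fast == slow


def test_clustering_partition_and_translation(rng):
    for _ in range(20):
        positions = rng.integers(0, 1500, size=60).tolist()
        clusters = cluster_read_starts(positions)
        assert sorted(p for c in clusters for p in c) == sorted(positions)
        shifted = cluster_read_starts([p + 1000 for p in positions])
        assert shifted == [[p + 1000 for p in c] for c in clusters]


def test_output_clusters_pairwise_above_cutoff(rng):
    for _ in range(20):
        positions = rng.integers(0, 3000, size=80).tolist()
        clusters = cluster_read_starts(positions)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                assert average_linkage(clusters[i], clusters[j]) >= 100.0


def _cluster_from_counts(counts, strand="+", g_frac=0.0):
    reads = []
    k = 0
    for pos, n in counts.items():
        for _ in range(n):
            reads.append(make_read(pos=pos, umi=f"u{k}", strand=strand))
            k += 1
    gene = GeneModel("G", "chr1", strand, 0, 10**6)
    return summarize_cluster(reads, gene)


def test_summarize_counts_summit_and_std():
    cl = _cluster_from_counts({100: 3, 101: 7})
    assert cl.total_umi == 10
    assert cl.summit_pos == 101
    assert cl.summit_count == 7
    # sample std (ddof=1) of the multiset {100 x3, 101 x7}
    assert cl.std_dev == pytest.approx(
        np.std([100] * 3 + [101] * 7, ddof=1), abs=1e-9)
    assert cl.std_dev == pytest.approx(0.483, abs=5e-4)


def test_summit_tie_breaks_to_five_prime_most():
    plus = _cluster_from_counts({100: 5, 120: 5})
    minus = _cluster_from_counts({100: 5, 120: 5}, strand="-")
    assert plus.summit_pos == 100
    assert minus.summit_pos == 120


def test_unencoded_g_fraction():
    reads = [make_read(pos=10, umi=f"g{i}", cigar=[("S", 14), ("M", 80)])
             for i in range(4)]
    reads += [make_read(pos=10, umi=f"n{i}", cigar=[("S", 9), ("M", 80)])
              for i in range(6)]
    cl = summarize_cluster(reads, GENE)
    assert cl.unencoded_g_frac == pytest.approx(0.4)


def test_single_umi_cluster_has_zero_std():
    cl = _cluster_from_counts({55: 1})
    assert cl.std_dev == 0.0


def test_dedup_umis_keeps_one_record_per_cell_umi():
    reads = [make_read(pos=5, cb="C1", umi="U1"),
             make_read(pos=6, cb="C1", umi="U1"),
             make_read(pos=5, cb="C2", umi="U1"),
             make_read(pos=7, cb="C1", umi="U2")]
    dd = dedup_umis(reads)
    assert len(dd) == 3
    assert {(r.cell_barcode, r.umi) for r in dd} == {("C1", "U1"), ("C2", "U1"), ("C1", "U2")}


def _mk(counts, strand="+"):
    cl = TSSCluster("G", "chr1", strand, dict(counts))
    return cl


def test_umi_filter_boundary():
    keep = _mk({0: 50})
    drop = _mk({0: 49})
    assert apply_umi_filter([keep, drop], 50) == [keep]
    assert apply_umi_filter([], 50) == []
    assert apply_umi_filter([drop], 0) == [drop]


def test_distance_filter_greedy_by_count():
    strong = _mk({0: 100})
    weak = _mk({200: 60})
    assert apply_distance_filter([strong, weak], 300) == [strong]
    far = _mk({400: 60})
    assert apply_distance_filter([strong, far], 300) == [strong, far]
    assert apply_distance_filter([weak], 300) == [weak]
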