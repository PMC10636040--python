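"""Assignment of detected TSS clusters to annotated transcript starts by
minimum-total-distance matching, cluster naming, and genomic-feature calls.

For one gene with clusters c = 1..n_c and transcripts t = 1..n_t, the cost
matrix is C[c, t] = |tss_t - summit_c| in bp and the matching minimises
sum C[c, t] X[c, t] over partial matchings X that pair each cluster and each
transcript at most once (Hungarian / linear sum assignment); rectangular
matrices are matched on the smaller dimension, leaving surplus clusters
unassigned (hence novel) or surplus transcripts unused.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import TSSCluster
from .io_models import GeneModel, TranscriptModel

log = logging.getLogger(__name__)

FEATURE_PRECEDENCE = ("5'UTR", "3'UTR", "exon", "intron")


@dataclass
class AssignmentResult:
    cost_matrix: np.ndarray
    pairs: list[tuple[int, int]]
    total_cost: float


def build_cost_matrix(clusters: list[TSSCluster],
                      transcripts: list[TranscriptModel]) -> np.ndarray:
    summits = np.array([c.summit_pos for c in clusters], dtype=float)
    starts = np.array([t.tss_position for t in transcripts], dtype=float)
    return np.abs(summits[:, None] - starts[None, :])


def _optimal_cost(cost: np.ndarray) -> float:
    if cost.size == 0 or 0 in cost.shape:
        return 0.0
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].sum())


def assign_transcripts(cost: np.ndarray) -> AssignmentResult:
    """Minimal-total-distance partial matching on the smaller dimension.

    Among cost-equal optima the lexicographically smallest pair set is
    returned: rows are fixed in order to the smallest column that still
    admits an optimal completion (checked by re-solving the remainder).
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost matrix must be non-empty 2-D")
    n_c, n_t = cost.shape
    n_match = min(n_c, n_t)
    best = _optimal_cost(cost)

    pairs: list[tuple[int, int]] = []
    used_cols: set[int] = set()
    fixed_cost = 0.0
    for r in range(n_c):
        if len(pairs) == n_match:
            break
        rows_left_after = n_c - r - 1
        free_cols = [c for c in range(n_t) if c not in used_cols]
        chosen = None
        for c in sorted(free_cols):
            rem_rows = list(range(r + 1, n_c))
            rem_cols = [x for x in free_cols if x != c]
            sub = cost[np.ix_(rem_rows, rem_cols)] if rem_rows and rem_cols else np.empty((0, 0))
            total = fixed_cost + cost[r, c] + _optimal_cost(sub)
            if np.isclose(total, best, rtol=0, atol=1e-9):
                chosen = c
                break
        if chosen is None:
            # optimality requires skipping this row (only possible when n_c > n_t)
            if rows_left_after < n_match - len(pairs):
                raise RuntimeError("assignment refinement failed")  # pragma: no cover
            continue
        pairs.append((r, chosen))
        used_cols.add(chosen)
        fixed_cost += cost[r, chosen]

    return AssignmentResult(cost_matrix=cost, pairs=pairs, total_cost=best)


def name_cluster(cluster: TSSCluster, assigned: TranscriptModel | None,
                 ordinal: int = 1) -> tuple[str, bool]:
    """Name a cluster after its assigned transcript when that transcript's
    start lies within the cluster span (inclusive); otherwise it is a novel
    TSS named ``<gene>_newTSS_<ordinal>``."""
    lo, hi = cluster.span
    if assigned is not None and lo <= assigned.tss_position <= hi:
        return f"{cluster.gene_id}_{assigned.transcript_id}", False
    return f"{cluster.gene_id}_newTSS_{ordinal}", True


def annotate_gene_clusters(clusters: list[TSSCluster], gene: GeneModel) -> None:
    """Assign, name, and feature-classify all clusters of one gene in place.

    Novel ordinals are assigned in genomic-position order among the novel
    clusters of the gene.
    """
    assigned: dict[int, TranscriptModel] = {}
    if gene.transcripts and clusters:
        cost = build_cost_matrix(clusters, gene.transcripts)
        res = assign_transcripts(cost)
        assigned = {ci: gene.transcripts[ti] for ci, ti in res.pairs}
    novel: list[TSSCluster] = []
    for i, c in enumerate(clusters):
        name, is_novel = name_cluster(c, assigned.get(i))
        if is_novel:
            novel.append(c)
        else:
            c.name, c.is_novel = name, False
        c.feature_class = assign_genomic_feature(c, gene)
    for k, c in enumerate(sorted(novel, key=lambda c: c.summit_pos), start=1):
        c.name, _ = name_cluster(c, None, ordinal=k)
        c.is_novel = True


def assign_genomic_feature(cluster: TSSCluster, gene: GeneModel) -> str:
    """Classify the cluster's start site (5'-most span bound along the
    transcription direction) against the gene's feature intervals with
    precedence 5'UTR > 3'UTR > exon > intron."""
    lo, hi = cluster.span
    start = lo if cluster.strand == "+" else hi
    for label in FEATURE_PRECEDENCE:
        for s, e in gene.feature_intervals.get(label, []):
            if s <= start < e:
                return label
    log.warning("cluster start %d of %s in no annotated feature; calling intron",
                start, cluster.gene_id)
    return "intron"
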