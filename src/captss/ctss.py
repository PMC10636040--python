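"""Single-nucleotide start-site (CTSS) detection inside a validated TSS
cluster, farthest-pair selection and per-cell PSI.

Only reads with the unencoded-G cap signature contribute. For a query
position with UMI count C0, a sliding window of W positions downstream along
the transcription direction gives the fold change

    FC = (C0 + 1) / ((1/W) * sum_{i=1..W} C_i + 1)

and a position is a CTSS when both its count and FC clear the thresholds
(defaults: count >= 100, FC >= 6, W = 15). Positions absent from the count
map contribute C_i = 0; windows truncated at the cluster edge still divide
by W.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import TSSCluster, dedup_umis
from .filters import FilterConfig, has_unencoded_g
from .io_models import Read1Record

log = logging.getLogger(__name__)


@dataclass
class CTSSRecord:
    position: int
    count: int
    fold_change: float
    window: int


def ctss_position_counts(cluster: TSSCluster,
                         reads: list[Read1Record],
                         cfg: FilterConfig | None = None) -> dict[int, int]:
    """UMI counts per 5' position within the cluster span, using only reads
    carrying the unencoded-G signature."""
    lo, hi = cluster.span
    kept = [r for r in dedup_umis(reads)
            if has_unencoded_g(r, cfg) and lo <= r.five_prime_pos <= hi]
    return dict(sorted(Counter(r.five_prime_pos for r in kept).items()))


def fold_change(counts: dict[int, int], pos: int, W: int = 15,
                direction: str = "+") -> float:
    """Sliding-window fold change at ``pos`` (window strictly downstream
    along the transcription direction)."""
    if W < 1:
        raise ValueError("window size must be >= 1")
    c0 = counts.get(pos, 0)
    step = 1 if direction == "+" else -1
    downstream = sum(counts.get(pos + step * i, 0) for i in range(1, W + 1))
    return (c0 + 1) / (downstream / W + 1)


def detect_ctss(cluster: TSSCluster, reads: list[Read1Record], W: int = 15,
                min_fc: float = 6.0, min_count: int = 100,
                cfg: FilterConfig | None = None) -> list[CTSSRecord]:
    """Positions passing both thresholds (inclusive), in coordinate order."""
    counts = ctss_position_counts(cluster, reads, cfg)
    out = []
    for pos in sorted(counts):
        c0 = counts[pos]
        if c0 < min_count:
            continue
        fc = fold_change(counts, pos, W=W, direction=cluster.strand)
        if fc >= min_fc:
            out.append(CTSSRecord(position=pos, count=c0, fold_change=fc, window=W))
    return out


def farthest_ctss_pair(ctss: list[CTSSRecord], strand: str
                       ) -> tuple[CTSSRecord, CTSSRecord] | None:
    """The two records with maximal coordinate separation; the first element
    is the most upstream along the transcription direction."""
    if len(ctss) < 2:
        log.info("fewer than two CTSS; no pair selected")
        return None
    lo = min(ctss, key=lambda r: r.position)
    hi = max(ctss, key=lambda r: r.position)
    return (lo, hi) if strand == "+" else (hi, lo)


def compute_psi(c1: float, c2: float) -> float:
    """Proportion of the first (most upstream) start among the two: c1/(c1+c2).
    NaN when both counts are zero."""
    if c1 + c2 == 0:
        return float("nan")
    return c1 / (c1 + c2)


def per_cell_psi(reads: list[Read1Record], pos1: int, pos2: int) -> pd.DataFrame:
    """Per-cell UMI counts at two selected start positions and the resulting
    PSI (cells with no counts at either position are omitted)."""
    dedup = dedup_umis(reads)
    c1: Counter = Counter()
    c2: Counter = Counter()
    for r in dedup:
        if r.five_prime_pos == pos1:
            c1[r.cell_barcode] += 1
        elif r.five_prime_pos == pos2:
            c2[r.cell_barcode] += 1
    cells = sorted(set(c1) | set(c2))
    rows = [(cb, c1[cb], c2[cb], compute_psi(c1[cb], c2[cb])) for cb in cells]
    return pd.DataFrame(rows, columns=["cell", "count_tss1", "count_tss2", "psi"])


def export_brie_input(matrix, gene_to_pair: dict[str, tuple[str, str]],
                      out_prefix: str, cell_states: pd.DataFrame | None = None):
    """Two-layer per-gene isoform counts plus a design table, the input of an
    external differential-usage engine.

    ``matrix`` is a CellTSSMatrix; ``gene_to_pair`` maps gene id to the two
    selected TSS/CTSS ids (isoform1 = most upstream). Writes an .h5ad with
    layers ``isoform1``/``isoform2`` and a TSV design table carrying each
    cell's detection rate (fraction of included genes with any signal) plus
    optional cell-state covariates. Genes lacking either id are excluded.
    Returns the AnnData.
    """
    import anndata as ad

    tss_index = {t: i for i, t in enumerate(matrix.tss_ids)}
    genes, i1, i2 = [], [], []
    for gene, (a, b) in sorted(gene_to_pair.items()):
        if a in tss_index and b in tss_index:
            genes.append(gene)
            i1.append(tss_index[a])
            i2.append(tss_index[b])
        else:
            log.info("gene %s lacks both isoforms in the matrix; excluded", gene)
    counts = matrix.counts.tocsc()
    layer1 = counts[:, i1].toarray()
    layer2 = counts[:, i2].toarray()
    total = layer1 + layer2
    detection = (total > 0).mean(axis=1) if genes else np.zeros(len(matrix.cell_ids))
    obs = pd.DataFrame({"detection_rate": detection},
                       index=pd.Index(matrix.cell_ids, name="cell"))
    if cell_states is not None:
        obs = obs.join(cell_states, how="left")
    adata = ad.AnnData(X=total.astype(np.float32), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")),
                       layers={"isoform1": layer1.astype(np.float32),
                               "isoform2": layer2.astype(np.float32)})
    adata.write_h5ad(out_prefix + ".h5ad")
    obs.to_csv(out_prefix + ".design.tsv", sep="\t")
    return adata


def ctss_to_bed(records: list[CTSSRecord], chrom: str, strand: str,
                name_prefix: str, out_fh) -> None:
    """Append CTSS records as single-base BED6 lines (count as score)."""
    for i, r in enumerate(records, 1):
        out_fh.write(f"{chrom}\t{r.position}\t{r.position + 1}\t"
                     f"{name_prefix}_ctss{i}\t{r.count}\t{strand}\n")
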