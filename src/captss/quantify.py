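"""Sparse cell x TSS UMI counting from surviving clusters and reads."""
from __future__ import annotations

import scipy.sparse as sp

from .clustering import TSSCluster
from .io_models import CellTSSMatrix, Read1Record


def count_umis(clusters: list[TSSCluster], reads: list[Read1Record],
               cell_ids: list[str] | None = None) -> CellTSSMatrix:
    """Count distinct UMIs per (cell, cluster).

    A (cell, UMI) pair counts once in every cluster whose span contains its
    5' position (clusters within one gene are disjoint after the distance
    filter, so double counting can only arise across genes). The result is
    invariant to read order. Clusters must be annotated (named) already.
    """
    tss_ids = [c.name or f"{c.gene_id}_{c.summit_pos}" for c in clusters]
    seen: set[tuple[str, str, int]] = set()
    triples: dict[tuple[str, int], int] = {}
    cells = set(cell_ids) if cell_ids is not None else None
    for j, cl in enumerate(clusters):
        lo, hi = cl.span
        for r in reads:
            if r.chrom != cl.chrom or r.strand != cl.strand:
                continue
            if not (lo <= r.five_prime_pos <= hi):
                continue
            if cells is not None and r.cell_barcode not in cells:
                continue
            key = (r.cell_barcode, r.umi, j)
            if key in seen:
                continue
            seen.add(key)
            triples[(r.cell_barcode, j)] = triples.get((r.cell_barcode, j), 0) + 1

    if cell_ids is None:
        cell_ids = sorted({cb for cb, _ in triples})
    cell_index = {cb: i for i, cb in enumerate(cell_ids)}
    mat = sp.dok_matrix((len(cell_ids), len(tss_ids)), dtype=int)
    for (cb, j), n in triples.items():
        mat[cell_index[cb], j] = n
    meta = [(c.gene_id, c.chrom, c.summit_pos, c.strand) for c in clusters]
    return CellTSSMatrix(list(cell_ids), tss_ids, mat.tocsr(), meta)
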