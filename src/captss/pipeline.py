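"""End-to-end orchestration: fetch -> filter -> cluster -> classify ->
annotate -> quantify, plus the CTSS stage, with a machine-readable run
report (config echo, seeds, input checksums, per-stage survivor counts).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__
from .annotate import annotate_gene_clusters
from .classify import (LogisticModel, classify_cluster, cluster_features,
                       load_default_model)
from .clustering import (apply_distance_filter, apply_umi_filter,
                         cluster_read_starts, dedup_umis, summarize_cluster)
from .ctss import (ctss_to_bed, detect_ctss, farthest_ctss_pair, per_cell_psi)
from .filters import (FilterConfig, is_strand_invader, passes_cap_criteria,
                      subsample_reads)
from .io_models import (clusters_to_bed, fetch_gene_reads, load_gene_models,
                        write_cell_tss_matrix)
from .quantify import count_umis

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    bam: str = ""
    gtf: str = ""
    fasta: str = ""
    barcodes: str | None = None
    model: str | None = None
    outdir: str = "captss_out"
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    linkage_cutoff: float = 100.0
    min_umi: int = 50
    min_dist: int = 300
    threshold: float = 0.5
    mode: str = "cluster"  # cluster | sequence | combined-separate | combined-joint
    ctss_window: int = 15
    ctss_min_fc: float = 6.0
    ctss_min_count: int = 100
    xf_filter: bool = True
    seed: int = 0


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_barcodes(path: str | None) -> set[str] | None:
    if path is None:
        return None
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def run_detect(cfg: RunConfig) -> dict:
    """The three-step detection pipeline over every annotated gene.

    Writes clusters.bed, clusters.tsv, the MTX matrix directory and
    report.json into ``cfg.outdir``; returns a dict with the surviving
    clusters, their reads, the matrix and the report.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    cfg.filter.seed = cfg.seed
    genes = load_gene_models(cfg.gtf)
    genome = pyfaidx.Fasta(cfg.fasta)
    barcodes = _load_barcodes(cfg.barcodes)
    model = LogisticModel.load(cfg.model) if cfg.model else load_default_model()

    stages = {s: 0 for s in ("fetched", "invasion_pass", "cap_pass", "subsampled",
                             "clustered", "umi_filter", "classified", "distance_filter")}
    clusters_all, reads_by_cluster = [], []
    for gene in genes:
        reads = fetch_gene_reads(cfg.bam, gene, barcodes, xf_filter=cfg.xf_filter)
        stages["fetched"] += len(reads)
        reads = [r for r in reads if not is_strand_invader(r, genome, cfg.filter)]
        stages["invasion_pass"] += len(reads)
        reads = [r for r in reads if passes_cap_criteria(r, cfg.filter)]
        stages["cap_pass"] += len(reads)
        reads = subsample_reads(reads, cfg.filter)
        stages["subsampled"] += len(reads)
        if not reads:
            continue
        dedup = dedup_umis(reads)
        by_pos: dict[int, list] = {}
        for r in dedup:
            by_pos.setdefault(r.five_prime_pos, []).append(r)
        groups = cluster_read_starts([r.five_prime_pos for r in dedup],
                                     cfg.linkage_cutoff)
        stages["clustered"] += len(groups)
        gene_clusters, gene_reads = [], []
        for grp in groups:
            members = [m for pos in sorted(set(grp)) for m in by_pos[pos]]
            gene_clusters.append(summarize_cluster(members, gene, cfg.filter))
            gene_reads.append(members)
        keep = apply_umi_filter(gene_clusters, cfg.min_umi)
        stages["umi_filter"] += len(keep)
        kept_idx = [gene_clusters.index(c) for c in keep]
        survivors, surv_reads = [], []
        for ci, cl in zip(kept_idx, keep):
            prob, ok = classify_cluster(cluster_features(cl), model, cfg.threshold)
            cl.prob_true = prob
            if ok:
                survivors.append(cl)
                surv_reads.append(gene_reads[ci])
        stages["classified"] += len(survivors)
        final = apply_distance_filter(survivors, cfg.min_dist)
        stages["distance_filter"] += len(final)
        final_reads = [surv_reads[survivors.index(c)] for c in final]
        annotate_gene_clusters(final, gene)
        clusters_all.extend(final)
        reads_by_cluster.extend(final_reads)

    order = sorted(range(len(clusters_all)),
                   key=lambda i: (clusters_all[i].chrom, clusters_all[i].span[0]))
    clusters_all = [clusters_all[i] for i in order]
    reads_by_cluster = [reads_by_cluster[i] for i in order]

    all_reads = [r for grp in reads_by_cluster for r in grp]
    cell_ids = sorted(barcodes) if barcodes is not None else None
    matrix = count_umis(clusters_all, all_reads, cell_ids)

    clusters_to_bed(clusters_all, os.path.join(cfg.outdir, "clusters.bed"))
    rows = [{
        "name": c.name, "gene_id": c.gene_id, "chrom": c.chrom,
        "start": c.span[0], "end": c.span[1] + 1, "strand": c.strand,
        "summit": c.summit_pos, "total_umi": c.total_umi,
        "summit_count": c.summit_count, "std_dev": round(c.std_dev, 4),
        "unencoded_g_frac": round(c.unencoded_g_frac, 4),
        "prob_true": round(c.prob_true, 6) if c.prob_true is not None else "",
        "feature_class": c.feature_class, "is_novel": int(c.is_novel),
    } for c in clusters_all]
    pd.DataFrame(rows).to_csv(os.path.join(cfg.outdir, "clusters.tsv"),
                              sep="\t", index=False)
    write_cell_tss_matrix(matrix, os.path.join(cfg.outdir, "matrix"))

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": stages,
        "n_clusters": len(clusters_all),
        "inputs": {k: _md5(v) for k, v in
                   [("bam", cfg.bam), ("gtf", cfg.gtf), ("fasta", cfg.fasta)]
                   if v and os.path.exists(v)},
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if k != "filter"} |
                  {"filter": {k: (sorted(v) if isinstance(v, frozenset) else v)
                              for k, v in dataclasses.asdict(cfg.filter).items()}},
    }
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    return {"clusters": clusters_all, "reads_by_cluster": reads_by_cluster,
            "matrix": matrix, "report": report, "genes": genes}


def run_ctss(cfg: RunConfig, detect_result: dict | None = None) -> dict:
    """CTSS calling inside every surviving cluster, farthest-pair selection
    per gene and per-cell PSI tables. Runs detection first when needed."""
    res = detect_result or run_detect(cfg)
    clusters, reads_by_cluster = res["clusters"], res["reads_by_cluster"]
    os.makedirs(cfg.outdir, exist_ok=True)

    records_per_cluster = {}
    psi_tables = []
    with open(os.path.join(cfg.outdir, "ctss.bed"), "w") as bed:
        for cl, reads in zip(clusters, reads_by_cluster):
            recs = detect_ctss(cl, reads, W=cfg.ctss_window,
                               min_fc=cfg.ctss_min_fc,
                               min_count=cfg.ctss_min_count, cfg=cfg.filter)
            records_per_cluster[cl.name] = recs
            ctss_to_bed(recs, cl.chrom, cl.strand, cl.name or cl.gene_id, bed)
            pair = farthest_ctss_pair(recs, cl.strand)
            if pair is None:
                continue
            tss1, tss2 = pair
            table = per_cell_psi(reads, tss1.position, tss2.position)
            table.insert(0, "cluster", cl.name)
            table.insert(1, "tss1_pos", tss1.position)
            table.insert(2, "tss2_pos", tss2.position)
            psi_tables.append(table)

    psi = (pd.concat(psi_tables, ignore_index=True) if psi_tables
           else pd.DataFrame(columns=["cluster", "tss1_pos", "tss2_pos",
                                      "cell", "count_tss1", "count_tss2", "psi"]))
    psi.to_csv(os.path.join(cfg.outdir, "ctss_psi.tsv"), sep="\t", index=False)
    if not psi_tables:
        log.warning("no cluster yielded a CTSS pair")
    return {"ctss": records_per_cluster, "psi": psi, **res}


def select_top_two_tss(matrix) -> dict[str, tuple[str, str]]:
    """Per gene, the two TSS ids with the highest total expression, ordered
    with the most upstream first (genes with fewer than two TSS excluded)."""
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    by_gene: dict[str, list[int]] = {}
    for j, (gid, _, _, _) in enumerate(matrix.tss_meta):
        by_gene.setdefault(gid, []).append(j)
    out = {}
    for gid, idx in sorted(by_gene.items()):
        if len(idx) < 2:
            continue
        top = sorted(idx, key=lambda j: -totals[j])[:2]
        (g1, _, p1, s1), (g2, _, p2, s2) = (matrix.tss_meta[j] for j in top)
        upstream_first = (p1 <= p2) if s1 == "+" else (p1 >= p2)
        if not upstream_first:
            top = top[::-1]
        out[gid] = (matrix.tss_ids[top[0]], matrix.tss_ids[top[1]])
    return out
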