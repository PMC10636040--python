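"""Synthetic-data generator: a small genome, a GTF, an aligned SAM with
planted TSS clusters and artifacts, ground truth, and a labeled classifier
benchmark.

The generator emulates what the pipeline consumes: genes on both strands;
read-1 5' ends drawn around planted summits (or from fixed single-nucleotide
start positions with weights); leading soft clips that carry the
template-switch signature, 14-16 nt for capped (unencoded-G) reads and
8-13 nt otherwise; strand-invasion artifacts placed at sites whose upstream
genomic sequence is the TSO verbatim; and diffuse low-cap-signal noise
clusters near gene 3' ends as negatives. Reads are written pre-aligned with
synthetic CIGARs, so no aligner is needed; soft-clip sequences are prepended
to the query consistently with the CIGAR and strand.

It does not emulate sequencing errors, quality strings, doublets, ambient
RNA, or realistic barcode chemistry.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io_models import revcomp

TSO_SEQ = "TTTCTTATATGGG"
PROMOTER_MOTIF = "TATAAAGG"  # planted at positive summits for sequence models
BASES = np.array(list("ACGT"))


@dataclass
class PlantedCluster:
    gene_id: str
    summit: int
    spread_sd: float
    n_umis: int
    unencoded_g_rate: float
    is_artifact: bool = False
    #: optional exact start positions [(coordinate, weight)], weights sum to 1
    ctss_positions: list[tuple[int, float]] | None = None

    def __post_init__(self):
        if self.n_umis < 1:
            raise ValueError("n_umis must be >= 1")
        if self.ctss_positions:
            total = sum(w for _, w in self.ctss_positions)
            if abs(total - 1.0) > 1e-6:
                raise ValueError("ctss position weights must sum to 1")


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    #: (transcript_id, tss 0-based). Exon/UTR structure is derived.
    transcripts: list[tuple[str, int]] = field(default_factory=list)


def generate_genome(n_chroms: int = 2, length: int = 30000, gc: float = 0.5,
                    seed: int = 0) -> dict[str, np.ndarray]:
    """Random chromosome sequences as mutable char arrays (A/C/G/T)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {f"chr{i + 1}": rng.choice(BASES, size=length, p=p)
            for i in range(n_chroms)}


def write_fasta(genome: dict[str, np.ndarray], path: str | os.PathLike,
                width: int = 70) -> str:
    with open(str(path), "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return str(path)


def write_gtf(genes: list[SimGene], path: str | os.PathLike) -> str:
    """Emit gene/transcript/exon/UTR lines (1-based inclusive coordinates).

    Each transcript runs from its TSS to the 3' gene boundary with two exons
    separated by an intron; the first 150 nt are 5'UTR and the last 150 nt
    3'UTR, giving every feature class some representation.
    """
    def attrs(gid, tid=None):
        s = f'gene_id "{gid}";'
        if tid:
            s += f' transcript_id "{tid}";'
        return s

    lines = []
    for g in genes:
        lines.append((g.chrom, "gene", g.start + 1, g.end, g.strand, attrs(g.gene_id)))
        for tid, tss in g.transcripts:
            if g.strand == "+":
                t_lo, t_hi = tss, g.end
            else:
                t_lo, t_hi = g.start, tss + 1
            a = attrs(g.gene_id, tid)
            lines.append((g.chrom, "transcript", t_lo + 1, t_hi, g.strand, a))
            tlen = t_hi - t_lo
            exon1 = (t_lo, t_lo + max(tlen // 3, 200))
            exon2 = (t_hi - max(tlen // 3, 200), t_hi)
            if exon1[1] >= exon2[0]:  # short transcript: single exon
                exons = [(t_lo, t_hi)]
            else:
                exons = [exon1, exon2]
            for e in exons:
                lines.append((g.chrom, "exon", e[0] + 1, e[1], g.strand, a))
            if g.strand == "+":
                utr5 = (t_lo, t_lo + 150)
                utr3 = (t_hi - 150, t_hi)
            else:
                utr5 = (t_hi - 150, t_hi)
                utr3 = (t_lo, t_lo + 150)
            lines.append((g.chrom, "five_prime_utr", utr5[0] + 1, utr5[1], g.strand, a))
            lines.append((g.chrom, "three_prime_utr", utr3[0] + 1, utr3[1], g.strand, a))
    with open(str(path), "w") as fh:
        for chrom, feat, lo, hi, strand, a in lines:
            fh.write(f"{chrom}\tsim\t{feat}\t{lo}\t{hi}\t.\t{strand}\t.\t{a}\n")
    return str(path)


def _random_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


def _clip_for_read(rng, unencoded_g: bool) -> str:
    """A soft-clip sequence consistent with the cap criteria. Capped reads
    get 14-16 nt ending in ATGGG; others 8-13 nt ending one edit away."""
    if unencoded_g:
        n = int(rng.integers(14, 17))
        return _random_seq(rng, n - 5) + "ATGGG"
    n = int(rng.integers(8, 14))
    return _random_seq(rng, n - 5) + "ATGCG"


def simulate_reads(genome: dict[str, np.ndarray], genes: list[SimGene],
                   planted: list[PlantedCluster], out_sam: str | os.PathLike,
                   n_cells: int = 100, seed: int = 0, read_len: int = 91,
                   invader_sites: list[tuple[str, int, int]] | None = None,
                   truth_tsv: str | os.PathLike | None = None) -> str:
    """Write a coordinate-sorted SAM of read-1 records with CB/UB/xf:i:25
    tags; every planted cluster contributes exactly ``n_umis`` distinct
    (cell, UMI) pairs. ``invader_sites`` entries are (gene_id, position,
    n_umis): the genome already carries a TSO-identical 13-mer immediately
    upstream of each (see :func:`embed_invader_site`).
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    barcodes = sorted({"".join(rng.choice(BASES, size=16)) for _ in range(n_cells * 2)})
    barcodes = barcodes[:n_cells]

    records = []  # (chrom, pos0, flag, cigar, seq, cb, ub)
    umi_serial = 0

    def emit(gene: SimGene, pos: int, unencoded_g: bool):
        nonlocal umi_serial
        pos = int(np.clip(pos, gene.start, gene.end - 1))
        clip = _clip_for_read(rng, unencoded_g)
        match = read_len - len(clip)
        chrom_seq = genome[gene.chrom]
        cb = barcodes[int(rng.integers(0, n_cells))]
        ub = f"{umi_serial:010d}".translate(str.maketrans("0123456789", "ACGTACGTAC"))
        ub = ub + _random_seq(rng, 2)
        umi_serial += 1
        if gene.strand == "+":
            if pos + match > len(chrom_seq):
                pos = len(chrom_seq) - match
            body = "".join(chrom_seq[pos:pos + match])
            return (gene.chrom, pos, 0, f"{len(clip)}S{match}M", clip + body, cb, ub)
        if pos - match + 1 < 0:
            pos = match - 1
        ref_lo = pos - match + 1
        body = "".join(chrom_seq[ref_lo:pos + 1])
        seq = body + revcomp(clip)
        return (gene.chrom, ref_lo, 16, f"{match}M{len(clip)}S", seq, cb, ub)

    for pc in planted:
        gene = gene_by_id[pc.gene_id]
        if not (gene.start <= pc.summit < gene.end):
            raise ValueError(f"planted cluster summit {pc.summit} outside "
                             f"gene span of {pc.gene_id}")
        if pc.ctss_positions:
            sites = np.array([p for p, _ in pc.ctss_positions])
            weights = np.array([w for _, w in pc.ctss_positions])
            draws = rng.choice(len(sites), size=pc.n_umis, p=weights)
            positions = sites[draws]
        else:
            positions = np.rint(rng.normal(pc.summit, pc.spread_sd,
                                           size=pc.n_umis)).astype(int)
        g_flags = rng.random(pc.n_umis) < pc.unencoded_g_rate
        for pos, gf in zip(positions, g_flags):
            records.append(emit(gene, int(pos), bool(gf)))

    for gid, site, n in (invader_sites or []):
        # invader reads sit exactly at the embedded site, so the upstream
        # 13-mer is the TSO verbatim for every one of them
        gene = gene_by_id[gid]
        for _ in range(n):
            records.append(emit(gene, site, bool(rng.random() < 0.05)))

    records.sort(key=lambda r: (r[0], r[1], r[5], r[6]))
    with open(str(out_sam), "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, seq in genome.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for i, (chrom, pos, flag, cigar, seq, cb, ub) in enumerate(records):
            fh.write(f"r{i:07d}\t{flag}\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t"
                     f"{seq}\t*\tCB:Z:{cb}\tUB:Z:{ub}\txf:i:25\n")

    if truth_tsv is not None:
        with open(str(truth_tsv), "w") as fh:
            fh.write("gene_id\tchrom\tstrand\tsummit\tn_umis\tunencoded_g_rate\t"
                     "is_artifact\tctss_positions\n")
            for pc in planted:
                gene = gene_by_id[pc.gene_id]
                ctss = (";".join(f"{p}:{w}" for p, w in pc.ctss_positions)
                        if pc.ctss_positions else "")
                fh.write(f"{pc.gene_id}\t{gene.chrom}\t{gene.strand}\t{pc.summit}\t"
                         f"{pc.n_umis}\t{pc.unencoded_g_rate}\t"
                         f"{int(pc.is_artifact)}\t{ctss}\n")
    return str(out_sam)


def embed_sequence(genome: dict[str, np.ndarray], chrom: str, start: int,
                   seq: str) -> None:
    genome[chrom][start:start + len(seq)] = list(seq)


def embed_invader_site(genome: dict[str, np.ndarray], chrom: str, pos: int,
                       strand: str) -> None:
    """Plant a TSO-identical 13-mer immediately upstream of ``pos`` so reads
    starting there are strand invaders by construction."""
    if strand == "+":
        embed_sequence(genome, chrom, pos - len(TSO_SEQ), TSO_SEQ)
    else:
        embed_sequence(genome, chrom, pos + 1, revcomp(TSO_SEQ))


def embed_promoter_motif(genome: dict[str, np.ndarray], chrom: str, summit: int,
                         strand: str, motif: str = PROMOTER_MOTIF) -> None:
    seq = motif if strand == "+" else revcomp(motif)
    embed_sequence(genome, chrom, summit - len(motif) // 2, seq)


# ---------------------------------------------------------------------------
# default fixture

@dataclass
class Fixture:
    outdir: str
    fasta: str
    gtf: str
    sam: str
    bam: str
    truth_tsv: str
    whitelist: str
    genes: list[SimGene]
    planted: list[PlantedCluster]
    invader_sites: list[tuple[str, int, int]]


def make_default_fixture(outdir: str | os.PathLike, seed: int = 0,
                         n_cells: int = 100, umi_scale: float = 1.0) -> Fixture:
    """The standard end-to-end test substrate.

    Two 30 kb chromosomes carry 6 genes (both strands). 10 genuine TSS
    clusters (tight, high unencoded-G, 2000-3200 UMIs each at the default
    scale) are planted at transcript starts, one of them deliberately away
    from any annotated transcript (a novel TSS) and two carrying a pair of
    fixed single-nucleotide CTSS positions. 6 diffuse low-cap-signal
    artifact clusters sit near gene 3' ends and 4 strand-invasion sites have
    a TSO-identical upstream 13-mer; at the default scale the file holds
    roughly 50k reads. ``umi_scale`` shrinks every cluster proportionally
    (UMI counts floored at 60) for quick tests.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(n_chroms=2, length=30000, gc=0.5, seed=seed)

    def n(base):
        return max(60, int(round(base * umi_scale)))

    genes = [
        SimGene("G1", "chr1", "+", 1000, 8000,
                [("G1-T1", 1500), ("G1-T2", 3600)]),
        SimGene("G2", "chr1", "-", 9500, 16500,
                [("G2-T1", 16000), ("G2-T2", 13200)]),
        SimGene("G3", "chr1", "+", 18000, 25000, [("G3-T1", 18497)]),
        SimGene("G4", "chr2", "-", 1000, 8000,
                [("G4-T1", 7500), ("G4-T2", 4800)]),
        SimGene("G5", "chr2", "+", 9500, 16500, [("G5-T1", 9998)]),
        SimGene("G6", "chr2", "-", 18000, 25000, [("G6-T1", 24500)]),
    ]
    planted = [
        PlantedCluster("G1", 1500, 3.0, n(2800), 0.65),
        PlantedCluster("G1", 3600, 3.5, n(2200), 0.55),
        PlantedCluster("G2", 16000, 2.5, n(3000), 0.70),
        PlantedCluster("G2", 13200, 3.5, n(2000), 0.60),
        PlantedCluster("G3", 18497, 3.0, n(3200), 0.75,
                       ctss_positions=[(18497, 0.50), (18517, 0.12), (18539, 0.38)]),
        PlantedCluster("G4", 7500, 3.0, n(2600), 0.62),
        PlantedCluster("G4", 4800, 3.5, n(2100), 0.58),
        PlantedCluster("G5", 9998, 3.0, n(3000), 0.68,
                       ctss_positions=[(9998, 0.50), (10018, 0.12), (10040, 0.38)]),
        # novel: no transcript annotated near 12500
        PlantedCluster("G5", 12500, 3.0, n(2400), 0.64),
        PlantedCluster("G6", 24500, 2.5, n(2800), 0.66),
    ]
    artifacts = [
        PlantedCluster("G1", 7200, 45, n(1600), 0.04, is_artifact=True),
        PlantedCluster("G2", 10200, 50, n(1800), 0.05, is_artifact=True),
        PlantedCluster("G3", 24000, 55, n(1500), 0.03, is_artifact=True),
        PlantedCluster("G4", 1800, 45, n(1700), 0.05, is_artifact=True),
        PlantedCluster("G5", 15800, 50, n(1600), 0.04, is_artifact=True),
        PlantedCluster("G6", 18800, 55, n(1800), 0.04, is_artifact=True),
    ]
    invader_sites = [("G1", 5600, n(900)), ("G2", 11600, n(900)),
                     ("G4", 3000, n(900)), ("G5", 14200, n(900))]

    for pc in planted:
        gene = next(g for g in genes if g.gene_id == pc.gene_id)
        if not pc.is_artifact:
            embed_promoter_motif(genome, gene.chrom, pc.summit, gene.strand)
    for gid, site, _ in invader_sites:
        gene = next(g for g in genes if g.gene_id == gid)
        embed_invader_site(genome, gene.chrom, site, gene.strand)

    fasta = write_fasta(genome, os.path.join(outdir, "genome.fa"))
    gtf = write_gtf(genes, os.path.join(outdir, "annotation.gtf"))
    sam = os.path.join(outdir, "reads.sam")
    truth = os.path.join(outdir, "truth.tsv")
    simulate_reads(genome, genes, planted + artifacts, sam, n_cells=n_cells,
                   seed=seed + 1, invader_sites=invader_sites, truth_tsv=truth)

    from .io_models import sam_to_indexed_bam
    bam = sam_to_indexed_bam(sam, os.path.join(outdir, "reads.sorted.bam"))

    import pysam
    whitelist = os.path.join(outdir, "barcodes.txt")
    cbs = set()
    with pysam.AlignmentFile(sam) as fh:
        for aln in fh:
            cbs.add(aln.get_tag("CB"))
    with open(whitelist, "w") as fh:
        for cb in sorted(cbs):
            fh.write(cb + "\n")

    return Fixture(outdir, fasta, gtf, sam, bam, truth, whitelist,
                   genes, planted + artifacts, invader_sites)


# ---------------------------------------------------------------------------
# classifier benchmark

def simulate_labeled_benchmark(n_per_class: int = 500, seed: int = 0,
                               with_sequence: bool = True,
                               motif: str = PROMOTER_MOTIF):
    """Feature/sequence benchmark for the classifiers.

    Positives mimic genuine promoters: high, concentrated UMI counts with a
    substantial unencoded-G fraction, and (when sequences are generated) the
    fixed promoter 8-mer planted near the center. Negatives mimic diffuse
    3'-end noise: wider, weaker, nearly cap-free, random sequence. The
    distributions deliberately overlap so the 4-feature task is hard but
    solvable (target AUROC around 0.95-0.99, not 1.0).

    Returns a list of :class:`~captss.classify.LabeledCluster`.
    """
    from .classify import ClusterFeatures, LabeledCluster

    rng = np.random.default_rng(seed)
    data = []
    for label in (1, 0):
        for i in range(n_per_class):
            if label == 1:
                total = float(rng.lognormal(np.log(1800), 0.6))
                summit = total * rng.beta(2.5, 30)
                # sharp and broad promoter shape classes
                if rng.random() < 0.25:
                    std = float(abs(rng.normal(28, 8)) + 8)
                    summit = total * rng.beta(6, 12)
                else:
                    std = float(abs(rng.normal(9, 4)) + 1)
                g = float(rng.beta(5, 4))
            else:
                total = float(rng.lognormal(np.log(1200), 0.7))
                summit = total * rng.beta(2, 40)
                std = float(abs(rng.normal(28, 16)) + 3)
                g = float(rng.beta(2.5, 6))
            seq = None
            if with_sequence:
                seq = _random_seq(rng, 200)
                if label == 1:
                    off = int(rng.integers(80, 112))
                    seq = seq[:off] + motif + seq[off + len(motif):]
            data.append(LabeledCluster(
                features=ClusterFeatures(total, summit, std, g),
                label=label, sequence=seq))
    order = rng.permutation(len(data))
    return [data[i] for i in order]
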