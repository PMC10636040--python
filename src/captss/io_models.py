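"""Readers/writers for the standard formats the pipeline touches and the
in-memory gene/transcript models.

Coordinate convention: everything internal is 0-based half-open. GTF input
(1-based, end-inclusive) is converted at the boundary; BED export needs no
conversion. A transcript's TSS is its 5' end: the minimal genomic coordinate
on the + strand, the maximal one on the - strand.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pysam
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GENOMIC_FEATURES = ("5'UTR", "3'UTR", "exon", "intron")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """An annotated transcript reduced to its 5' start (assignment target)."""

    transcript_id: str
    tss_position: int  # 0-based genomic coordinate of the 5'-most base


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open span
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)
    #: label -> sorted, non-overlapping list of (start, end), 0-based half-open
    feature_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Read1Record:
    """One read-1 alignment reduced to its 5' position and cap evidence.

    ``cigar_read_oriented`` is ordered 5'->3' in *read* orientation, so the
    cap-side soft clip (if any) is always the first operation regardless of
    the aligned strand. ``five_prime_pos`` is the 5'-most aligned base: the
    leftmost reference position for + alignments, the rightmost for -.
    """

    cell_barcode: str
    umi: str
    chrom: str
    strand: str
    five_prime_pos: int
    cigar_read_oriented: list[tuple[str, int]]
    soft_clip_len: int
    soft_clip_seq: str
    first_match_len: int
    xf_pass: bool


# ---------------------------------------------------------------------------
# GTF

def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def load_gene_models(gtf_path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GENCODE-style GTF into one :class:`GeneModel` per gene.

    Transcript TSS positions follow strand semantics; introns are derived as
    the gene span minus the union of exons. Plain ``UTR`` features (GENCODE
    dialect) are classified 5'/3' against the transcript's CDS span when one
    is present, otherwise skipped with a log message.
    """
    try:
        db = gffutils.create_db(
            str(gtf_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    except Exception as exc:
        raise ValueError(f"failed to parse GTF {gtf_path}: {exc}") from exc

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            log.warning("gene %s has unknown strand %r; skipped", g.id, g.strand)
            continue
        gene = GeneModel(
            gene_id=g.attributes.get("gene_id", [g.id])[0],
            chrom=g.seqid, strand=g.strand, start=g.start - 1, end=g.end,
        )
        exons: list[tuple[int, int]] = []
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes.get("transcript_id", [t.id])[0]
            tss = t.start - 1 if g.strand == "+" else t.end - 1
            gene.transcripts.append(TranscriptModel(tid, tss))
            cds = [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
            cds_span = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else None
            for child in db.children(t):
                iv = (child.start - 1, child.end)
                ft = child.featuretype
                if ft == "exon":
                    exons.append(iv)
                elif ft == "five_prime_utr":
                    utr5.append(iv)
                elif ft == "three_prime_utr":
                    utr3.append(iv)
                elif ft == "UTR":
                    if cds_span is None:
                        log.info("UTR without CDS in %s; skipped", tid)
                        continue
                    upstream = iv[1] <= cds_span[0] if g.strand == "+" else iv[0] >= cds_span[1]
                    (utr5 if upstream else utr3).append(iv)
        gene.feature_intervals["exon"] = _merge_intervals(exons)
        gene.feature_intervals["5'UTR"] = _merge_intervals(utr5)
        gene.feature_intervals["3'UTR"] = _merge_intervals(utr3)
        introns, cursor = [], gene.start
        for s, e in gene.feature_intervals["exon"]:
            if s > cursor:
                introns.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < gene.end:
            introns.append((cursor, gene.end))
        gene.feature_intervals["intron"] = introns
        genes.append(gene)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# SAM/BAM

def read1_from_alignment(aln: pysam.AlignedSegment) -> Read1Record | None:
    """Reduce a pysam alignment to a :class:`Read1Record`.

    Returns None for unmapped records or records missing CB/UB tags.
    """
    if aln.is_unmapped or aln.cigartuples is None:
        return None
    try:
        cb = aln.get_tag("CB")
        ub = aln.get_tag("UB")
    except KeyError:
        return None
    strand = "-" if aln.is_reverse else "+"
    cig = aln.cigartuples
    seq = aln.query_sequence or ""
    if strand == "-":
        cig = cig[::-1]
        five_prime = aln.reference_end - 1
    else:
        five_prime = aln.reference_start
    ops = "MIDNSHP=XB"
    cigar_ro = [(ops[op], ln) for op, ln in cig]
    sc_len, sc_seq = 0, ""
    idx = 0
    if cigar_ro and cigar_ro[0][0] == "H":  # hard clip carries no sequence
        idx = 1
    if idx < len(cigar_ro) and cigar_ro[idx][0] == "S":
        sc_len = cigar_ro[idx][1]
        sc_seq = seq[:sc_len] if strand == "+" else revcomp(seq[-sc_len:])
        idx += 1
    first_match = 0
    for op, ln in cigar_ro[idx:]:
        if op in "M=X":
            first_match = ln
            break
        if op == "S":
            break
    try:
        xf_pass = aln.get_tag("xf") == 25
    except KeyError:
        xf_pass = False
    return Read1Record(
        cell_barcode=cb, umi=ub, chrom=aln.reference_name, strand=strand,
        five_prime_pos=five_prime, cigar_read_oriented=cigar_ro,
        soft_clip_len=sc_len, soft_clip_seq=sc_seq,
        first_match_len=first_match, xf_pass=xf_pass,
    )


def fetch_gene_reads(
    bam_path: str | os.PathLike,
    gene: GeneModel,
    barcodes: set[str] | None,
    xf_filter: bool = True,
) -> list[Read1Record]:
    """Fetch read-1 alignments whose 5' end lies in the gene span on the
    gene's strand, keeping only whitelisted barcodes and (by default) records
    with the confident-assignment tag xf:i:25.
    """
    n_missing_tags = 0
    out: list[Read1Record] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} has no index; sort and index it first")
        for aln in bam.fetch(gene.chrom, gene.start, gene.end):
            if aln.is_paired and not aln.is_read1:
                continue
            rec = read1_from_alignment(aln)
            if rec is None:
                if not aln.is_unmapped:
                    n_missing_tags += 1
                continue
            if rec.strand != gene.strand:
                continue
            if not (gene.start <= rec.five_prime_pos < gene.end):
                continue
            if xf_filter and not rec.xf_pass:
                continue
            if barcodes is not None and rec.cell_barcode not in barcodes:
                continue
            out.append(rec)
    if n_missing_tags:
        log.info("%s: %d records lacked CB/UB tags and were skipped",
                 gene.gene_id, n_missing_tags)
    out.sort(key=lambda r: (r.five_prime_pos, r.cell_barcode, r.umi))
    return out


def merge_sample_bams(
    bam_paths: list[str | os.PathLike],
    sample_ids: list[str],
    out_path: str | os.PathLike,
) -> str:
    """Merge per-sample alignment files, suffixing every cell barcode with
    ``-<sample_id>`` so that barcodes stay unique across samples; output is
    coordinate-sorted and indexed.
    """
    if not bam_paths:
        raise ValueError("no input files")
    if len(bam_paths) != len(sample_ids):
        raise ValueError("bam_paths and sample_ids differ in length")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids: {sample_ids}")
    out_path = str(out_path)
    tmp = out_path + ".unsorted.bam"
    header = None
    with pysam.AlignmentFile(str(bam_paths[0])) as first:
        header = first.header.to_dict()
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for path, sid in zip(bam_paths, sample_ids):
            with pysam.AlignmentFile(str(path)) as bam:
                for aln in bam:
                    if aln.has_tag("CB"):
                        aln.set_tag("CB", f"{aln.get_tag('CB')}-{sid}")
                    out.write(aln)
    pysam.sort("-o", out_path, tmp)
    os.remove(tmp)
    pysam.index(out_path)
    return out_path


def sam_to_indexed_bam(sam_path: str | os.PathLike, bam_path: str | os.PathLike) -> str:
    """Coordinate-sort a SAM/BAM into an indexed BAM (random access needs one)."""
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return str(bam_path)


# ---------------------------------------------------------------------------
# cell x TSS matrix

@dataclass
class CellTSSMatrix:
    """Sparse cells x TSS UMI counts with aligned id lists."""

    cell_ids: list[str]
    tss_ids: list[str]
    counts: sp.spmatrix  # shape (n_cells, n_tss)
    #: per-TSS metadata rows aligned to tss_ids: (gene_id, chrom, pos, strand)
    tss_meta: list[tuple[str, str, int, str]] | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.tss_ids)):
            raise ValueError("matrix shape inconsistent with id lists")


def write_cell_tss_matrix(matrix: CellTSSMatrix, out_dir: str | os.PathLike) -> None:
    """Write MTX + barcodes.tsv + features.tsv (round-trippable)."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"),
                     sp.coo_matrix(matrix.counts), field="integer")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        for cb in matrix.cell_ids:
            fh.write(cb + "\n")
    meta = matrix.tss_meta or [("", "", -1, "")] * len(matrix.tss_ids)
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        for tss_id, (gid, chrom, pos, strand) in zip(matrix.tss_ids, meta):
            fh.write(f"{tss_id}\t{gid}\t{chrom}:{pos}:{strand}\n")


def read_cell_tss_matrix(out_dir: str | os.PathLike) -> CellTSSMatrix:
    out_dir = str(out_dir)
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(out_dir, "matrix.mtx")))
    with open(os.path.join(out_dir, "barcodes.tsv")) as fh:
        cells = [line.strip() for line in fh if line.strip()]
    tss_ids, meta = [], []
    with open(os.path.join(out_dir, "features.tsv")) as fh:
        for line in fh:
            tss_id, gid, loc = line.rstrip("\n").split("\t")
            chrom, pos, strand = loc.rsplit(":", 2)
            tss_ids.append(tss_id)
            meta.append((gid, chrom, int(pos), strand))
    counts.resize((len(cells), len(tss_ids)))
    return CellTSSMatrix(cells, tss_ids, counts, meta)


def clusters_to_bed(clusters, out_path: str | os.PathLike) -> None:
    """Export clusters as BED6: span, name, total UMIs as score, strand."""
    with open(str(out_path), "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.span[0]}\t{c.span[1] + 1}\t"
                     f"{c.name or '.'}\t{c.total_umi}\t{c.strand}\n")
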