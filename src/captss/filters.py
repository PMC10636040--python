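"""Read-1 filters: strand-invasion removal, cap (template-switch) criteria,
unencoded-G flagging and per-gene subsampling.

The template switch oligo (TSO) ends in ...ATGGG; during library construction
it is appended to the cDNA 5' end, so a genuine capped read 1 begins with a
soft-clipped prefix whose tail resembles ATGGG. When the TSO instead anneals
to an internal genomic stretch that looks like it (strand invasion), the read
reports a false 5' end; such reads are recognised by comparing the genomic
sequence immediately upstream of the aligned start with the TSO.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_models import Read1Record, revcomp

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    tso_seq: str = "TTTCTTATATGGG"
    invasion_max_ed: int = 3          # strand invader iff edit distance < this
    invasion_window: int = 13         # nt of upstream genome compared to the TSO
    tso_tail: str = "ATGGG"
    tail_max_ed: int = 4              # clip tail must be < this from ATGGG
    softclip_min: int = 6             # exclusive: clip length must be > 6
    softclip_max: int = 20            # exclusive: ... and < 20
    match_min: int = 5                # exclusive: first aligned block > 5
    unencoded_g_clips: frozenset[int] = field(default_factory=lambda: frozenset({14, 15, 16}))
    max_reads_per_gene: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.softclip_min >= self.softclip_max:
            raise ValueError("softclip_min must be < softclip_max")


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit-cost insertion/deletion/substitution."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def upstream_window(read: Read1Record, genome, window: int) -> str | None:
    """Strand-aware genomic sequence covering ``window`` nt immediately
    upstream of the read's aligned 5' start (reverse-complemented for -).

    ``genome`` is a pyfaidx.Fasta-like mapping chrom -> sliceable sequence.
    Returns None when the window runs past the contig edge.
    """
    chrom_seq = genome[read.chrom]
    if read.strand == "+":
        lo, hi = read.five_prime_pos - window, read.five_prime_pos
        if lo < 0:
            return None
        return str(chrom_seq[lo:hi]).upper()
    lo, hi = read.five_prime_pos + 1, read.five_prime_pos + 1 + window
    if hi > len(chrom_seq):
        return None
    return revcomp(str(chrom_seq[lo:hi]).upper())


def is_strand_invader(read: Read1Record, genome, cfg: FilterConfig) -> bool:
    """True iff the upstream genomic window resembles the TSO (edit distance
    below ``invasion_max_ed``), i.e. the 5' end is a template-switch artifact."""
    window = upstream_window(read, genome, cfg.invasion_window)
    if window is None:
        log.debug("upstream window out of contig for read at %s:%d; not flagged",
                  read.chrom, read.five_prime_pos)
        return False
    return edit_distance(window, cfg.tso_seq) < cfg.invasion_max_ed


def passes_cap_criteria(read: Read1Record, cfg: FilterConfig) -> bool:
    """Cap-signature criteria on the read-oriented CIGAR: (1) the clip tail
    resembles the TSO tail ATGGG, (2) the leading soft clip is strictly
    between 6 and 20 nt, (3) the first aligned block exceeds 5 nt."""
    if read.soft_clip_len <= cfg.softclip_min or read.soft_clip_len >= cfg.softclip_max:
        return False
    if read.first_match_len <= cfg.match_min:
        return False
    tail = read.soft_clip_seq[-len(cfg.tso_tail):].upper()
    return edit_distance(tail, cfg.tso_tail) < cfg.tail_max_ed


def has_unencoded_g(read: Read1Record, cfg: FilterConfig | None = None) -> bool:
    """True iff the leading soft clip length is 14-16 nt: the TSO (13 nt) plus
    1-3 guanosines added opposite the mRNA cap, evidence of a genuine 5' end."""
    clips = cfg.unencoded_g_clips if cfg is not None else frozenset({14, 15, 16})
    return read.soft_clip_len in clips


def subsample_reads(reads: list[Read1Record], cfg: FilterConfig) -> list[Read1Record]:
    """Uniform without-replacement subsample to ``max_reads_per_gene`` when a
    gene is over-covered; deterministic for a fixed seed, order preserved."""
    if len(reads) <= cfg.max_reads_per_gene:
        return list(reads)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(reads), size=cfg.max_reads_per_gene, replace=False)
    return [reads[i] for i in np.sort(idx)]
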