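import numpy as np
import pytest

from captss.io_models import Read1Record
from captss.pipeline import RunConfig, run_detect
from captss.simulate import make_default_fixture


def make_read(pos=1000, cigar=((("S", 14), ("M", 76))), clip_seq=None,
              cb="AAAC", umi="UUUU", chrom="chr1", strand="+", xf=True):
    cigar = list(cigar)
    sc_len = cigar[0][1] if cigar and cigar[0][0] == "S" else 0
    if clip_seq is None:
        clip_seq = ("T" * max(sc_len - 5, 0) + "ATGGG")[:sc_len] if sc_len else ""
    first_match = next((ln for op, ln in cigar if op in "M=X"), 0)
    return Read1Record(cell_barcode=cb, umi=umi, chrom=chrom, strand=strand,
                       five_prime_pos=pos, cigar_read_oriented=cigar,
                       soft_clip_len=sc_len, soft_clip_seq=clip_seq,
                       first_match_len=first_match, xf_pass=xf)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Reduced copy of the default synthetic bundle (shared across tests)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_default_fixture(outdir, seed=11, n_cells=80, umi_scale=0.15)


@pytest.fixture(scope="session")
def detect_result(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("detect")
    cfg = RunConfig(bam=small_fixture.bam, gtf=small_fixture.gtf,
                    fasta=small_fixture.fasta, barcodes=small_fixture.whitelist,
                    outdir=str(outdir), seed=11)
    return cfg, run_detect(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def seq_benchmark():
    from captss.simulate import simulate_labeled_benchmark
    return simulate_labeled_benchmark(n_per_class=500, seed=5)


@pytest.fixture(scope="session")
def trained_cnn(seq_benchmark):
    """One sequence model trained at reduced settings, shared by all tests
    that need sequence embeddings."""
    from captss.seqmodel import SequenceModelConfig, train_sequence_model
    seqs = [d.sequence for d in seq_benchmark]
    y = np.array([d.label for d in seq_benchmark])
    cfg = SequenceModelConfig(epochs=100, batch_size=64, seed=5)
    model, auroc = train_sequence_model(seqs, y, cfg)
    return model, auroc
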