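"""Sliding-window CTSS detection, farthest-pair selection and PSI."""
import numpy as np
import pytest

from captss.clustering import TSSCluster
from captss.ctss import (CTSSRecord, compute_psi, ctss_position_counts,
                         detect_ctss, farthest_ctss_pair, fold_change,
                         per_cell_psi)

from conftest import make_read


def _cluster(counts, strand="+"):
    return TSSCluster("G", "chr1", strand, dict(counts))


def _reads_at(counts, unencoded=True, strand="+", cb="C1"):
    reads = []
    k = 0
    for pos, n in counts.items():
        for _ in range(n):
            cigar = [("S", 14 if unencoded else 9), ("M", 80)]
            tag = "g" if unencoded else "n"
            reads.append(make_read(pos=pos, umi=f"{tag}{pos}_{k}", cigar=cigar,
                                   strand=strand, cb=cb))
            k += 1
    return reads


@pytest.mark.parametrize("c0,downstream,expected", [
    (5, {}, 6.0),                 # (5+1)/(0/15+1)
    (0, {}, 1.0),
    (100, {i: 1 for i in range(1, 16)}, 50.5),  # downstream mean 1
])
def test_fold_change_closed_forms(c0, downstream, expected):
    counts = {50: c0} | {50 + i: v for i, v in downstream.items()}
    assert fold_change(counts, 50, W=15) == pytest.approx(expected)


def test_fold_change_direction_follows_strand():
    counts = {50: 10} | {50 + i: 4 for i in range(1, 16)}
    plus = fold_change(counts, 50, W=15, direction="+")
    minus = fold_change(counts, 50, W=15, direction="-")
    assert plus == pytest.approx(11 / 5)
    assert minus == pytest.approx(11.0)  # upstream side is empty


def test_fold_change_truncated_window_still_divides_by_w():
    counts = {50: 9, 51: 30}
    # only one downstream position has counts; mean is 30/15 = 2
    assert fold_change(counts, 50, W=15) == pytest.approx(10 / 3)


def test_fold_change_rejects_bad_window():
    with pytest.raises(ValueError):
        fold_change({0: 1}, 0, W=0)


def test_fold_change_monotone_in_c0():
    counts = {50 + i: 3 for i in range(1, 16)}
    fcs = [fold_change(counts | {50: c0}, 50) for c0 in range(0, 200, 10)]
    assert all(b > a for a, b in zip(fcs, fcs[1:]))


def test_ctss_counts_use_only_unencoded_g_reads():
    cl = _cluster({100: 5})
    reads = _reads_at({100: 3}, unencoded=True) + _reads_at({100: 2}, unencoded=False)
    counts = ctss_position_counts(cl, reads)
    assert counts == {100: 3}
    assert ctss_position_counts(cl, _reads_at({100: 2}, unencoded=False)) == {}


def test_detect_ctss_threshold_boundaries():
    # isolated spike: count 100, FC = 101 >= 6 -> kept
    cl = _cluster({100: 100, 160: 100})
    reads = _reads_at({100: 100, 160: 100})
    recs = detect_ctss(cl, reads, W=15, min_fc=6, min_count=100)
    assert [r.position for r in recs] == [100, 160]
    # count 99 dropped regardless of fold change
    cl2 = _cluster({100: 99})
    recs2 = detect_ctss(cl2, _reads_at({100: 99}), W=15)
    assert recs2 == []


def test_detect_ctss_exact_fc_boundary():
    # downstream mean 20 -> FC = (c0+1)/21; c0 = 125 gives exactly 6.0
    profile = {100: 125} | {100 + i: 20 for i in range(1, 16)}
    cl = _cluster(profile)
    recs = detect_ctss(cl, _reads_at(profile), W=15, min_fc=6, min_count=100)
    assert 100 in [r.position for r in recs]
    profile[100] = 124  # FC 5.95 < 6
    recs = detect_ctss(_cluster(profile), _reads_at(profile), W=15)
    assert 100 not in [r.position for r in recs]


def test_uniform_plateau_yields_no_ctss():
    profile = {100 + i: 150 for i in range(30)}
    cl = _cluster(profile)
    recs = detect_ctss(cl, _reads_at(profile), W=15, min_fc=6, min_count=100)
    # interior positions have FC close to 1; the trailing edge benefits from
    # the empty window but the leading plateau never reaches FC 6
    assert all(r.fold_change >= 6 for r in recs)
    assert not any(100 <= r.position < 115 for r in recs)


def test_planted_ctss_recovered_exactly():
    """Two spikes >= 100 over background <= 5 are recovered and nothing else."""
    background = {100 + i: 5 for i in range(60)}
    profile = background | {110: 300, 150: 200}
    cl = _cluster(profile)
    recs = detect_ctss(cl, _reads_at(profile), W=15, min_fc=6, min_count=100)
    assert [r.position for r in recs] == [110, 150]


def test_window_size_robustness():
    """Detected sets for W in {10, 15, 20} differ by at most 10%."""
    rng = np.random.default_rng(3)
    background = {200 + i: int(rng.integers(0, 6)) for i in range(120)}
    profile = background | {220: 250, 300: 180, 280: 140}
    cl = _cluster(profile)
    reads = _reads_at(profile)
    sets = [frozenset(r.position for r in detect_ctss(cl, reads, W=w))
            for w in (10, 15, 20)]
    union = set().union(*sets)
    inter = set(sets[0]).intersection(*sets[1:])
    assert len(union) - len(inter) <= max(1, 0.1 * len(union))


def test_farthest_pair_and_strand_orientation():
    recs = [CTSSRecord(p, 150, 10.0, 15) for p in (10, 40, 90)]
    plus = farthest_ctss_pair(recs, "+")
    minus = farthest_ctss_pair(recs, "-")
    assert (plus[0].position, plus[1].position) == (10, 90)
    assert (minus[0].position, minus[1].position) == (90, 10)
    assert farthest_ctss_pair(recs[:1], "+") is None
    two = farthest_ctss_pair(recs[:2], "+")
    assert (two[0].position, two[1].position) == (10, 40)


@pytest.mark.parametrize("c1,c2,expected", [
    (5, 5, 0.5), (0, 10, 0.0), (3, 1, 0.75),
])
def test_psi_values(c1, c2, expected):
    assert compute_psi(c1, c2) == pytest.approx(expected)


def test_psi_complement_and_undefined(rng):
    for _ in range(50):
        a, b = rng.integers(0, 100, size=2)
        if a + b == 0:
            continue
        assert compute_psi(a, b) + compute_psi(b, a) == pytest.approx(1.0)
    assert np.isnan(compute_psi(0, 0))


def test_per_cell_psi_table():
    reads = (_reads_at({100: 3}, cb="C1") + _reads_at({200: 1}, cb="C1")
             + _reads_at({200: 4}, cb="C2"))
    table = per_cell_psi(reads, 100, 200)
    assert set(table["cell"]) == {"C1", "C2"}
    c1 = table[table.cell == "C1"].iloc[0]
    assert (c1.count_tss1, c1.count_tss2, c1.psi) == (3, 1, 0.75)
    c2 = table[table.cell == "C2"].iloc[0]
    assert c2.psi == 0.0
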