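"""Label construction from ranked peaks, the logistic classifiers and the
feature plumbing."""
import numpy as np
import pytest

from captss.classify import (ClusterFeatures, LabeledCluster, LogisticModel,
                             PeakRecord, build_training_labels,
                             classify_cluster, cluster_features,
                             combine_models, fit_logistic, load_default_model,
                             load_peaks_bed)
from captss.clustering import TSSCluster
from captss.simulate import simulate_labeled_benchmark


def _cl(lo, hi, chrom="chr1"):
    counts = {lo: 5, hi: 5}
    return TSSCluster("G", chrom, "+", counts)


def _peaks(n=100, chrom="chr1", width=100, gap=1000):
    """n peaks with strictly decreasing scores, left to right."""
    return [PeakRecord(chrom, i * gap, i * gap + width, float(n - i))
            for i in range(n)]


def oracle_overlap_frac(span, peak):
    lo, hi = span[0], span[1] + 1
    inter = sum(1 for x in range(lo, hi) if peak.start <= x < peak.end)
    return inter / (hi - lo)


def test_labels_from_extreme_peaks():
    peaks = _peaks(100)  # top 5%: peaks 0..4; bottom 5%: peaks 95..99
    pos = _cl(10, 80)           # inside peak 0
    neg = _cl(95010, 95080)     # inside peak 95
    mid = _cl(50010, 50080)     # inside a mid-ranked peak: unlabeled
    labeled = build_training_labels([pos, neg, mid], peaks)
    by_label = {x.label for x in labeled}
    assert by_label == {0, 1}
    assert len(labeled) == 2


def test_label_overlap_fraction_boundary():
    peaks = _peaks(100)
    # span of 100 bp overlapping peak 0 by exactly 5 bp: below the 0.1 cut
    low = _cl(95, 194)
    # overlap 10/100 = exactly 0.1: labeled positive
    at = _cl(90, 189)
    neg = _cl(95010, 95080)  # inside a bottom-5% peak
    labeled = build_training_labels([at, low, neg], peaks)
    keys = {x.key for x in labeled}
    assert ("chr1", at.span, "+") in keys
    assert ("chr1", low.span, "+") not in keys
    # a 5%-overlap cluster alone yields no positive class at all
    with pytest.raises(ValueError):
        build_training_labels([low, neg], peaks)


def test_label_fraction_matches_bruteforce_oracle(rng):
    from captss.classify import _overlap_frac
    for _ in range(500):
        lo = int(rng.integers(0, 500))
        hi = lo + int(rng.integers(0, 80))
        ps = int(rng.integers(0, 500))
        peak = PeakRecord("chr1", ps, ps + int(rng.integers(1, 120)), 1.0)
        assert _overlap_frac((lo, hi), peak) == pytest.approx(
            oracle_overlap_frac((lo, hi), peak))


def test_labels_balanced_by_subsampling():
    peaks = _peaks(200)  # top/bottom 10 peaks each
    pos = [_cl(i * 1000 + 10, i * 1000 + 60) for i in range(10)]      # peaks 0..9
    neg = [_cl((196 + i // 3) * 1000 + 10 + (i % 3) * 61,
               (196 + i // 3) * 1000 + 60 + (i % 3) * 61) for i in range(4)]
    labeled = build_training_labels(pos + neg, peaks, top_frac=0.05)
    n_pos = sum(x.label == 1 for x in labeled)
    n_neg = sum(x.label == 0 for x in labeled)
    assert n_pos == n_neg > 0


def test_low_coverage_mode_takes_peakless_clusters_as_negative():
    peaks = _peaks(100)
    pos = _cl(10, 80)
    nowhere = _cl(990100, 990200)  # no peak anywhere near
    labeled = build_training_labels([pos, nowhere], peaks, low_coverage_mode=True)
    assert sorted(x.label for x in labeled) == [0, 1]


def test_duplicate_spans_removed():
    peaks = _peaks(100)
    a, b = _cl(10, 80), _cl(10, 80)
    neg = _cl(95010, 95080)
    labeled = build_training_labels([a, b, neg], peaks)
    assert len(labeled) == 2


def test_logistic_separable_and_shuffled(rng):
    data = simulate_labeled_benchmark(n_per_class=150, seed=1, with_sequence=False)
    # fully separable variant: push the classes far apart
    for d in data:
        d.features.unencoded_g_frac = 0.9 if d.label else 0.01
        d.features.std_dev = 3.0 if d.label else 80.0
    model, aurocs = fit_logistic(data, folds=10, seed=1)
    assert aurocs.mean() == pytest.approx(1.0, abs=1e-6)
    shuffled = rng.permutation([d.label for d in data])
    for d, y in zip(data, shuffled):
        d.label = int(y)
    _, null_aurocs = fit_logistic(data, folds=10, seed=1)
    assert null_aurocs.mean() == pytest.approx(0.5, abs=0.1)


def test_logistic_scale_equivariant_after_standardization():
    data = simulate_labeled_benchmark(n_per_class=100, seed=2, with_sequence=False)
    model, _ = fit_logistic(data, folds=5, seed=2)
    scaled = simulate_labeled_benchmark(n_per_class=100, seed=2, with_sequence=False)
    for d in scaled:
        d.features.cluster_count *= 10.0
    model10, _ = fit_logistic(scaled, folds=5, seed=2)
    X = np.stack([d.features.vector() for d in data])
    X10 = X.copy()
    X10[:, 0] *= 10.0
    np.testing.assert_allclose(model.predict_proba(X), model10.predict_proba(X10),
                               atol=1e-6)


def test_classify_threshold_is_strict():
    model = LogisticModel(["a", "b", "c", "d"], np.zeros(4), np.ones(4),
                          np.zeros(4), 0.0)  # always prob 0.5
    feats = ClusterFeatures(1, 1, 1, 0.5)
    prob, keep = classify_cluster(feats, model, threshold=0.5)
    assert prob == pytest.approx(0.5)
    assert keep is False
    model.intercept = 0.1  # prob ~0.525
    _, keep = classify_cluster(feats, model, threshold=0.5)
    assert keep is True
    model.intercept = -5.0
    _, keep = classify_cluster(feats, model, threshold=0.5)
    assert keep is False


def test_classify_rejects_nan_features():
    model = load_default_model()
    with pytest.raises(ValueError):
        classify_cluster(ClusterFeatures(1, 1, float("nan"), 0.1), model)


def test_combine_models_concatenation():
    four = np.arange(4.0)
    emb = np.zeros(32)
    vec = combine_models(four, emb)
    assert vec.shape == (36,)
    np.testing.assert_array_equal(vec[:4], four)
    np.testing.assert_array_equal(combine_models(four, emb),
                                  combine_models(four, emb))


def test_missing_embedding_falls_back_to_four_features():
    feats = ClusterFeatures(1, 2, 3, 0.4, seq_embedding=None)
    assert feats.vector(use_embedding=True).shape == (4,)


def test_model_json_round_trip(tmp_path):
    model = load_default_model()
    path = tmp_path / "m.json"
    model.save(path)
    back = LogisticModel.load(path)
    X = np.random.default_rng(0).random((5, 4))
    np.testing.assert_allclose(model.predict_proba(X), back.predict_proba(X))
    assert back.feature_names == model.feature_names


def test_load_peaks_bed(tmp_path):
    bed = tmp_path / "p.bed"
    bed.write_text("chr1\t0\t100\tp1\t10\n"
                   "chr1\t200\t300\tp2\t5\t+\t33.5\t-1\t-1\t50\n")
    peaks = load_peaks_bed(bed)
    assert peaks[0].score == 10.0
    assert peaks[1].score == 33.5  # narrowPeak signal column preferred
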