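"""TSS-cluster artifact classification.

Three variants are supported:

* a logistic regression on four read-derived cluster features (total UMI
  count, summit count, positional standard deviation, unencoded-G fraction);
* a sequence CNN on the 200 bp around the cluster summit (see ``seqmodel``);
* their combination: the CNN's 32-unit embedding concatenated after the four
  cluster features (36 inputs) into the same logistic regression, or a
  jointly trained variant where the four features enter the network before
  its final dense layer.

Training labels come from ranked chromatin-accessibility (ATAC) peaks: a
cluster overlapping a top-ranked peak by at least 10% of its span is a
positive, one overlapping a bottom-ranked peak (or, for sparse data, no peak
at all) is a negative. Features are z-standardised before the logistic fit.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .clustering import TSSCluster

log = logging.getLogger(__name__)

CLUSTER_FEATURE_NAMES = ("cluster_count", "summit_count", "std_dev", "unencoded_g_frac")


@dataclass
class ClusterFeatures:
    cluster_count: float
    summit_count: float
    std_dev: float
    unencoded_g_frac: float
    seq_embedding: np.ndarray | None = None

    def vector(self, use_embedding: bool = False) -> np.ndarray:
        base = np.array([self.cluster_count, self.summit_count,
                         self.std_dev, self.unencoded_g_frac], dtype=float)
        if use_embedding:
            if self.seq_embedding is None:
                log.warning("no sequence embedding available; "
                            "falling back to 4 cluster features")
                return base
            return combine_models(base, np.asarray(self.seq_embedding, dtype=float))
        return base


@dataclass
class LabeledCluster:
    features: ClusterFeatures
    label: int  # 1 positive, 0 negative
    sequence: str | None = None  # 200 nt centered on the summit
    key: tuple | None = None  # identity for duplicate-span removal

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != 200:
            raise ValueError("sequence must be 200 nt")


@dataclass
class PeakRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    score: float  # rank statistic, higher = more confident

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("malformed peak interval")


def cluster_features(cluster: TSSCluster,
                     seq_embedding: np.ndarray | None = None) -> ClusterFeatures:
    return ClusterFeatures(
        cluster_count=float(cluster.total_umi),
        summit_count=float(cluster.summit_count),
        std_dev=float(cluster.std_dev),
        unencoded_g_frac=float(cluster.unencoded_g_frac),
        seq_embedding=seq_embedding,
    )


def combine_models(cluster_vec: np.ndarray, seq_embedding: np.ndarray) -> np.ndarray:
    """Concatenate the 4 cluster features and the 32-d sequence embedding."""
    return np.concatenate([np.asarray(cluster_vec, float).ravel(),
                           np.asarray(seq_embedding, float).ravel()])


def load_peaks_bed(path: str | os.PathLike) -> list[PeakRecord]:
    """Read a scored BED / narrowPeak file (column 5 or 7 used as the score,
    preferring the narrowPeak signal column when present)."""
    peaks = []
    with open(str(path)) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            score = float(parts[6]) if len(parts) >= 7 else float(parts[4])
            peaks.append(PeakRecord(parts[0], int(parts[1]), int(parts[2]), score))
    return peaks


def _overlap_frac(span: tuple[int, int], peak: PeakRecord) -> float:
    lo, hi = span[0], span[1] + 1  # cluster span is inclusive of both bounds
    inter = min(hi, peak.end) - max(lo, peak.start)
    return max(inter, 0) / (hi - lo)


def build_training_labels(
    clusters: list[TSSCluster],
    peaks: list[PeakRecord],
    top_frac: float = 0.05,
    overlap_frac: float = 0.1,
    low_coverage_mode: bool = False,
    seed: int = 0,
    sequences: list[str] | None = None,
) -> list[LabeledCluster]:
    """Label clusters against rank-extreme peaks and balance the classes.

    Top ``top_frac`` peaks by score define positives, the bottom fraction
    negatives; a cluster must overlap a peak by at least ``overlap_frac`` of
    its own span to take its label. Clusters matching both extremes are
    dropped, duplicate spans removed, and the majority class subsampled with
    a seeded RNG to balance.
    """
    ranked = sorted(peaks, key=lambda p: -p.score)
    n_ext = max(1, int(round(top_frac * len(ranked))))
    top, bottom = ranked[:n_ext], ranked[-n_ext:]

    labeled: list[LabeledCluster] = []
    seen_spans: set[tuple] = set()
    for i, cl in enumerate(clusters):
        key = (cl.chrom, cl.span, cl.strand)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        same_chrom = lambda ps: (p for p in ps if p.chrom == cl.chrom)
        is_pos = any(_overlap_frac(cl.span, p) >= overlap_frac for p in same_chrom(top))
        is_neg = any(_overlap_frac(cl.span, p) >= overlap_frac for p in same_chrom(bottom))
        if low_coverage_mode and not is_neg:
            is_neg = not any(_overlap_frac(cl.span, p) > 0 for p in same_chrom(peaks))
        if is_pos == is_neg:  # unlabeled, or contradictory -> dropped
            continue
        labeled.append(LabeledCluster(
            features=cluster_features(cl), label=int(is_pos),
            sequence=sequences[i] if sequences is not None else None, key=key))

    return _balance(labeled, seed)


def build_training_labels_from_table(df, peaks: list[PeakRecord],
                                     top_frac: float = 0.05,
                                     overlap_frac: float = 0.1,
                                     low_coverage_mode: bool = False,
                                     seed: int = 0) -> list[LabeledCluster]:
    """Label a cluster table (columns chrom/start/end/strand + the four
    feature columns, as written by the detect pipeline) against ranked peaks.
    The table's ``end`` is half-open BED-style."""
    ranked = sorted(peaks, key=lambda p: -p.score)
    n_ext = max(1, int(round(top_frac * len(ranked))))
    top, bottom = ranked[:n_ext], ranked[-n_ext:]
    labeled, seen = [], set()
    for row in df.itertuples():
        key = (row.chrom, row.start, row.end, row.strand)
        if key in seen:
            continue
        seen.add(key)
        span = (row.start, row.end - 1)
        mine = lambda ps: (p for p in ps if p.chrom == row.chrom)
        is_pos = any(_overlap_frac(span, p) >= overlap_frac for p in mine(top))
        is_neg = any(_overlap_frac(span, p) >= overlap_frac for p in mine(bottom))
        if low_coverage_mode and not is_neg:
            is_neg = not any(_overlap_frac(span, p) > 0 for p in mine(peaks))
        if is_pos == is_neg:
            continue
        feats = ClusterFeatures(float(row.total_umi), float(row.summit_count),
                                float(row.std_dev), float(row.unencoded_g_frac))
        labeled.append(LabeledCluster(features=feats, label=int(is_pos), key=key))
    return _balance(labeled, seed)


def _balance(labeled: list[LabeledCluster], seed: int) -> list[LabeledCluster]:
    pos = [x for x in labeled if x.label == 1]
    neg = [x for x in labeled if x.label == 0]
    if not pos or not neg:
        raise ValueError("labeling produced a single class; "
                         f"{len(pos)} positives / {len(neg)} negatives")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        pos = [pos[i] for i in np.sort(rng.choice(len(pos), len(neg), replace=False))]
    elif len(neg) > len(pos):
        neg = [neg[i] for i in np.sort(rng.choice(len(neg), len(pos), replace=False))]
    return pos + neg


# ---------------------------------------------------------------------------
# logistic model

@dataclass
class LogisticModel:
    """Standardised logistic regression with JSON persistence."""

    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    version: str = "1"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X - self.scaler_mean) / self.scaler_scale
        logit = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def save(self, path: str | os.PathLike) -> None:
        payload = {
            "format": "captss-logistic", "version": self.version,
            "feature_names": list(self.feature_names),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": self.coef.tolist(), "intercept": float(self.intercept),
        }
        with open(str(path), "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LogisticModel":
        with open(str(path)) as fh:
            p = json.load(fh)
        if p.get("format") != "captss-logistic":
            raise ValueError(f"{path} is not a logistic model file")
        return cls(p["feature_names"], np.array(p["scaler_mean"]),
                   np.array(p["scaler_scale"]), np.array(p["coef"]),
                   p["intercept"], p.get("version", "?"))


def default_model_path() -> str:
    return os.path.join(os.path.dirname(__file__), "models", "cluster_logistic.json")


def load_default_model() -> LogisticModel:
    return LogisticModel.load(default_model_path())


def _design(data: list[LabeledCluster], use_embedding: bool) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([d.features.vector(use_embedding) for d in data])
    y = np.array([d.label for d in data])
    return X, y


def fit_logistic(data: list[LabeledCluster], folds: int = 10,
                 use_embedding: bool = False, C: float = 1.0,
                 seed: int = 0) -> tuple[LogisticModel, np.ndarray]:
    """Fit the (4- or 36-feature) logistic classifier with stratified
    cross-validation; returns the model refit on all data and per-fold AUROC."""
    X, y = _design(data, use_embedding)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurocs = []
    for train, test in skf.split(X, y):
        pipe = Pipeline([("scale", StandardScaler()),
                         ("lr", LogisticRegression(C=C, max_iter=1000))])
        pipe.fit(X[train], y[train])
        aurocs.append(roc_auc_score(y[test], pipe.predict_proba(X[test])[:, 1]))
    pipe = Pipeline([("scale", StandardScaler()),
                     ("lr", LogisticRegression(C=C, max_iter=1000))])
    pipe.fit(X, y)
    scaler, lr = pipe["scale"], pipe["lr"]
    names = list(CLUSTER_FEATURE_NAMES)
    if use_embedding and X.shape[1] > 4:
        names += [f"seq_emb_{i}" for i in range(X.shape[1] - 4)]
    model = LogisticModel(names, scaler.mean_.copy(), scaler.scale_.copy(),
                          lr.coef_.ravel().copy(), float(lr.intercept_[0]))
    return model, np.array(aurocs)


def classify_cluster(features: ClusterFeatures, model: LogisticModel,
                     threshold: float = 0.5) -> tuple[float, bool]:
    """Probability that the cluster is a genuine TSS, and whether to keep it
    (strictly above the threshold)."""
    vec = features.vector(use_embedding=len(model.feature_names) > 4)
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"non-finite feature vector: {vec}")
    prob = float(model.predict_proba(vec)[0])
    return prob, prob > threshold
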