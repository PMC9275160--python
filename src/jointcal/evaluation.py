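"""Evaluation protocols: batch-mismatch quantification and classification.

Batch-effect removal is quantified by a subsampled MMD protocol: repeat
``n_repeats`` times, draw ``n_subsample`` rows from each side, compute
the kernel MMD, and report mean and standard deviation.  The in-batch
variant splits one batch into two random disjoint halves and serves as
the empirical floor of the measure, since no batch effect exists inside
a single batch.

Classification quality is reported as accuracy, F-score, AUC, and the
Matthews correlation coefficient.  The AUC uses the rank (pair-counting)
statistic with ties counted one half, which is exact on small samples;
MCC falls back to 0 whenever a confusion-table margin is empty.  For
replicate-based designs, per-sample probabilities are ensembled to one
diagnosis per subject by a median-then-threshold rule.

A permutation test re-trains the full pipeline under shuffled source
labels to draw the null distribution of target accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import FeatureTable
from .losses import KernelConfig, calibration_loss

__all__ = [
    "MMDEstimate", "MetricsReport", "mmd_value", "mmd_protocol", "in_batch_mmd",
    "classification_metrics", "ensemble_to_subject", "permutation_test",
    "export_embedding",
]


@dataclass(frozen=True)
class MMDEstimate:
    mean: float
    std: float
    n_subsample: int
    n_repeats: int
    seed: int


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    f_score: float
    auc: float       # NaN when y_true is single-class (AUC undefined)
    mcc: float
    n: int
    level: str = "sample"

    def to_dict(self) -> dict:
        return {"acc": self.acc, "f_score": self.f_score, "auc": self.auc,
                "mcc": self.mcc, "n": self.n, "level": self.level}


def mmd_value(A, B, kernel: KernelConfig = KernelConfig()) -> float:
    """Scalar MMD between two matrices: root of the clipped squared
    Gaussian estimator, or the mean-vector L1 distance for the linear kind."""
    v = calibration_loss(A, B, kernel)
    if kernel.kind == "multiscale_gaussian":
        return float(np.sqrt(v))
    return v


def _draw(rng, n_rows: int, k: int) -> np.ndarray:
    if n_rows >= k:
        return rng.choice(n_rows, size=k, replace=False)
    return rng.choice(n_rows, size=k, replace=True)  # documented fallback


def mmd_protocol(A, B, n_subsample: int = 500, n_repeats: int = 10,
                 kernel: KernelConfig = KernelConfig(), seed: int = 0) -> MMDEstimate:
    """Mean +- std of the MMD over repeated random subsamples of each side."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("matrices must be 2-D with equal widths")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_repeats):
        ia = _draw(rng, len(A), n_subsample)
        ib = _draw(rng, len(B), n_subsample)
        vals.append(mmd_value(A[ia], B[ib], kernel))
    vals = np.asarray(vals)
    std = float(vals.std(ddof=1)) if n_repeats > 1 else 0.0
    return MMDEstimate(float(vals.mean()), std, n_subsample, n_repeats, seed)


def in_batch_mmd(A, n_subsample: int = 500, n_repeats: int = 10,
                 kernel: KernelConfig = KernelConfig(), seed: int = 0) -> MMDEstimate:
    """The MMD floor: repeated random disjoint half-splits of one batch."""
    A = np.asarray(A, float)
    if A.ndim != 2 or len(A) < 4:
        raise ValueError("in-batch MMD needs a 2-D matrix with >= 4 rows")
    rng = np.random.default_rng(seed)
    half = len(A) // 2
    k = min(n_subsample, half)
    vals = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(A))
        vals.append(mmd_value(A[perm[:half]][:k], A[perm[half:]][:k], kernel))
    vals = np.asarray(vals)
    std = float(vals.std(ddof=1)) if n_repeats > 1 else 0.0
    return MMDEstimate(float(vals.mean()), std, n_subsample, n_repeats, seed)


def _rank_auc(y: np.ndarray, p: np.ndarray) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(p)  # average ranks resolve ties at 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(y_true, p, threshold: float = 0.5,
                           level: str = "sample") -> MetricsReport:
    """ACC, F-score, AUC, and MCC of scores ``p`` against binary truth."""
    y = np.asarray(y_true).ravel()
    p = np.asarray(p, float).ravel()
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("y_true and p must have equal length")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("y_true must be binary in {0, 1}")
    yhat = (p >= threshold).astype(int)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsReport(acc=float(acc), f_score=float(f),
                         auc=_rank_auc(y, p), mcc=float(mcc),
                         n=len(y), level=level)


def ensemble_to_subject(sample_probs, sample_subjects,
                        threshold: float = 0.5) -> pd.DataFrame:
    """Median-then-threshold subject diagnoses from per-sample probabilities.

    Returns a frame with columns ``subject``, ``prob`` (median of that
    subject's sample probabilities), and ``label`` (1 iff prob >= threshold),
    sorted by subject identifier.
    """
    p = np.asarray(sample_probs, float).ravel()
    subjects = np.asarray(sample_subjects).astype(str)
    if len(p) != len(subjects):
        raise ValueError("probabilities and subject ids must align")
    if np.isnan(p).any():
        raise ValueError("NaN probability encountered")
    med = pd.Series(p).groupby(subjects, sort=True).median()
    return pd.DataFrame({
        "subject": med.index.to_numpy(),
        "prob": med.to_numpy(),
        "label": (med.to_numpy() >= threshold).astype(int),
    })


def permutation_test(source: FeatureTable, target_with_labels: FeatureTable,
                     cfg, n_permutations: int = 100, bin_width: float = 0.05,
                     seed: int | None = None):
    """Null distribution of target accuracy under shuffled source labels.

    Each permutation shuffles the source labels, retrains the whole
    pipeline, and scores the target batch.  Returns (accuracies,
    histogram counts, bin edges); fully seeded.
    """
    from .data_io import FeatureTable as FT
    from .training import predict, train_joint

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if target_with_labels.labels is None:
        raise ValueError("target labels are required to score the null runs")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    target_unlabeled = target_with_labels.without_labels()
    accs = []
    for i in range(n_permutations):
        y_perm = rng.permutation(source.labels)
        if len(np.unique(y_perm)) < 2:  # cannot happen with both classes present
            raise ValueError("degenerate permutation")
        shuffled = FT(source.values, source.feature_ids, source.sample_ids,
                      source.subject_ids, source.batch_id, labels=y_perm)
        cfg_i = replace(cfg, seed=int((cfg.seed + 1000003 * (i + 1)) % (2**31 - 1)))
        model, _ = train_joint(shuffled, target_unlabeled, cfg_i)
        p, yhat = predict(model, target_unlabeled, cfg.decision_threshold,
                          batch_stats=True)
        accs.append(float(np.mean(yhat == target_with_labels.labels)))
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, edges = np.histogram(accs, bins=edges)
    return np.asarray(accs), counts, edges


def export_embedding(matrices, batches, labels=None, stages=None,
                     method: str = "tsne", seed: int = 0,
                     perplexity: float = 30.0) -> pd.DataFrame:
    """Joint 2-D embedding of several matrices on shared axes.

    All matrices are concatenated and embedded together so that raw and
    calibrated panels share one coordinate system.  Returns a frame with
    columns ``x``, ``y``, ``batch``, ``label``, ``stage``.
    """
    mats = [np.asarray(m, float) for m in matrices]
    widths = {m.shape[1] for m in mats}
    if len(widths) != 1:
        raise ValueError("all matrices must share the same width")
    counts = [len(m) for m in mats]
    total = int(np.sum(counts))

    def expand(per_matrix, default):
        if per_matrix is None:
            return np.repeat(default, total)
        out = []
        for tag, c in zip(per_matrix, counts):
            tag = np.asarray(tag)
            out.append(np.repeat(tag, c) if tag.ndim == 0 else tag)
        return np.concatenate(out)

    X = np.vstack(mats)
    if method == "tsne":
        from sklearn.manifold import TSNE
        emb = TSNE(n_components=2, random_state=seed, init="pca",
                   perplexity=min(perplexity, (total - 1) / 3.0)).fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method: {method!r}")
    return pd.DataFrame({
        "x": emb[:, 0], "y": emb[:, 1],
        "batch": expand(batches, "all"),
        "label": expand(labels, -1),
        "stage": expand(stages, "raw"),
    })
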