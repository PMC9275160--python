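"""Putative-biomarker screening by selection frequency plus a rank test.

Candidate features must be selected by a sparse classifier in a large
fraction of bootstrap refits (stability of the multivariate signal) AND
differ between classes by a univariate two-sample rank-sum test.  The
sparse selector is an L1-penalized logistic regression on standardized
features with the penalty strength chosen by inner cross-validation.
No multiple-testing correction is applied to the univariate p-values:
the frequency filter is the primary gatekeeper and the raw p < 0.05
condition mirrors the screening convention this package follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .data_io import FeatureTable

__all__ = ["BiomarkerResult", "selection_frequency", "screen_biomarkers",
           "results_to_frame"]


@dataclass(frozen=True)
class BiomarkerResult:
    feature_id: str
    selection_frequency: float
    p_value: float
    passes: bool


def _require_binary(batch: FeatureTable) -> None:
    if batch.labels is None or len(np.unique(batch.labels)) < 2:
        raise ValueError("biomarker screening requires binary labels with both classes")


def selection_frequency(batch: FeatureTable, n_resamples: int = 100,
                        Cs=(0.01, 0.1, 1.0), cv: int = 3, seed: int = 0,
                        max_redraws: int = 10) -> np.ndarray:
    """Per-feature fraction of bootstrap refits with a nonzero coefficient.

    Each resample draws a bootstrap of the samples, fits the sparse
    selector, and records which features receive nonzero weight.
    Single-class bootstraps are redrawn (a bounded number of times).
    """
    _require_binary(batch)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    n = batch.n_samples
    counts = np.zeros(batch.n_features)
    for _ in range(n_resamples):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            y = batch.labels[idx]
            if len(np.unique(y)) == 2:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap sample")
        X = StandardScaler().fit_transform(batch.values[idx])
        clf = LogisticRegressionCV(
            Cs=list(Cs), cv=cv, penalty="l1", solver="liblinear", scoring="accuracy",
            max_iter=500, random_state=int(rng.integers(2**31 - 1)),
        ).fit(X, y)
        counts += (np.abs(clf.coef_.ravel()) > 1e-12)
    return counts / n_resamples


def screen_biomarkers(batch: FeatureTable, freq_threshold: float = 0.9,
                      p_threshold: float = 0.05, n_resamples: int = 100,
                      Cs=(0.01, 0.1, 1.0), cv: int = 3,
                      seed: int = 0) -> list[BiomarkerResult]:
    """Flag features with selection frequency above ``freq_threshold`` and
    a two-sided rank-sum p-value below ``p_threshold``.

    Returns one result per feature (candidates are those with
    ``passes=True``), so intersections across batches reduce to set
    algebra on the flagged feature ids.
    """
    _require_binary(batch)
    freqs = selection_frequency(batch, n_resamples, Cs, cv, seed)
    g0 = batch.values[batch.labels == 0]
    g1 = batch.values[batch.labels == 1]
    results = []
    for j, fid in enumerate(batch.feature_ids):
        p = float(mannwhitneyu(g0[:, j], g1[:, j],
                               alternative="two-sided").pvalue)
        passes = bool(freqs[j] > freq_threshold and p < p_threshold)
        results.append(BiomarkerResult(fid, float(freqs[j]), p, passes))
    return results


def results_to_frame(results: list[BiomarkerResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
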