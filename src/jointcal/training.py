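"""Joint training of calibrator, reconstructors, and discriminator.

Each optimization step draws one minibatch from the labeled source batch
and one from the unlabeled target batch, pushes both through the shared
calibrator (each minibatch standardized against its own statistics by
the leading batch-norm layer), decodes each through its own
reconstructor, classifies the source codes with the discriminator, and
takes a single Adam step on the weighted total loss

    L = alpha * L_R + beta * L_C + gamma * L_D.

Target labels are never consumed: the target table is accepted without
labels, and any labels present are ignored.  Runs are bit-for-bit
reproducible under a fixed seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .data_io import FeatureTable
from .losses import (KernelConfig, LossWeights, calibration_loss_grad,
                     discrimination_loss_grad, reconstruction_loss_grad,
                     total_loss)
from .networks import ModelState, calibrate, discriminate, init_model
from .nn import Adam

__all__ = ["TrainConfig", "TrainReport", "train_joint", "predict",
           "in_batch_cross_validation", "train_config_from_yaml"]

_PROB_EPS = 1e-7  # clamp for the BCE, which requires p strictly in (0, 1)


@dataclass(frozen=True)
class TrainConfig:
    weights: LossWeights = LossWeights()
    kernel: KernelConfig = KernelConfig()
    epochs: int = 200
    minibatch_size: int = 128
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    decision_threshold: float = 0.5
    negative_slope: float = 0.01
    one_sided_bce: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.minibatch_size < 1:
            raise ValueError("epochs and minibatch_size must be positive")
        if self.kernel.kind == "multiscale_gaussian" and self.minibatch_size < 2:
            raise ValueError("minibatch_size must be >= 2 with the gaussian kernel")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer!r}")


def train_config_from_yaml(path) -> TrainConfig:
    """Build a TrainConfig from a flat YAML run-config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    if "weights" in cfg:
        kwargs["weights"] = LossWeights(**cfg.pop("weights"))
    if "kernel" in cfg:
        k = cfg.pop("kernel")
        for key in ("bandwidth_multipliers", "bandwidths"):
            if k.get(key) is not None:
                k[key] = tuple(k[key])
        kwargs["kernel"] = KernelConfig(**k)
    kwargs.update(cfg)
    return TrainConfig(**kwargs)


@dataclass
class TrainReport:
    """Per-epoch loss trace plus wall-clock cost of one training run."""

    trace: pd.DataFrame   # columns: epoch, loss_r, loss_c, loss_d, loss_total
    seconds: float


def _validate_pair(source: FeatureTable, target: FeatureTable) -> None:
    if source.labels is None:
        raise ValueError("source batch must carry binary labels")
    if len(np.unique(source.labels)) < 2:
        raise ValueError("source labels must contain both classes")
    if source.n_features != target.n_features or \
            source.feature_ids != target.feature_ids:
        raise ValueError("source and target must share feature count and ordering")


def _minibatches(n_large: int, n_small: int, batch_size: int, rng):
    """Chunk a permutation of the larger side; resample the smaller side."""
    perm = rng.permutation(n_large)
    chunks = [perm[i:i + batch_size] for i in range(0, n_large, batch_size)]
    if len(chunks) > 1 and len(chunks[-1]) < 2:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks = chunks[:-1]
    for chunk in chunks:
        small = rng.integers(0, n_small, size=max(len(chunk), 2))
        yield chunk, small


def _train_step(model: ModelState, X1, y1, X2, cfg: TrainConfig, opt: Adam):
    w = cfg.weights
    opt.zero_grad()

    Z1, c1 = model.calibrator.forward(X1, training=True)
    Z2, c2 = model.calibrator.forward(X2, training=True)
    X1p, r1c = model.reconstructor_1.forward(Z1, training=True)
    X2p, r2c = model.reconstructor_2.forward(Z2, training=True)
    p_raw, dc = model.discriminator.forward(Z1, training=True)
    p = np.clip(p_raw.ravel(), _PROB_EPS, 1.0 - _PROB_EPS)

    l_r1, gX1p = reconstruction_loss_grad(X1, X1p)
    l_r2, gX2p = reconstruction_loss_grad(X2, X2p)
    l_c, gZ1_c, gZ2_c = calibration_loss_grad(Z1, Z2, cfg.kernel)
    l_d, gp = discrimination_loss_grad(p, y1, cfg.one_sided_bce)
    l_r = l_r1 + l_r2

    gZ1 = w.beta * gZ1_c
    gZ2 = w.beta * gZ2_c
    if w.alpha != 0.0:
        gZ1 = gZ1 + model.reconstructor_1.backward(r1c, w.alpha * gX1p)
        gZ2 = gZ2 + model.reconstructor_2.backward(r2c, w.alpha * gX2p)
    if w.gamma != 0.0:
        gZ1 = gZ1 + model.discriminator.backward(
            dc, (w.gamma * gp).reshape(p_raw.shape))
    model.calibrator.backward(c1, gZ1)
    model.calibrator.backward(c2, gZ2)
    opt.step()
    return l_r, l_c, l_d, total_loss(l_r, l_c, l_d, w)


def train_joint(source: FeatureTable, target: FeatureTable,
                cfg: TrainConfig = TrainConfig()) -> tuple[ModelState, TrainReport]:
    """Jointly train all networks on (labeled source, unlabeled target).

    The target table's labels, if present, are ignored.  Returns the
    final model state and the per-epoch loss trace.
    """
    _validate_pair(source, target)
    t0 = time.perf_counter()
    X1 = source.values
    X2 = target.values
    y1 = source.labels.astype(float)
    model = init_model(source.n_features, cfg.seed,
                       negative_slope=cfg.negative_slope)
    opt = Adam(model.stacks(), learning_rate=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    source_is_large = len(X1) >= len(X2)
    n_large = max(len(X1), len(X2))
    n_small = min(len(X1), len(X2))

    rows = []
    for epoch in range(cfg.epochs):
        sums = np.zeros(4)
        n_steps = 0
        for large_idx, small_idx in _minibatches(n_large, n_small,
                                                 cfg.minibatch_size, rng):
            if source_is_large:
                i1, i2 = large_idx, small_idx
            else:
                i1, i2 = small_idx, large_idx
            step_losses = _train_step(model, X1[i1], y1[i1], X2[i2], cfg, opt)
            sums += step_losses
            n_steps += 1
        l_r, l_c, l_d, l_tot = sums / n_steps
        if not np.all(np.isfinite(sums)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        rows.append({"epoch": epoch, "loss_r": l_r, "loss_c": l_c,
                     "loss_d": l_d, "loss_total": l_tot})
    report = TrainReport(trace=pd.DataFrame(rows),
                         seconds=time.perf_counter() - t0)
    return model, report


def predict(model: ModelState, X, threshold: float = 0.5,
            batch_stats: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Class-1 probabilities ``D(C(X))`` and thresholded labels (p >= t).

    ``X`` may be a FeatureTable or a plain matrix.  ``batch_stats=True``
    calibrates the whole input against its own statistics (transductive
    mode, used when scoring a complete measurement batch); the default
    applies the model as a frozen function of single samples.
    """
    values = X.values if isinstance(X, FeatureTable) else np.asarray(X, float)
    p = discriminate(model, calibrate(model, values, batch_stats=batch_stats))
    return p, (p >= threshold).astype(int)


def in_batch_cross_validation(batch: FeatureTable, folds: int = 10,
                              cfg: TrainConfig = TrainConfig()):
    """Stratified k-fold CV inside one batch, pooled over held-out folds.

    Per fold, the held-out samples play the unlabeled-target role during
    training (they enter the calibration loss but never the classifier
    loss) and are then scored transductively.  Returns the evaluation
    report pooled over all held-out predictions.
    """
    from .evaluation import classification_metrics

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if batch.labels is None or len(np.unique(batch.labels)) < 2:
        raise ValueError("cross-validation requires both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    p_pooled = np.zeros(batch.n_samples)
    for train_idx, test_idx in skf.split(batch.values, batch.labels):
        tr = batch.subset(train_idx)
        te = batch.subset(test_idx).without_labels()
        if len(np.unique(tr.labels)) < 2:
            raise ValueError("a fold lost one class entirely; reduce folds")
        model, _ = train_joint(tr, te, cfg)
        p, _ = predict(model, te, cfg.decision_threshold, batch_stats=True)
        p_pooled[test_idx] = p
    return classification_metrics(batch.labels, p_pooled,
                                  threshold=cfg.decision_threshold)
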