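"""Loss functions of the joint framework.

The training objective is a weighted sum

    L = alpha * L_R + beta * L_C + gamma * L_D

of a reconstruction residual (mean squared Euclidean norm per sample), a
calibration loss measuring the distribution mismatch between the two
batches' latent codes, and the binary cross entropy of the discriminator
on the labeled source batch.

Two calibration-loss kinds are provided.  ``multiscale_gaussian`` is the
biased (V-statistic) squared maximum mean discrepancy with a sum of
Gaussian kernels whose bandwidths follow the median heuristic of pooled
pairwise squared distances times configurable multipliers; this is the
training default.  ``linear_mean_l1`` is the L1 distance between the two
latent mean vectors — the literal per-pair reading of the calibration
objective, kept as an auditable fallback.  Both are symmetric and
nonnegative.

Each loss comes in a value-only form and a ``*_grad`` form returning the
gradient with respect to its array inputs, which the training loop feeds
into the layer-wise backward passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LossWeights", "KernelConfig", "median_heuristic_bandwidths",
    "calibration_loss", "calibration_loss_grad",
    "reconstruction_loss", "reconstruction_loss_grad",
    "discrimination_loss", "discrimination_loss_grad",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights (alpha, beta, gamma) of the three loss components."""

    alpha: float = 1.0   # reconstruction
    beta: float = 1.0    # calibration (MMD)
    gamma: float = 1.0   # discrimination

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class KernelConfig:
    """Calibration-loss kernel settings.

    ``bandwidths=None`` activates the per-call median heuristic scaled by
    ``bandwidth_multipliers``; explicit positive bandwidths (squared-distance
    scales of ``exp(-||a-b||^2 / h)``) override it.  ``unbiased=True``
    switches the Gaussian estimator to the U-statistic (diagonal terms
    removed), for evaluation parity studies only.
    """

    kind: str = "multiscale_gaussian"
    bandwidth_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    bandwidths: tuple[float, ...] | None = None
    unbiased: bool = False

    def __post_init__(self):
        if self.kind not in ("multiscale_gaussian", "linear_mean_l1"):
            raise ValueError(f"unknown kernel kind: {self.kind!r}")
        if self.bandwidths is not None and any(h <= 0 for h in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        if any(m <= 0 for m in self.bandwidth_multipliers):
            raise ValueError("bandwidth multipliers must be positive")


def median_heuristic_bandwidths(Z1, Z2, multipliers=(0.5, 1.0, 2.0)) -> tuple[float, ...]:
    """Median of pooled pairwise squared distances times each multiplier."""
    pooled = np.vstack([Z1, Z2])
    d2 = cdist(pooled, pooled, "sqeuclidean")
    iu = np.triu_indices_from(d2, k=1)
    med = float(np.median(d2[iu])) if iu[0].size else 1.0
    if med <= 0:
        med = 1.0
    return tuple(med * m for m in multipliers)


def _check_pair(Z1, Z2, kernel: KernelConfig):
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    if Z1.ndim != 2 or Z2.ndim != 2 or Z1.shape[1] != Z2.shape[1]:
        raise ValueError("latent matrices must be 2-D with equal widths")
    if kernel.kind == "multiscale_gaussian" and (len(Z1) < 2 or len(Z2) < 2):
        raise ValueError("gaussian MMD needs at least 2 rows per side")
    return Z1, Z2


def _bandwidths(Z1, Z2, kernel: KernelConfig) -> tuple[float, ...]:
    if kernel.bandwidths is not None:
        return kernel.bandwidths
    return median_heuristic_bandwidths(Z1, Z2, kernel.bandwidth_multipliers)


def _kernel_sum(D2, bandwidths):
    K = np.zeros_like(D2)
    for h in bandwidths:
        K += np.exp(-D2 / h)
    return K


def gaussian_mmd2(Z1, Z2, bandwidths, unbiased=False) -> float:
    """Squared MMD with a sum-of-Gaussians kernel (V- or U-statistic)."""
    n, m = len(Z1), len(Z2)
    K11 = _kernel_sum(cdist(Z1, Z1, "sqeuclidean"), bandwidths)
    K22 = _kernel_sum(cdist(Z2, Z2, "sqeuclidean"), bandwidths)
    K12 = _kernel_sum(cdist(Z1, Z2, "sqeuclidean"), bandwidths)
    if unbiased:
        t11 = (K11.sum() - np.trace(K11)) / (n * (n - 1))
        t22 = (K22.sum() - np.trace(K22)) / (m * (m - 1))
    else:
        t11 = K11.sum() / (n * n)
        t22 = K22.sum() / (m * m)
    return float(t11 + t22 - 2.0 * K12.sum() / (n * m))


def calibration_loss(Z1, Z2, kernel: KernelConfig = KernelConfig()) -> float:
    """Distribution mismatch between the two latent batches (nonnegative)."""
    Z1, Z2 = _check_pair(Z1, Z2, kernel)
    if kernel.kind == "linear_mean_l1":
        return float(np.abs(Z1.mean(axis=0) - Z2.mean(axis=0)).sum())
    mmd2 = gaussian_mmd2(Z1, Z2, _bandwidths(Z1, Z2, kernel), kernel.unbiased)
    return max(mmd2, 0.0)


def calibration_loss_grad(Z1, Z2, kernel: KernelConfig = KernelConfig()):
    """Loss value plus gradients with respect to Z1 and Z2.

    For the Gaussian kind the median-heuristic bandwidths are treated as
    constants of the current minibatch (detached), the standard practice
    for MMD-matching objectives.
    """
    Z1, Z2 = _check_pair(Z1, Z2, kernel)
    if kernel.kind == "linear_mean_l1":
        diff = Z1.mean(axis=0) - Z2.mean(axis=0)
        s = np.sign(diff)
        g1 = np.broadcast_to(s / len(Z1), Z1.shape).copy()
        g2 = np.broadcast_to(-s / len(Z2), Z2.shape).copy()
        return float(np.abs(diff).sum()), g1, g2

    if kernel.unbiased:
        raise NotImplementedError("gradients are provided for the biased estimator only")
    bandwidths = _bandwidths(Z1, Z2, kernel)
    n, m = len(Z1), len(Z2)
    D11 = cdist(Z1, Z1, "sqeuclidean")
    D22 = cdist(Z2, Z2, "sqeuclidean")
    D12 = cdist(Z1, Z2, "sqeuclidean")
    K11 = _kernel_sum(D11, bandwidths)
    K22 = _kernel_sum(D22, bandwidths)
    K12 = _kernel_sum(D12, bandwidths)
    mmd2 = float(K11.sum() / n**2 + K22.sum() / m**2 - 2.0 * K12.sum() / (n * m))

    # dK/dz_i for k = sum_h exp(-d2/h): each term contributes -exp(-d2/h)/h * 2(z_i - z_j)
    def weights(D2):
        W = np.zeros_like(D2)
        for h in bandwidths:
            W += np.exp(-D2 / h) / h
        return W

    W11, W22, W12 = weights(D11), weights(D22), weights(D12)
    # grad of sum_ij k(a_i,a_j) wrt a_i: sum_j -2*W[i,j]*2*(a_i - a_j)  (i appears twice)
    g1 = (-4.0 / n**2) * (W11.sum(axis=1)[:, None] * Z1 - W11 @ Z1)
    g1 += (4.0 / (n * m)) * (W12.sum(axis=1)[:, None] * Z1 - W12 @ Z2)
    g2 = (-4.0 / m**2) * (W22.sum(axis=1)[:, None] * Z2 - W22 @ Z2)
    g2 += (4.0 / (n * m)) * (W12.sum(axis=0)[:, None] * Z2 - W12.T @ Z1)
    if mmd2 < 0.0:
        return 0.0, np.zeros_like(Z1), np.zeros_like(Z2)
    return mmd2, g1, g2


def reconstruction_loss(X, X_prime) -> float:
    """Mean over samples of the squared Euclidean reconstruction residual."""
    X = np.asarray(X, dtype=float)
    X_prime = np.asarray(X_prime, dtype=float)
    if X.shape != X_prime.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_prime.shape}")
    return float(np.sum((X - X_prime) ** 2) / len(X))


def reconstruction_loss_grad(X, X_prime):
    """Loss value plus the gradient with respect to the reconstruction."""
    val = reconstruction_loss(X, X_prime)
    g = 2.0 * (np.asarray(X_prime, float) - np.asarray(X, float)) / len(X)
    return val, g


def _check_bce(p, y):
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError("probability and label vectors must have equal length")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1); clamp upstream")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary in {0, 1}")
    return p, y


def discrimination_loss(p, y, one_sided: bool = False) -> float:
    """Mean binary cross entropy of predicted class-1 probabilities.

    ``one_sided=True`` keeps only the positive-class term (the literal
    printed form of the objective), for audit purposes.
    """
    p, y = _check_bce(p, y)
    if one_sided:
        return float(-(y * np.log(p)).mean())
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())


def discrimination_loss_grad(p, y, one_sided: bool = False):
    p, y = _check_bce(p, y)
    n = len(p)
    if one_sided:
        val = float(-(y * np.log(p)).mean())
        g = -y / p / n
    else:
        val = float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())
        g = (-(y / p) + (1 - y) / (1 - p)) / n
    return val, g


def total_loss(lr: float, lc: float, ld: float, w: LossWeights) -> float:
    """Weighted sum ``alpha*lr + beta*lc + gamma*ld`` of finite components."""
    for name, v in (("reconstruction", lr), ("calibration", lc), ("discrimination", ld)):
        if not np.isfinite(v):
            raise ValueError(f"{name} loss is not finite: {v}")
    return w.alpha * lr + w.beta * lc + w.gamma * ld
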