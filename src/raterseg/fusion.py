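"""Multirater label fusion and label smoothing.

Turns a stack of R hard annotation masks into a per-pixel class-probability
map (a *soft label*).  The primary route is plain averaging of one-hot
rater maps, optionally preceded by spatially varied label smoothing (SVLS),
which replaces each pixel's one-hot vector with a Gaussian-weighted average
of its neighbourhood before the rater average is taken.  Classical
baselines — majority vote, binary STAPLE, global label smoothing, and
temperature sharpening — are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import RaterStack


@dataclass
class SoftLabel:
    """Per-pixel class-probability map, shape (H, W, C), channels sum to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3:
            raise ValueError("probs must be (H, W, C)")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("soft label channels must sum to 1 per pixel")

    @property
    def num_classes(self) -> int:
        return self.probs.shape[-1]

    def argmax(self) -> np.ndarray:
        return np.argmax(self.probs, axis=-1)


def _gaussian_weights(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    return np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


@dataclass
class SVLSKernel:
    """Gaussian neighbourhood weights for spatially varied label smoothing.

    ``weights`` holds the unnormalised kernel exp(-d²/2σ²); its sum is the
    normaliser applied after the weighted neighbourhood sum.
    """

    sigma: float = 1.0
    size: int = 3
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.size % 2 == 0 or self.size < 1:
            raise ValueError("kernel size must be odd and positive")
        self.weights = _gaussian_weights(self.size, self.sigma)

    @property
    def normalizer(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def delta(cls, size: int = 3) -> "SVLSKernel":
        """Kernel with all weight at the centre (smoothing becomes a no-op)."""
        k = cls(sigma=1.0, size=size)
        w = np.zeros_like(k.weights)
        w[size // 2, size // 2] = 1.0
        k.weights = w
        return k


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(…, H, W) int -> (…, H, W, C) float one-hot."""
    return np.eye(num_classes, dtype=np.float64)[np.asarray(labels)]


def average_fusion(stack: RaterStack) -> SoftLabel:
    """Soft label as the plain mean of one-hot rater maps: p(c) = votes/R."""
    if stack.num_raters < 1:
        raise ValueError("need at least one rater")
    probs = one_hot(stack.labels, stack.num_classes).mean(axis=0)
    return SoftLabel(probs)


def svls_smooth(stack: RaterStack, kernel: SVLSKernel | None = None) -> SoftLabel:
    """Smooth each rater's one-hot map with the SVLS kernel, then average.

    Each pixel's class vector becomes the kernel-weighted mean of its
    neighbourhood's one-hot vectors, normalised by the kernel sum.  Borders
    use replicate padding so the normaliser is constant across the image.
    """
    if kernel is None:
        kernel = SVLSKernel()
    h, w = stack.labels.shape[1:]
    if h < kernel.size or w < kernel.size:
        raise ValueError("image smaller than the smoothing kernel")
    k = kernel.weights / kernel.normalizer
    onehot = one_hot(stack.labels, stack.num_classes)  # (R, H, W, C)
    smoothed = np.empty_like(onehot)
    for r in range(stack.num_raters):
        for c in range(stack.num_classes):
            smoothed[r, :, :, c] = ndimage.correlate(onehot[r, :, :, c], k, mode="nearest")
    probs = smoothed.mean(axis=0)
    probs /= probs.sum(axis=-1, keepdims=True)  # fix rounding drift
    return SoftLabel(probs)


def majority_vote(stack: RaterStack) -> np.ndarray:
    """Per-pixel plurality class; ties go to the lowest class index."""
    counts = one_hot(stack.labels, stack.num_classes).sum(axis=0)
    return np.argmax(counts, axis=-1)


def staple_fusion(stack: RaterStack, max_iter: int = 100, tol: float = 1e-7) -> SoftLabel:
    """Binary STAPLE: EM estimation of a consensus probability map together
    with per-rater sensitivity/specificity.

    Only the two-class case is supported.  Initialisation follows common
    practice: sensitivity = specificity = 0.99999 and a scalar foreground
    prior equal to the mean rater foreground fraction.
    """
    if stack.num_classes != 2:
        raise ValueError("STAPLE fusion supports exactly 2 classes")
    if stack.num_raters < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    d = (stack.labels.reshape(stack.num_raters, -1) == 1).astype(np.float64)  # (R, P)
    r, p_ = d.shape
    sens = np.full(r, 0.99999)
    spec = np.full(r, 0.99999)
    prior = float(np.clip(d.mean(), 1e-6, 1 - 1e-6))
    w = np.full(p_, prior)
    eps = 1e-12
    for _ in range(max_iter):
        # E-step: posterior that the true label is foreground
        log_a = np.log(prior) + (
            d.T @ np.log(sens + eps) + (1 - d).T @ np.log(1 - sens + eps)
        )
        log_b = np.log(1 - prior) + (
            d.T @ np.log(1 - spec + eps) + (1 - d).T @ np.log(spec + eps)
        )
        m = np.maximum(log_a, log_b)
        a = np.exp(log_a - m)
        b = np.exp(log_b - m)
        w = a / (a + b)
        # M-step
        sw = w.sum()
        new_sens = (d @ w) / max(sw, eps)
        new_spec = ((1 - d) @ (1 - w)) / max(p_ - sw, eps)
        delta = max(np.abs(new_sens - sens).max(), np.abs(new_spec - spec).max())
        sens, spec = np.clip(new_sens, eps, 1 - eps), np.clip(new_spec, eps, 1 - eps)
        if delta < tol:
            break
    fg = w.reshape(stack.labels.shape[1:])
    return SoftLabel(np.stack([1 - fg, fg], axis=-1))


def staple_parameters(stack: RaterStack, max_iter: int = 100, tol: float = 1e-7):
    """Per-rater (sensitivity, specificity) from the same EM as
    :func:`staple_fusion`; exposed for diagnostics."""
    if stack.num_classes != 2:
        raise ValueError("STAPLE fusion supports exactly 2 classes")
    d = (stack.labels.reshape(stack.num_raters, -1) == 1).astype(np.float64)
    r, p_ = d.shape
    sens = np.full(r, 0.99999)
    spec = np.full(r, 0.99999)
    prior = float(np.clip(d.mean(), 1e-6, 1 - 1e-6))
    eps = 1e-12
    for _ in range(max_iter):
        log_a = np.log(prior) + d.T @ np.log(sens + eps) + (1 - d).T @ np.log(1 - sens + eps)
        log_b = np.log(1 - prior) + d.T @ np.log(1 - spec + eps) + (1 - d).T @ np.log(spec + eps)
        m = np.maximum(log_a, log_b)
        a, b = np.exp(log_a - m), np.exp(log_b - m)
        w = a / (a + b)
        sw = w.sum()
        new_sens = (d @ w) / max(sw, eps)
        new_spec = ((1 - d) @ (1 - w)) / max(p_ - sw, eps)
        delta = max(np.abs(new_sens - sens).max(), np.abs(new_spec - spec).max())
        sens, spec = np.clip(new_sens, eps, 1 - eps), np.clip(new_spec, eps, 1 - eps)
        if delta < tol:
            break
    return sens, spec


def gls_smooth(stack: RaterStack, epsilon: float = 0.1) -> SoftLabel:
    """Global label smoothing of the rater average: (1-ε)·p + ε/C."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    avg = average_fusion(stack)
    probs = (1.0 - epsilon) * avg.probs + epsilon / stack.num_classes
    return SoftLabel(probs)


def sharpen(label: SoftLabel, temperature: float) -> SoftLabel:
    """Temperature sharpening: p ** (1/T), renormalised per pixel.

    T < 1 sharpens towards the argmax, T > 1 flattens, T = 1 is the identity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    powed = np.power(np.clip(label.probs, 1e-12, None), 1.0 / temperature)
    return SoftLabel(powed / powed.sum(axis=-1, keepdims=True))


FUSION_METHODS = ("average", "svls", "majority_vote", "staple", "gls", "sharpen")


@dataclass
class FusionConfig:
    """Which fusion/smoothing strategy to run, with its hyperparameters."""

    method: str = "svls"
    sharpen_temperature: float = 0.5
    gls_epsilon: float = 0.1
    svls: SVLSKernel = field(default_factory=SVLSKernel)

    def __post_init__(self) -> None:
        if self.method not in FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.method!r}")


def fuse(stack: RaterStack, config: FusionConfig) -> SoftLabel:
    """Dispatch to the configured fusion strategy, always returning a soft
    label (hard strategies are one-hot encoded)."""
    if config.method == "average":
        return average_fusion(stack)
    if config.method == "svls":
        return svls_smooth(stack, config.svls)
    if config.method == "majority_vote":
        return SoftLabel(one_hot(majority_vote(stack), stack.num_classes))
    if config.method == "staple":
        return staple_fusion(stack)
    if config.method == "gls":
        return gls_smooth(stack, config.gls_epsilon)
    if config.method == "sharpen":
        return sharpen(average_fusion(stack), config.sharpen_temperature)
    raise ValueError(config.method)
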