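"""Synthetic multirater segmentation data.

Generates ground-truth shapes (smooth blobs and ellipses on a noisy
intensity background) and simulates a panel of annotators with distinct
systematic biases, so that the whole fusion/uncertainty/training pipeline
can be exercised without any external dataset.

The default five-rater panel emulates the archetypes commonly used to
benchmark multirater fusion: a faithful rater with small boundary jitter,
a systematic over-segmenter, a systematic under-segmenter, a rater that
over-segments and additionally introduces small fractures through the
structure, and a rater that annotates everything as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.morphology import disk


class RaterKind(str, Enum):
    """Annotator archetypes for the simulated panel."""

    FAITHFUL = "faithful"
    OVERSEGMENT = "oversegment"
    UNDERSEGMENT = "undersegment"
    FRACTURE_OVERSEG = "fracture_overseg"
    ALL_BACKGROUND = "all_background"


@dataclass(frozen=True)
class RaterModel:
    """Parameters of one simulated annotator.

    ``strength`` is the radius (pixels) of the disk structuring element used
    for dilation/erosion (or the jitter band half-width for a faithful
    rater); ``fracture_count`` only matters for ``fracture_overseg``.
    """

    kind: RaterKind
    strength: int = 2
    fracture_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.kind, RaterKind):
            object.__setattr__(self, "kind", RaterKind(self.kind))
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        if self.fracture_count < 0:
            raise ValueError("fracture_count must be non-negative")


@dataclass
class ImageSample:
    """One synthetic image with its true segmentation mask."""

    image: np.ndarray  # (H, W) float in [0, 1]
    gt_mask: np.ndarray  # (H, W) int in {0..C-1}
    id: str
    num_classes: int = 2

    def __post_init__(self) -> None:
        if self.image.shape != self.gt_mask.shape:
            raise ValueError("image and gt_mask must share a spatial shape")
        if self.gt_mask.min() < 0 or self.gt_mask.max() >= self.num_classes:
            raise ValueError("gt_mask contains an invalid class index")


@dataclass
class RaterStack:
    """R stacked integer label maps for one image."""

    labels: np.ndarray  # (R, H, W) int
    rater_ids: list[str] = field(default_factory=list)
    num_classes: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (R, H, W)")
        if not self.rater_ids:
            self.rater_ids = [f"rater_{r}" for r in range(self.labels.shape[0])]
        if len(self.rater_ids) != self.labels.shape[0]:
            raise ValueError("rater_ids length must equal R")
        if self.labels.max(initial=0) >= self.num_classes:
            raise ValueError("rater label exceeds num_classes - 1")

    @property
    def num_raters(self) -> int:
        return self.labels.shape[0]


# Default panel, in the canonical order faithful / over / under /
# fracture+over / all-background.  Strengths are picked so the five raters
# visibly disagree on a ~64 px structure while each remains a plausible
# annotation of it.
DEFAULT_PANEL: tuple[tuple[RaterKind, int, int], ...] = (
    (RaterKind.FAITHFUL, 1, 0),
    (RaterKind.OVERSEGMENT, 2, 0),
    (RaterKind.UNDERSEGMENT, 2, 0),
    (RaterKind.FRACTURE_OVERSEG, 2, 2),
    (RaterKind.ALL_BACKGROUND, 0, 0),
)


def _blob_mask(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Random smooth blob: thresholded low-pass-filtered noise, largest
    connected component kept."""
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=min(height, width) / 8.0)
    mask = smooth > np.quantile(smooth, 0.72)
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((height, width), dtype=bool)
    sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _ellipse_mask(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    cy = rng.uniform(0.3, 0.7) * height
    cx = rng.uniform(0.3, 0.7) * width
    ry = rng.uniform(0.12, 0.3) * height
    rx = rng.uniform(0.12, 0.3) * width
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(phi) + dx * np.sin(phi)
    v = -dy * np.sin(phi) + dx * np.cos(phi)
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _fallback_ellipse(height: int, width: int, k: int) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    r = min(height, width) / (6 + 2 * k)
    return (yy - height / 2) ** 2 + (xx - width / 2) ** 2 <= r**2


def generate_shapes(
    n: int,
    height: int = 64,
    width: int = 64,
    num_classes: int = 2,
    seed: int = 0,
    noise_sigma: float = 0.08,
    blur_sigma: float = 1.0,
) -> list[ImageSample]:
    """Generate ``n`` reproducible image/mask samples.

    Masks alternate between smooth random blobs and ellipses; with more than
    two classes each foreground class gets its own shape, overlaps resolved
    in favour of the lower class index.  The image is the class map rendered
    at distinct intensity levels, blurred and corrupted with additive
    Gaussian noise, so segmentation is learnable but not pixel-trivial.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if height < 16 or width < 16:
        raise ValueError("height and width must be >= 16")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")

    root = np.random.default_rng(seed)
    samples: list[ImageSample] = []
    for i in range(n):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        gt = np.zeros((height, width), dtype=np.int64)
        # paint higher classes first so lower foreground classes win overlaps
        for c in range(num_classes - 1, 0, -1):
            if (i + c) % 2 == 0:
                m = _blob_mask(rng, height, width)
            else:
                m = _ellipse_mask(rng, height, width)
            if not m.any():
                m = _fallback_ellipse(height, width, c)
            gt[m] = c
        # guarantee every foreground class is represented
        for c in range(1, num_classes):
            if not (gt == c).any():
                gt[_fallback_ellipse(height, width, c)] = c

        levels = np.linspace(0.15, 0.85, num_classes)
        image = levels[gt]
        image = ndimage.gaussian_filter(image, sigma=blur_sigma)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0).astype(np.float32)
        samples.append(
            ImageSample(image=image, gt_mask=gt, id=f"sample_{seed}_{i:05d}", num_classes=num_classes)
        )
    return samples


def _per_class_morphology(gt_mask: np.ndarray, num_classes: int, op, radius: int) -> np.ndarray:
    """Apply a binary morphology op to each foreground class independently.

    After dilation two classes may claim a pixel; the lower class index wins
    (deterministic tie-break).
    """
    if radius == 0:
        return gt_mask.copy()
    selem = disk(radius)
    out = np.zeros_like(gt_mask)
    for c in range(num_classes - 1, 0, -1):
        m = op(gt_mask == c, structure=selem)
        out[m] = c
    return out


def _fracture_lines(
    mask: np.ndarray, count: int, rng: np.random.Generator, width_px: float = 1.5
) -> np.ndarray:
    """Remove ``count`` straight strips through the foreground centroid."""
    if count == 0 or not mask.any():
        return mask
    cy, cx = ndimage.center_of_mass(mask)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    out = mask.copy()
    for _ in range(count):
        angle = rng.uniform(0, np.pi)
        # signed distance from the line through (cy, cx) at `angle`
        d = (yy - cy) * np.cos(angle) - (xx - cx) * np.sin(angle)
        out[np.abs(d) <= width_px / 2.0] = False
    return out


def simulate_rater(gt_mask: np.ndarray, model: RaterModel, num_classes: int | None = None) -> np.ndarray:
    """Produce one simulated annotation of ``gt_mask`` under ``model``."""
    gt_mask = np.asarray(gt_mask)
    if num_classes is None:
        num_classes = int(gt_mask.max()) + 1 if gt_mask.size else 2
        num_classes = max(num_classes, 2)
    rng = np.random.default_rng(model.seed)

    if model.kind is RaterKind.ALL_BACKGROUND:
        return np.zeros_like(gt_mask)
    if model.kind is RaterKind.OVERSEGMENT:
        return _per_class_morphology(gt_mask, num_classes, ndimage.binary_dilation, model.strength)
    if model.kind is RaterKind.UNDERSEGMENT:
        return _per_class_morphology(gt_mask, num_classes, ndimage.binary_erosion, model.strength)
    if model.kind is RaterKind.FRACTURE_OVERSEG:
        dil = _per_class_morphology(gt_mask, num_classes, ndimage.binary_dilation, model.strength)
        out = np.zeros_like(dil)
        for c in range(num_classes - 1, 0, -1):
            m = _fracture_lines(dil == c, model.fracture_count, rng)
            out[m] = c
        return out
    if model.kind is RaterKind.FAITHFUL:
        if model.strength == 0:
            return gt_mask.copy()
        # boundary jitter: keep the eroded core, then add back a random
        # subset of the annulus between erosion and dilation
        selem = disk(model.strength)
        out = np.zeros_like(gt_mask)
        for c in range(num_classes - 1, 0, -1):
            m = gt_mask == c
            core = ndimage.binary_erosion(m, structure=selem)
            halo = ndimage.binary_dilation(m, structure=selem) & ~core
            keep = halo & (rng.random(m.shape) < 0.5)
            out[core | keep] = c
        return out
    raise ValueError(f"unknown rater kind: {model.kind!r}")


def build_default_panel(
    gt_mask: np.ndarray,
    seed: int = 0,
    num_classes: int | None = None,
    panel: tuple[tuple[RaterKind, int, int], ...] = DEFAULT_PANEL,
) -> RaterStack:
    """Simulate the default five-rater panel on one ground-truth mask."""
    gt_mask = np.asarray(gt_mask)
    if num_classes is None:
        num_classes = max(int(gt_mask.max()) + 1, 2)
    root = np.random.default_rng(seed)
    labels, ids = [], []
    for k, (kind, strength, fractures) in enumerate(panel):
        model = RaterModel(
            kind=kind, strength=strength, fracture_count=fractures,
            seed=int(root.integers(0, 2**31 - 1)),
        )
        labels.append(simulate_rater(gt_mask, model, num_classes=num_classes))
        ids.append(f"{kind.value}_{k}")
    return RaterStack(labels=np.stack(labels), rater_ids=ids, num_classes=num_classes)
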