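"""Dataset manifests and on-disk formats.

A dataset on disk is a directory of 8-bit PNGs (class index = pixel value
for masks; intensities scaled to 0-255 for images) plus a JSON manifest
listing, per sample, the image path, optional ground-truth path, and the
per-rater mask paths.  Soft labels and variance maps are written as
multi-channel 32-bit float TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .fusion import SoftLabel
from .synthetic import ImageSample, RaterStack

MANIFEST_NAME = "manifest.json"


@dataclass
class ManifestEntry:
    id: str
    image: str
    raters: list[str]
    gt: str | None = None


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    num_classes: int
    root: Path = field(default_factory=Path)
    notes: dict = field(default_factory=dict)

    @property
    def num_raters(self) -> int:
        return len(self.entries[0].raters) if self.entries else 0


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.int64)


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0


def write_softlabel_tiff(label: SoftLabel | np.ndarray, path: str | Path) -> None:
    probs = label.probs if isinstance(label, SoftLabel) else np.asarray(label)
    tifffile.imwrite(path, probs.astype(np.float32))


def read_softlabel_tiff(path: str | Path) -> SoftLabel:
    arr = tifffile.imread(path).astype(np.float64)
    arr /= arr.sum(axis=-1, keepdims=True)  # undo float32 rounding
    return SoftLabel(arr)


def save_dataset(
    samples: list[ImageSample],
    stacks: list[RaterStack],
    out_dir: str | Path,
    notes: dict | None = None,
) -> DatasetManifest:
    """Write images, GT and rater masks as PNG plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    num_classes = samples[0].num_classes if samples else 2
    for sample, stack in zip(samples, stacks, strict=True):
        img_rel = f"{sample.id}_image.png"
        gt_rel = f"{sample.id}_gt.png"
        write_image_png(sample.image, out / img_rel)
        write_mask_png(sample.gt_mask, out / gt_rel)
        rater_rels = []
        for rid, lab in zip(stack.rater_ids, stack.labels):
            rel = f"{sample.id}_{rid}.png"
            write_mask_png(lab, out / rel)
            rater_rels.append(rel)
        entries.append(ManifestEntry(id=sample.id, image=img_rel, gt=gt_rel, raters=rater_rels))
    manifest = DatasetManifest(
        entries=entries, num_classes=num_classes, root=out, notes=notes or {}
    )
    payload = {
        "num_classes": manifest.num_classes,
        "notes": manifest.notes,
        "samples": [
            {"id": e.id, "image": e.image, "gt": e.gt, "raters": e.raters} for e in entries
        ],
    }
    (out / MANIFEST_NAME).write_text(json.dumps(payload, indent=2))
    return manifest


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest.

    Raises a descriptive error naming the first offending entry for missing
    files, inconsistent rater counts, or out-of-range class indices.
    """
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    payload = json.loads(path.read_text())
    root = path.parent
    entries = [
        ManifestEntry(id=s["id"], image=s["image"], gt=s.get("gt"), raters=list(s["raters"]))
        for s in payload.get("samples", [])
    ]
    if not entries:
        raise ValueError(f"manifest {path} lists no samples")
    num_classes = int(payload["num_classes"])
    r = len(entries[0].raters)
    for e in entries:
        if len(e.raters) != r:
            raise ValueError(f"sample {e.id!r}: expected {r} rater masks, found {len(e.raters)}")
        for rel in [e.image, *(([e.gt]) if e.gt else []), *e.raters]:
            if not (root / rel).exists():
                raise FileNotFoundError(f"sample {e.id!r}: missing file {root / rel}")
    return DatasetManifest(
        entries=entries, num_classes=num_classes, root=root, notes=payload.get("notes", {})
    )


def load_sample(manifest: DatasetManifest, entry: ManifestEntry) -> tuple[ImageSample, RaterStack]:
    image = read_image_png(manifest.root / entry.image)
    if entry.gt is not None:
        gt = read_mask_png(manifest.root / entry.gt)
    else:
        gt = np.zeros(image.shape, dtype=np.int64)
    labels = np.stack([read_mask_png(manifest.root / r) for r in entry.raters])
    if labels.max(initial=0) >= manifest.num_classes:
        raise ValueError(
            f"sample {entry.id!r}: rater class index {labels.max()} "
            f">= num_classes {manifest.num_classes}"
        )
    sample = ImageSample(image=image, gt_mask=gt, id=entry.id, num_classes=manifest.num_classes)
    stack = RaterStack(labels=labels, num_classes=manifest.num_classes)
    return sample, stack
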