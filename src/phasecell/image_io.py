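"""Image and dataset I/O.

Conventions used throughout the package:

* pixels are 0-based, row-major ``(row, col)``; bounding boxes are half-open
  ``[r0, r1) x [c0, c1)``;
* images are held as float arrays on the 0-255 intensity scale (network inputs
  are rescaled to [-1, 1] only at the model boundary, so image-quality metrics
  stay on the 8-bit scale);
* the six cell classes are always ordered ``CC, DEB, UN, AT, DYN, APO``
  (Cell clusters, Debris, Unattached, Attached, Dynamically blebbing,
  Apoptotically blebbing) — confusion-matrix axes, score vectors and manifests
  all follow this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

CLASS_LABELS: tuple[str, ...] = ("CC", "DEB", "UN", "AT", "DYN", "APO")
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_LABELS)}

#: Luminance weights for RGB -> gray collapse (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

CROP_SIZE = 64


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a float grayscale array in [0, 255].

    Multi-channel images are collapsed to luminance; an alpha channel, if
    present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr @ _LUMA if arr.shape[2] == 3 else arr[:, :, 0]
    elif arr.ndim != 2:
        raise OSError(f"cannot read image {path}: unsupported shape {arr.shape}")
    arr = arr.astype(np.float64)
    if arr.max() <= 1.0 and arr.dtype != np.uint8:
        arr = arr * 255.0
    return np.clip(arr, 0.0, 255.0)


def write_gray_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 255] float/int array as an 8-bit grayscale image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(image), 0, 255)
    iio.imwrite(path, np.rint(arr).astype(np.uint8))


def resize_to_crop(image: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Bilinear-resize any grayscale image to the classifier crop size."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.shape == (size, size):
        return image.copy()
    out = resize(image, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 255.0)


@dataclass
class DatasetManifest:
    """Per-class image paths of a class-per-directory dataset."""

    root: Path
    files: dict[str, list[Path]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(self.files.get(c, [])) for c in CLASS_LABELS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def labeled_paths(self) -> list[tuple[Path, str]]:
        out = []
        for c in CLASS_LABELS:
            out.extend((p, c) for p in self.files.get(c, []))
        return out

    def subset(self, keep: dict[str, list[Path]]) -> "DatasetManifest":
        return DatasetManifest(self.root, {c: list(keep.get(c, [])) for c in CLASS_LABELS})


def load_dataset(root: str | Path) -> DatasetManifest:
    """Scan ``<root>/<CC|DEB|UN|AT|DYN|APO>/*`` into a manifest.

    Ordering is deterministic (sorted file names).  A subdirectory that is not
    one of the six class labels is an error; a missing or empty class
    directory simply yields a zero count.
    """
    root = Path(root)
    if not root.is_dir():
        raise OSError(f"dataset root {root} is not a directory")
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if sub.name not in CLASS_LABELS:
            raise ValueError(f"unknown class directory {sub.name!r} under {root}")
    files: dict[str, list[Path]] = {}
    for c in CLASS_LABELS:
        d = root / c
        files[c] = sorted(p for p in d.glob("*") if p.is_file()) if d.is_dir() else []
    return DatasetManifest(root=root, files=files)


def load_crops(manifest: DatasetManifest) -> tuple[np.ndarray, np.ndarray]:
    """Load all manifest images as (N, 64, 64) crops plus integer labels."""
    images, labels = [], []
    for path, label in manifest.labeled_paths():
        images.append(resize_to_crop(read_gray_image(path)))
        labels.append(CLASS_INDEX[label])
    if not images:
        return np.zeros((0, CROP_SIZE, CROP_SIZE)), np.zeros(0, dtype=int)
    return np.stack(images), np.asarray(labels, dtype=int)


def to_network_range(images: np.ndarray) -> np.ndarray:
    """[0, 255] intensities -> [-1, 1] float32 network inputs (B,1,H,W)."""
    x = np.asarray(images, dtype=np.float32) / 127.5 - 1.0
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    return x


def from_network_range(x: np.ndarray) -> np.ndarray:
    """[-1, 1] network outputs -> [0, 255] intensities."""
    return np.clip((np.asarray(x, dtype=float) + 1.0) * 127.5, 0.0, 255.0)
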