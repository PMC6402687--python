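"""Seeded synthetic phase-contrast image generator.

Emulates the statistical structure the pipeline assumes — cell bodies whose
interior intensities follow one Gaussian on a substrate following another —
plus six visually distinct 64x64 class archetypes:

* ``UN``  round blob with a bright halo ring (unattached cells float and show
  a strong phase halo);
* ``AT``  homogeneous elongated blob (attached, spread cells);
* ``DYN`` blob with discrete boundary protrusions (dynamic blebs);
* ``APO`` blob with high-variance internal texture (apoptotic blebbing);
* ``CC``  central blob with several small adjacent sub-cells (a colony);
* ``DEB`` scattered small irregular fragments.

Full frames come with their exact ground-truth mask and generating Gaussian
parameters so detection tests have an oracle.  All randomness flows from a
single master seed via per-image child seeds, so datasets are reproducible
file by file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.draw import disk, ellipse

from .detection import GaussianPair
from .image_io import CLASS_LABELS, DatasetManifest, load_dataset, write_gray_image

CROP = 64

#: Default per-class crop counts of the emulated cropped-image dataset
#: (CC, DEB, UN, AT, DYN, APO) — 784 images in total.
DEFAULT_COUNTS: dict[str, int] = {
    "CC": 122, "DEB": 113, "UN": 135, "AT": 132, "DYN": 104, "APO": 178,
}


@dataclass
class FixtureSpec:
    """Generating parameters of the synthetic imagery.

    The default intensity regime (background N(90, 64), foreground
    N(180, 225)) is well separated; ``hard_preset`` narrows the gap for
    stress tests.
    """

    mu_f: float = 180.0
    var_f: float = 225.0
    mu_b: float = 90.0
    var_b: float = 64.0
    radius_range: tuple[int, int] = (8, 14)
    bleb_count: int = 4
    bleb_radius: int = 3
    halo_width: int = 3
    cluster_subcells: int = 3
    debris_fragments: int = 6


def hard_preset() -> FixtureSpec:
    return FixtureSpec(mu_f=130.0, var_f=400.0, mu_b=90.0, var_b=225.0)


def _noise_fill(shape, mu, var, rng):
    return rng.normal(mu, np.sqrt(var), size=shape)


def _render(mask: np.ndarray, spec: FixtureSpec, rng: np.random.Generator,
            fg_values: np.ndarray | None = None) -> np.ndarray:
    img = _noise_fill(mask.shape, spec.mu_b, spec.var_b, rng)
    fg = _noise_fill(mask.shape, spec.mu_f, spec.var_f, rng) if fg_values is None else fg_values
    img[mask] = fg[mask]
    return np.clip(img, 0.0, 255.0)


def _blob_mask(shape, center, radius) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def archetype_mask(label: str, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Noiseless binary morphology of one class archetype on a 64x64 canvas."""
    shape = (CROP, CROP)
    center = (CROP // 2 + rng.integers(-4, 5), CROP // 2 + rng.integers(-4, 5))
    radius = int(rng.integers(*spec.radius_range))
    if label == "UN":
        return _blob_mask(shape, center, radius)
    if label == "AT":
        m = np.zeros(shape, dtype=bool)
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(center[0], center[1], radius, max(radius // 2, 3),
                         shape=shape, rotation=angle)
        m[rr, cc] = True
        return m
    if label == "DYN" or label == "APO":
        m = _blob_mask(shape, center, radius)
        for _ in range(spec.bleb_count):
            theta = rng.uniform(0, 2 * np.pi)
            br = center[0] + radius * np.sin(theta)
            bc = center[1] + radius * np.cos(theta)
            m |= _blob_mask(shape, (br, bc), spec.bleb_radius + rng.integers(0, 2))
        return m
    if label == "CC":
        m = _blob_mask(shape, center, radius)
        for _ in range(spec.cluster_subcells):
            theta = rng.uniform(0, 2 * np.pi)
            dist = radius + spec.bleb_radius + 3
            br = np.clip(center[0] + dist * np.sin(theta), 4, CROP - 5)
            bc = np.clip(center[1] + dist * np.cos(theta), 4, CROP - 5)
            m |= _blob_mask(shape, (br, bc), spec.bleb_radius)
        return m
    if label == "DEB":
        m = np.zeros(shape, dtype=bool)
        for _ in range(spec.debris_fragments):
            c = (rng.integers(6, CROP - 6), rng.integers(6, CROP - 6))
            rr, cc = ellipse(c[0], c[1], rng.integers(2, 4), rng.integers(1, 3),
                             shape=shape, rotation=rng.uniform(0, np.pi))
            m[rr, cc] = True
        return m
    raise ValueError(f"unknown class label {label!r}")


def make_crop(label: str, spec: FixtureSpec | None = None,
              rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Render one labeled 64x64 crop (intensities in [0, 255])."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(rng)
    mask = archetype_mask(label, spec, rng)
    if label == "APO":
        # exaggerate internal texture: mottled foreground with doubled spread
        rough = replace(spec, var_f=spec.var_f * 6)
        img = _render(mask, rough, rng)
    else:
        img = _render(mask, spec, rng)
    if label == "UN":
        halo = np.zeros_like(mask)
        center = tuple(np.mean(np.nonzero(mask), axis=1))
        r_out = np.sqrt(mask.sum() / np.pi)
        rr, cc = disk(center, r_out + spec.halo_width, shape=mask.shape)
        halo[rr, cc] = True
        ring = halo & ~mask
        img[ring] = np.clip(img[ring] + 60.0, 0, 255)
    return img


def make_frame(n_cells: int, spec: FixtureSpec | None = None,
               rng: np.random.Generator | int | None = None,
               shape: tuple[int, int] = (600, 800), min_gap: int = 12,
               max_tries: int = 200) -> tuple[np.ndarray, np.ndarray, GaussianPair]:
    """Render a full frame with disk-shaped cells and return its oracle.

    Returns (frame, ground-truth mask, generating GaussianPair).  Placement
    enforces ``min_gap`` pixels between cell borders; impossible placements
    raise after bounded retries.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(rng)
    mask = np.zeros(shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_cells):
        for attempt in range(max_tries):
            radius = float(rng.integers(*spec.radius_range))
            r = rng.uniform(radius + 2, shape[0] - radius - 2)
            c = rng.uniform(radius + 2, shape[1] - radius - 2)
            ok = all(
                np.hypot(r - pr, c - pc) >= radius + prad + min_gap
                for pr, pc, prad in placed
            )
            if ok:
                placed.append((r, c, radius))
                rr, cc = disk((r, c), radius, shape=shape)
                mask[rr, cc] = True
                break
        else:
            raise RuntimeError(f"could not place cell after {max_tries} tries")
    frame = _render(mask, spec, rng)
    return frame, mask, GaussianPair(spec.mu_f, spec.var_f, spec.mu_b, spec.var_b)


def make_dataset(out_dir: str | Path, counts: dict[str, int] | None = None,
                 spec: FixtureSpec | None = None, seed: int = 0) -> DatasetManifest:
    """Write a class-per-directory crop dataset to disk and return its manifest."""
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    for ci, label in enumerate(CLASS_LABELS):
        n = counts.get(label, 0)
        if n < 0:
            raise ValueError("counts must be non-negative")
        d = out_dir / label
        d.mkdir(parents=True, exist_ok=True)
        for i in range(n):
            child = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, i)))
            img = make_crop(label, spec, child)
            write_gray_image(d / f"{label}_{i:04d}.png", img)
    return load_dataset(out_dir)


def make_arrays(counts: dict[str, int], spec: FixtureSpec | None = None,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """In-memory equivalent of :func:`make_dataset`: (N,64,64) crops + labels."""
    spec = spec or FixtureSpec()
    images, labels = [], []
    for ci, label in enumerate(CLASS_LABELS):
        for i in range(counts.get(label, 0)):
            child = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, i)))
            images.append(make_crop(label, spec, child))
            labels.append(ci)
    if not images:
        return np.zeros((0, CROP, CROP)), np.zeros(0, dtype=int)
    return np.stack(images), np.asarray(labels, dtype=int)
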