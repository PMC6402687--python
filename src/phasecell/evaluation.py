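"""Image-quality metrics and the significance test for synthetic-image studies.

SSIM here is the single *global-statistics* form — one mean/variance/covariance
over the whole image, no sliding window — with the usual stabilizers
C1 = (K1 L)^2, C2 = (K2 L)^2 on the 8-bit scale (L = 255).  PSNR is
10 log10(L^2 / MSE) in decibels.  Quality reports average each synthetic image
against every real image of its class, then average over the synthetic set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_io import CLASS_LABELS, DatasetManifest, read_gray_image, resize_to_crop


@dataclass
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0
    #: use sample (n-1) variance/covariance; population (n) form when False
    sample_stats: bool = True

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


def ssim_global(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Global structural-similarity statistic between two equally shaped images."""
    params = params or SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("images must be non-empty and equally shaped")
    x, y = x.ravel(), y.ravel()
    ddof = 1 if params.sample_stats else 0
    if x.size <= ddof:
        raise ValueError("image too small for the requested statistics")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    cxy = ((x - mx) * (y - my)).sum() / (x.size - ddof)
    c1, c2 = params.C1, params.C2
    return float(
        (2 * mx * my + c1) * (2 * cxy + c2) / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
    )


def psnr(x: np.ndarray, y: np.ndarray, L: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must have equal shapes")
    mse = float(((x - y) ** 2).mean())
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(L ** 2 / mse))


def quality_report(
    synthetic: DatasetManifest,
    real: DatasetManifest,
    params: SSIMParams | None = None,
) -> dict[str, dict[str, float]]:
    """Per-class mean SSIM/PSNR of a synthetic set against a real set.

    For each synthetic image the SSIM and PSNR against *all* real images of its
    class are averaged; those per-image means are then averaged over the
    synthetic set.  Classes without real references are skipped.
    """
    report: dict[str, dict[str, float]] = {}
    for c in CLASS_LABELS:
        syn_paths = synthetic.files.get(c, [])
        real_paths = real.files.get(c, [])
        if not syn_paths:
            continue
        if not real_paths:
            import warnings

            warnings.warn(f"class {c}: no real reference images, skipped", stacklevel=2)
            continue
        refs = [resize_to_crop(read_gray_image(p)) for p in real_paths]
        ssims, psnrs = [], []
        for sp in syn_paths:
            img = resize_to_crop(read_gray_image(sp))
            ssims.append(np.mean([ssim_global(img, r, params) for r in refs]))
            psnrs.append(np.mean([psnr(img, r) for r in refs]))
        report[c] = {"ssim": float(np.mean(ssims)), "psnr": float(np.mean(psnrs))}
    return report


def one_way_anova(group_a, group_b) -> tuple[float, float]:
    """One-way ANOVA between two groups: F statistic and p-value.

    p comes from the F distribution with (1, nA + nB - 2) degrees of freedom.
    If every value in both groups is identical the decomposition is degenerate
    and (F, p) = (0, 1) is returned.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
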