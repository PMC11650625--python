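"""Image-quality metrics against a radius-profiled gold-standard morphology.

The foreground mask is the rasterized neuronal volume: a sphere at every SWC
node plus conical frusta along parent-child edges (radius linearly
interpolated).  The background is the 2-fold-enlarged mask (all radii scaled
about the centerline) minus the foreground — a shell hugging the neuron, so
the background statistics probe exactly the voxels a tracer must tell apart
from signal.

Metrics (all guarded against zero division):

* SBC, signal-background contrast: ``median(fg) / (median(bg) + 1)``.
* Background uniformity: z-normalize the whole image, histogram the
  background z-scores into ``bins`` equal-width bins, return ``sum(p_i^2)``
  over the bin fractions — 1 iff all background mass sits in one bin.
* Foreground relative standard deviation: ``std(fg) / (median(fg) + 1)``
  (population std); its increase flags signal loss / heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import SWCMorphology, Volume3D

__all__ = [
    "RegionMasks",
    "QualityReport",
    "rasterize_masks",
    "sbc",
    "background_uniformity",
    "foreground_rsd",
    "quality_report",
]


@dataclass
class RegionMasks:
    foreground: np.ndarray  # bool (z, y, x)
    background: np.ndarray  # bool, disjoint from foreground
    enlargement_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.foreground.shape != self.background.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.foreground & self.background):
            raise ValueError("foreground and background masks overlap")


@dataclass
class QualityReport:
    sbc: float
    bg_uniformity: float
    fg_rsd: float
    n_fg_voxels: int
    n_bg_voxels: int
    bins: int = 256


def _paint_mask(morph: SWCMorphology, shape: tuple[int, int, int], scale: float) -> np.ndarray:
    """Voxels within the (radius-scaled) tube/sphere union, centers at integer grids."""
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)

    def ball(cx: float, cy: float, cz: float, r: float) -> None:
        r = max(r, 0.5) * scale
        z0, z1 = max(int(np.floor(cz - r)), 0), min(int(np.ceil(cz + r)), nz - 1)
        y0, y1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)), ny - 1)
        x0, x1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)), nx - 1)
        if z0 > z1 or y0 > y1 or x0 > x1:
            return
        zz, yy, xx = np.ogrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        mask[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] |= d2 <= r * r

    def frustum(a, b, ra: float, rb: float) -> None:
        ra, rb = max(ra, 0.5) * scale, max(rb, 0.5) * scale
        rmax = max(ra, rb)
        lo = np.floor(np.minimum(a, b) - rmax).astype(int)
        hi = np.ceil(np.maximum(a, b) + rmax).astype(int)
        (x0, y0, z0) = np.maximum(lo, 0)
        (x1, y1, z1) = np.minimum(hi, [nx - 1, ny - 1, nz - 1])
        if x0 > x1 or y0 > y1 or z0 > z1:
            return
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1 + 1), np.arange(y0, y1 + 1), np.arange(x0, x1 + 1), indexing="ij"
        )
        p = np.stack([xx, yy, zz], axis=-1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            return
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((p - closest) ** 2, axis=-1)
        r_t = ra + t * (rb - ra)
        mask[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] |= d2 <= r_t * r_t

    for n in morph.nodes:
        ball(n.x, n.y, n.z, n.radius)
    for parent, child in morph.edges():
        frustum(parent.xyz, child.xyz, parent.radius, child.radius)
    return mask


def rasterize_masks(
    morph: SWCMorphology, shape: tuple[int, int, int], enlargement: float = 2.0
) -> RegionMasks:
    """Foreground and background masks from a radius-profiled morphology.

    Foreground: union of node spheres and edge frusta at the annotated radii
    (zero radii promoted to 0.5 voxel).  Background: same construction with
    radii scaled by ``enlargement``, minus the foreground.
    """
    if not morph.nodes:
        raise ValueError("empty morphology")
    fg = _paint_mask(morph, shape, 1.0)
    if not fg.any():
        raise ValueError("morphology lies entirely outside the volume")
    enlarged = _paint_mask(morph, shape, enlargement) if enlargement != 1.0 else fg
    return RegionMasks(fg, enlarged & ~fg, enlargement)


def sbc(fg_values: np.ndarray, bg_values: np.ndarray) -> float:
    """Signal-background contrast: ``median(fg) / (median(bg) + 1)``."""
    fg_values, bg_values = np.asarray(fg_values), np.asarray(bg_values)
    if fg_values.size == 0:
        raise ValueError("empty foreground region")
    if bg_values.size == 0:
        raise ValueError("empty background region")
    return float(np.median(fg_values) / (np.median(bg_values) + 1.0))


def background_uniformity(bg_values: np.ndarray, whole_image: np.ndarray, bins: int = 256) -> float:
    """Uniformity ``sum(p_i^2)`` of the background z-score histogram.

    The whole image is z-normalized first (population std); the histogram
    spans the observed [min, max] of the background z-scores with ``bins``
    equal-width bins, count-normalized.  A constant background (degenerate
    range) scores 1.
    """
    img = np.asarray(whole_image, dtype=np.float64)
    std = img.std()
    if std == 0:
        raise ValueError("zero variance: cannot z-normalize a constant image")
    bg = (np.asarray(bg_values, dtype=np.float64) - img.mean()) / std
    if bg.size == 0:
        raise ValueError("empty background region")
    lo, hi = float(bg.min()), float(bg.max())
    if lo == hi:
        return 1.0
    counts, _ = np.histogram(bg, bins=bins, range=(lo, hi))
    p = counts / bg.size
    return float(np.sum(p**2))


def foreground_rsd(fg_values: np.ndarray) -> float:
    """Relative standard deviation of the foreground:
    ``std(fg) / (median(fg) + 1)`` with population std."""
    fg = np.asarray(fg_values, dtype=np.float64)
    if fg.size == 0:
        raise ValueError("empty foreground region")
    return float(fg.std() / (np.median(fg) + 1.0))


def quality_report(
    vol: Volume3D, morph: SWCMorphology, enlargement: float = 2.0, bins: int = 256
) -> QualityReport:
    """SBC, background uniformity and foreground RSD for one (image, gold) pair."""
    masks = rasterize_masks(morph, vol.shape, enlargement)
    fg = vol.data[masks.foreground]
    bg = vol.data[masks.background]
    return QualityReport(
        sbc=sbc(fg, bg),
        bg_uniformity=background_uniformity(bg, vol.data, bins=bins),
        fg_rsd=foreground_rsd(fg),
        n_fg_voxels=int(fg.size),
        n_bg_voxels=int(bg.size),
        bins=bins,
    )
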