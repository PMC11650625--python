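"""Instance-aware intensity shifting and the 16→8-bit downgrade.

After high-pass filtering the stack is still spread over a wide dynamic range
and a naive bit-depth downgrade would drop faint neurites.  This stage picks
a narrow window [lower, upper], clips and linearly rescales into it:

* ``lower`` is the quantile that keeps only the brightest ``keep_fraction``
  of voxels (default 1%), clearing most of the background volume — neurites
  are sparse.
* ``upper`` is the lesser of ``lower + 255`` and half the peak intensity of
  the soma region (a soma-centered block, default 128 × 128 × 32 voxels in
  XYZ), so that very weak neurons are amplified.  This instance-aware rule
  can be switched off, in which case ``upper = lower + 255``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_io import Volume3D

__all__ = ["IntensityBounds", "compute_bounds", "shift_to_8bit"]

#: default soma-region block shape in (z, y, x) voxels
DEFAULT_SOMA_BLOCK = (32, 128, 128)


@dataclass(frozen=True)
class IntensityBounds:
    """The rescaling window and how it was obtained."""

    lower: float
    upper: float
    soma_peak: float
    method: str  # "instance_aware" | "fixed_span"
    fallback: bool = False  # instance-aware upper collapsed onto lower

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(f"upper ({self.upper}) must exceed lower ({self.lower})")


def compute_bounds(
    vol: Volume3D,
    keep_fraction: float = 0.01,
    soma_center: tuple[int, int, int] | None = None,
    soma_block: tuple[int, int, int] = DEFAULT_SOMA_BLOCK,
    instance_aware: bool = True,
) -> IntensityBounds:
    """Choose the clip-rescale window for the 8-bit downgrade.

    ``lower`` is the (1 - keep_fraction) quantile of all voxel intensities
    (zeros included).  ``soma_center`` defaults to the volume center, since
    the input blocks are soma-centered; the block is clipped to the volume
    extent.  If the instance-aware upper bound does not exceed ``lower`` the
    fixed span ``lower + 255`` is used and the fallback recorded.
    """
    if not 0.0 < keep_fraction < 0.5:
        raise ValueError(f"keep_fraction must lie in (0, 0.5), got {keep_fraction}")
    data = np.asarray(vol.data)
    if data.size == 0:
        raise ValueError("empty volume")
    lower = float(np.quantile(data, 1.0 - keep_fraction))

    if soma_center is None:
        soma_center = tuple(s // 2 for s in data.shape)  # type: ignore[assignment]
    slices = []
    for c, half, extent in zip(soma_center, soma_block, data.shape):
        lo = max(int(c) - half // 2, 0)
        hi = min(int(c) + (half + 1) // 2, extent)
        slices.append(slice(lo, max(hi, lo + 1)))
    soma_peak = float(data[tuple(slices)].max())

    if instance_aware:
        upper = min(lower + 255.0, 0.5 * soma_peak)
        if upper <= lower:
            return IntensityBounds(lower, lower + 255.0, soma_peak, "instance_aware", fallback=True)
        return IntensityBounds(lower, upper, soma_peak, "instance_aware")
    return IntensityBounds(lower, lower + 255.0, soma_peak, "fixed_span")


def shift_to_8bit(vol: Volume3D, bounds: IntensityBounds) -> Volume3D:
    """Clip to [lower, upper], rescale linearly to [0, 255] and quantize.

    ``out = round(255 * clamp((v - lower) / (upper - lower), 0, 1))`` with
    round-half-away-from-zero, fixed across platforms so outputs are
    bit-reproducible.  Monotone non-decreasing in the input intensity.
    """
    v = np.asarray(vol.data, dtype=np.float64)
    scaled = np.clip((v - bounds.lower) / (bounds.upper - bounds.lower), 0.0, 1.0)
    # floor(x + 0.5) == round-half-away-from-zero for non-negative x
    out = np.floor(255.0 * scaled + 0.5).astype(np.uint8)
    return replace(vol, data=out, dtype_bits=8)
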