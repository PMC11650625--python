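"""Synthetic phantoms and forward degradation models.

Generates soma-centered blocks that mimic sparsely labeled neurons in
block-face whole-brain microscopy: a bright soma blob with a handful of
tubular neurites (persistent random walks with tapering radii) on a dark
background, together with the matching gold-standard SWC morphology.  The
degradations mirror the noise classes the enhancement pipeline targets:

* an axial flare — the forward run of the diffusion model the filter
  inverts, each section leaking a growing Gaussian blur into later sections;
* separable low-frequency background ``f(y, z) + g(x, z)`` with optional
  step edges (mosaic seams, stripes, uneven illumination);
* a baseline offset plus additive Gaussian sensor noise, quantized to the
  16-bit acquisition depth.

Everything is bitwise-deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import zoom

from .highpass import gaussian_blur_2d
from .volume_io import FLOAT_BITS, SWCMorphology, SWCNode, Volume3D

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "apply_flare_forward",
    "add_separable_background",
    "add_noise",
    "perturb_morphology",
    "degrade",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic soma-centered block.

    Defaults model a sparse 16-bit block at sub-micrometer lateral
    resolution: foreground tubes near 2000 counts over a ~300-count baseline
    with 30-count sensor noise, mosaic/stripe fields of comparable amplitude,
    and a 1 px/slice flare diffusion speed.
    """

    shape: tuple[int, int, int] = (64, 256, 256)  # (z, y, x)
    n_neurites: int = 5
    neurite_steps: int = 300
    radius_range: tuple[float, float] = (1.0, 2.5)
    soma_radius: float = 6.0
    fg_intensity: float = 2000.0
    flare_speed: float = 1.0
    separable_amp: float = 300.0
    noise_sigma: float = 30.0
    bg_offset: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8 or self.shape[1] < 32 or self.shape[2] < 32:
            raise ValueError(f"shape must be at least (8, 32, 32), got {self.shape}")
        for name in ("fg_intensity", "separable_amp", "noise_sigma", "bg_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _paint_gaussian_ball(vol: np.ndarray, center_xyz: np.ndarray, radius: float, peak: float) -> None:
    """Max-combine a radially Gaussian blob (sigma = radius/2) into ``vol``."""
    nz, ny, nx = vol.shape
    cx, cy, cz = center_xyz
    ext = 2.0 * radius
    z0, z1 = max(int(np.floor(cz - ext)), 0), min(int(np.ceil(cz + ext)), nz - 1)
    y0, y1 = max(int(np.floor(cy - ext)), 0), min(int(np.ceil(cy + ext)), ny - 1)
    x0, x1 = max(int(np.floor(cx - ext)), 0), min(int(np.ceil(cx + ext)), nx - 1)
    if z0 > z1 or y0 > y1 or x0 > x1:
        return
    zz, yy, xx = np.ogrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    sigma = radius / 2.0
    blob = peak * np.exp(-d2 / (2.0 * sigma**2))
    region = vol[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
    np.maximum(region, blob, out=region)


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, SWCMorphology]:
    """Clean phantom volume plus its gold-standard morphology.

    Neurites are persistent random walks of unit steps launched from the
    soma surface, reflected at a small boundary margin, with radius tapering
    linearly from ``radius_range[1]`` at the soma to ``radius_range[0]`` at
    the tip.  Tube intensity is ``fg_intensity`` with Gaussian radial falloff
    (sigma = radius/2), max-combined so crossings do not add.  Gold nodes are
    laid every other step; radii in voxel units.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    vol = np.zeros(spec.shape, dtype=np.float32)
    center = np.array([nx / 2.0, ny / 2.0, nz / 2.0])  # (x, y, z)

    _paint_gaussian_ball(vol, center, spec.soma_radius, spec.fg_intensity)
    nodes = [SWCNode(1, 1, *center, spec.soma_radius, -1)]
    next_id = 2
    extent = np.array([nx, ny, nz], dtype=float)
    margin = spec.radius_range[1] + 2.0
    r_hi, r_lo = spec.radius_range[1], spec.radius_range[0]

    for _ in range(spec.n_neurites):
        direction = rng.standard_normal(3)
        direction[2] *= 0.5  # neurites wander less along the sectioning axis
        direction /= np.linalg.norm(direction)
        pos = center + direction * spec.soma_radius
        parent_id = 1
        for step in range(spec.neurite_steps):
            direction = direction + 0.25 * rng.standard_normal(3) * np.array([1.0, 1.0, 0.5])
            direction /= np.linalg.norm(direction)
            nxt = pos + direction
            for ax in range(3):
                if nxt[ax] < margin or nxt[ax] > extent[ax] - margin:
                    direction[ax] = -direction[ax]
            pos = pos + direction
            pos = np.clip(pos, margin, extent - margin)
            t = step / max(spec.neurite_steps - 1, 1)
            radius = r_hi + t * (r_lo - r_hi)
            _paint_gaussian_ball(vol, pos, radius, spec.fg_intensity)
            if step % 2 == 0 or step == spec.neurite_steps - 1:
                nodes.append(SWCNode(next_id, 3, pos[0], pos[1], pos[2], radius, parent_id))
                parent_id = next_id
                next_id += 1

    clean = Volume3D(vol, dtype_bits=FLOAT_BITS)
    gold = SWCMorphology(nodes, provenance=f"make_phantom(seed={spec.seed})")
    return clean, gold


def apply_flare_forward(clean: Volume3D, s: float, kernel_truncate: float = 4.0) -> Volume3D:
    """Forward flare degradation: each section leaks into the next.

    ``out_n = clean_n + noise_n`` with ``noise_1 = 0`` and
    ``noise_n = G_s * (clean_{n-1} + noise_{n-1})`` — the recursion the
    diffusion filter is built to undo, sharing its blur primitive.
    """
    if s <= 0:
        raise ValueError("diffusion speed must be positive")
    data = clean.data
    out = np.empty(data.shape, dtype=np.float32)
    out[0] = data[0]
    noise = np.zeros(data.shape[1:], dtype=np.float64)
    for n in range(1, data.shape[0]):
        noise = gaussian_blur_2d(data[n - 1].astype(np.float64) + noise, s, kernel_truncate)
        out[n] = data[n] + noise
    return replace(clean, data=out, dtype_bits=FLOAT_BITS)


def add_separable_background(vol: Volume3D, amp: float, seed: int = 0) -> Volume3D:
    """Add a separable field ``f(y, z) + g(x, z)``: smooth low-frequency
    random components plus one step edge each, mimicking mosaic seams."""
    if amp < 0:
        raise ValueError("amplitude must be non-negative")
    data = vol.data.astype(np.float32)
    if amp == 0:
        return replace(vol, data=data, dtype_bits=FLOAT_BITS)
    rng = np.random.default_rng(seed)
    nz, ny, nx = data.shape

    def smooth_field(n_rows: int, n_cols: int) -> np.ndarray:
        coarse = rng.random((max(nz // 16, 2) + 1, max(n_cols // 32, 2) + 1))
        field = zoom(coarse, (n_rows / coarse.shape[0], n_cols / coarse.shape[1]), order=3)
        field = field[:n_rows, :n_cols]
        span = field.max() - field.min()
        return (field - field.min()) / span if span > 0 else field * 0.0

    f = 0.5 * amp * smooth_field(nz, ny)  # (z, y)
    g = 0.5 * amp * smooth_field(nz, nx)  # (z, x)
    # mosaic-boundary step edges at random lateral positions
    f[:, rng.integers(ny // 4, 3 * ny // 4) :] += 0.25 * amp
    g[:, rng.integers(nx // 4, 3 * nx // 4) :] += 0.25 * amp
    # float64 so the field stays exactly separable (the orthogonal filter
    # annihilates it to numerical precision)
    out = data.astype(np.float64) + f[:, :, None] + g[:, None, :]
    return replace(vol, data=out, dtype_bits=FLOAT_BITS)


def add_noise(vol: Volume3D, sigma: float, offset: float = 0.0, seed: int = 0) -> Volume3D:
    """Baseline offset plus Gaussian sensor noise, quantized to 16-bit."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    data = vol.data.astype(np.float64) + offset
    if sigma > 0:
        data = data + rng.normal(0.0, sigma, size=data.shape)
    data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    return replace(vol, data=data, dtype_bits=16)


def degrade(clean: Volume3D, spec: PhantomSpec) -> Volume3D:
    """Full forward model: flare, separable background, offset + noise."""
    out = apply_flare_forward(clean, spec.flare_speed)
    out = add_separable_background(out, spec.separable_amp, seed=spec.seed + 1)
    return add_noise(out, spec.noise_sigma, spec.bg_offset, seed=spec.seed + 2)


def perturb_morphology(
    gold: SWCMorphology, fraction: float, displacement: float, seed: int = 0
) -> SWCMorphology:
    """Rigidly displace a contiguous ``fraction`` of the cable length.

    Walking up from the deepest leaves, whole edges are claimed until the
    length quota is met; the final edge is split exactly at the quota, so the
    displaced cable length is ``fraction * total`` to float precision.  The
    displaced piece is detached (it gets its own root) and shifted by a
    random direction of magnitude ``displacement``; cable length is
    conserved.  Fixtures built this way have known expected deviation
    fractions for the reconstruction-scoring metrics.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0 or displacement == 0.0:
        return SWCMorphology(list(gold.nodes), provenance=gold.provenance + "|perturb(0)")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    disp = direction * displacement

    by_id = {n.id: n for n in gold.nodes}
    children: dict[int, list[int]] = {n.id: [] for n in gold.nodes}
    for n in gold.nodes:
        if n.parent != -1:
            children[n.parent].append(n.id)
    total = gold.total_length()
    quota = fraction * total

    def depth(nid: int) -> float:
        d = 0.0
        n = by_id[nid]
        while n.parent != -1:
            p = by_id[n.parent]
            d += float(np.linalg.norm(n.xyz - p.xyz))
            n = p
        return d

    leaves = sorted((nid for nid, ch in children.items() if not ch), key=depth, reverse=True)
    displaced: set[int] = set()
    # cut -> (kept parent id, cut point, radius) for mid-edge splits
    splits: list[tuple[int, int, np.ndarray, float]] = []  # (child id, parent id, q, r)
    remaining = quota
    for leaf in leaves:
        if remaining <= 1e-9:
            break
        nid = leaf
        while remaining > 1e-9:
            node = by_id[nid]
            if node.parent == -1:
                displaced.add(nid)
                break
            if nid in displaced:
                break
            parent = by_id[node.parent]
            length = float(np.linalg.norm(node.xyz - parent.xyz))
            if length <= remaining + 1e-9:
                displaced.add(nid)
                remaining -= length
                nid = parent.id
            else:
                q = node.xyz + (parent.xyz - node.xyz) * (remaining / length)
                r = node.radius + (parent.radius - node.radius) * (remaining / length)
                splits.append((nid, parent.id, q, r))
                displaced.add(nid)
                remaining = 0.0

    next_id = max(by_id) + 1
    out: list[SWCNode] = []
    extra: list[SWCNode] = []
    new_parent: dict[int, int] = {}

    for child_id, parent_id, q, r in splits:
        kept = SWCNode(next_id, by_id[child_id].type_code, q[0], q[1], q[2], r, parent_id)
        moved = SWCNode(next_id + 1, by_id[child_id].type_code,
                        q[0] + disp[0], q[1] + disp[1], q[2] + disp[2], r, -1)
        extra.extend([kept, moved])
        new_parent[child_id] = moved.id
        next_id += 2

    for n in gold.nodes:
        parent = new_parent.get(n.id, n.parent)
        if n.id in displaced:
            if parent != -1 and parent not in displaced and n.id not in new_parent:
                # whole-edge cut at a kept node: anchor at its displaced image
                p = by_id[parent]
                anchor = SWCNode(next_id, p.type_code,
                                 p.x + disp[0], p.y + disp[1], p.z + disp[2], p.radius, -1)
                extra.append(anchor)
                parent = anchor.id
                next_id += 1
            out.append(SWCNode(n.id, n.type_code, n.x + disp[0], n.y + disp[1],
                               n.z + disp[2], n.radius, parent))
        else:
            if parent != -1 and parent in displaced:
                # kept subtree hanging off a displaced node: re-root a copy in place
                p = by_id[parent]
                root = SWCNode(next_id, p.type_code, p.x, p.y, p.z, p.radius, -1)
                extra.append(root)
                parent = root.id
                next_id += 1
            out.append(SWCNode(n.id, n.type_code, n.x, n.y, n.z, n.radius, parent))

    return SWCMorphology(
        out + extra,
        provenance=gold.provenance + f"|perturb(fraction={fraction}, d={displacement}, seed={seed})",
    )
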