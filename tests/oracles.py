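"""Independent brute-force oracles the test suite checks the package against.

These deliberately re-derive results by the most literal route available —
explicit sums, all-pairs distances, triple loops — and never call into the
code paths they validate.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist


def blur_n_times(slice2d: np.ndarray, sigma: float, times: int, truncate: float = 4.0) -> np.ndarray:
    """``times`` successive Gaussian blurs of std ``sigma`` (reflect padding)."""
    out = np.asarray(slice2d, dtype=np.float64)
    for _ in range(times):
        out = gaussian_filter(out, sigma=sigma, mode="reflect", truncate=truncate)
    return out


def explicit_sum_diffusion(raw: np.ndarray, s: float, k: float, truncate: float = 4.0) -> np.ndarray:
    """Slice-recursive flare removal evaluated as the literal explicit sum.

    The noise estimate for slice n is the sum over all previous restored
    slices i of res_i blurred (n - i) successive times with std s — no
    two-slice recursion, no composed kernels.
    """
    raw = np.asarray(raw, dtype=np.float64)
    res = [np.clip(raw[0], 0, None)]
    for n in range(1, raw.shape[0]):
        noise = np.zeros(raw.shape[1:], dtype=np.float64)
        for i in range(n):
            noise += blur_n_times(res[i], s, n - i, truncate)
        m = noise.mean()
        alpha = k * raw[n].mean() / m if m > 0 else 0.0
        res.append(np.clip(raw[n] - alpha * noise, 0, None))
    return np.stack(res)


def explicit_sum_flare_noise(clean: np.ndarray, s: float, n: int, truncate: float = 4.0) -> np.ndarray:
    """Forward flare noise for slice ``n``: sum of clean_i blurred (n - i) times."""
    clean = np.asarray(clean, dtype=np.float64)
    noise = np.zeros(clean.shape[1:], dtype=np.float64)
    for i in range(n):
        noise += blur_n_times(clean[i], s, n - i, truncate)
    return noise


def brute_force_tube_mask(morph, shape: tuple[int, int, int], scale: float = 1.0) -> np.ndarray:
    """Triple-loop rasterization: voxel in mask iff within the interpolated
    radius of some node sphere or edge segment."""
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    nodes = list(morph.nodes)
    by_id = {n.id: n for n in nodes}
    segs = []
    for n in nodes:
        segs.append((n.xyz, n.xyz, max(n.radius, 0.5) * scale, max(n.radius, 0.5) * scale))
        if n.parent != -1:
            p = by_id[n.parent]
            segs.append((p.xyz, n.xyz, max(p.radius, 0.5) * scale, max(n.radius, 0.5) * scale))
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                pt = np.array([x, y, z], dtype=float)
                for a, b, ra, rb in segs:
                    ab = b - a
                    d2ab = float(ab @ ab)
                    t = 0.0 if d2ab == 0 else float(np.clip((pt - a) @ ab / d2ab, 0, 1))
                    r = ra + t * (rb - ra)
                    if np.sum((pt - (a + t * ab)) ** 2) <= r * r:
                        mask[z, y, x] = True
                        break
    return mask


def brute_force_pds(points_m: np.ndarray, weights_m: np.ndarray, points_ref: np.ndarray,
                    thr: float) -> float:
    """All-pairs distance PDS on already-resampled point sets."""
    d = cdist(points_m, points_ref).min(axis=1)
    return float(weights_m[d > thr].sum() / weights_m.sum())


def histogram_uniformity(values: np.ndarray, whole: np.ndarray, bins: int) -> float:
    """Background-uniformity recomputation via sorting and searchsorted."""
    whole = np.asarray(whole, dtype=np.float64)
    z = (np.asarray(values, dtype=np.float64) - whole.mean()) / whole.std()
    lo, hi = z.min(), z.max()
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    p = counts / z.size
    return float((p**2).sum())
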