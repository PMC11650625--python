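"""3D image stacks, SWC neuron morphologies, and their file formats.

Shared conventions for the whole package:

* Volumes are indexed ``(z, y, x)`` — ``data[k]`` is the k-th optical/physical
  section.  Z is the sectioning axis along which the flare artifact of
  block-face microscopy extends; microscope vendors usually quote shapes in
  XYZ order, the conversion happens here at the I/O boundary.
* SWC coordinates and radii are in voxel units (0-based, voxel-center) of the
  stack they annotate.  Anisotropy (e.g. 0.2–0.35 μm lateral vs 1 μm axial) is
  carried as metadata only; morphology distances are taken in voxel units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "Volume3D",
    "SWCNode",
    "SWCMorphology",
    "read_stack",
    "write_stack",
    "read_swc",
    "write_swc",
]

#: dtype_bits value used for floating-point volumes.
FLOAT_BITS = "float"

_DTYPE_FOR_BITS = {8: np.uint8, 16: np.uint16}


@dataclass
class Volume3D:
    """A 3D grayscale stack with bit depth and voxel-size metadata.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.
    dtype_bits
        ``8`` or ``16`` for unsigned integer stacks, ``"float"`` for
        intermediate floating-point results.
    voxel_size
        Physical voxel size ``(z_um, y_um, x_um)``.  Defaults to
        ``(1.0, lateral_res_um, lateral_res_um)``.
    lateral_res_um
        Micrometers per pixel in X/Y; drives the diffusion-speed default.
    """

    data: np.ndarray
    dtype_bits: int | str = 16
    lateral_res_um: float = 0.25
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must have exactly 3 axes (z, y, x), got {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        if self.voxel_size is None:
            self.voxel_size = (1.0, self.lateral_res_um, self.lateral_res_um)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size entries must be positive, got {self.voxel_size}")
        if self.dtype_bits in _DTYPE_FOR_BITS:
            lo, hi = 0, 2 ** int(self.dtype_bits) - 1
            if self.data.size and (self.data.min() < lo or self.data.max() > hi):
                raise ValueError(
                    f"values outside the declared {self.dtype_bits}-bit range "
                    f"[{lo}, {hi}]"
                )
        elif self.dtype_bits != FLOAT_BITS:
            raise ValueError(f"dtype_bits must be 8, 16 or 'float', got {self.dtype_bits!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_float(self) -> "Volume3D":
        """Return a float32 view-copy of this volume (``dtype_bits='float'``)."""
        return replace(self, data=self.data.astype(np.float32), dtype_bits=FLOAT_BITS)

    def quantize(self, bits: int) -> "Volume3D":
        """Round, clamp to the target bit range and cast to ``bits``-bit unsigned."""
        if bits not in _DTYPE_FOR_BITS:
            raise ValueError("bits must be 8 or 16")
        hi = 2**bits - 1
        data = np.clip(np.rint(np.asarray(self.data, dtype=np.float64)), 0, hi)
        return replace(self, data=data.astype(_DTYPE_FOR_BITS[bits]), dtype_bits=bits)


@dataclass(frozen=True)
class SWCNode:
    """One sample of a neuron reconstruction (standard 7-column SWC row)."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for a root

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SWCMorphology:
    """An ordered collection of SWC nodes forming one or more trees."""

    nodes: list[SWCNode] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids in morphology")
        id_set = set(ids)
        for n in self.nodes:
            if n.parent != -1 and n.parent not in id_set:
                raise ValueError(f"node {n.id} references missing parent {n.parent}")
            if n.radius < 0:
                raise ValueError(f"node {n.id} has negative radius")
        if self.nodes and not any(n.parent == -1 for n in self.nodes):
            raise ValueError("non-empty morphology has no root node")

    def __len__(self) -> int:
        return len(self.nodes)

    def node_by_id(self) -> dict[int, SWCNode]:
        return {n.id: n for n in self.nodes}

    def edges(self) -> list[tuple[SWCNode, SWCNode]]:
        """(parent, child) pairs for every non-root node."""
        by_id = self.node_by_id()
        return [(by_id[n.parent], n) for n in self.nodes if n.parent != -1]

    def coordinates(self) -> np.ndarray:
        """Node coordinates as an (N, 3) array in (x, y, z) order."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float).reshape(-1, 3)

    def total_length(self) -> float:
        """Total cable length (sum of parent-child edge lengths, voxel units)."""
        return float(
            sum(np.linalg.norm(p.xyz - c.xyz) for p, c in self.edges())
        )


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | os.PathLike,
    lateral_res_um: float = 0.25,
    voxel_size: tuple[float, float, float] | None = None,
) -> Volume3D:
    """Read a multi-page grayscale TIFF as a ``(z, y, x)`` volume.

    The page index maps to Z.  Voxel size is taken from the arguments, never
    from TIFF metadata (which is unreliable in practice).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page shapes in {path}: {sorted(shapes)}")
        spp = {getattr(p, "samplesperpixel", 1) for p in pages}
        if spp != {1}:
            raise ValueError(
                f"unsupported sample format in {path}: {max(spp)} samples per pixel, "
                "expected single-channel grayscale"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported sample format in {path}: expected single-channel "
            f"grayscale pages, got array of shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        bits = 8
    elif arr.dtype == np.uint16:
        bits = 16
    else:
        raise ValueError(
            f"unsupported sample format in {path}: dtype {arr.dtype}, "
            "expected 8- or 16-bit unsigned grayscale"
        )
    return Volume3D(arr, dtype_bits=bits, lateral_res_um=lateral_res_um, voxel_size=voxel_size)


def write_stack(vol: Volume3D, path: str | os.PathLike, compress: bool = False) -> None:
    """Write a volume as a lossless multi-page TIFF (page per Z-slice)."""
    if vol.dtype_bits not in _DTYPE_FOR_BITS:
        raise ValueError(
            "cannot write a float volume; convert explicitly first "
            "(e.g. Volume3D.quantize(8) or .quantize(16))"
        )
    data = vol.data.astype(_DTYPE_FOR_BITS[vol.dtype_bits], copy=False)
    compression = "zlib" if compress else None
    tifffile.imwrite(path, data, photometric="minisblack", compression=compression)


# ---------------------------------------------------------------------------
# SWC morphologies


def read_swc(path: str | os.PathLike) -> SWCMorphology:
    """Parse a whitespace-delimited 7-column SWC file.

    ``#`` comment lines and blank lines are ignored.  Duplicate ids and
    references to missing parents fail with the offending line number.
    """
    nodes: list[SWCNode] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                tc = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable SWC row: {exc}") from None
            if nid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate node id {nid}")
            seen.add(nid)
            nodes.append(SWCNode(nid, tc, x, y, z, r, parent))
    for i, n in enumerate(nodes):
        if n.parent != -1 and n.parent not in seen:
            raise ValueError(f"{path}: node {n.id} references missing parent {n.parent}")
    return SWCMorphology(nodes, provenance=str(path))


def write_swc(morph: SWCMorphology, path: str | os.PathLike) -> None:
    """Write a morphology as standard 7-column SWC text."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in morph.nodes:
            fh.write(f"{n.id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} {n.radius:.6g} {n.parent}\n")
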