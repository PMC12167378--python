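"""3D volume container and elementary stack operations.

Volumes are grayscale intensity z-stacks stored as ``(x, y, z)`` arrays with
voxel-size metadata in micrometres.  TIFF is the interchange format: one page
per z-plane, so the page index is the z coordinate.  All coordinates are
0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml

__all__ = [
    "VolumeStack",
    "PatchSpec",
    "read_volume",
    "write_volume",
    "percentile_normalize",
    "truncate_negative",
    "bin_volume",
    "extract_random_patches",
    "tile_nonoverlapping",
    "augment",
    "load_manifest",
    "save_manifest",
]


@dataclass
class VolumeStack:
    """A 3D grayscale intensity volume.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Real-valued intensities, axis order (x, y, z) with z the optical
        section index.
    voxel_size : tuple of float
        Physical voxel extents (x, y, z) in micrometres.
    name : str
        Free-text label (typically the protein name).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating) and not np.issubdtype(
            self.data.dtype, np.integer
        ):
            raise TypeError(f"intensities must be real, got dtype {self.data.dtype}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size components must be positive, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype_float(self) -> "VolumeStack":
        if np.issubdtype(self.data.dtype, np.floating):
            return self
        return replace(self, data=self.data.astype(np.float32))

    def copy(self) -> "VolumeStack":
        return replace(self, data=self.data.copy())


@dataclass
class PatchSpec:
    """Random-crop specification: 2D ``(nx, ny)`` or 3D ``(nx, ny, nz)``."""

    size: tuple[int, ...]
    count: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.size = tuple(int(s) for s in self.size)
        if len(self.size) not in (2, 3):
            raise ValueError("size must be (nx, ny) or (nx, ny, nz)")
        if any(s < 1 for s in self.size):
            raise ValueError("patch size components must be >= 1")
        if self.count < 1:
            raise ValueError("count must be positive")


def read_volume(path: str | os.PathLike) -> VolumeStack:
    """Read a single- or multi-page grayscale TIFF as a :class:`VolumeStack`.

    The TIFF page index becomes the z axis.  Voxel size is taken from the
    ImageJ/resolution metadata when present, else (1, 1, 1).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) == 0:
            raise ValueError(f"{path}: TIFF has zero pages")
        if tf.pages[0].samplesperpixel != 1:
            raise ValueError(f"{path}: multi-sample (RGB) TIFF; expected grayscale")
        arr = tf.asarray()
        voxel = _voxel_size_from_tiff(tf)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    # tifffile yields (pages, y, x) == (z, y, x); store as (x, y, z)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    name = os.path.splitext(os.path.basename(path))[0]
    return VolumeStack(data=data, voxel_size=voxel, name=name)


def _voxel_size_from_tiff(tf: "tifffile.TiffFile") -> tuple[float, float, float]:
    try:
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        vx = vy = vz = 1.0
        if xres is not None and xres.value[0]:
            vx = xres.value[1] / xres.value[0]
        if yres is not None and yres.value[0]:
            vy = yres.value[1] / yres.value[0]
        if "spacing" in meta:
            vz = float(meta["spacing"])
        return (float(vx), float(vy), float(vz))
    except Exception:
        return (1.0, 1.0, 1.0)


def write_volume(vol: VolumeStack, path: str | os.PathLike) -> None:
    """Write a volume as a lossless multi-page TIFF, one page per z-plane."""
    data = vol.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    pages = np.ascontiguousarray(data.transpose(2, 1, 0))  # (z, y, x)
    vx, vy, vz = vol.voxel_size
    tifffile.imwrite(
        path,
        pages,
        imagej=pages.dtype in (np.dtype("uint8"), np.dtype("uint16"), np.dtype("float32")),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def percentile_normalize(
    vol: VolumeStack, p_low: float = 10.0, p_high: float = 99.0
) -> VolumeStack:
    """Affinely rescale intensities so percentile ``p_low`` maps to 0 and
    ``p_high`` maps to 1.

    Percentiles use linear interpolation and are computed over the whole
    stack (per volume, not per plane or patch).  Values outside the
    percentile window fall below 0 / above 1; they are *not* clipped here —
    see :func:`truncate_negative`.
    """
    data = vol.data.astype(np.float64)
    lo, hi = np.percentile(data, [p_low, p_high])
    if hi <= lo:
        raise ValueError(
            f"degenerate volume: percentile {p_high} ({hi}) <= percentile {p_low} ({lo})"
        )
    out = (data - lo) / (hi - lo)
    return replace(vol, data=out.astype(np.float32))


def truncate_negative(vol: VolumeStack) -> VolumeStack:
    """Elementwise ``max(value, 0)`` — background removal after normalization."""
    v = vol.astype_float()
    return replace(v, data=np.maximum(v.data, 0))


def bin_volume(vol: VolumeStack, factor: int) -> VolumeStack:
    """Downsample x and y by averaging ``factor`` × ``factor`` blocks.

    z is untouched.  Trailing remainder rows/columns are dropped rather than
    padded; voxel size is scaled accordingly.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nx, ny, nz = vol.shape
    if factor > nx or factor > ny:
        raise ValueError(f"factor {factor} exceeds x–y extent {(nx, ny)}")
    if factor == 1:
        return vol.copy()
    cx, cy = (nx // factor) * factor, (ny // factor) * factor
    data = vol.data[:cx, :cy].astype(np.float64)
    data = data.reshape(cx // factor, factor, cy // factor, factor, nz).mean(axis=(1, 3))
    vx, vy, vz = vol.voxel_size
    return VolumeStack(
        data=data,  # float64: block averaging preserves the global mean exactly
        voxel_size=(vx * factor, vy * factor, vz),
        name=vol.name,
    )


def extract_random_patches(vol: VolumeStack, spec: PatchSpec) -> list[np.ndarray]:
    """Uniformly sample ``spec.count`` random crops from the volume.

    2D specs return single z-planes (the plane is drawn uniformly per patch);
    3D specs return sub-volumes.  Reproducible for a fixed ``spec.seed``.
    """
    nx, ny, nz = vol.shape
    size = spec.size
    if size[0] > nx or size[1] > ny or (len(size) == 3 and size[2] > nz):
        raise ValueError(f"patch size {size} does not fit in volume {vol.shape}")
    rng = np.random.default_rng(spec.seed)
    patches = []
    for _ in range(spec.count):
        x0 = rng.integers(0, nx - size[0] + 1)
        y0 = rng.integers(0, ny - size[1] + 1)
        if len(size) == 2:
            z = rng.integers(0, nz)
            patches.append(np.array(vol.data[x0 : x0 + size[0], y0 : y0 + size[1], z]))
        else:
            z0 = rng.integers(0, nz - size[2] + 1)
            patches.append(
                np.array(
                    vol.data[x0 : x0 + size[0], y0 : y0 + size[1], z0 : z0 + size[2]]
                )
            )
    return patches


def tile_nonoverlapping(
    vol: VolumeStack, n_tiles: int | None = None, grid: tuple[int, int] | None = None
) -> list[np.ndarray]:
    """Partition the x–y extent into an even grid of non-overlapping 3D tiles
    spanning full z.

    ``n_tiles`` must be a perfect square unless an explicit ``grid`` is
    given.  Remainder voxels are dropped symmetrically.
    """
    if grid is None:
        if n_tiles is None:
            raise ValueError("give n_tiles or grid")
        root = int(round(n_tiles**0.5))
        if root * root != n_tiles:
            raise ValueError(f"n_tiles={n_tiles} is not a perfect square; pass grid=")
        grid = (root, root)
    gx, gy = grid
    nx, ny, nz = vol.shape
    tx, ty = nx // gx, ny // gy
    if tx < 1 or ty < 1:
        raise ValueError(f"grid {grid} finer than volume {vol.shape}")
    offx, offy = (nx - gx * tx) // 2, (ny - gy * ty) // 2
    tiles = []
    for i in range(gx):
        for j in range(gy):
            x0, y0 = offx + i * tx, offy + j * ty
            tiles.append(np.array(vol.data[x0 : x0 + tx, y0 : y0 + ty, :]))
    return tiles


def augment(patch: np.ndarray, rotation_k: int = 0, flip_x: bool = False, flip_y: bool = False) -> np.ndarray:
    """Apply a dihedral-group augmentation in the x–y plane.

    ``rotation_k`` is the number of 90° rotations; flips act along x and y.
    z (if present) is untouched, so the intensity multiset is preserved.
    """
    out = patch
    if rotation_k % 4:
        out = np.rot90(out, k=rotation_k % 4, axes=(0, 1))
    if flip_x:
        out = np.flip(out, axis=0)
    if flip_y:
        out = np.flip(out, axis=1)
    return np.ascontiguousarray(out)


def save_manifest(manifest: dict[str, list[str]], path: str | os.PathLike) -> None:
    """Write a protein-label → stack-path mapping as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump({str(k): [str(p) for p in v] for k, v in manifest.items()}, fh)


def load_manifest(path: str | os.PathLike) -> dict[str, list[str]]:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError(f"{path}: manifest must map labels to path lists")
    base = os.path.dirname(os.path.abspath(path))
    out: dict[str, list[str]] = {}
    for label, paths in manifest.items():
        out[str(label)] = [
            p if os.path.isabs(p) else os.path.join(base, p) for p in paths
        ]
    return out
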