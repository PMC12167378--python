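"""Synthetic 3D immunofluorescence phantoms.

Real multiplexed panels image each protein's characteristic spatial
expression pattern — fibrous intermediate filaments, solid nuclei, bright
nucleolar puncta nested in dim nuclei, hollow nuclear envelopes, diffuse
neuropil haze.  This module emulates those pattern families as labeled 3D
volumes with controllable density, object size, intensity and noise, so the
whole pairing/unmixing pipeline can be exercised without microscope data.

Rendering is deterministic for a fixed seed: object counts are Poisson,
positions uniform, and every random draw goes through one
``numpy.random.Generator``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeStack, save_manifest, write_volume

__all__ = [
    "PatternSpec",
    "NoiseSpec",
    "FAMILIES",
    "generate_volume",
    "generate_panel",
    "generate_registered_pair",
]

FAMILIES = ("filament", "blob", "punctate", "shell", "diffuse")

DEFAULT_SHAPE = (256, 256, 16)
DEFAULT_VOXEL = (0.2, 0.2, 1.0)


@dataclass
class PatternSpec:
    """One protein's spatial-expression phantom.

    Parameters
    ----------
    family : str
        Pattern family: ``filament`` (dilated persistent random walks),
        ``blob`` (solid soft-edged spheres), ``punctate`` (bright dots
        nested in dim nuclear disks), ``shell`` (hollow sphere rims) or
        ``diffuse`` (smoothed random field).
    density : float
        Objects per 1000 µm³ (for ``diffuse``: correlation-length control).
    size_um : float
        Characteristic radius/length in µm.
    intensity : float
        Mean object brightness, arbitrary units.
    haze : float
        Nonspecific-staining background as a fraction of ``intensity``
        (default 0: background voxels stay exactly at the noise-model
        background).  A small haze emulates the faint autofluorescence of
        real tissue and keeps sparse fields normalizable.
    seed : int
        Content seed; the family stays fixed per protein label.
    """

    family: str
    density: float = 2.0
    size_um: float = 2.0
    intensity: float = 1.0
    haze: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.density < 0 or self.size_um <= 0 or self.intensity <= 0:
            raise ValueError("density must be >= 0; size_um and intensity > 0")
        if self.haze < 0:
            raise ValueError("haze must be >= 0")


@dataclass
class NoiseSpec:
    """Acquisition-noise model: Poisson shot noise, Gaussian read noise,
    constant background — applied in that order."""

    gaussian_sigma: float = 0.0
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_scale < 0:
            raise ValueError("gaussian_sigma and poisson_scale must be >= 0")

    def apply(self, data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(data, dtype=np.float64)
        if self.poisson_scale > 0:
            out = rng.poisson(np.maximum(out, 0) * self.poisson_scale) / self.poisson_scale
        if self.gaussian_sigma > 0:
            out = out + rng.normal(0.0, self.gaussian_sigma, out.shape)
        if self.background:
            out = out + self.background
        return out.astype(np.float32)


def _poisson_count(rng: np.random.Generator, density: float, shape, voxel) -> int:
    vol_um3 = shape[0] * voxel[0] * shape[1] * voxel[1] * shape[2] * voxel[2]
    lam = density * vol_um3 / 1000.0
    return int(rng.poisson(lam))


def _radius_grid(center, radius_vox, shape):
    """Local anisotropy-aware distance grid around ``center`` (voxel units
    scaled so that ``radius_vox`` is 1), plus its slice into the volume."""
    lo, hi, axes = [], [], []
    for c, r, n in zip(center, radius_vox, shape):
        a = max(int(np.floor(c - 3 * r)), 0)
        b = min(int(np.ceil(c + 3 * r)) + 1, n)
        lo.append(a)
        hi.append(b)
        axes.append((np.arange(a, b) - c) / r)
    if any(a >= b for a, b in zip(lo, hi)):
        return None, None
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    rgrid = np.sqrt(gx**2 + gy**2 + gz**2)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return rgrid, sl


def _render_blobs(canvas, rng, n, radius_vox, intensity, hollow=False):
    shape = canvas.shape
    for _ in range(n):
        center = [rng.uniform(0, s - 1) for s in shape]
        jitter = rng.uniform(0.7, 1.3)
        rvox = [r * jitter for r in radius_vox]
        rgrid, sl = _radius_grid(center, rvox, shape)
        if rgrid is None:
            continue
        amp = intensity * rng.uniform(0.7, 1.3)
        if hollow:
            profile = np.exp(-(((rgrid - 1.0) / 0.25) ** 2))
        else:
            profile = np.exp(-(rgrid**4))  # flat core, sharp soft edge
        np.maximum(canvas[sl], amp * profile, out=canvas[sl])
    return canvas


def _render_filaments(canvas, rng, n, spec: PatternSpec, voxel):
    """Constant-speed persistent random walks dilated to fibre thickness."""
    shape = canvas.shape
    length_um = spec.size_um * 10.0  # fibres are long relative to their width
    step_um = min(voxel[0], voxel[1])
    n_steps = max(int(length_um / step_um), 4)
    thickness_um = max(spec.size_um / 6.0, 1.5 * step_um)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n):
        pos = np.array([rng.uniform(0, s - 1) for s in shape], dtype=float)
        theta = rng.uniform(0, 2 * np.pi)
        phi = rng.normal(0, 0.15)  # fibres run mostly in-plane
        for _ in range(n_steps):
            d_um = np.array(
                [
                    np.cos(theta) * np.cos(phi),
                    np.sin(theta) * np.cos(phi),
                    np.sin(phi),
                ]
            ) * step_um
            pos = pos + d_um / np.array(voxel)
            theta += rng.normal(0, 0.12)  # angular persistence
            phi = 0.8 * phi + rng.normal(0, 0.04)
            idx = np.round(pos).astype(int)
            if np.all(idx >= 0) and np.all(idx < shape):
                mask[tuple(idx)] = True
    rad = [max(int(round(thickness_um / v)), 1) for v in voxel]
    struct = _ellipsoid(rad)
    mask = ndimage.binary_dilation(mask, structure=struct)
    fil = mask.astype(np.float32) * spec.intensity
    fil = ndimage.gaussian_filter(fil, sigma=(0.7, 0.7, 0.3))
    np.maximum(canvas, fil, out=canvas)
    return canvas


def _ellipsoid(radii):
    ax = [np.arange(-r, r + 1) / max(r, 1) for r in radii]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= 1.0


def _render_punctate(canvas, rng, n, spec: PatternSpec, voxel):
    # dim nuclear disks with bright nucleolar dots inside
    shape = canvas.shape
    r_nuc = [spec.size_um / v for v in voxel]
    for _ in range(n):
        center = [rng.uniform(0, s - 1) for s in shape]
        rgrid, sl = _radius_grid(center, r_nuc, shape)
        if rgrid is None:
            continue
        canvas[sl] = np.maximum(
            canvas[sl], 0.25 * spec.intensity * np.exp(-(rgrid**4))
        )
        for _ in range(rng.integers(1, 4)):
            off = rng.uniform(-0.5, 0.5, size=3)
            dot_c = [c + o * r for c, o, r in zip(center, off, r_nuc)]
            r_dot = [max(r / 4.0, 1.0) for r in r_nuc]
            dgrid, dsl = _radius_grid(dot_c, r_dot, shape)
            if dgrid is None:
                continue
            canvas[dsl] = np.maximum(
                canvas[dsl], spec.intensity * rng.uniform(0.8, 1.2) * np.exp(-(dgrid**4))
            )
    return canvas


def _render_diffuse(canvas, rng, spec: PatternSpec, voxel):
    field = rng.normal(0, 1, canvas.shape)
    sig_xy = spec.size_um / voxel[0]
    sig_z = max(spec.size_um / voxel[2], 0.5)
    field = ndimage.gaussian_filter(field, sigma=(sig_xy, sig_xy, sig_z))
    sd = field.std()
    if sd > 0:
        field = field / sd
    # positive haze with mean ~ intensity, modulated by the random field
    haze = spec.intensity * np.clip(0.5 + 0.35 * field, 0, None)
    np.maximum(canvas, haze.astype(np.float32), out=canvas)
    return canvas


def generate_volume(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spec: PatternSpec | None = None,
    noise: NoiseSpec | None = None,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
    name: str = "",
) -> VolumeStack:
    """Render one phantom volume for a single protein.

    Deterministic for fixed ``spec.seed``; noise (if any) is applied last
    with a seed derived from the content seed.
    """
    if spec is None:
        spec = PatternSpec(family="blob")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(shape, dtype=np.float32)
    radius_vox = [spec.size_um / v for v in voxel_size]
    if spec.family == "diffuse":
        if spec.density > 0:
            canvas = _render_diffuse(canvas, rng, spec, voxel_size)
    else:
        n = _poisson_count(rng, spec.density, shape, voxel_size)
        if spec.family == "blob":
            canvas = _render_blobs(canvas, rng, n, radius_vox, spec.intensity)
        elif spec.family == "shell":
            canvas = _render_blobs(canvas, rng, n, radius_vox, spec.intensity, hollow=True)
        elif spec.family == "filament":
            canvas = _render_filaments(canvas, rng, n, spec, voxel_size)
        elif spec.family == "punctate":
            canvas = _render_punctate(canvas, rng, n, spec, voxel_size)
    if spec.haze > 0:
        base = spec.haze * spec.intensity
        field = rng.normal(0, 1, shape)
        field = ndimage.gaussian_filter(field, sigma=(4.0, 4.0, 1.0))
        sd = field.std()
        if sd > 0:
            field = field / sd
        canvas = canvas + base * np.clip(1.0 + 0.4 * field, 0.2, 2.0).astype(
            np.float32
        )
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    data = noise.apply(canvas, noise_rng)
    return VolumeStack(data=data, voxel_size=voxel_size, name=name)


def _derive_seed(base: int, *keys: int) -> int:
    return int(np.random.SeedSequence([base, *keys]).generate_state(1)[0] % (2**31))


def generate_panel(
    labels: list[tuple[str, PatternSpec]],
    n_stacks: int = 4,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
) -> dict[str, list[VolumeStack]]:
    """Render a labeled panel: ``n_stacks`` independent volumes per protein.

    Per-stack seeds are derived from ``seed`` and the label/stack indices.
    With ``out_dir`` given, stacks are written as
    ``<protein>_<stack_id>.tif`` plus a ``panel.yaml`` manifest.
    """
    if not labels:
        raise ValueError("labels must be nonempty")
    names = [lab for lab, _ in labels]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate labels in {names}")
    panel: dict[str, list[VolumeStack]] = {}
    for li, (label, spec) in enumerate(labels):
        stacks = []
        for k in range(n_stacks):
            s = PatternSpec(
                family=spec.family,
                density=spec.density,
                size_um=spec.size_um,
                intensity=spec.intensity,
                haze=spec.haze,
                seed=_derive_seed(seed, li, k),
            )
            stacks.append(
                generate_volume(shape, s, noise, voxel_size, name=f"{label}_{k}")
            )
        panel[label] = stacks
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        manifest: dict[str, list[str]] = {}
        for label, stacks in panel.items():
            manifest[label] = []
            for k, vol in enumerate(stacks):
                fname = f"{label}_{k}.tif"
                write_volume(vol, os.path.join(out_dir, fname))
                manifest[label].append(fname)
        save_manifest(manifest, os.path.join(out_dir, "panel.yaml"))
    return panel


def generate_registered_pair(
    specA: PatternSpec,
    specB: PatternSpec,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
) -> tuple[VolumeStack, VolumeStack]:
    """Two co-registered single-protein channels over the same field.

    Protein content is independent between channels (disjoint derived
    seeds), but any haze is rendered as a *shared* field: autofluorescence
    and nonspecific background come from the tissue, so co-registered
    channels see the same background structure (scaled by each channel's
    haze level).  The volumes are returned unmixed — mixing is a separate
    operation.
    """
    sA = PatternSpec(specA.family, specA.density, specA.size_um, specA.intensity,
                     haze=0.0, seed=_derive_seed(seed, 0, specA.seed))
    sB = PatternSpec(specB.family, specB.density, specB.size_um, specB.intensity,
                     haze=0.0, seed=_derive_seed(seed, 1, specB.seed))
    volA = generate_volume(shape, sA, None, voxel_size, name="alpha")
    volB = generate_volume(shape, sB, None, voxel_size, name="beta")
    if specA.haze > 0 or specB.haze > 0:
        field_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xF1E1D]))
        field = field_rng.normal(0, 1, shape)
        field = ndimage.gaussian_filter(field, sigma=(4.0, 4.0, 1.0))
        sd = field.std()
        if sd > 0:
            field = field / sd
        shared = np.clip(1.0 + 0.4 * field, 0.2, 2.0).astype(np.float32)
        volA.data = volA.data + specA.haze * specA.intensity * shared
        volB.data = volB.data + specB.haze * specB.intensity * shared
    noise = noise or NoiseSpec()
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA05E]))
    volA.data = noise.apply(volA.data, noise_rng)
    volB.data = noise.apply(volB.data, noise_rng)
    return volA, volB
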