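"""Self-supervised blind-spot denoising of z-stacks.

The denoiser predicts each z-plane from (a) its neighbouring planes via a
small 2D U-Net and (b) the plane itself via a blind-spot branch whose
receptive field excludes the centre pixel.  Because the prediction at a
pixel never sees that pixel's own value (J-invariance), training against
the noisy plane itself cannot learn the identity and converges to the
clean signal under pixelwise-independent noise.

Blind-spot construction: the branch applies one 3×3 convolution whose
central tap is structurally zero, followed exclusively by 1×1 convolutions.
Stacking several centre-masked 3×3 layers would *not* preserve the
property (information routes back through neighbours), so depth is added
only through 1×1 layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .volume import VolumeStack

__all__ = [
    "DenoiserConfig",
    "DenoiseNet",
    "build_denoiser",
    "train_denoiser",
    "denoise_stack",
    "BlindSpotDenoiser",
    "DenoiserResults",
]


@dataclass
class DenoiserConfig:
    """Blind-spot denoiser hyperparameters.

    ``z_context`` neighbour planes are taken per side; stacks must have
    z ≥ 2·z_context + 1.  Training uses Adam at 5e-4 without weight decay
    on the L1 + L2 self-supervised loss.  Epoch count and batch size are
    reduced-scale defaults (not fixed by the published recipe).
    """

    z_context: int = 2
    unet_channels: tuple[int, int] = (8, 16)
    blind_channels: int = 16
    patch_size: int = 48
    batch_size: int = 4
    lr: float = 5e-4
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_context < 1:
            raise ValueError("z_context must be >= 1")
        if self.patch_size % 2:
            raise ValueError("patch_size must be even (one 2×2 pool level)")

    @property
    def min_z(self) -> int:
        return 2 * self.z_context + 1


class DenoiseNet(nn.Module):
    """Two-branch denoiser: neighbour-plane 2D U-Net + blind-spot branch,
    fused by 1×1 convolutions into the denoised centre plane."""

    def __init__(self, cfg: DenoiserConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c_in = 2 * cfg.z_context
        c1, c2 = cfg.unet_channels
        cb = cfg.blind_channels
        # branch 1: one-pool U-Net over the neighbour planes
        self.enc1 = nn.ConvNd(c_in, c1, (3, 3), rng)
        self.enc2 = nn.ConvNd(c1, c2, (3, 3), rng)
        self.up = nn.UpConvNd(c2, c1, (2, 2), rng)
        self.dec = nn.ConvNd(2 * c1, c1, (3, 3), rng)
        # branch 2: blind-spot on [branch-1 output, centre plane]
        self.blind = nn.MaskedConv2d(c1 + 1, cb, rng)
        self.mix1 = nn.ConvNd(cb, cb, (1, 1), rng)
        # fusion head: 1×1 convolutions only
        self.fuse1 = nn.ConvNd(c1 + cb, cb, (1, 1), rng)
        self.fuse2 = nn.ConvNd(cb, 1, (1, 1), rng)

    def __call__(self, neighbours, center) -> Tensor:
        """``neighbours``: (N, 2·z_context, H, W); ``center``: (N, 1, H, W);
        H and W must be even."""
        nb = neighbours if isinstance(neighbours, Tensor) else Tensor(neighbours)
        ct = center if isinstance(center, Tensor) else Tensor(center)
        if nb.data.shape[1] != 2 * self.cfg.z_context:
            raise ValueError(
                f"expected {2 * self.cfg.z_context} neighbour planes, "
                f"got {nb.data.shape[1]}")
        if nb.data.shape[2] % 2 or nb.data.shape[3] % 2:
            raise ValueError("plane extents must be even")
        e1 = ag.relu(self.enc1(nb))
        e2 = ag.relu(self.enc2(ag.maxpool_nd(e1, (2, 2))))
        u = self.up(e2)
        b1 = ag.relu(self.dec(ag.concat([u, e1], axis=1)))
        b2 = ag.relu(self.blind(ag.concat([b1, ct], axis=1)))
        b2 = ag.relu(self.mix1(b2))
        f = ag.relu(self.fuse1(ag.concat([b1, b2], axis=1)))
        return self.fuse2(f)


def build_denoiser(cfg: DenoiserConfig) -> DenoiseNet:
    """Construct the (deterministically initialised) denoiser."""
    return DenoiseNet(cfg)


def _padded_planes(data: np.ndarray, z: int, zc: int) -> np.ndarray:
    """Neighbour planes of plane ``z`` with reflective z-padding, centre
    excluded; returns (2·zc, nx, ny)."""
    nz = data.shape[2]
    planes = []
    for off in range(-zc, zc + 1):
        if off == 0:
            continue
        zz = z + off
        if zz < 0:
            zz = -zz  # reflect (edge not repeated)
        elif zz >= nz:
            zz = 2 * (nz - 1) - zz
        if zz == z:
            # reflection landed on the centre plane, which would break the
            # blind spot; mirror to the opposite side instead
            zz = z - off
        planes.append(data[:, :, zz])
    return np.stack(planes)


class BlindSpotDenoiser:
    """Self-supervised denoising model over one or more noisy stacks."""

    def __init__(self, stacks, config: DenoiserConfig | None = None):
        if isinstance(stacks, VolumeStack):
            stacks = [stacks]
        if not stacks:
            raise ValueError("need at least one stack")
        self.config = config or DenoiserConfig()
        for s in stacks:
            if s.shape[2] < self.config.min_z:
                raise ValueError(
                    f"stack z={s.shape[2]} < required {self.config.min_z}")
        self.stacks = [s.astype_float() for s in stacks]

    def _sample_batch(self, rng: np.random.Generator):
        cfg = self.config
        ps = cfg.patch_size
        nbs, cts = [], []
        for _ in range(cfg.batch_size):
            vol = self.stacks[rng.integers(len(self.stacks))]
            nx, ny, nz = vol.shape
            if ps > nx or ps > ny:
                raise ValueError(f"patch {ps} larger than plane {(nx, ny)}")
            x0 = rng.integers(0, nx - ps + 1)
            y0 = rng.integers(0, ny - ps + 1)
            z = int(rng.integers(0, nz))
            nb = _padded_planes(vol.data, z, cfg.z_context)[:, x0:x0 + ps, y0:y0 + ps]
            ct = vol.data[x0:x0 + ps, y0:y0 + ps, z]
            nbs.append(nb)
            cts.append(ct[None])
        return (np.stack(nbs).astype(np.float32),
                np.stack(cts).astype(np.float32))

    def fit(self, epochs: int | None = None, verbose: bool = False
            ) -> "DenoiserResults":
        """Train against the noisy centre planes themselves (self-supervised
        L1 + L2; the blind spot prevents the identity shortcut)."""
        cfg = self.config
        epochs = cfg.epochs if epochs is None else int(epochs)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
        net = build_denoiser(cfg)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        trace = []
        for epoch in range(epochs):
            nb, ct = self._sample_batch(rng)
            pred = net(nb, ct)
            loss = ag.l1l2_loss(pred, ct)
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
            if verbose and (epoch % 25 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:.4f}")
        return DenoiserResults(self, net, np.asarray(trace))


class DenoiserResults:
    """Fitted denoiser; applies plane-by-plane with reflective z-padding."""

    def __init__(self, model_spec: BlindSpotDenoiser, net: DenoiseNet,
                 loss_trace: np.ndarray):
        self.model = model_spec
        self.net = net
        self.loss_trace = loss_trace
        self.config = model_spec.config

    def denoise(self, vol: VolumeStack) -> VolumeStack:
        return denoise_stack(self.net, vol)

    def summary(self) -> str:
        cfg = self.config
        return "\n".join([
            "Blind-spot denoiser",
            "=" * 30,
            f"z context:     ±{cfg.z_context} planes",
            f"epochs run:    {len(self.loss_trace)}",
            f"initial loss:  {self.loss_trace[0]:.4f}",
            f"final loss:    {self.loss_trace[-1]:.4f}",
        ])


def train_denoiser(stacks, cfg: DenoiserConfig | None = None) -> DenoiserResults:
    """Functional wrapper: fit a :class:`BlindSpotDenoiser`."""
    return BlindSpotDenoiser(stacks, cfg).fit()


def denoise_stack(net: DenoiseNet | DenoiserResults, vol: VolumeStack
                  ) -> VolumeStack:
    """Denoise every plane of a stack; output shape equals input shape.

    Odd plane extents are reflect-padded to even for the U-Net pool and
    cropped back.
    """
    if isinstance(net, DenoiserResults):
        net = net.net
    cfg = net.cfg
    v = vol.astype_float()
    nx, ny, nz = v.shape
    if nz < cfg.min_z:
        raise ValueError(f"stack z={nz} < required {cfg.min_z}")
    padx, pady = nx % 2, ny % 2
    out = np.empty((nx, ny, nz), dtype=np.float32)
    for z in range(nz):
        nb = _padded_planes(v.data, z, cfg.z_context)
        ct = v.data[:, :, z][None]
        if padx or pady:
            nb = np.pad(nb, ((0, 0), (0, padx), (0, pady)), mode="reflect")
            ct = np.pad(ct, ((0, 0), (0, padx), (0, pady)), mode="reflect")
        pred = net(nb[None].astype(np.float32), ct[None].astype(np.float32))
        out[:, :, z] = pred.data[0, 0, :nx, :ny]
    return VolumeStack(out, v.voxel_size, name=v.name)
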