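"""Protein separation: 3D encoder–decoder unmixing of two co-labeled proteins.

One network is trained per protein pair.  Training samples random 3D
patches from registered single-protein channels, blends them with random
coefficients (see :mod:`fluorosep.mixing`), and minimises the equally
weighted L1 + L2 loss between the two-channel prediction and the truncated
single-protein targets.  Inference tiles large volumes with overlapping
windows and linear-ramp blending.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .mixing import MixCoefficients, make_training_example, sample_coefficients
from .volume import VolumeStack, augment, percentile_normalize

__all__ = [
    "SeparationNetConfig",
    "UnmixedPair",
    "SeparationNet",
    "build_separation_network",
    "separation_loss",
    "train_separation_network",
    "unmix",
    "PairSeparator",
    "PairSeparatorResults",
]


@dataclass
class SeparationNetConfig:
    """3D U-Net architecture and training hyperparameters.

    The default profile keeps the published 5-level (8, 12, 16, 32, 48)
    channel layout at a reduced 64×64×8 patch so it runs on one CPU;
    :meth:`full_scale` restores 512×512×16 patches, batch 512, lr 3e-4 and
    10,000 epochs, and :meth:`reduced` is a 3-level fast profile for tests.
    The per-level z-pooling schedule may be 1 or 2 (pool kernels
    2×2×1 or 2×2×2); x/y patch extent must divide by 2^levels and z by the
    schedule product.
    """

    levels: int = 5
    kernel: int = 3
    channels: tuple[int, ...] = (8, 12, 16, 32, 48)
    pool_z_schedule: tuple[int, ...] = (1, 1, 2, 2, 1)
    out_channels: int = 2
    patch_size: tuple[int, int, int] = (64, 64, 8)
    batch_size: int = 2
    lr: float = 3e-4
    lr_decay: str = "cosine"  # "cosine" anneals to lr/10; "none" keeps lr fixed
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")
        self.channels = tuple(int(c) for c in self.channels)
        self.pool_z_schedule = tuple(int(p) for p in self.pool_z_schedule)
        self.patch_size = tuple(int(s) for s in self.patch_size)
        if len(self.channels) != self.levels:
            raise ValueError("channels must have `levels` entries")
        if len(self.pool_z_schedule) != self.levels:
            raise ValueError("pool_z_schedule must have `levels` entries")
        if any(p not in (1, 2) for p in self.pool_z_schedule):
            raise ValueError("pool_z_schedule entries must be 1 or 2")
        if self.out_channels != 2:
            raise ValueError("out_channels is 2 (one per protein)")
        px, py, pz = self.patch_size
        if px % (2**self.levels) or py % (2**self.levels):
            raise ValueError(
                f"x,y patch extent must divide by 2^{self.levels}")
        if pz % int(np.prod(self.pool_z_schedule)):
            raise ValueError("z patch extent must divide the pool_z product")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "SeparationNetConfig":
        return cls(patch_size=(512, 512, 16), batch_size=512, lr=3e-4,
                   epochs=10000, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0, epochs: int = 220) -> "SeparationNetConfig":
        return cls(levels=3, channels=(8, 12, 16), pool_z_schedule=(1, 2, 2),
                   patch_size=(48, 48, 8), batch_size=2, lr=3e-3,
                   epochs=epochs, seed=seed)


@dataclass
class UnmixedPair:
    """Two unmixed volumes with provenance of the producing model."""

    vol_alpha: VolumeStack
    vol_beta: VolumeStack
    model_id: str = ""
    tile_layout: tuple[int, int, int] = (1, 1, 1)


class SeparationNet(nn.Module):
    """3D U-Net: conv+ReLU+pool encoder, transposed-conv decoder with
    channel-concatenated skip connections, 1×1×1 head to two channels."""

    def __init__(self, cfg: SeparationNetConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        k = (cfg.kernel,) * 3
        ch = cfg.channels
        self.enc = []
        c_prev = 1
        for c in ch:
            self.enc.append(nn.ConvNd(c_prev, c, k, rng))
            c_prev = c
        self.ups = []
        self.dec = []
        for i in range(cfg.levels - 1, -1, -1):
            block = (2, 2, cfg.pool_z_schedule[i])
            self.ups.append(nn.UpConvNd(c_prev, ch[i], block, rng))
            c_out = ch[i - 1] if i > 0 else ch[0]
            self.dec.append(nn.ConvNd(2 * ch[i], c_out, k, rng))
            c_prev = c_out
        self.head = nn.ConvNd(c_prev, cfg.out_channels, (1, 1, 1), rng)

    def __call__(self, x) -> Tensor:
        cfg = self.cfg
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.data.ndim != 5:
            raise ValueError(f"expected (N, 1, nx, ny, nz), got {t.data.shape}")
        nx, ny, nz = t.data.shape[2:]
        if nx % (2**cfg.levels) or ny % (2**cfg.levels) or \
                nz % int(np.prod(cfg.pool_z_schedule)):
            raise ValueError(f"input extent {(nx, ny, nz)} incompatible with "
                             f"{cfg.levels} levels / z schedule {cfg.pool_z_schedule}")
        skips = []
        for i, conv in enumerate(self.enc):
            t = ag.relu(conv(t))
            skips.append(t)
            t = ag.maxpool_nd(t, (2, 2, cfg.pool_z_schedule[i]))
        for j, (up, dec) in enumerate(zip(self.ups, self.dec)):
            t = up(t)
            t = ag.concat([t, skips[cfg.levels - 1 - j]], axis=1)
            t = ag.relu(dec(t))
        return self.head(t)


def build_separation_network(cfg: SeparationNetConfig) -> SeparationNet:
    """Construct the (deterministically initialised) separation network."""
    return SeparationNet(cfg)


def separation_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Equally weighted mean-absolute plus mean-squared error over both
    channels and all voxels."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    d = p - t
    return float(np.abs(d).mean() + (d * d).mean())


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PairSeparator:
    """Separation model for one protein pair.

    Parameters
    ----------
    pairs : list of (VolumeStack, VolumeStack)
        Registered single-protein channel stacks (α, β).  Channels are
        percentile-normalized on construction.
    config : SeparationNetConfig, optional
    pair_name : str
        Label used in checkpoints and provenance (one model per pair).
    """

    def __init__(self, pairs, config: SeparationNetConfig | None = None,
                 pair_name: str = ""):
        if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(
                pairs[0], VolumeStack):
            pairs = [pairs]
        if not pairs:
            raise ValueError("need at least one registered pair")
        self.config = config or SeparationNetConfig()
        self.pairs = []
        for volA, volB in pairs:
            if volA.shape != volB.shape:
                raise ValueError("registered channels must share a shape")
            self.pairs.append((percentile_normalize(volA),
                               percentile_normalize(volB)))
        self.pair_name = pair_name or f"{pairs[0][0].name}-{pairs[0][1].name}"

    def _sample_patch(self, rng: np.random.Generator):
        px, py, pz = self.config.patch_size
        volA, volB = self.pairs[rng.integers(len(self.pairs))]
        nx, ny, nz = volA.shape
        if px > nx or py > ny or pz > nz:
            raise ValueError(f"patch {self.config.patch_size} larger than "
                             f"volume {volA.shape}")
        x0 = rng.integers(0, nx - px + 1)
        y0 = rng.integers(0, ny - py + 1)
        z0 = rng.integers(0, nz - pz + 1)
        a = np.array(volA.data[x0:x0 + px, y0:y0 + py, z0:z0 + pz])
        b = np.array(volB.data[x0:x0 + px, y0:y0 + py, z0:z0 + pz])
        rot, fx, fy = int(rng.integers(4)), bool(rng.integers(2)), bool(rng.integers(2))
        a = augment(a, rot, fx, fy)
        b = augment(b, rot, fx, fy)
        ex = make_training_example(a, b, sample_coefficients(rng))
        return ex

    def fit(self, epochs: int | None = None, verbose: bool = False
            ) -> "PairSeparatorResults":
        """Train with Adam on synthetic mixtures of the registered channels.

        Each epoch draws ``batch_size`` random augmented patches, each with
        freshly sampled mixing coefficients, and takes one optimiser step.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else int(epochs)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        net = build_separation_network(cfg)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        trace = []
        for epoch in range(epochs):
            if cfg.lr_decay == "cosine":
                frac = epoch / max(epochs - 1, 1)
                opt.lr = cfg.lr * (0.1 + 0.45 * (1.0 + np.cos(np.pi * frac)))
            exs = [self._sample_patch(rng) for _ in range(cfg.batch_size)]
            x = np.stack([e.input for e in exs])[:, None]
            y = np.stack(
                [np.stack([e.target_alpha, e.target_beta]) for e in exs]
            )
            pred = net(x)
            loss = ag.l1l2_loss(pred, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
            if verbose and (epoch % 25 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:.4f}")
        return PairSeparatorResults(self, net, np.asarray(trace))


def _ramp_weights(shape, starts, extents):
    """Linear ramp window for overlap blending (triangular per axis)."""
    ws = []
    for n in shape:
        ax = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1)).astype(np.float64)
        ws.append(ax / ax.max())
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def _tile_starts(total: int, tile: int, overlap: float) -> list[int]:
    if tile >= total:
        return [0]
    stride = max(int(round(tile * (1.0 - overlap))), 1)
    starts = list(range(0, total - tile, stride))
    starts.append(total - tile)
    return sorted(set(starts))


class PairSeparatorResults:
    """Fitted separation network with tiled inference and evaluation."""

    def __init__(self, model_spec: PairSeparator, net: SeparationNet,
                 loss_trace: np.ndarray):
        self.model = model_spec
        self.net = net
        self.loss_trace = loss_trace
        self.config = model_spec.config

    def unmix(self, mixed: VolumeStack, normalized: bool = True,
              overlap: float = 0.25) -> UnmixedPair:
        """Predict the two single-protein volumes from one mixed volume.

        ``normalized=True`` expects the input already percentile-normalized
        with the training scheme; set False to normalize here.  Volumes
        larger than the training patch are processed as overlapping tiles
        blended with linear ramps; outputs are clipped at 0.
        """
        if not normalized:
            mixed = percentile_normalize(mixed)
        px, py, pz = self.config.patch_size
        nx, ny, nz = mixed.shape
        if nx < px or ny < py or nz < pz:
            raise ValueError(f"volume {mixed.shape} smaller than the minimum "
                             f"tile {self.config.patch_size}")
        xs = _tile_starts(nx, px, overlap)
        ys = _tile_starts(ny, py, overlap)
        zs = _tile_starts(nz, pz, overlap)
        acc = np.zeros((2, nx, ny, nz), dtype=np.float64)
        wacc = np.zeros((nx, ny, nz), dtype=np.float64)
        w = _ramp_weights((px, py, pz), None, None)
        for x0 in xs:
            for y0 in ys:
                for z0 in zs:
                    tile = mixed.data[x0:x0 + px, y0:y0 + py, z0:z0 + pz]
                    pred = self.net(tile[None, None].astype(np.float32)).data[0]
                    acc[:, x0:x0 + px, y0:y0 + py, z0:z0 + pz] += pred * w
                    wacc[x0:x0 + px, y0:y0 + py, z0:z0 + pz] += w
        out = acc / wacc
        out = np.clip(out, 0, None).astype(np.float32)
        vx = mixed.voxel_size
        return UnmixedPair(
            vol_alpha=VolumeStack(out[0], vx, name=f"{self.model.pair_name}_alpha"),
            vol_beta=VolumeStack(out[1], vx, name=f"{self.model.pair_name}_beta"),
            model_id=self.model.pair_name,
            tile_layout=(len(xs), len(ys), len(zs)),
        )

    def evaluate(self, mixed: VolumeStack, truth_alpha: VolumeStack,
                 truth_beta: VolumeStack, n_tiles: int = 16):
        from .metrics import evaluate_pair

        um = self.unmix(mixed)
        return evaluate_pair(um.vol_alpha, um.vol_beta, truth_alpha, truth_beta,
                             n_tiles=n_tiles, pair_name=self.model.pair_name)

    def save(self, path) -> None:
        import json

        cfg = {k: getattr(self.config, k) for k in
               ("levels", "kernel", "channels", "pool_z_schedule", "out_channels",
                "patch_size", "batch_size", "lr", "epochs", "seed")}
        np.savez(path, __config__=json.dumps(cfg), __trace__=self.loss_trace,
                 __pair__=self.model.pair_name, **self.net.state_dict())

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_trace)
        ax.set_xlabel("epoch")
        ax.set_ylabel("L1 + L2 loss")
        return ax

    def summary(self) -> str:
        cfg = self.config
        return "\n".join([
            f"Protein separation network — pair {self.model.pair_name!r}",
            "=" * 44,
            f"levels / channels:  {cfg.levels} / {cfg.channels}",
            f"z-pool schedule:    {cfg.pool_z_schedule}",
            f"patch size:         {cfg.patch_size}",
            f"epochs run:         {len(self.loss_trace)}",
            f"initial loss:       {self.loss_trace[0]:.4f}",
            f"final loss:         {self.loss_trace[-1]:.4f}",
        ])


def train_separation_network(pairs, cfg: SeparationNetConfig | None = None,
                             pair_name: str = "") -> PairSeparatorResults:
    """Functional wrapper: fit a :class:`PairSeparator`."""
    return PairSeparator(pairs, cfg, pair_name=pair_name).fit()


def unmix(results: PairSeparatorResults, mixed: VolumeStack, **kw) -> UnmixedPair:
    """Functional wrapper around :meth:`PairSeparatorResults.unmix`."""
    return results.unmix(mixed, **kw)
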