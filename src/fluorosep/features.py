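"""Contrastive feature extraction of protein spatial-expression patterns.

A small 2D CNN embeds image patches of singly stained proteins into a
feature space where patches of the same protein cluster and patches of
different proteins separate.  Training maximises the interclass distance
``d_inter`` (mean distance between class centers) and minimises the
intraclass distance ``d_intra`` (mean distance of vectors to their own
class center), both measured with the average of L1 and L2 norms.

The model object follows the fit/Results convention: build a
:class:`PatternEmbedder` from a labeled panel of volumes, call
:meth:`~PatternEmbedder.fit`, and use the returned
:class:`PatternEmbedderResults` to embed held-out patches and derive the
distance matrix for pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .volume import VolumeStack, augment, percentile_normalize

__all__ = [
    "FeatureExtractorConfig",
    "FeatureVectorSet",
    "LabeledPatchSet",
    "mixed_norm",
    "interclass_distance",
    "intraclass_distance",
    "contrastive_loss",
    "build_feature_extractor",
    "train_feature_extractor",
    "extract_features",
    "PatternEmbedder",
    "PatternEmbedderResults",
]


@dataclass
class FeatureExtractorConfig:
    """Architecture and training hyperparameters.

    Defaults are a reduced-scale profile (64×64 patches, 16-dim embedding,
    small batches) that trains in seconds on one CPU; :meth:`full_scale`
    returns the full-scale recipe (256×256 patches, 128-dim embedding,
    batch 512, lr 3e-3, 100 epochs).
    """

    n_layers: int = 5
    kernel: int = 3
    channels: tuple[int, ...] = (8, 12, 16, 32, 48)
    embed_dim: int = 16
    patch_size: int = 64
    batch_size: int = 32
    lr: float = 3e-3
    epochs: int = 80
    seed: int = 0
    loss_form: str = "difference"  # or "ratio"

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) != self.n_layers:
            raise ValueError("channels must have n_layers entries")
        if any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must be strictly increasing")
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if self.patch_size % (2**self.n_layers):
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^{self.n_layers}"
            )
        if self.loss_form not in ("difference", "ratio"):
            raise ValueError("loss_form must be 'difference' or 'ratio'")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "FeatureExtractorConfig":
        return cls(embed_dim=128, patch_size=256, batch_size=512, lr=3e-3,
                   epochs=100, seed=seed)


@dataclass
class LabeledPatchSet:
    """Patches with one protein label per patch, for contrastive training."""

    patches: list[np.ndarray]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must have equal length")

    def by_label(self) -> dict[str, list[np.ndarray]]:
        out: dict[str, list[np.ndarray]] = {}
        for p, l in zip(self.patches, self.labels):
            out.setdefault(l, []).append(p)
        return out


class FeatureVectorSet:
    """Per-protein collections of embedding vectors with their centers."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        self._vectors = {}
        for label, arr in vectors.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
            if arr.shape[0] < 1:
                raise ValueError(f"protein {label!r} has no vectors")
            self._vectors[label] = arr
        if not self._vectors:
            raise ValueError("empty feature-vector set")

    @property
    def labels(self) -> list[str]:
        return list(self._vectors)

    def vectors(self, label: str) -> np.ndarray:
        return self._vectors[label]

    def center(self, label: str) -> np.ndarray:
        return self._vectors[label].mean(axis=0)

    @property
    def centers(self) -> dict[str, np.ndarray]:
        return {l: self.center(l) for l in self.labels}

    def __len__(self) -> int:
        return len(self._vectors)

    def items(self):
        return self._vectors.items()

    def all_vectors(self) -> tuple[np.ndarray, list[str]]:
        """Stack every vector with its label (e.g. for 2D embedding plots)."""
        arrs, labs = [], []
        for l, arr in self._vectors.items():
            arrs.append(arr)
            labs.extend([l] * arr.shape[0])
        return np.vstack(arrs), labs


# ---------------------------------------------------------------------------
# the distance objective
# ---------------------------------------------------------------------------

def mixed_norm(v: np.ndarray) -> float:
    """Average of the L1 and L2 norms, ``(‖v‖₁ + ‖v‖₂)/2``."""
    v = np.asarray(v, dtype=np.float64).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("vector must be finite")
    return 0.5 * (np.abs(v).sum() + np.sqrt((v * v).sum()))


def interclass_distance(fvs: FeatureVectorSet) -> float:
    """Mean mixed-norm distance between class centers over ordered pairs,
    ``(1/|P|(|P|−1)) ΣΣ_{p1≠p2} ‖f̄_p1 − f̄_p2‖``."""
    labels = fvs.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 proteins")
    centers = [fvs.center(l) for l in labels]
    total = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i != j:
                total += mixed_norm(centers[i] - centers[j])
    return total / (len(labels) * (len(labels) - 1))


def intraclass_distance(fvs: FeatureVectorSet) -> float:
    """Mean over proteins of the mean mixed-norm distance of each vector to
    its own class center."""
    total = 0.0
    for label in fvs.labels:
        arr = fvs.vectors(label)
        c = arr.mean(axis=0)
        total += float(np.mean([mixed_norm(c - v) for v in arr]))
    return total / len(fvs)


def contrastive_loss(
    batch_features: np.ndarray, batch_labels, loss_form: str = "difference",
    eps: float = 1e-6,
) -> float:
    """``d_intra − d_inter`` on a batch, with class centers computed within
    the batch.  Lower is better; the ``ratio`` form is ``d_intra/(d_inter+ε)``."""
    batch_labels = list(batch_labels)
    uniq = sorted(set(batch_labels))
    if len(uniq) < 2:
        raise ValueError("batch must contain at least 2 labels")
    fvs = FeatureVectorSet(
        {
            l: np.asarray(batch_features)[[i for i, b in enumerate(batch_labels) if b == l]]
            for l in uniq
        }
    )
    di, dc = intraclass_distance(fvs), interclass_distance(fvs)
    if loss_form == "ratio":
        return di / (dc + eps)
    return di - dc


def _scalar_ratio(a: Tensor, b: Tensor, eps: float) -> Tensor:
    denom = float(b.data) + eps
    out = float(a.data) / denom

    def _bw(g):
        return (g / denom, -g * float(a.data) / denom**2)

    return Tensor(np.float32(out), _parents=(a, b), _backward=_bw)


def _contrastive_loss_graph(feats: Tensor, labels: list[str],
                            loss_form: str, eps: float = 1e-6) -> Tensor:
    """Autodiff version of :func:`contrastive_loss` used during training."""
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("batch must contain at least 2 labels")
    centers, intras = [], []
    for l in uniq:
        idx = [i for i, b in enumerate(labels) if b == l]
        rows = ag.take_rows(feats, idx)
        center = ag.mean_axis0(rows)
        centers.append(center)
        diffs = ag.sub(rows, center)
        intras.append(ag.smean(ag.mixed_norm_rows(diffs)))
    d_intra = ag.scalar_scale(ag.scalar_sum(intras), 1.0 / len(uniq))
    inters = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            inters.append(ag.mixed_norm_rows(ag.sub(centers[i], centers[j])))
    d_inter = ag.scalar_scale(
        ag.scalar_sum(inters), 2.0 / (len(uniq) * (len(uniq) - 1))
    )
    if loss_form == "ratio":
        return _scalar_ratio(d_intra, d_inter, eps)
    return ag.sub(d_intra, d_inter)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class FeatureNet(nn.Module):
    """Stack of 3×3 conv + ReLU + 2×2 max-pool blocks with increasing
    channels, flattened into one linear layer producing the embedding."""

    def __init__(self, cfg: FeatureExtractorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.convs = []
        c_prev = 1
        for c in cfg.channels:
            self.convs.append(nn.ConvNd(c_prev, c, (cfg.kernel, cfg.kernel), rng))
            c_prev = c
        final_sp = cfg.patch_size // (2**cfg.n_layers)
        self.head = nn.Linear(cfg.channels[-1] * final_sp * final_sp,
                              cfg.embed_dim, rng)

    def __call__(self, x) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(x)
        if t.data.ndim != 4 or t.data.shape[2] != t.data.shape[3] or \
                t.data.shape[2] != self.cfg.patch_size:
            raise ValueError(
                f"expected (N, 1, {self.cfg.patch_size}, {self.cfg.patch_size}), "
                f"got {t.data.shape}"
            )
        for conv in self.convs:
            t = ag.maxpool_nd(ag.relu(conv(t)), (2, 2))
        t = ag.reshape(t, (t.data.shape[0], -1))
        return self.head(t)


def build_feature_extractor(cfg: FeatureExtractorConfig) -> FeatureNet:
    """Construct the (deterministically initialised) feature extractor."""
    return FeatureNet(cfg)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PatternEmbedder:
    """Contrastive embedding model over a labeled panel of volumes.

    Parameters
    ----------
    panel : dict[str, list[VolumeStack]]
        Singly stained stacks grouped by protein label.  Each stack is
        percentile-normalized on construction (idempotent, so already
        normalized inputs are safe).
    config : FeatureExtractorConfig, optional
    holdout : int
        Number of stacks per protein reserved for testing (the panel recipe
        is train on all but one stack, test on the last).  0 disables.
    """

    def __init__(self, panel: dict[str, list[VolumeStack]],
                 config: FeatureExtractorConfig | None = None,
                 holdout: int = 1):
        if len(panel) < 2:
            raise ValueError("need at least 2 protein labels")
        self.config = config or FeatureExtractorConfig()
        self.train_panel: dict[str, list[VolumeStack]] = {}
        self.test_panel: dict[str, list[VolumeStack]] = {}
        for label, stacks in panel.items():
            if not stacks:
                raise ValueError(f"label {label!r} has no stacks")
            norm = [percentile_normalize(s) for s in stacks]
            cut = len(norm) - holdout if len(norm) > holdout else len(norm)
            self.train_panel[label] = norm[:cut]
            self.test_panel[label] = norm[cut:] if cut < len(norm) else []

    def _sample_batch(self, rng: np.random.Generator):
        cfg = self.config
        labels = sorted(self.train_panel)
        per = max(cfg.batch_size // len(labels), 2)
        ps = cfg.patch_size
        xs, ys = [], []
        for label in labels:
            stacks = self.train_panel[label]
            for _ in range(per):
                vol = stacks[rng.integers(len(stacks))]
                nx, ny, nz = vol.shape
                x0 = rng.integers(0, nx - ps + 1)
                y0 = rng.integers(0, ny - ps + 1)
                z = rng.integers(0, nz)
                patch = np.array(vol.data[x0:x0 + ps, y0:y0 + ps, z])
                patch = augment(patch, rotation_k=int(rng.integers(4)),
                                flip_x=bool(rng.integers(2)),
                                flip_y=bool(rng.integers(2)))
                xs.append(patch)
                ys.append(label)
        x = np.stack(xs)[:, None].astype(np.float32)
        return x, ys

    def fit(self, epochs: int | None = None, verbose: bool = False
            ) -> "PatternEmbedderResults":
        """Train with Adam on the contrastive objective.

        One epoch draws one fresh batch (``batch_size`` patches sampled
        evenly over proteins, dihedral-augmented) and takes one optimiser
        step; the loss trace has one entry per epoch.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else int(epochs)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        model = build_feature_extractor(cfg)
        opt = nn.Adam(model.parameters(), lr=cfg.lr)
        trace = []
        for epoch in range(epochs):
            x, ys = self._sample_batch(rng)
            feats = model(x)
            loss = _contrastive_loss_graph(feats, ys, cfg.loss_form)
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
            if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  loss {trace[-1]:+.4f}")
        return PatternEmbedderResults(self, model, np.asarray(trace))


class PatternEmbedderResults:
    """Fitted contrastive embedding: trained weights, loss trace, and
    embedding/distance utilities."""

    def __init__(self, model_spec: PatternEmbedder, net: FeatureNet,
                 loss_trace: np.ndarray):
        self.model = model_spec
        self.net = net
        self.loss_trace = loss_trace
        self.config = model_spec.config

    def embed_patches(self, patches: list[np.ndarray]) -> np.ndarray:
        """Embed 2D patches (each ``patch_size``²) to feature vectors."""
        ps = self.config.patch_size
        x = np.stack([np.asarray(p, dtype=np.float32) for p in patches])
        if x.shape[1:] != (ps, ps):
            raise ValueError(f"patches must be {ps}×{ps}, got {x.shape[1:]}")
        outs = []
        for i in range(0, len(x), 64):
            outs.append(self.net(x[i:i + 64, None]).data)
        return np.concatenate(outs, axis=0)

    def extract_features(
        self, panel: dict[str, list[VolumeStack]] | None = None,
        n_patches: int = 16, seed: int = 0, normalized: bool = False,
    ) -> FeatureVectorSet:
        """Embed random patches from a panel into a :class:`FeatureVectorSet`.

        Defaults to the held-out test stacks of the training panel.
        """
        if panel is None:
            panel = {l: s for l, s in self.model.test_panel.items() if s}
            if not panel:
                panel = self.model.train_panel
            normalized = True
        ps = self.config.patch_size
        rng = np.random.default_rng(seed)
        vectors = {}
        for label, stacks in panel.items():
            if not stacks:
                raise ValueError(f"label {label!r} has no stacks")
            patches = []
            use = stacks if normalized else [percentile_normalize(s) for s in stacks]
            for _ in range(n_patches):
                vol = use[rng.integers(len(use))]
                nx, ny, nz = vol.shape
                x0 = rng.integers(0, nx - ps + 1)
                y0 = rng.integers(0, ny - ps + 1)
                z = rng.integers(0, nz)
                patches.append(np.array(vol.data[x0:x0 + ps, y0:y0 + ps, z]))
            vectors[label] = self.embed_patches(patches)
        return FeatureVectorSet(vectors)

    def distance_matrix(self, n_patches: int = 16, seed: int = 0):
        from .pairing import feature_distance_matrix

        return feature_distance_matrix(self.extract_features(n_patches=n_patches,
                                                             seed=seed))

    def save(self, path) -> None:
        import json

        state = self.net.state_dict()
        cfg = {k: getattr(self.config, k) for k in
               ("n_layers", "kernel", "channels", "embed_dim", "patch_size",
                "batch_size", "lr", "epochs", "seed", "loss_form")}
        np.savez(path, __config__=json.dumps(cfg),
                 __trace__=self.loss_trace, **state)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_trace)
        ax.set_xlabel("epoch")
        ax.set_ylabel("contrastive loss")
        return ax

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Contrastive pattern embedding",
            "=" * 34,
            f"proteins:        {', '.join(sorted(self.model.train_panel))}",
            f"embedding dim:   {cfg.embed_dim}",
            f"patch size:      {cfg.patch_size}",
            f"channels:        {cfg.channels}",
            f"epochs run:      {len(self.loss_trace)}",
            f"initial loss:    {self.loss_trace[0]:+.4f}",
            f"final loss:      {self.loss_trace[-1]:+.4f}",
        ]
        return "\n".join(lines)


def train_feature_extractor(
    panel: dict[str, list[VolumeStack]], cfg: FeatureExtractorConfig | None = None,
) -> PatternEmbedderResults:
    """Functional wrapper: fit a :class:`PatternEmbedder` on a panel."""
    return PatternEmbedder(panel, cfg).fit()


def extract_features(results_or_net, patch_set: LabeledPatchSet) -> FeatureVectorSet:
    """Embed a labeled patch set with a trained model, grouped by label."""
    if isinstance(results_or_net, PatternEmbedderResults):
        net = results_or_net.net
    else:
        net = results_or_net
    grouped = patch_set.by_label()
    vectors = {}
    for label, patches in grouped.items():
        x = np.stack([np.asarray(p, dtype=np.float32) for p in patches])[:, None]
        outs = [net(x[i:i + 64]).data for i in range(0, len(x), 64)]
        vectors[label] = np.concatenate(outs, axis=0)
    return FeatureVectorSet(vectors)
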