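"""Pattern-guided protein pairing.

Given per-protein clusters of feature vectors, the pairwise average-linkage
distance (mean of all cross-cluster Euclidean distances) quantifies how
distinguishable two proteins' spatial expression patterns are.  Pairing 2n
proteins for shared fluorophores is then a bottleneck (max-min) perfect
matching problem:

    G_opt = argmax_G min(d_1, ..., d_n)

over all (2n−1)!! perfect matchings G.  An exhaustive solver with a
deterministic lexicographic tie-break handles panels up to 16 proteins; a
threshold/bisection solver using maximum-cardinality matching scales beyond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .features import FeatureVectorSet

__all__ = [
    "DistanceMatrix",
    "Grouping",
    "average_linkage_distance",
    "feature_distance_matrix",
    "enumerate_matchings",
    "optimal_grouping",
    "bottleneck_grouping",
    "compare_distance_matrices",
    "embed_2d",
    "normalize_feature_space",
]

EXHAUSTIVE_LIMIT = 16


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances between protein clusters."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.D = np.asarray(self.D, dtype=np.float64)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError(f"matrix shape {self.D.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any(self.D < -1e-12):
            raise ValueError("distances must be nonnegative")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.D[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.columns), D=df.to_numpy())


@dataclass
class Grouping:
    """A perfect matching of the protein set into disjoint pairs."""

    pairs: list[tuple[str, str]]
    min_distance: float

    def __post_init__(self) -> None:
        flat = [p for pair in self.pairs for p in pair]
        if len(flat) != len(set(flat)):
            raise ValueError("pairs must be disjoint")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {"pairs": [list(p) for p in self.pairs],
                 "min_distance": float(self.min_distance)}, fh)


def average_linkage_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Mean Euclidean distance over all |A|·|B| cross-cluster pairs."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("clusters must be nonempty")
    from scipy.spatial.distance import cdist

    return float(cdist(A, B).mean())


def feature_distance_matrix(fvs: FeatureVectorSet) -> DistanceMatrix:
    """Average-linkage distances between every pair of protein clusters."""
    labels = fvs.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 proteins")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = average_linkage_distance(fvs.vectors(labels[i]),
                                         fvs.vectors(labels[j]))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, D=D)


def enumerate_matchings(labels: list[str]):
    """Yield every perfect matching of ``labels`` exactly once.

    Pairs the first unmatched label with each remaining label and recurses;
    yields (2n−1)!! matchings, each as a list of label pairs in canonical
    order.
    """
    labels = list(labels)
    if len(labels) % 2:
        raise ValueError("need an even number of labels")

    def rec(remaining):
        if not remaining:
            yield []
            return
        first = remaining[0]
        for k in range(1, len(remaining)):
            partner = remaining[k]
            rest = remaining[1:k] + remaining[k + 1:]
            for tail in rec(rest):
                yield [(first, partner)] + tail

    yield from rec(labels)


def _pair_distances(dm: DistanceMatrix, matching) -> list[float]:
    return [dm.value(a, b) for a, b in matching]


def optimal_grouping(dm: DistanceMatrix) -> Grouping:
    """Exhaustively solve ``argmax_G min_i d_i`` over all perfect matchings.

    Ties on the minimum are broken by lexicographically maximising the
    sorted vector of pair distances, then by canonical label order, so the
    result is deterministic.  Limited to 16 proteins; use
    :func:`bottleneck_grouping` beyond.
    """
    n = len(dm.labels)
    if n % 2:
        raise ValueError("need an even number of proteins")
    if n > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive solver limited to {EXHAUSTIVE_LIMIT} proteins; "
            "use bottleneck_grouping")
    best = None
    best_key = None
    for matching in enumerate_matchings(dm.labels):
        ds = sorted(_pair_distances(dm, matching))
        key = tuple(ds)  # compares min first, then the rest — the tie-break
        if best_key is None or key > best_key:
            best, best_key = matching, key
    return Grouping(pairs=[tuple(p) for p in best], min_distance=float(best_key[0]))


def bottleneck_grouping(dm: DistanceMatrix) -> Grouping:
    """Max-min perfect matching by bisection over the distance threshold.

    A matching with minimum pair distance ≥ t exists iff the graph keeping
    only edges with distance ≥ t has a perfect matching; the optimum is the
    largest such t among the edge weights present.  Agrees with
    :func:`optimal_grouping` in the optimal value.
    """
    labels = dm.labels
    n = len(labels)
    if n % 2:
        raise ValueError("need an even number of proteins")
    iu = np.triu_indices(n, k=1)
    thresholds = np.unique(dm.D[iu])

    def matching_at(t):
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for i, j in zip(*iu):
            if dm.D[i, j] >= t:
                G.add_edge(int(i), int(j))
        m = nx.max_weight_matching(G, maxcardinality=True)
        return m if 2 * len(m) == n else None

    lo, hi = 0, len(thresholds) - 1
    best = matching_at(thresholds[0])
    if best is None:
        raise ValueError("no perfect matching exists (should not happen on a full matrix)")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        m = matching_at(thresholds[mid])
        if m is not None:
            best, lo = m, mid
        else:
            hi = mid - 1
    pairs = sorted(
        tuple(sorted((labels[i], labels[j]), key=labels.index)) for i, j in best
    )
    return Grouping(pairs=[tuple(p) for p in pairs],
                    min_distance=float(min(dm.value(a, b) for a, b in pairs)))


def compare_distance_matrices(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of the vectorised strict upper triangles."""
    if d1.labels != d2.labels:
        raise ValueError("label mismatch")
    n = len(d1.labels)
    if n < 3:
        raise ValueError("need at least 3 proteins for a meaningful correlation")
    iu = np.triu_indices(n, k=1)
    from scipy.stats import pearsonr

    return float(pearsonr(d1.D[iu], d2.D[iu]).statistic)


def normalize_feature_space(fvs: FeatureVectorSet) -> FeatureVectorSet:
    """Scale all vectors by the maximum vector norm so the cloud fits in the
    unit ball.  Optional utility — not part of the default pairing path."""
    arrs, _ = fvs.all_vectors()
    max_norm = float(np.linalg.norm(arrs, axis=1).max())
    if max_norm == 0:
        return fvs
    return FeatureVectorSet({l: v / max_norm for l, v in fvs.items()})


def embed_2d(fvs: FeatureVectorSet, seed: int = 0, perplexity: float | None = None):
    """t-SNE layout of all feature vectors, for visualization only.

    Returns ``(coords, labels)``; pairing never consumes this output.
    """
    from sklearn.manifold import TSNE

    X, labels = fvs.all_vectors()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if perplexity is None:
        perplexity = max(min(30.0, (X.shape[0] - 1) / 3.0), 1.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(X), labels
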