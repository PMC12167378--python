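"""Unmixing performance metrics.

Per-channel SSIM and Pearson correlation against ground truth, the
cross-similarity-normalized variants

    normalized SSIM = (SSIM(x_A, y_A) + SSIM(x_B, y_B)) / (2 (1 + SSIM(y_A, y_B)))

(and the PCC analogue), patch-wise evaluation over non-overlapping 3D
tiles, and the distance-versus-performance correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .volume import VolumeStack, tile_nonoverlapping

__all__ = [
    "ssim",
    "pcc",
    "normalized_ssim",
    "normalized_pcc",
    "PairEvaluation",
    "evaluate_pair",
    "distance_performance_correlation",
    "paired_grouping_test",
]

SSIM_WIN = 7
SSIM_K1, SSIM_K2 = 0.01, 0.03


def _as_array(x) -> np.ndarray:
    if isinstance(x, VolumeStack):
        x = x.data
    return np.asarray(x, dtype=np.float64)


def ssim(x, y, data_range: float | None = None) -> float:
    """Structural similarity between two equally shaped volumes (or planes).

    Computed with a 7-voxel window per axis and stabilizers K1=0.01,
    K2=0.03; the data range defaults to the joint range of both inputs.
    Symmetric and equal to 1 for identical inputs.
    """
    xa, ya = _as_array(x), _as_array(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {ya.shape}")
    win = min(SSIM_WIN, *[s if s % 2 else s - 1 for s in xa.shape])
    if win < 3:
        raise ValueError(f"volume {xa.shape} too small for an SSIM window")
    if data_range is None:
        lo = min(xa.min(), ya.min())
        hi = max(xa.max(), ya.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(
        structural_similarity(
            xa, ya, win_size=win, data_range=data_range, K1=SSIM_K1, K2=SSIM_K2
        )
    )


def pcc(x, y) -> float:
    """Pearson correlation over all voxels; errors on zero variance."""
    xa, ya = _as_array(x).ravel(), _as_array(y).ravel()
    if xa.shape != ya.shape:
        raise ValueError("shape mismatch")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)


def normalized_ssim(xA, xB, yA, yB) -> float:
    """Cross-similarity-normalized SSIM of an unmixed pair."""
    return (ssim(xA, yA) + ssim(xB, yB)) / (2.0 * (1.0 + ssim(yA, yB)))


def normalized_pcc(xA, xB, yA, yB) -> float:
    """Cross-similarity-normalized PCC of an unmixed pair."""
    return (pcc(xA, yA) + pcc(xB, yB)) / (2.0 * (1.0 + pcc(yA, yB)))


@dataclass
class PairEvaluation:
    """Tile-wise unmixing metrics for one protein pair.

    ``table`` has one row per tile; aggregates average the two channels per
    tile first ("individual performance metrics ... averaged"), then take
    mean/median over tiles.  Zero-variance tiles are excluded from PCC
    aggregation and counted in ``n_degenerate_pcc``.
    """

    table: "object"  # pandas DataFrame
    mean_ssim: float
    median_ssim: float
    mean_pcc: float
    median_pcc: float
    mean_norm_ssim: float
    mean_norm_pcc: float
    n_degenerate_pcc: int = 0

    def summary(self) -> str:
        return "\n".join([
            "Unmixing evaluation",
            "=" * 30,
            f"tiles:               {len(self.table)}",
            f"mean SSIM:           {self.mean_ssim:.4f}",
            f"median SSIM:         {self.median_ssim:.4f}",
            f"mean PCC:            {self.mean_pcc:.4f}",
            f"median PCC:          {self.median_pcc:.4f}",
            f"mean norm. SSIM:     {self.mean_norm_ssim:.4f}",
            f"mean norm. PCC:      {self.mean_norm_pcc:.4f}",
            f"degenerate PCC tiles: {self.n_degenerate_pcc}",
        ])


def evaluate_pair(
    unmixed_alpha, unmixed_beta, truth_alpha, truth_beta, n_tiles: int = 16,
    pair_name: str = "",
) -> PairEvaluation:
    """Tile all four volumes into ``n_tiles`` non-overlapping 3D patches and
    score each tile independently."""
    import pandas as pd

    vols = []
    for v in (unmixed_alpha, unmixed_beta, truth_alpha, truth_beta):
        if not isinstance(v, VolumeStack):
            v = VolumeStack(np.asarray(v, dtype=np.float32))
        vols.append(v)
    shape = vols[0].shape
    if any(v.shape != shape for v in vols[1:]):
        raise ValueError("all four volumes must share a shape")
    tiles = [tile_nonoverlapping(v, n_tiles) for v in vols]
    rows = []
    n_degenerate = 0
    for k, (xa, xb, ya, yb) in enumerate(zip(*tiles)):
        row = {"pair": pair_name, "tile": k}
        row["ssim_a"] = ssim(xa, ya)
        row["ssim_b"] = ssim(xb, yb)
        row["cross_ssim"] = ssim(ya, yb)
        row["norm_ssim"] = (row["ssim_a"] + row["ssim_b"]) / (
            2.0 * (1.0 + row["cross_ssim"])
        )
        try:
            row["pcc_a"] = pcc(xa, ya)
            row["pcc_b"] = pcc(xb, yb)
            row["cross_pcc"] = pcc(ya, yb)
            row["norm_pcc"] = (row["pcc_a"] + row["pcc_b"]) / (
                2.0 * (1.0 + row["cross_pcc"])
            )
        except ValueError:
            n_degenerate += 1
            row["pcc_a"] = row["pcc_b"] = row["cross_pcc"] = row["norm_pcc"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    ssim_avg = (df["ssim_a"] + df["ssim_b"]) / 2.0
    pcc_avg = (df["pcc_a"] + df["pcc_b"]) / 2.0
    return PairEvaluation(
        table=df,
        mean_ssim=float(ssim_avg.mean()),
        median_ssim=float(ssim_avg.median()),
        mean_pcc=float(pcc_avg.mean(skipna=True)) if pcc_avg.notna().any() else np.nan,
        median_pcc=float(pcc_avg.median(skipna=True)) if pcc_avg.notna().any() else np.nan,
        mean_norm_ssim=float(df["norm_ssim"].mean()),
        mean_norm_pcc=float(df["norm_pcc"].mean(skipna=True))
        if df["norm_pcc"].notna().any() else np.nan,
        n_degenerate_pcc=n_degenerate,
    )


def distance_performance_correlation(distances, performances) -> float:
    """Pearson r between per-pair feature distances and unmixing scores."""
    d = np.asarray(distances, dtype=np.float64)
    p = np.asarray(performances, dtype=np.float64)
    if d.shape != p.shape:
        raise ValueError("length mismatch")
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(d) == 0 or np.ptp(p) == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(d, p).statistic)


def paired_grouping_test(perf_optimal, perf_alternative) -> tuple[float, float]:
    """Two-sided paired-sample t test, matched by protein.

    Returns ``(t, p)``.  Identical vectors are degenerate and return
    ``(0.0, 1.0)`` by convention; nonzero constant differences (zero
    variance) raise.
    """
    a = np.asarray(perf_optimal, dtype=np.float64)
    b = np.asarray(perf_alternative, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length vectors with >= 2 entries")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
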