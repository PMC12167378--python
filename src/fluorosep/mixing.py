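"""Synthetic linear mixing of registered single-protein volumes.

Separation networks are trained on synthetic mixtures ``c_α·I_α + c_β·I_β``
of percentile-normalized channels rather than on wet-lab co-stains, with
coefficients floored at 0.01 and their sum constrained to [0.8, 1.2] —
which spans relative brightness ratios up to (1.2 − 0.01)/0.01 = 119,
i.e. roughly 100-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume import VolumeStack, truncate_negative

__all__ = [
    "COEFF_MIN",
    "SUM_RANGE",
    "MixCoefficients",
    "TrainingExample",
    "sample_coefficients",
    "make_training_example",
    "simulate_brightness_sweep",
    "max_feasible_ratio",
]

COEFF_MIN = 0.01
SUM_RANGE = (0.8, 1.2)


@dataclass(frozen=True)
class MixCoefficients:
    """Blending coefficients for a two-protein synthetic mixture."""

    c_alpha: float
    c_beta: float
    in_window: bool = True  # False only for deliberate stress-test sweeps

    def __post_init__(self) -> None:
        if self.in_window:
            if self.c_alpha < COEFF_MIN or self.c_beta < COEFF_MIN:
                raise ValueError(f"coefficients must be >= {COEFF_MIN}")
            s = self.c_alpha + self.c_beta
            if not (SUM_RANGE[0] <= s <= SUM_RANGE[1]):
                raise ValueError(f"coefficient sum {s} outside {SUM_RANGE}")

    @property
    def ratio(self) -> float:
        return max(self.c_alpha, self.c_beta) / min(self.c_alpha, self.c_beta)


@dataclass
class TrainingExample:
    """One separation-training sample: mixed input plus truncated targets."""

    input: np.ndarray
    target_alpha: np.ndarray
    target_beta: np.ndarray
    coeffs: MixCoefficients


def sample_coefficients(rng: np.random.Generator) -> MixCoefficients:
    """Draw coefficients uniformly over the feasible polygon
    ``{c ≥ 0.01 componentwise, 0.8 ≤ c_α + c_β ≤ 1.2}`` by rejection."""
    hi = SUM_RANGE[1] - COEFF_MIN
    while True:
        ca = rng.uniform(COEFF_MIN, hi)
        cb = rng.uniform(COEFF_MIN, hi)
        if SUM_RANGE[0] <= ca + cb <= SUM_RANGE[1]:
            return MixCoefficients(float(ca), float(cb))


def make_training_example(
    volA: VolumeStack | np.ndarray,
    volB: VolumeStack | np.ndarray,
    coeffs: MixCoefficients,
) -> TrainingExample:
    """Blend two registered, already-normalized channels.

    The input is the exact linear combination (negative normalized values
    retained); the targets are the single channels with negatives truncated.
    """
    a = volA.data if isinstance(volA, VolumeStack) else np.asarray(volA)
    b = volB.data if isinstance(volB, VolumeStack) else np.asarray(volB)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a = a.astype(np.float32)
    b = b.astype(np.float32)
    mixed = coeffs.c_alpha * a + coeffs.c_beta * b
    return TrainingExample(
        input=mixed,
        target_alpha=np.maximum(a, 0),
        target_beta=np.maximum(b, 0),
        coeffs=coeffs,
    )


def max_feasible_ratio() -> float:
    """Largest brightness ratio the coefficient window permits:
    ``(1.2 − 0.01)/0.01 = 119``."""
    return (SUM_RANGE[1] - COEFF_MIN) / COEFF_MIN


def _coeffs_for_ratio(r: float) -> MixCoefficients:
    """Coefficients with c_β/c_α = r at unit sum, floored at 0.01.

    Ratios beyond the feasible window are generated anyway (flagged
    ``in_window=False``) for stress testing.
    """
    if r <= 0:
        raise ValueError("ratios must be positive")
    ca = 1.0 / (1.0 + r)
    cb = r / (1.0 + r)
    if min(ca, cb) >= COEFF_MIN:
        return MixCoefficients(float(ca), float(cb))
    # pin the small coefficient at the floor, keep the ratio exact
    if ca < cb:
        ca, cb = COEFF_MIN, COEFF_MIN * r
    else:
        cb, ca = COEFF_MIN, COEFF_MIN * r
    in_window = SUM_RANGE[0] <= ca + cb <= SUM_RANGE[1]
    return MixCoefficients(float(ca), float(cb), in_window=in_window)


def simulate_brightness_sweep(
    volA: VolumeStack | np.ndarray,
    volB: VolumeStack | np.ndarray,
    ratios: list[float],
) -> list[TrainingExample]:
    """One mixture per requested brightness ratio c_β/c_α."""
    return [make_training_example(volA, volB, _coeffs_for_ratio(r)) for r in ratios]
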