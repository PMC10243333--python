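"""Short-time / full-time frame-pair dataset construction and standardization.

A 10-minute dynamic acquisition of ten 1-minute frames yields one full-time
composite (the sum of all ten frames) and C(10, 2) = 45 distinct short-time
composites (each the sum of two frames, a 2-minute equivalent).  Every
2-subset is used, so a single case contributes 45 training pairs sharing
one target; a 109-case training split therefore contributes 4 905 pairs.

Standardization maps an image to zero mean and unit standard deviation
(population, divide-by-N).  For a training pair, the *input* image's
statistics standardize both input and target, which makes the roughly
five-fold count amplification between the 2-frame and 10-frame composites
a learnable, exactly invertible mapping: at inference the network output is
inverse-standardized with the input's parameters to return to count scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import DynamicSeries

__all__ = [
    "TrainingPair",
    "StandardizationParams",
    "enumerate_subsets",
    "build_pairs",
    "split_cases",
    "standardize",
    "inverse_standardize",
]


@dataclass
class StandardizationParams:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"standardization sd must be positive, got {self.sd}")


@dataclass
class TrainingPair:
    """One (2-frame-sum input, all-frame-sum target) pair of count images."""

    case_id: str
    frame_indices: tuple[int, int]
    short_time: np.ndarray
    full_time: np.ndarray


def enumerate_subsets(n_frames: int, k: int) -> list[tuple[int, ...]]:
    """All C(n_frames, k) unordered frame-index subsets, lexicographic."""
    if not 1 <= k <= n_frames:
        raise ValueError(f"need 1 <= k <= n_frames, got k={k}, n_frames={n_frames}")
    return list(combinations(range(n_frames), k))


def build_pairs(series: DynamicSeries, case_id: str, k: int = 2) -> list[TrainingPair]:
    """Build one TrainingPair per k-subset of frames.

    The full-time target (sum of all frames) is shared across the case's
    pairs; sums are exact integer additions so counts are preserved.
    """
    if series.n_frames < 2:
        raise ValueError("build_pairs needs a series with at least 2 frames")
    full = series.frame_sum()
    pairs = []
    for idx in enumerate_subsets(series.n_frames, k):
        pairs.append(
            TrainingPair(
                case_id=case_id,
                frame_indices=tuple(idx),
                short_time=series.frame_sum(idx),
                full_time=full,
            )
        )
    return pairs


def split_cases(
    case_ids: list[str],
    fractions: tuple[float, float, float] = (109 / 155, 23 / 155, 23 / 155),
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Seeded case-level partition into (train, validation, test).

    Split sizes are the rounded fractions with the remainder absorbed by
    the training split, so e.g. 155 cases at the default fractions give
    109/23/23.  Cases never span splits (no pair-level leakage).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    n = len(case_ids)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("fractions leave a negative split size")
    train = sorted(order[:n_train])
    val = sorted(order[n_train : n_train + n_val])
    test = sorted(order[n_train + n_val :])
    return train, val, test


def standardize(image: np.ndarray) -> tuple[np.ndarray, StandardizationParams]:
    """Zero-mean, unit-sd (population) standardization of one image."""
    image = np.asarray(image, dtype=float)
    mean = float(image.mean())
    sd = float(image.std())  # population (divide-by-N)
    if sd == 0:
        raise ValueError("cannot standardize a constant image (sd = 0)")
    return (image - mean) / sd, StandardizationParams(mean=mean, sd=sd)


def inverse_standardize(image: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Map a standardized image back to count scale."""
    return np.asarray(image, dtype=float) * params.sd + params.mean
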