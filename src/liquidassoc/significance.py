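"""Permutation null distributions, thresholds, empirical P values and FDR.

Genome-wide significance is judged against a reference distribution of
extreme LA scores under no linkage: in each permutation two null profiles
are built by resampling expression values (cells) from the whole matrix,
normal-score-transformed, and scored against every gene as conditioner; the
most positive and most negative scores are recorded. Tail quantiles of
these per-permutation extremes give score thresholds, and the same arrays
yield add-one empirical P values. The plug-in false discovery rate is
FDR = N p / D with N candidate pairs, P-value cutoff p and D discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, floor
from typing import Callable

import numpy as np

from .containers import DegenerateProfileError, ExpressionMatrix
from .preprocess import normal_quantile_transform

__all__ = [
    "ReferenceDistribution",
    "build_reference_distribution",
    "la_threshold",
    "permutation_p_value",
    "estimate_fdr",
    "local_permutation_p",
    "sample_cells",
    "sample_rows",
]

#: callable (rng, matrix) -> (x_raw, y_raw), each of length n_samples
NullSampler = Callable[[np.random.Generator, ExpressionMatrix], tuple[np.ndarray, np.ndarray]]


@dataclass
class ReferenceDistribution:
    """Per-permutation extreme LA scores under the no-linkage null.

    ``pos_extremes`` holds the most positive score of each permutation and
    ``neg_extremes`` the most negative; both are stored sorted ascending.
    """

    pos_extremes: np.ndarray
    neg_extremes: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.pos_extremes = np.sort(np.asarray(self.pos_extremes, dtype=float))
        self.neg_extremes = np.sort(np.asarray(self.neg_extremes, dtype=float))
        if len(self.pos_extremes) != self.n_permutations:
            raise ValueError("pos_extremes length must equal n_permutations")
        if len(self.neg_extremes) != self.n_permutations:
            raise ValueError("neg_extremes length must equal n_permutations")


def sample_cells(
    rng: np.random.Generator, matrix: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two null profiles by resampling cells from the whole matrix.

    Destroys gene identity while preserving the global expression-value
    distribution; profiles are drawn with replacement.
    """
    flat = matrix.values.ravel()
    m = matrix.n_samples
    return rng.choice(flat, size=m), rng.choice(flat, size=m)


def sample_rows(
    rng: np.random.Generator, matrix: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two random gene rows and independently permute their samples."""
    i, j = rng.choice(matrix.n_genes, size=2, replace=False)
    return (
        rng.permutation(matrix.values[i]),
        rng.permutation(matrix.values[j]),
    )


def _perm_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: independent of execution order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def build_reference_distribution(
    matrix: ExpressionMatrix,
    n_permutations: int,
    seed: int,
    sampler: NullSampler | str = "cells",
) -> ReferenceDistribution:
    """Build the no-linkage reference distribution of extreme LA scores.

    Per permutation, two null profiles X, Y are drawn by ``sampler``
    (default cell resampling), normal-score-transformed, and the LA score
    is computed against every gene row as Z; the maximum and minimum are
    recorded. Deterministic given ``seed``: each permutation uses its own
    counter-based random substream.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if matrix.n_genes < 3:
        raise ValueError("need at least 3 genes")
    if isinstance(sampler, str):
        sampler = {"cells": sample_cells, "rows": sample_rows}[sampler]
    m = matrix.n_samples
    pos = np.empty(n_permutations)
    neg = np.empty(n_permutations)
    for b in range(n_permutations):
        rng = _perm_rng(seed, b)
        for _attempt in range(100):
            x_raw, y_raw = sampler(rng, matrix)
            try:
                x = normal_quantile_transform(x_raw)
                y = normal_quantile_transform(y_raw)
                break
            except DegenerateProfileError:
                continue
        else:  # pragma: no cover - pathological constant matrix
            raise DegenerateProfileError("null sampler kept producing constant profiles")
        scores = matrix.values @ (x * y) / m
        pos[b] = scores.max()
        neg[b] = scores.min()
    return ReferenceDistribution(pos, neg, n_permutations, seed)


def la_threshold(
    ref: ReferenceDistribution, tail_quantile: float
) -> tuple[float, float]:
    """Tail-quantile score cutoffs from the reference distribution.

    Returns ``(pos_threshold, neg_threshold)``: the upper ``tail_quantile``
    point of the positive extremes and the lower ``tail_quantile`` point of
    the negative extremes, both as inverse-ECDF (type-1) order statistics
    so thresholds are bit-reproducible.
    """
    if not 0.0 < tail_quantile < 1.0:
        raise ValueError("tail_quantile must lie in (0, 1)")
    B = ref.n_permutations
    if B < 1:
        raise ValueError("empty reference distribution")
    if B < 1.0 / tail_quantile:
        warnings.warn(
            f"{B} permutations cannot resolve a {tail_quantile:g} tail; "
            "threshold is the extreme order statistic",
            stacklevel=2,
        )
    pos_idx = min(B - 1, floor(B * (1.0 - tail_quantile)))
    neg_idx = max(0, ceil(B * tail_quantile) - 1)
    return float(ref.pos_extremes[pos_idx]), float(ref.neg_extremes[neg_idx])


def permutation_p_value(score: float, ref: ReferenceDistribution) -> float:
    """Add-one empirical P value of a score against the reference extremes.

    Positive scores are compared against the positive extremes (count of
    extremes >= score), negative against the negative extremes (count of
    extremes <= score); ties count as exceedances. The add-one convention
    (1 + count)/(B + 1) keeps P values strictly positive.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    B = ref.n_permutations
    if score >= 0:
        count = B - int(np.searchsorted(ref.pos_extremes, score, side="left"))
    else:
        count = int(np.searchsorted(ref.neg_extremes, score, side="right"))
    return (1 + count) / (B + 1)


def estimate_fdr(
    n_pairs: int, p_cutoff: float, n_discoveries: int
) -> float | None:
    """Plug-in FDR = N p / D, capped at 1; None when there are no discoveries."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    if n_discoveries < 0:
        raise ValueError("n_discoveries must be >= 0")
    if n_discoveries == 0:
        return None
    return min(1.0, n_pairs * p_cutoff / n_discoveries)


def local_permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_perm: int,
    seed: int,
) -> float:
    """Local permutation P value: permute the conditioner, rescore, count.

    The sample order of z is permuted ``n_perm`` times and the LA score
    recomputed; the P value is the add-one fraction of permuted scores at
    least as extreme in magnitude as the observed score,
    (1 + #{|LA_perm| >= |LA_obs|}) / (n_perm + 1), which is uniform under
    the null for the sign-symmetric permutation distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    m = x.size
    observed = np.dot(x * y, z) / m
    rng = np.random.default_rng(seed)
    xy = x * y
    count = 0
    # batch permutations to bound memory at ~2k x m floats
    batch = 2048
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        perm_idx = np.argsort(rng.random((nb, m)), axis=1)
        perm_scores = xy[perm_idx] @ z / m
        count += int(np.sum(np.abs(perm_scores) >= abs(observed)))
        done += nb
    return (1 + count) / (n_perm + 1)
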