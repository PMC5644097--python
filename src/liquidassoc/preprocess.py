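"""Filtering, imputation and the rank-based normal score transformation.

Liquid association rests on the identity LA(X,Y|Z) = E(XYZ), which holds
when the conditioner is standard normal. Every profile is therefore mapped
to normal scores before any scoring: ranks are converted to plotting
positions (r - a)/(n + 1 - 2a) and passed through the standard-normal
quantile function. The offset ``a`` follows the classical convention of
a = 3/8 for n <= 10 (Blom) and a = 1/2 for larger n.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .containers import DegenerateProfileError, ExpressionMatrix, TraitVector

__all__ = [
    "filter_by_missing_rate",
    "impute_missing",
    "normal_quantile_transform",
    "transform_matrix",
    "transform_trait",
    "align_samples",
]


class NoGenesRetainedError(ValueError):
    """The missing-rate filter removed every gene."""


def filter_by_missing_rate(
    matrix: ExpressionMatrix, max_missing_fraction: float = 0.20
) -> ExpressionMatrix:
    """Keep genes whose fraction of missing entries is strictly below the cutoff.

    Parameters
    ----------
    matrix : ExpressionMatrix
    max_missing_fraction : float in [0, 1]
        Genes with missing fraction >= this value are dropped.

    Returns
    -------
    ExpressionMatrix
        Retained genes in their original order; samples unchanged.
    """
    if matrix.n_genes < 1 or matrix.n_samples < 1:
        raise ValueError("matrix must have at least one gene and one sample")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac < max_missing_fraction)
    if keep.size == 0:
        raise NoGenesRetainedError(
            f"no genes retained at max_missing_fraction={max_missing_fraction}"
        )
    return matrix.subset_genes(keep)


def impute_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing entry with the mean of that gene's observed values."""
    n_obs = (~matrix.missing_mask).sum(axis=1)
    empty = np.flatnonzero(n_obs == 0)
    if empty.size:
        names = ", ".join(matrix.gene_ids[i] for i in empty[:5])
        raise ValueError(f"gene(s) with no observed values: {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(matrix.values, axis=1)
    values = np.where(matrix.missing_mask, row_means[:, None], matrix.values)
    return matrix.copy_with(
        values=values, missing_mask=np.zeros_like(matrix.missing_mask)
    )


def _plotting_offset(n: int, a: float | None) -> float:
    if a is not None:
        return a
    return 3.0 / 8.0 if n <= 10 else 0.5


def normal_quantile_transform(v: np.ndarray, a: float | None = None) -> np.ndarray:
    """Map a complete numeric vector to mean-centred normal scores.

    Tie-averaged ranks r are converted to plotting positions
    (r - a)/(n + 1 - 2a) and through the standard-normal quantile; the
    result is then centred exactly at zero. For untied input the centring
    is a no-op (the plotting positions are symmetric about 1/2), so the
    output is the classical normal score; under ties it restores the
    mean-zero standardization the E(XYZ) identity presumes.

    Parameters
    ----------
    v : 1-D array, no missing values, length >= 2.
    a : float, optional
        Plotting-position offset. Default: 3/8 for n <= 10, 1/2 otherwise.

    Raises
    ------
    DegenerateProfileError
        If all values are identical (ranks carry no information).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values to transform")
    if np.isnan(v).any():
        raise ValueError("input contains missing values; impute first")
    if np.all(v == v[0]):
        raise DegenerateProfileError("degenerate profile: all values identical")
    offset = _plotting_offset(n, a)
    ranks = rankdata(v, method="average")
    scores = ndtri((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return scores - scores.mean()


def transform_matrix(matrix: ExpressionMatrix, a: float | None = None) -> ExpressionMatrix:
    """Normal-score transform every gene row of a complete matrix."""
    if matrix.missing_mask.any():
        raise ValueError("matrix contains missing values; run impute_missing first")
    out = np.empty_like(matrix.values)
    for i in range(matrix.n_genes):
        try:
            out[i] = normal_quantile_transform(matrix.values[i], a=a)
        except DegenerateProfileError as exc:
            raise DegenerateProfileError(
                f"gene {matrix.gene_ids[i]!r}: {exc}"
            ) from None
    return matrix.copy_with(values=out)


def transform_trait(trait: TraitVector, a: float | None = None) -> TraitVector:
    """Normal-score transform a trait with the same routine used for genes."""
    if trait.missing_mask.any():
        obs = ~trait.missing_mask
        values = trait.values.copy()
        values[~obs] = np.nanmean(trait.values)
        trait = TraitVector(
            sample_ids=list(trait.sample_ids), values=values, name=trait.name
        )
    return TraitVector(
        sample_ids=list(trait.sample_ids),
        values=normal_quantile_transform(trait.values, a=a),
        name=trait.name,
    )


def align_samples(
    matrix: ExpressionMatrix, trait: TraitVector
) -> tuple[ExpressionMatrix, TraitVector, int]:
    """Restrict matrix and trait to their shared samples (ID intersection).

    Returns the aligned pair plus the intersection size. Matrix sample
    order is preserved; the trait is reordered to match.
    """
    trait_pos = {s: i for i, s in enumerate(trait.sample_ids)}
    keep = [i for i, s in enumerate(matrix.sample_ids) if s in trait_pos]
    if not keep:
        raise ValueError("matrix and trait share no sample identifiers")
    mat = matrix.subset_samples(np.array(keep))
    order = [trait_pos[matrix.sample_ids[i]] for i in keep]
    tr = TraitVector(
        sample_ids=[trait.sample_ids[i] for i in order],
        values=trait.values[order],
        missing_mask=trait.missing_mask[order],
        name=trait.name,
    )
    return mat, tr, len(keep)
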