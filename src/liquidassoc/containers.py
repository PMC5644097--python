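"""In-memory containers for expression data, traits and triplet records.

The analysis operates on a gene x sample expression matrix (rows are genes,
columns are inbred lines / samples) and, optionally, a per-sample
quantitative trait. Missing values are carried explicitly as a boolean mask
alongside a float matrix that stores NaN at masked positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class DegenerateProfileError(ValueError):
    """A profile carries no rank information (all observed values equal)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with explicit missing-value mask.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Expression values; entries flagged in ``missing_mask`` hold NaN.
    missing_mask : ndarray of bool, same shape
        True where the value is missing. Defaults to ``isnan(values)``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")
            self.values = np.where(self.missing_mask, np.nan, self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def row(self, gene: int | str) -> np.ndarray:
        idx = gene if isinstance(gene, int) else self.gene_index(gene)
        return self.values[idx]

    def subset_genes(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in indices],
            sample_ids=list(self.sample_ids),
            values=self.values[indices].copy(),
            missing_mask=self.missing_mask[indices].copy(),
        )

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in indices],
            values=self.values[:, indices].copy(),
            missing_mask=self.missing_mask[:, indices].copy(),
        )

    def copy_with(self, **kwargs) -> "ExpressionMatrix":
        return replace(self, **kwargs)


@dataclass
class TraitVector:
    """Per-sample quantitative phenotype aligned to matrix samples by ID."""

    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trait values must be 1-D")
        if len(self.values) != len(self.sample_ids):
            raise ValueError("trait length does not match sample_ids")
        _check_unique(self.sample_ids, "sample")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")
            self.values = np.where(self.missing_mask, np.nan, self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TripletResult:
    """One scored (X, Y, Z) triplet.

    ``la`` is the mean triple product of the transformed profiles; the
    conditional correlations are Pearson r of (X, Y) within conditioner
    expression groups ordered low -> high. ``scout_id`` names the member
    designated as the LA-scouting gene by the binned MLA estimator.
    """

    x_id: str
    y_id: str
    z_id: str
    la: float
    r_xy: float = np.nan
    r_xz: float = np.nan
    r_yz: float = np.nan
    corr_low: float = np.nan
    corr_mid: float = np.nan
    corr_high: float = np.nan
    mla: float = np.nan
    scout_id: str | None = None
    p_value: float = np.nan

    RESULT_COLUMNS = (
        "x_id", "y_id", "z_id", "la", "r_xy", "r_xz", "r_yz",
        "corr_low", "corr_mid", "corr_high", "mla", "scout_id", "p_value",
    )

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in self.RESULT_COLUMNS)
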