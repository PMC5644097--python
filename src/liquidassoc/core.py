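"""Core triplet statistics: LA score, conditional correlations, MLA.

The LA score of a triplet (X, Y, Z) of normal-score-transformed profiles of
length m is the mean triple product sum(x_i y_i z_i)/m. With a standard-
normal conditioner it estimates E{g'(Z)} where g(z) = E(XY | Z=z), i.e. how
fast the co-expression of the pair changes along the conditioner.

The modified LA (MLA) replaces the conditional expectation with the
conditional correlation h(z) = rho(X1, X2 | X3 = z); by Stein's lemma
E{h'(X3)} = E{h(X3) X3}, estimated by binning on the conditioner:
sum over bins of (within-bin Pearson r) * (bin mean of X3), divided by the
number of bins (3 throughout). The member whose conditioner-role MLA has
the largest magnitude is designated the LA-scouting gene of the triplet.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "la_score",
    "la_scan_for_pair",
    "partition_by_rank",
    "conditional_correlations",
    "mla",
    "assign_scouting_gene",
    "pearson",
]


def _as_triplet(x, y, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D vectors of equal length")
    return x, y, z


def la_score(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Mean triple product (sum_i x_i y_i z_i)/m; symmetric in all arguments.

    Each sample's triple is multiplied in a canonical (value-sorted) order
    so the score is bit-identical under every argument permutation.
    """
    x, y, z = _as_triplet(x, y, z)
    m = x.size
    if m < 3:
        raise ValueError(f"need at least 3 samples, got {m}")
    p = np.sort(np.vstack((x, y, z)), axis=0)
    return float((p[0] * p[1] * p[2]).sum() / m)


def la_scan_for_pair(
    matrix: ExpressionMatrix, x_index: int, y_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """LA score of the pair (x_index, y_index) against every other gene as Z.

    Returns
    -------
    z_indices : int array of length n_genes - 2
    scores : float array, scores[k] = la_score(row x, row y, row z_indices[k])
    """
    g = matrix.n_genes
    for idx in (x_index, y_index):
        if not 0 <= idx < g:
            raise IndexError(f"gene index {idx} out of range for {g} genes")
    if x_index == y_index:
        raise ValueError("x_index and y_index must differ")
    z_indices = np.array([j for j in range(g) if j not in (x_index, y_index)])
    x = matrix.values[x_index]
    y = matrix.values[y_index]
    scores = np.array([la_score(x, y, matrix.values[j]) for j in z_indices])
    return z_indices, scores


def partition_by_rank(z: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign samples to ``n_groups`` equal-size (+-1) groups by ascending z.

    Ties are broken by stable input order; when m is not divisible by
    n_groups the lower groups receive the extra samples first. Returns an
    integer label per sample, 0 = lowest conditioner group.
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    order = np.argsort(z, kind="stable")
    base, rem = divmod(m, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    labels = np.empty(m, dtype=int)
    start = 0
    for grp, size in enumerate(sizes):
        labels[order[start:start + size]] = grp
        start += size
    return labels


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN if either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa = a - a.mean()
    sb = b - b.mean()
    denom = np.sqrt(np.dot(sa, sa) * np.dot(sb, sb))
    if denom == 0.0:
        return float("nan")
    return float(np.dot(sa, sb) / denom)


def conditional_correlations(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, n_groups: int = 3
) -> tuple[list[float], np.ndarray]:
    """Pearson r of (x, y) within conditioner-expression groups.

    Samples are split into ``n_groups`` equal-size (+-1) groups by ascending
    rank of z. Returns the per-group correlations ordered low -> high plus
    each sample's group label. A group with fewer than 3 samples yields NaN
    with a warning rather than an exception.
    """
    x, y, z = _as_triplet(x, y, z)
    if x.size < 2 * n_groups:
        raise ValueError("need at least 2 samples per group")
    labels = partition_by_rank(z, n_groups)
    corrs: list[float] = []
    for grp in range(n_groups):
        sel = labels == grp
        if sel.sum() < 3:
            warnings.warn(
                f"conditioner group {grp} has fewer than 3 samples; "
                "correlation reported as NaN",
                stacklevel=2,
            )
            corrs.append(float("nan"))
        else:
            corrs.append(pearson(x[sel], y[sel]))
    return corrs, labels


def mla(
    x1: np.ndarray, x2: np.ndarray, x3: np.ndarray, n_bins: int = 3
) -> float:
    """Binned MLA estimator: sum_i rho_i * mean(x3 in bin i) / n_bins.

    Bins partition the samples into ``n_bins`` equal-size (+-1) groups by
    ascending x3 (same partition rule as ``conditional_correlations``).
    """
    x1, x2, x3 = _as_triplet(x1, x2, x3)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    labels = partition_by_rank(x3, n_bins)
    total = 0.0
    for grp in range(n_bins):
        sel = labels == grp
        if sel.sum() < 3:
            raise ValueError(f"bin {grp} has fewer than 3 samples")
        rho = pearson(x1[sel], x2[sel])
        if np.isnan(rho):
            raise ValueError(
                f"bin {grp}: within-bin correlation undefined (constant profile)"
            )
        total += rho * x3[sel].mean()
    return total / n_bins


def assign_scouting_gene(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    ids: tuple[str, str, str],
    n_bins: int = 3,
) -> tuple[str, dict[str, float]]:
    """Designate the LA-scouting gene of a triplet by largest |MLA|.

    Each member takes the conditioner role in turn (the other two form the
    pair); the member whose conditioner-role MLA has the largest absolute
    value is the scout. Ties are broken by input order (first wins).

    Returns
    -------
    scout_id : str
    mla_by_role : dict mapping member id -> its conditioner-role MLA.
    """
    profiles = (x, y, z)
    mla_by_role: dict[str, float] = {}
    for k, cid in enumerate(ids):
        pair = [profiles[j] for j in range(3) if j != k]
        mla_by_role[cid] = mla(pair[0], pair[1], profiles[k], n_bins=n_bins)
    mags = [abs(mla_by_role[c]) for c in ids]
    best = int(np.argmax(mags))  # argmax keeps the first maximum
    if mags.count(max(mags)) > 1:
        logger.info("MLA tie among %s; keeping first in input order", ids)
    return ids[best], mla_by_role
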