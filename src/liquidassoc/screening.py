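"""Genome-wide triplet screening, post-hoc filters, leaders, network export.

``scan_all`` enumerates every unordered gene pair {X, Y} against every third
gene Z (C(g,2)*(g-2) combinations), keeps the triplets whose LA score
passes the permutation-derived positive or negative threshold, and
decorates the survivors with P values, pairwise and conditional
correlations, and the MLA scouting-gene designation.

Downstream filters follow the screening conventions: a "conditional" LAP is
a pair correlated only conditionally on its scout (|r_xy| below a cutoff
while |LA| is high), and a scouting "leader" is a gene designated scout in
at least a cutoff number of significant linkages of a given sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np

from .containers import ExpressionMatrix, TripletResult
from .core import assign_scouting_gene, conditional_correlations, pearson
from .significance import (
    ReferenceDistribution,
    build_reference_distribution,
    la_threshold,
    permutation_p_value,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "scan_all",
    "top_laps",
    "classify_conditional_laps",
    "count_linkages_per_scout",
    "select_leaders",
    "export_network",
]


@dataclass
class ScanConfig:
    """Tunable thresholds and scales of the genome-wide screen.

    Defaults mirror the screening conventions: 1e-5 tail quantile, top 1000
    LAPs, conditional filter |r| < 0.17 with |LA| > 0.60, and a leader
    cutoff of 5e5 linkages (meaningful at the ~25k-gene scale; scale it
    down for synthetic runs).
    """

    tail_quantile: float = 1e-5
    top_k_laps: int = 1000
    conditional_r_max: float = 0.17
    conditional_la_min: float = 0.60
    leader_min_linkages: int = 500_000
    n_permutations: int = 10_000
    seed: int = 0
    n_groups: int = 3
    n_bins: int = 3
    null_sampler: str = "cells"

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_quantile < 1.0:
            raise ValueError("tail_quantile must lie in (0, 1)")
        if self.conditional_r_max <= 0 or self.conditional_r_max >= 1:
            raise ValueError("conditional_r_max must lie in (0, 1)")
        if self.conditional_la_min <= 0:
            raise ValueError("conditional_la_min must be > 0")
        if self.leader_min_linkages < 1:
            raise ValueError("leader_min_linkages must be >= 1")
        if self.top_k_laps < 1:
            raise ValueError("top_k_laps must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _check_transformed(matrix: ExpressionMatrix, tol: float = 1e-6) -> None:
    worst = float(np.abs(matrix.values.mean(axis=1)).max())
    if worst > tol:
        raise ValueError(
            f"matrix does not look normal-score transformed (max |row mean| = "
            f"{worst:.3g}); transform first or pass allow_untransformed=True"
        )


def scan_all(
    matrix: ExpressionMatrix,
    config: ScanConfig,
    reference: ReferenceDistribution | None = None,
    allow_untransformed: bool = False,
) -> list[TripletResult]:
    """Score every (pair, conditioner) combination and keep significant triplets.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normal-score transformed (checked via row means unless overridden).
    config : ScanConfig
    reference : ReferenceDistribution, optional
        Prebuilt null; built from ``config`` when omitted.
    allow_untransformed : bool
        Skip the standardization check.

    Returns
    -------
    list of TripletResult sorted by descending |LA|.
    """
    if not allow_untransformed:
        _check_transformed(matrix)
    g, m = matrix.n_genes, matrix.n_samples
    n_comb = comb(g, 2) * (g - 2)
    logger.info("scanning %d genes: %d (pair, conditioner) combinations", g, n_comb)
    if reference is None:
        reference = build_reference_distribution(
            matrix, config.n_permutations, config.seed, sampler=config.null_sampler
        )
    pos_thr, neg_thr = la_threshold(reference, config.tail_quantile)

    V = matrix.values
    results: list[TripletResult] = []
    for i in range(g - 1):
        # all pairs (i, j>i) against all conditioners in one matmul
        block = (V[i + 1:] * V[i]) @ V.T / m  # (g-i-1, g)
        hit_rows, hit_cols = np.nonzero((block >= pos_thr) | (block <= neg_thr))
        for r, zc in zip(hit_rows, hit_cols):
            j = i + 1 + r
            if zc == i or zc == j:
                continue
            results.append(
                _decorate_triplet(matrix, i, j, int(zc), float(block[r, zc]),
                                  reference, config)
            )
    results.sort(key=lambda t: (-abs(t.la), t.x_id, t.y_id, t.z_id))
    logger.info("%d significant triplets (pos_thr=%.4f, neg_thr=%.4f)",
                len(results), pos_thr, neg_thr)
    return results


def _decorate_triplet(
    matrix: ExpressionMatrix,
    i: int,
    j: int,
    k: int,
    la: float,
    reference: ReferenceDistribution,
    config: ScanConfig,
) -> TripletResult:
    x, y, z = matrix.values[i], matrix.values[j], matrix.values[k]
    ids = (matrix.gene_ids[i], matrix.gene_ids[j], matrix.gene_ids[k])
    corrs, _ = conditional_correlations(x, y, z, n_groups=config.n_groups)
    scout, mla_by_role = assign_scouting_gene(x, y, z, ids, n_bins=config.n_bins)
    return TripletResult(
        x_id=ids[0], y_id=ids[1], z_id=ids[2],
        la=la,
        r_xy=pearson(x, y), r_xz=pearson(x, z), r_yz=pearson(y, z),
        corr_low=corrs[0],
        corr_mid=corrs[len(corrs) // 2] if len(corrs) > 2 else float("nan"),
        corr_high=corrs[-1],
        mla=mla_by_role[scout],
        scout_id=scout,
        p_value=permutation_p_value(la, reference),
    )


def top_laps(results: list[TripletResult], k: int) -> list[TripletResult]:
    """Top-k LA pairs by |LA|, keeping each unordered pair's best triplet."""
    best: dict[tuple[str, str], TripletResult] = {}
    for t in results:
        key = tuple(sorted((t.x_id, t.y_id)))
        if key not in best or abs(t.la) > abs(best[key].la):
            best[key] = t
    ranked = sorted(best.values(), key=lambda t: (-abs(t.la), t.x_id, t.y_id))
    return ranked[:k]


def classify_conditional_laps(
    results: list[TripletResult], r_max: float = 0.17, la_min: float = 0.60
) -> list[TripletResult]:
    """Triplets whose pair is correlated only conditionally: |r_xy| < r_max and |LA| > la_min.

    Both conditions are applied to magnitudes; the signed values remain on
    the records.
    """
    return [t for t in results if abs(t.r_xy) < r_max and abs(t.la) > la_min]


def count_linkages_per_scout(
    results: list[TripletResult],
) -> dict[str, tuple[int, int]]:
    """Count significant triplets per scouting gene, split by LA sign."""
    counts: dict[str, list[int]] = {}
    for t in results:
        pos, neg = counts.setdefault(t.scout_id, [0, 0])
        if t.la >= 0:
            counts[t.scout_id][0] = pos + 1
        else:
            counts[t.scout_id][1] = neg + 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def select_leaders(
    counts: dict[str, tuple[int, int]], min_linkages: int, sign: str
) -> list[str]:
    """Scouting genes with at least ``min_linkages`` linkages of the given sign.

    ``sign`` is "positive" or "negative"; the cutoff is inclusive. Sorted
    by descending count, ties by gene id for determinism.
    """
    if min_linkages < 1:
        raise ValueError("min_linkages must be >= 1")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    idx = 0 if sign == "positive" else 1
    hits = [(gid, c[idx]) for gid, c in counts.items() if c[idx] >= min_linkages]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [gid for gid, _ in hits]


def export_network(
    results: list[TripletResult], focus_genes: list[str] | None = None
) -> tuple[list[tuple[str, str, float, float]], int, int]:
    """Edge list (x_id, z_id, la, p_value) for a focus-gene regulatory network.

    Restricted to results whose X is a focus gene (all results when
    ``focus_genes`` is None); duplicated (x_id, z_id) edges keep the
    largest |LA|.

    Returns
    -------
    edges, n_nodes, n_edges
    """
    if focus_genes is not None:
        focus = set(focus_genes)
        results = [t for t in results if t.x_id in focus]
    best: dict[tuple[str, str], TripletResult] = {}
    for t in results:
        key = (t.x_id, t.z_id)
        if key not in best or abs(t.la) > abs(best[key].la):
            best[key] = t
    edges = sorted(
        ((t.x_id, t.z_id, t.la, t.p_value) for t in best.values()),
        key=lambda e: (e[0], e[1]),
    )
    nodes = {e[0] for e in edges} | {e[1] for e in edges}
    return edges, len(nodes), len(edges)
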