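"""Gene-trait liquid association: a quantitative phenotype in the Y role.

Each candidate gene's transformed profile is X, the normal-score
transformed trait is Y, and every other gene is screened as conditioner Z.
Significance uses a local permutation of the conditioner's sample order
(the genome-wide extreme-value null is far stricter than needed inside one
pathway). A retained triplet is labelled co-regulated when LA > 0 (the
gene-trait correlation strengthens as the mediator rises) and
contra-regulated when LA < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, TraitVector
from .core import conditional_correlations, la_score, pearson
from .preprocess import align_samples, normal_quantile_transform

__all__ = ["TraitLaResult", "gene_trait_la", "summarize_regulation"]

MIN_SHARED_SAMPLES = 30


@dataclass
class TraitLaResult:
    """One retained gene-trait triplet (candidate X, trait Y, mediator Z)."""

    gene_id: str
    trait_name: str
    z_id: str
    la: float
    p_value: float
    corr_gene_trait: float
    corr_low: float
    corr_high: float
    regulation: str  # "co-regulated" (la > 0) or "contra-regulated"

    RESULT_COLUMNS = (
        "gene_id", "trait_name", "z_id", "la", "p_value",
        "corr_gene_trait", "corr_low", "corr_high", "regulation",
    )

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in self.RESULT_COLUMNS)


def _candidate_perm_rng(seed: int, cand_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cand_index,))
    )


def gene_trait_la(
    matrix: ExpressionMatrix,
    candidate_ids: list[str],
    trait: TraitVector,
    p_cutoff: float = 1e-4,
    n_perm: int = 10_000,
    seed: int = 0,
    n_groups: int = 3,
    return_all: bool = False,
) -> list[TraitLaResult]:
    """Screen all genes as mediators of each candidate's trait association.

    The matrix and trait are aligned on the intersection of sample IDs,
    then every profile and the trait are normal-score transformed on the
    aligned samples. For each candidate X and every other gene Z the LA
    score la_score(X, trait, Z) is computed; triplets with local
    permutation P value <= ``p_cutoff`` are retained (one shared set of
    ``n_perm`` conditioner permutations per candidate, seeded by a
    counter-based substream of ``seed``).

    Parameters
    ----------
    matrix : ExpressionMatrix
        Complete (imputed) expression matrix; raw or already transformed —
        profiles are (re)transformed on the aligned samples either way.
    candidate_ids : list of gene identifiers present in the matrix.
    trait : TraitVector
    p_cutoff : float
        Local-permutation P value cutoff (default 1e-4).
    return_all : bool
        Return every scored triplet instead of only those passing p_cutoff.

    Returns
    -------
    list of TraitLaResult sorted by descending |LA|.
    """
    missing = [c for c in candidate_ids if c not in set(matrix.gene_ids)]
    if missing:
        raise KeyError(f"candidate gene(s) not in matrix: {', '.join(missing)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    mat, tr, n_shared = align_samples(matrix, trait)
    if n_shared < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"only {n_shared} shared samples; need >= {MIN_SHARED_SAMPLES} "
            "for stable correlation estimates"
        )
    m = n_shared
    V = np.empty_like(mat.values)
    for i in range(mat.n_genes):
        V[i] = normal_quantile_transform(mat.values[i])
    t = normal_quantile_transform(tr.values)

    results: list[TraitLaResult] = []
    for ci, cand in enumerate(candidate_ids):
        xi = mat.gene_index(cand)
        x = V[xi]
        w = x * t
        rng = _candidate_perm_rng(seed, ci)
        # one permutation set shared by every Z of this candidate:
        # permuting Z's sample order is equivalent to permuting x*trait
        perm_idx = np.argsort(rng.random((n_perm, m)), axis=1)
        perm_scores = w[perm_idx] @ V.T / m  # (n_perm, n_genes)
        abs_perm = np.abs(perm_scores)
        for zi in range(mat.n_genes):
            if zi == xi:
                continue
            la = la_score(x, t, V[zi])
            p = (1 + int(np.sum(abs_perm[:, zi] >= abs(la)))) / (n_perm + 1)
            if not return_all and p > p_cutoff:
                continue
            corrs, _ = conditional_correlations(x, t, V[zi], n_groups=n_groups)
            results.append(
                TraitLaResult(
                    gene_id=cand,
                    trait_name=tr.name,
                    z_id=mat.gene_ids[zi],
                    la=la,
                    p_value=p,
                    corr_gene_trait=pearson(x, t),
                    corr_low=corrs[0],
                    corr_high=corrs[-1],
                    regulation="co-regulated" if la > 0 else "contra-regulated",
                )
            )
    results.sort(key=lambda r: (-abs(r.la), r.gene_id, r.z_id))
    return results


def summarize_regulation(
    results: list[TraitLaResult],
) -> tuple[int, int, int, int]:
    """Tally candidates by regulation polarity.

    Returns
    -------
    (n_co_genes, n_contra_genes, n_both, n_unique_scouts) :
        distinct candidate genes with at least one co-regulated hit, with
        at least one contra-regulated hit, with both, and the number of
        distinct mediator (Z) genes across all results.
    """
    co = {r.gene_id for r in results if r.regulation == "co-regulated"}
    contra = {r.gene_id for r in results if r.regulation == "contra-regulated"}
    scouts = {r.z_id for r in results}
    return len(co), len(contra), len(co & contra), len(scouts)
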