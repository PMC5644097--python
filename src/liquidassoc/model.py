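"""Model/Results objects presenting the screen in a fit-then-inspect style.

``LiquidAssociationScan`` wraps preprocessing + permutation null + the
genome-wide triplet scan; its ``fit()`` returns a ``LAScanResults`` object
carrying the significant triplets, thresholds, leader counts and a
``summary()`` table. ``GeneTraitLA`` does the same for the trait-in-the-
Y-role analysis, and ``LiquidAssociationTriplet`` fits a single triplet
(LA, MLA per role, conditional correlations, local permutation P value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitVector, TripletResult
from .core import assign_scouting_gene, conditional_correlations, la_score, pearson
from .preprocess import (
    filter_by_missing_rate,
    impute_missing,
    transform_matrix,
)
from .screening import (
    ScanConfig,
    classify_conditional_laps,
    count_linkages_per_scout,
    export_network,
    scan_all,
    select_leaders,
    top_laps,
)
from .significance import (
    ReferenceDistribution,
    build_reference_distribution,
    estimate_fdr,
    la_threshold,
    local_permutation_p,
)
from .trait import TraitLaResult, gene_trait_la, summarize_regulation

__all__ = [
    "LiquidAssociationScan",
    "LAScanResults",
    "GeneTraitLA",
    "GeneTraitResults",
    "LiquidAssociationTriplet",
    "TripletFit",
]


def _results_frame(results: list[TripletResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [t.as_tuple() for t in results], columns=list(TripletResult.RESULT_COLUMNS)
    )


class LiquidAssociationScan:
    """Genome-wide liquid-association screen over an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Raw matrix; genes failing the missing-rate filter are dropped,
        remaining gaps mean-imputed, and every profile normal-score
        transformed. Pass ``preprocessed=True`` to skip all three steps.
    config : ScanConfig, optional
    max_missing_fraction : float
        Missing-rate filter cutoff (strict "<", default 0.20).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        config: ScanConfig | None = None,
        max_missing_fraction: float = 0.20,
        preprocessed: bool = False,
    ) -> None:
        self.config = config or ScanConfig()
        self.n_genes_input = matrix.n_genes
        if preprocessed:
            self.matrix = matrix
        else:
            filtered = filter_by_missing_rate(matrix, max_missing_fraction)
            self.matrix = transform_matrix(impute_missing(filtered))
        self.n_genes_retained = self.matrix.n_genes

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "LiquidAssociationScan":
        from .io import read_expression_matrix

        return cls(read_expression_matrix(path), **kwargs)

    def build_reference(self) -> ReferenceDistribution:
        return build_reference_distribution(
            self.matrix,
            self.config.n_permutations,
            self.config.seed,
            sampler=self.config.null_sampler,
        )

    def fit(self, reference: ReferenceDistribution | None = None) -> "LAScanResults":
        """Build the null (unless given), scan all triplets, package results."""
        if reference is None:
            reference = self.build_reference()
        triplets = scan_all(self.matrix, self.config, reference=reference)
        return LAScanResults(self, reference, triplets)


class LAScanResults:
    """Significant triplets plus the null and the post-hoc filter chain."""

    def __init__(
        self,
        model: LiquidAssociationScan,
        reference: ReferenceDistribution,
        triplets: list[TripletResult],
    ) -> None:
        self.model = model
        self.config = model.config
        self.reference = reference
        self.triplets = triplets
        self.pos_threshold, self.neg_threshold = la_threshold(
            reference, model.config.tail_quantile
        )

    @property
    def frame(self) -> pd.DataFrame:
        return _results_frame(self.triplets)

    def top_laps(self, k: int | None = None) -> list[TripletResult]:
        return top_laps(self.triplets, k or self.config.top_k_laps)

    def conditional_laps(self) -> list[TripletResult]:
        return classify_conditional_laps(
            self.top_laps(),
            r_max=self.config.conditional_r_max,
            la_min=self.config.conditional_la_min,
        )

    def linkage_counts(self) -> dict[str, tuple[int, int]]:
        return count_linkages_per_scout(self.triplets)

    def leaders(self, sign: str, min_linkages: int | None = None) -> list[str]:
        return select_leaders(
            self.linkage_counts(),
            min_linkages or self.config.leader_min_linkages,
            sign,
        )

    def network(self, focus_genes: list[str] | None = None):
        return export_network(self.triplets, focus_genes)

    def fdr(self) -> float | None:
        """Plug-in FDR = N p / D with N scanned pairs, D significant pairs."""
        g = self.model.matrix.n_genes
        n_pairs = g * (g - 1) // 2
        sig_pairs = {tuple(sorted((t.x_id, t.y_id))) for t in self.triplets}
        return estimate_fdr(n_pairs, self.config.tail_quantile, len(sig_pairs))

    def stage_counts(self) -> dict[str, int]:
        return {
            "genes_input": self.model.n_genes_input,
            "genes_retained": self.model.n_genes_retained,
            "samples": self.model.matrix.n_samples,
            "n_permutations": self.reference.n_permutations,
            "triplets_significant": len(self.triplets),
            "laps_top_k": len(self.top_laps()),
            "laps_conditional": len(self.conditional_laps()),
            "leaders_positive": len(self.leaders("positive")),
            "leaders_negative": len(self.leaders("negative")),
        }

    def summary(self) -> str:
        c = self.stage_counts()
        fdr = self.fdr()
        lines = [
            "Liquid association scan",
            "=" * 56,
            f"genes (input -> retained)   {c['genes_input']} -> {c['genes_retained']}",
            f"samples                     {c['samples']}",
            f"permutations                {c['n_permutations']}",
            f"tail quantile               {self.config.tail_quantile:g}",
            f"LA thresholds (pos, neg)    {self.pos_threshold:.4f}, {self.neg_threshold:.4f}",
            f"significant triplets        {c['triplets_significant']}",
            f"top-{self.config.top_k_laps} LAPs                {c['laps_top_k']}",
            f"conditional LAPs (|r|<{self.config.conditional_r_max:g}, |LA|>{self.config.conditional_la_min:g})"
            f"  {c['laps_conditional']}",
            f"leaders (pos, neg) at >={self.config.leader_min_linkages}  "
            f"{c['leaders_positive']}, {c['leaders_negative']}",
            f"plug-in FDR                 {'NA' if fdr is None else format(fdr, '.4g')}",
        ]
        if self.triplets:
            lines += ["", "top triplets by |LA|:",
                      self.frame.head(10).to_string(index=False)]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_results

        write_results(self.triplets, path)


class GeneTraitLA:
    """Gene-trait liquid association model (trait in the Y role)."""

    def __init__(
        self,
        matrix: ExpressionMatrix,
        trait: TraitVector,
        candidate_ids: list[str],
        p_cutoff: float = 1e-4,
        n_perm: int = 10_000,
        seed: int = 0,
    ) -> None:
        self.matrix = matrix
        self.trait = trait
        self.candidate_ids = list(candidate_ids)
        self.p_cutoff = p_cutoff
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, return_all: bool = False) -> "GeneTraitResults":
        results = gene_trait_la(
            self.matrix,
            self.candidate_ids,
            self.trait,
            p_cutoff=self.p_cutoff,
            n_perm=self.n_perm,
            seed=self.seed,
            return_all=return_all,
        )
        return GeneTraitResults(self, results)


class GeneTraitResults:
    def __init__(self, model: GeneTraitLA, results: list[TraitLaResult]) -> None:
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.as_tuple() for r in self.results],
            columns=list(TraitLaResult.RESULT_COLUMNS),
        )

    def regulation_summary(self) -> tuple[int, int, int, int]:
        return summarize_regulation(self.results)

    def summary(self) -> str:
        n_co, n_contra, n_both, n_scouts = self.regulation_summary()
        lines = [
            "Gene-trait liquid association",
            "=" * 56,
            f"candidates screened         {len(self.model.candidate_ids)}",
            f"local permutations          {self.model.n_perm}",
            f"P cutoff                    {self.model.p_cutoff:g}",
            f"retained triplets           {len(self.results)}",
            f"co-regulated genes          {n_co}",
            f"contra-regulated genes      {n_contra}",
            f"both polarities             {n_both}",
            f"distinct mediators (Z)      {n_scouts}",
        ]
        if self.results:
            lines += ["", "top mediators by |LA|:",
                      self.frame.head(10).to_string(index=False)]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_trait_results

        write_trait_results(self.results, path)


class LiquidAssociationTriplet:
    """A single (X, Y, Z) triplet of transformed profiles."""

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        z: np.ndarray,
        ids: tuple[str, str, str] = ("X", "Y", "Z"),
    ) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.ids = ids

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> "TripletFit":
        la = la_score(self.x, self.y, self.z)
        corrs, _ = conditional_correlations(self.x, self.y, self.z)
        scout, mla_by_role = assign_scouting_gene(self.x, self.y, self.z, self.ids)
        p = local_permutation_p(self.x, self.y, self.z, n_perm=n_perm, seed=seed)
        return TripletFit(
            ids=self.ids,
            la=la,
            r_xy=pearson(self.x, self.y),
            corr_low=corrs[0],
            corr_mid=corrs[len(corrs) // 2],
            corr_high=corrs[-1],
            mla_by_role=mla_by_role,
            scout_id=scout,
            p_value=p,
            n_perm=n_perm,
        )


class TripletFit:
    def __init__(self, ids, la, r_xy, corr_low, corr_mid, corr_high,
                 mla_by_role, scout_id, p_value, n_perm) -> None:
        self.ids = ids
        self.la = la
        self.r_xy = r_xy
        self.corr_low = corr_low
        self.corr_mid = corr_mid
        self.corr_high = corr_high
        self.mla_by_role = mla_by_role
        self.scout_id = scout_id
        self.p_value = p_value
        self.n_perm = n_perm

    def summary(self) -> str:
        x_id, y_id, z_id = self.ids
        mla_txt = ", ".join(f"{k}: {v:+.4f}" for k, v in self.mla_by_role.items())
        return "\n".join([
            f"Triplet ({x_id}, {y_id} | {z_id})",
            "=" * 56,
            f"LA score                    {self.la:+.4f}",
            f"overall corr(X, Y)          {self.r_xy:+.4f}",
            f"corr by conditioner group   low {self.corr_low:+.4f}  "
            f"mid {self.corr_mid:+.4f}  high {self.corr_high:+.4f}",
            f"MLA by conditioner role     {mla_txt}",
            f"LA-scouting gene            {self.scout_id}",
            f"local permutation P         {self.p_value:.4g}  ({self.n_perm} permutations)",
        ])
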