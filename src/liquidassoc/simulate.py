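"""Synthetic expression data with planted conditioner-dependent correlation.

The generator emulates the data regime the screen is designed for: a few
hundred inbred lines, Gaussian normal-score-like profiles, per-gene missing
values, a sea of null genes, and planted triplets in which the correlation
of a pair (X, Y) varies monotonically with a conditioner Z through a
bounded odd link, corr(X, Y | Z = z) = tanh(theta * z). Because the link
is odd and Z is standard normal, the *overall* correlation of a planted
pair is near zero — the pair is correlated only conditionally, which is
exactly the signature the screen hunts for. The theoretical LA of a
planted triplet, E[tanh(theta Z) Z], is computed by Gauss-Hermite
quadrature against the standard-normal density.

Construction of a planted triplet: z, w, e ~ iid N(0, 1),
x = w, y = tanh(theta z) w + sqrt(1 - tanh^2(theta z)) e, so that
corr(x, y | z) = tanh(theta z) exactly and all marginals are standard
normal. The trait generator plays the same game with the trait in the Y
role; with several mediators for one gene the link is the mediator-average
of the tanh terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitVector

__all__ = [
    "PlantedTripletSpec",
    "theoretical_la",
    "generate_la_dataset",
    "generate_trait_dataset",
]

def theoretical_la(theta: float) -> float:
    """E[tanh(theta Z) Z] for standard-normal Z, by quadrature.

    Adaptive quadrature on the half line (the integrand is even): robust
    even for large theta, where tanh(theta z) z approaches the kinked |z|.
    """
    from scipy.integrate import quad

    val, _ = quad(
        lambda z: np.tanh(theta * z) * z * np.exp(-0.5 * z * z), 0.0, np.inf
    )
    return float(2.0 * val / np.sqrt(2.0 * np.pi))


@dataclass
class PlantedTripletSpec:
    """Ground truth for one planted triplet.

    ``y_index`` is -1 for gene-trait triplets (the trait plays Y).
    """

    x_index: int
    y_index: int
    z_index: int
    theta: float
    kind: str = "gene-gene"  # or "gene-trait"
    theoretical_la: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        members = [self.x_index, self.z_index]
        if self.kind == "gene-gene":
            members.append(self.y_index)
        if len(set(members)) != len(members):
            raise ValueError("planted triplet member indices must be distinct")
        if self.theoretical_la is None:
            self.theoretical_la = theoretical_la(self.theta)


def _truth_frame(specs: list[PlantedTripletSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_index": s.x_index,
                "y_index": s.y_index,
                "z_index": s.z_index,
                "theta": s.theta,
                "kind": s.kind,
                "theoretical_la": s.theoretical_la,
            }
            for s in specs
        ],
        columns=["x_index", "y_index", "z_index", "theta", "kind", "theoretical_la"],
    )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"L{i:0{width}d}" for i in range(n)]


def _apply_missingness(
    values: np.ndarray, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if missing_rate == 0.0:
        return values
    mask = rng.random(values.shape) < missing_rate
    # keep every gene estimable: never blank an entire row
    full_rows = mask.all(axis=1)
    mask[full_rows, 0] = False
    out = values.copy()
    out[mask] = np.nan
    return out


def _plant_triplet(
    values: np.ndarray, spec: PlantedTripletSpec, rng: np.random.Generator
) -> None:
    m = values.shape[1]
    z = rng.standard_normal(m)
    w = rng.standard_normal(m)
    e = rng.standard_normal(m)
    c = np.tanh(spec.theta * z)
    values[spec.x_index] = w
    values[spec.y_index] = c * w + np.sqrt(1.0 - c**2) * e
    values[spec.z_index] = z


def generate_la_dataset(
    n_genes: int,
    n_samples: int = 368,
    planted: list[PlantedTripletSpec] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression matrix of null genes plus planted gene-gene triplets.

    Background genes are i.i.d. standard normal. Missing entries are
    inserted completely at random at ``missing_rate``.

    Returns
    -------
    matrix : ExpressionMatrix
    truth : DataFrame with one row per planted triplet (member indices,
        theta, quadrature theoretical LA).
    """
    planted = planted or []
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    used: set[int] = set()
    for s in planted:
        idx = {s.x_index, s.y_index, s.z_index}
        if idx & used:
            raise ValueError("planted triplets share gene indices")
        if max(idx) >= n_genes or min(idx) < 0:
            raise ValueError("planted index out of range")
        used |= idx
    if n_genes < 3 * len(planted):
        raise ValueError("n_genes too small for the requested planted triplets")

    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    for s in planted:
        _plant_triplet(values, s, rng)
    values = _apply_missingness(values, missing_rate, rng)
    matrix = ExpressionMatrix(
        gene_ids=_gene_ids(n_genes),
        sample_ids=_sample_ids(n_samples),
        values=values,
    )
    return matrix, _truth_frame(planted)


def generate_trait_dataset(
    n_genes: int,
    n_samples: int = 349,
    mediator_specs: list[tuple[int, int, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    trait_name: str = "trait",
) -> tuple[ExpressionMatrix, TraitVector, pd.DataFrame]:
    """Expression matrix plus a trait whose gene correlation is mediated.

    ``mediator_specs`` lists (gene_index, mediator_index, theta): the
    correlation between the gene and the trait follows the mediator through
    the tanh link. Several mediators may target one gene, in which case
    the link is the average of their tanh terms. The trait has no missing
    values.

    Returns
    -------
    matrix : ExpressionMatrix
    trait : TraitVector
    truth : DataFrame (x_index = target gene, y_index = -1 for the trait,
        z_index = mediator).
    """
    mediator_specs = mediator_specs or []
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must lie in [0, 0.5)")
    specs = [
        PlantedTripletSpec(x_index=g, y_index=-1, z_index=z, theta=th,
                           kind="gene-trait")
        for g, z, th in mediator_specs
    ]
    targets = {s.x_index for s in specs}
    if len(targets) > 1:
        raise ValueError("one trait can mediate only one target gene")
    for s in specs:
        for idx in (s.x_index, s.z_index):
            if not 0 <= idx < n_genes:
                raise ValueError("mediator spec index out of range")
    mediators = [s.z_index for s in specs]
    if len(set(mediators)) != len(mediators):
        raise ValueError("duplicate mediator indices")

    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    if specs:
        target = specs[0].x_index
        x = values[target]
        c = np.mean(
            [np.tanh(s.theta * values[s.z_index]) for s in specs], axis=0
        )
        e = rng.standard_normal(n_samples)
        trait_values = c * x + np.sqrt(1.0 - c**2) * e
    else:
        trait_values = rng.standard_normal(n_samples)
    values = _apply_missingness(values, missing_rate, rng)
    sample_ids = _sample_ids(n_samples)
    matrix = ExpressionMatrix(
        gene_ids=_gene_ids(n_genes), sample_ids=sample_ids, values=values
    )
    trait = TraitVector(
        sample_ids=list(sample_ids), values=trait_values, name=trait_name
    )
    return matrix, trait, _truth_frame(specs)
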