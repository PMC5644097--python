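"""Readers and writers: TSV throughout, plus the run manifest.

Matrix dialect: tab-delimited, first column the gene ID, header row of
sample IDs. The literal tokens "NA", "NaN" and the empty field are read as
missing; writers emit "NA". Trait files are two-column TSV (sample_id,
value) with a header. Floats are written at 12 significant digits so a
write -> read round trip is lossless at that precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, TraitVector, TripletResult
from .significance import ReferenceDistribution
from .trait import TraitLaResult

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_trait",
    "write_trait",
    "write_results",
    "read_results",
    "write_trait_results",
    "write_reference",
    "read_reference",
    "write_edges",
    "config_hash",
    "write_manifest",
]

MISSING_TOKENS = ("NA", "NaN", "")


def _find_duplicate(ids: list[str]) -> tuple[str, int] | None:
    seen: dict[str, int] = {}
    for pos, i in enumerate(ids):
        if i in seen:
            return i, pos
        seen[i] = pos
    return None


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV matrix; rejects duplicate IDs and ragged rows."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: malformed header (need >= 2 columns)")
        sample_ids = header[1:]
        dup = _find_duplicate(sample_ids)
        if dup:
            raise ValueError(f"{path}: duplicate sample ID {dup[0]!r} in header")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        n_cols = len(sample_ids)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            rows.append(
                [np.nan if p in MISSING_TOKENS else float(p) for p in parts[1:]]
            )
    dup = _find_duplicate(gene_ids)
    if dup:
        raise ValueError(
            f"{path}:{dup[1] + 2}: duplicate gene ID {dup[0]!r}"
        )
    if not gene_ids:
        raise ValueError(f"{path}: no gene rows")
    return ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=np.array(rows)
    )


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else format(v, ".12g")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_trait(path: str | Path, name: str | None = None) -> TraitVector:
    """Read a two-column (sample_id, value) TSV with header."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    if df.shape[1] != 2:
        raise ValueError(f"{path}: trait file must have exactly 2 columns")
    sample_ids = df.iloc[:, 0].tolist()
    dup = _find_duplicate(sample_ids)
    if dup:
        raise ValueError(f"{path}:{dup[1] + 2}: duplicate sample ID {dup[0]!r}")
    return TraitVector(
        sample_ids=sample_ids,
        values=df.iloc[:, 1].to_numpy(dtype=float),
        name=name or df.columns[1],
    )


def write_trait(trait: TraitVector, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"sample_id\t{trait.name}\n")
        for sid, v in zip(trait.sample_ids, trait.values):
            fh.write(f"{sid}\t{_fmt(v)}\n")


def _write_records(path: Path, columns: tuple[str, ...], records) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fields = []
            for v in rec.as_tuple():
                if isinstance(v, float):
                    fields.append(_fmt(v))
                else:
                    fields.append("NA" if v is None else str(v))
            fh.write("\t".join(fields) + "\n")


def write_results(results: list[TripletResult], path: str | Path) -> None:
    """Triplet results as TSV (one row per significant triplet)."""
    _write_records(Path(path), TripletResult.RESULT_COLUMNS, results)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_trait_results(results: list[TraitLaResult], path: str | Path) -> None:
    _write_records(Path(path), TraitLaResult.RESULT_COLUMNS, results)


def write_reference(ref: ReferenceDistribution, path: str | Path) -> None:
    """Reference distribution as two-column TSV (pos/neg extremes, sorted)."""
    with Path(path).open("w") as fh:
        fh.write("pos_extreme\tneg_extreme\n")
        for p, n in zip(ref.pos_extremes, ref.neg_extremes):
            fh.write(f"{_fmt(p)}\t{_fmt(n)}\n")


def read_reference(path: str | Path, seed: int = -1) -> ReferenceDistribution:
    df = pd.read_csv(path, sep="\t")
    return ReferenceDistribution(
        pos_extremes=df["pos_extreme"].to_numpy(),
        neg_extremes=df["neg_extreme"].to_numpy(),
        n_permutations=len(df),
        seed=seed,
    )


def write_edges(
    edges: list[tuple[str, str, float, float]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("x_id\tz_id\tla\tp_value\n")
        for x, z, la, p in edges:
            fh.write(f"{x}\t{z}\t{_fmt(la)}\t{_fmt(p)}\n")


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, manifest: dict) -> None:
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
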