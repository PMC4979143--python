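"""Ortholog joining, expression filtering and signed fold-change ranking.

Two single-library transcriptomes are compared gene-by-gene after joining on
shared (uppercased) gene symbols.  Because there is one library per species,
no replicate-based statistics are possible; the comparison is descriptive:
an expression floor (RPKM > 5 by default) restricts the analysis to genes
quantified reliably in every species, and genes are ranked either by
expression in one species or by the magnitude of the signed fold difference

    fold(a, b) =  a / b     if a >= b
               = -(b / a)   otherwise

whose magnitude is always >= 1 and whose sign says which species is higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .quantify import ExpressionTable

__all__ = [
    "JoinedMatrix",
    "FoldChangeRecord",
    "join_orthologs",
    "filter_expressed",
    "signed_fold_change",
    "rank_top_genes",
    "select_differential",
    "round_half_up",
    "UndefinedFoldError",
]


class UndefinedFoldError(ValueError):
    """Fold change requested for a non-positive RPKM value."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round to `decimals` places with ties away from zero (as in the tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class JoinedMatrix:
    """Ortholog-joined genes x species RPKM matrix with filter provenance."""

    values: pd.DataFrame  # index: gene symbols, columns: species_ids
    filter_min_rpkm: float | None = None
    filter_mode: str | None = None  # "strict_greater" | "greater_equal"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def column(self, species_id: str) -> pd.Series:
        if species_id not in self.values.columns:
            raise KeyError(f"unknown species_id {species_id!r}")
        return self.values[species_id]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FoldChangeRecord:
    gene_symbol: str
    rpkm_a: float
    rpkm_b: float
    signed_fold: float


def join_orthologs(tables: list[ExpressionTable]) -> JoinedMatrix:
    """Intersect symbol sets across species and collect RPKM columns.

    Genes absent from any contributing table are dropped (absence may be an
    annotation failure rather than zero expression).  Gene order in the
    result is lexicographic for determinism.
    """
    if len(tables) < 2:
        raise ValueError("need at least two expression tables to join")
    ids = [t.species_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species_ids in join: {ids}")
    shared = set(tables[0].symbols)
    for t in tables[1:]:
        shared &= set(t.symbols)
    if not shared:
        raise ValueError("no shared gene symbols between the input tables")
    genes = sorted(shared)
    values = pd.DataFrame(
        {t.species_id: t.rpkm.loc[genes].astype(float) for t in tables},
        index=pd.Index(genes, name="gene"),
    )
    return JoinedMatrix(values=values)


def filter_expressed(
    joined: JoinedMatrix,
    min_rpkm: float = 5.0,
    mode: str = "strict_greater",
    require_all: bool = True,
) -> JoinedMatrix:
    """Keep genes passing the expression floor in all (or any) species."""
    if mode == "strict_greater":
        passes = joined.values > min_rpkm
    elif mode == "greater_equal":
        passes = joined.values >= min_rpkm
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    keep = passes.all(axis=1) if require_all else passes.any(axis=1)
    return JoinedMatrix(
        values=joined.values.loc[keep],
        filter_min_rpkm=float(min_rpkm),
        filter_mode=mode,
    )


def signed_fold_change(rpkm_a: float, rpkm_b: float) -> float:
    """Signed fold difference between two positive RPKM values.

    Positive when species a is at least as high as species b, negative
    otherwise; the magnitude is the ratio of the larger to the smaller, so
    |fold| >= 1 and fold(a, b) == -fold(b, a) for a != b.
    """
    if rpkm_a <= 0 or rpkm_b <= 0:
        raise UndefinedFoldError(
            f"fold change undefined for non-positive RPKM ({rpkm_a}, {rpkm_b}); "
            "apply an expression filter first"
        )
    if rpkm_a >= rpkm_b:
        return rpkm_a / rpkm_b
    return -(rpkm_b / rpkm_a)


def _fold_records(joined: JoinedMatrix) -> list[FoldChangeRecord]:
    if len(joined.species) != 2:
        raise ValueError(
            f"fold-change operations need exactly 2 species, got {joined.species}"
        )
    a, b = joined.species
    return [
        FoldChangeRecord(
            gene_symbol=g,
            rpkm_a=float(joined.values.at[g, a]),
            rpkm_b=float(joined.values.at[g, b]),
            signed_fold=signed_fold_change(
                float(joined.values.at[g, a]), float(joined.values.at[g, b])
            ),
        )
        for g in joined.genes
    ]


def rank_top_genes(
    joined: JoinedMatrix,
    by: str = "expression_in_species",
    n: int = 10,
    species: str | None = None,
) -> list[FoldChangeRecord]:
    """Top genes by expression in one species or by |signed fold|.

    Descending order, ties broken lexicographically by gene symbol; returns
    exactly ``min(n, number of genes)`` records.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    records = _fold_records(joined)
    if by == "expression_in_species":
        if species is None:
            raise ValueError("ranking by expression requires a species_id")
        if species not in joined.species:
            raise KeyError(f"unknown species_id {species!r}")
        col = 0 if species == joined.species[0] else 1
        key = lambda r: (-(r.rpkm_a if col == 0 else r.rpkm_b), r.gene_symbol)
    elif by == "abs_signed_fold":
        key = lambda r: (-abs(r.signed_fold), r.gene_symbol)
    else:
        raise ValueError(f"unknown ranking criterion {by!r}")
    records.sort(key=key)
    return records[: min(n, len(records))]


def select_differential(
    joined: JoinedMatrix, min_fold: float = 2.0, direction: str = "a_over_b"
) -> list[str]:
    """Genes whose fold difference reaches `min_fold` in the given direction.

    The twofold boundary is inclusive (a gene at exactly min_fold is kept).
    """
    if min_fold < 1:
        raise ValueError(f"min_fold must be >= 1, got {min_fold}")
    records = _fold_records(joined)
    if direction == "a_over_b":
        return [r.gene_symbol for r in records if r.signed_fold >= min_fold]
    if direction == "b_over_a":
        return [r.gene_symbol for r in records if r.signed_fold <= -min_fold]
    raise ValueError(f"unknown direction {direction!r}")


def fold_change_table(joined: JoinedMatrix) -> pd.DataFrame:
    """All fold-change records as a DataFrame (gene, rpkm per species, fold)."""
    records = _fold_records(joined)
    a, b = joined.species
    return pd.DataFrame(
        {
            "gene": [r.gene_symbol for r in records],
            f"rpkm_{a}": [r.rpkm_a for r in records],
            f"rpkm_{b}": [r.rpkm_b for r in records],
            "fold_difference": [r.signed_fold for r in records],
        }
    ).set_index("gene")
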