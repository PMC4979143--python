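"""Gene-level expression tables and RPKM normalization.

RPKM (Reads Per Kilobase of transcript per Million mapped reads) rescales a
raw read count ``c_g`` by the transcript length ``L_g`` (bp) and the total
number of uniquely mapped reads ``N`` in the library::

    RPKM_g = 1e9 * c_g / (N * L_g)

so that expression is comparable across genes of different length and across
libraries of different depth.  Gene identity throughout the package is the
uppercased gene symbol, which is how genes are matched across species
annotations.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "compute_rpkm",
    "read_expression_table",
    "write_expression_table",
    "DuplicateSymbolError",
    "RpkmValidationError",
]

#: relative tolerance at which a supplied rpkm column must agree with the
#: value recomputed from count / length / library size
RPKM_RTOL = 1e-6


class DuplicateSymbolError(ValueError):
    """Two records collapse to the same symbol after uppercasing."""


class RpkmValidationError(ValueError):
    """A supplied RPKM value disagrees with the count-derived one."""


def compute_rpkm(count: float, gene_length_bp: int, library_size: int) -> float:
    """Reads Per Kilobase per Million mapped reads for a single gene.

    Parameters
    ----------
    count
        Number of reads mapped (uniquely) to the gene; non-negative.
    gene_length_bp
        Transcript length in base pairs; must be positive.
    library_size
        Total mapped reads in the library; must be positive.
    """
    if gene_length_bp <= 0:
        raise ValueError(f"gene_length_bp must be positive, got {gene_length_bp}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return 1e9 * count / (float(library_size) * float(gene_length_bp))


@dataclass
class ExpressionTable:
    """One species' gene-level expression.

    ``data`` is indexed by uppercased gene symbol and carries up to three
    columns: ``count``, ``length_bp`` and ``rpkm``.  When the count triplet
    (count, length_bp, library_size) is available the ``rpkm`` column is
    always the recomputed value; a user-supplied rpkm column is validated
    against it at construction time.
    """

    species_id: str
    data: pd.DataFrame
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError(
                f"library_size must be positive, got {self.library_size}"
            )
        df = self.data.copy()
        upper = df.index.astype(str).str.upper()
        dups = upper[upper.duplicated()]
        if len(dups):
            raise DuplicateSymbolError(
                f"duplicate gene symbol after uppercasing: {dups[0]!r} "
                f"(species {self.species_id})"
            )
        df.index = upper
        df.index.name = "gene"

        has_counts = "count" in df.columns and "length_bp" in df.columns
        if not has_counts and "rpkm" not in df.columns:
            raise ValueError(
                "expression table needs either count+length_bp (with "
                "library_size) or an rpkm column"
            )
        if has_counts:
            counts = df["count"].to_numpy(dtype=float)
            lengths = df["length_bp"].to_numpy(dtype=float)
            if (counts < 0).any():
                raise ValueError("counts must be non-negative")
            if (lengths <= 0).any():
                raise ValueError("gene lengths must be positive")
            recomputed = 1e9 * counts / (float(self.library_size) * lengths)
            if "rpkm" in df.columns:
                supplied = df["rpkm"].to_numpy(dtype=float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    bad = ~np.isclose(supplied, recomputed, rtol=RPKM_RTOL, atol=0.0)
                if bad.any():
                    sym = df.index[int(np.argmax(bad))]
                    raise RpkmValidationError(
                        f"rpkm column inconsistent with counts for {sym!r}: "
                        f"supplied {supplied[np.argmax(bad)]!r}, recomputed "
                        f"{recomputed[np.argmax(bad)]!r}"
                    )
            df["rpkm"] = recomputed
        self.data = df

    # -- convenience accessors -------------------------------------------------

    @property
    def symbols(self) -> pd.Index:
        return self.data.index

    @property
    def rpkm(self) -> pd.Series:
        """RPKM values indexed by uppercased symbol."""
        return self.data["rpkm"]

    def rpkm_of(self, symbol: str) -> float:
        key = symbol.upper()
        if key not in self.data.index:
            raise KeyError(
                f"gene {symbol!r} not present in species {self.species_id!r}"
            )
        return float(self.data.at[key, "rpkm"])

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(
        cls,
        species_id: str,
        records: list[tuple],
        library_size: int,
        columns: tuple[str, ...] = ("gene", "count", "length_bp"),
    ) -> "ExpressionTable":
        df = pd.DataFrame.from_records(records, columns=list(columns))
        df = df.set_index("gene")
        return cls(species_id=species_id, data=df, library_size=library_size)

    @classmethod
    def from_rpkm(
        cls, species_id: str, rpkm: pd.Series | dict, library_size: int
    ) -> "ExpressionTable":
        """Build an rpkm-only table (no counts), e.g. for public RPKM data."""
        s = pd.Series(rpkm, dtype=float)
        df = pd.DataFrame({"rpkm": s})
        return cls(species_id=species_id, data=df, library_size=library_size)


_META_RE = re.compile(r"^#\s*(\w+)\s*=\s*(\S+)\s*$")


def read_expression_table(path, species_id: str | None = None) -> ExpressionTable:
    """Read a TSV expression table.

    The format is UTF-8, tab-separated with ``.`` decimals, with ``# key=value``
    metadata lines (``library_size`` required, ``species_id`` optional) followed
    by a header line.  Recognized columns: ``gene`` (required), ``count``,
    ``length_bp``, ``rpkm``.
    """
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
            elif line.strip():
                body.write(line)
    if "library_size" not in meta:
        raise ValueError(f"{path}: missing '# library_size=<int>' metadata line")
    body.seek(0)
    df = pd.read_csv(body, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns:
        raise ValueError(f"{path}: missing 'gene' column")
    keep = [c for c in ("count", "length_bp", "rpkm") if c in df.columns]
    df = df.set_index("gene")[keep]
    if "count" in keep:
        df["count"] = df["count"].astype(np.int64)
    if "length_bp" in keep:
        df["length_bp"] = df["length_bp"].astype(np.int64)
    sid = species_id or meta.get("species_id")
    if sid is None:
        raise ValueError(f"{path}: species_id neither given nor in metadata")
    return ExpressionTable(
        species_id=sid, data=df, library_size=int(meta["library_size"])
    )


def write_expression_table(table: ExpressionTable, path) -> None:
    """Write a table in the format accepted by :func:`read_expression_table`.

    Round-trips losslessly: RPKM is written at full ``repr`` precision.
    """
    df = table.data
    cols = [c for c in ("count", "length_bp", "rpkm") if c in df.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# species_id={table.species_id}\n")
        fh.write(f"# library_size={table.library_size}\n")
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for sym, row in df.iterrows():
            fields = [sym]
            for c in cols:
                v = row[c]
                fields.append(repr(float(v)) if c == "rpkm" else str(int(v)))
            fh.write("\t".join(fields) + "\n")
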