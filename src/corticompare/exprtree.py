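"""Expression-correlation phylogenies.

Pairwise Pearson correlations of (optionally composition-corrected) RPKM
values over the shared ortholog set summarize how similar two species'
brain transcriptomes are; correlations are converted to distances
(d = 1 - r by default) and an unrooted tree is built with Saitou-Nei
neighbor joining using the Studier-Keppler Q criterion,

    Q_ij = (n - 2) d_ij - R_i - R_j,   R_i = sum_k d_ik,

joining the pair with minimal Q at each step.  On an additive distance
matrix the algorithm recovers the generating tree exactly, including branch
lengths.  Tie-breaking and negative-branch handling are deterministic (see
``neighbor_joining``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import JoinedMatrix
from .trees import Node, to_newick

__all__ = [
    "CorrelationMatrix",
    "DistanceMatrixTree",
    "pearson_matrix",
    "correlation_to_distance",
    "distance_matrix",
    "neighbor_joining",
    "build_expression_tree",
    "write_phylip_distances",
]


@dataclass
class CorrelationMatrix:
    """Symmetric species x species Pearson matrix with unit diagonal."""

    r: pd.DataFrame
    n_genes: int

    @property
    def species(self) -> list[str]:
        return list(self.r.index)


@dataclass
class DistanceMatrixTree:
    """Pairwise distances plus the unrooted NJ tree built from them."""

    d: pd.DataFrame
    tree: Node

    @property
    def species(self) -> list[str]:
        return list(self.d.index)

    @property
    def newick(self) -> str:
        return to_newick(self.tree)


def pearson_matrix(
    joined: JoinedMatrix, log_transform: bool = False
) -> CorrelationMatrix:
    """Pearson correlations between species over the shared gene vector.

    Computed on untransformed expression values by default; ``log_transform``
    applies log2(x + 1) first (useful when a few very high expressers would
    otherwise dominate).
    """
    vals = joined.values.to_numpy(dtype=float)
    n_genes, n_species = vals.shape
    if n_species < 3:
        raise ValueError(f"need >= 3 species for a tree, got {n_species}")
    if n_genes < 3:
        raise ValueError(f"need >= 3 genes, got {n_genes}")
    if log_transform:
        vals = np.log2(vals + 1.0)
    sd = vals.std(axis=0)
    for j, s in enumerate(joined.species):
        if sd[j] == 0:
            raise ValueError(f"constant expression column for species {s!r}")
    r = np.corrcoef(vals, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=joined.species, columns=joined.species),
        n_genes=n_genes,
    )


def correlation_to_distance(r, transform: str = "one_minus_r"):
    """Convert Pearson r in [-1, 1] to a dissimilarity.

    ``one_minus_r``: d = 1 - r (default).  ``sqrt``: d = sqrt(2 (1 - r)),
    which is a proper metric (the Euclidean distance between standardized
    vectors).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    arr = np.clip(arr, -1.0, 1.0)
    if transform == "one_minus_r":
        d = 1.0 - arr
    elif transform == "sqrt":
        d = np.sqrt(2.0 * (1.0 - arr))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return float(d) if np.isscalar(r) else d


def distance_matrix(
    corr: CorrelationMatrix, transform: str = "one_minus_r"
) -> pd.DataFrame:
    d = correlation_to_distance(corr.r.to_numpy(), transform=transform)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=corr.species, columns=corr.species)


def _check_distance_matrix(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=0, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")


def neighbor_joining(
    d, labels: list[str] | None = None, negative_branch: str = "clamp"
) -> Node:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Deterministic: ties in the Q criterion are broken by the lowest
    (row, column) index pair in the current working order.  NJ can estimate
    negative branch lengths on non-additive input; with
    ``negative_branch="clamp"`` (the convention PHYLIP-style programs use) a
    negative pendant estimate is set to zero and the deficit moved to the
    sibling edge so the joined pair's distance is preserved; ``"raw"`` keeps
    the estimates.  For >= 4 taxa the result has a trifurcating root and all
    internal nodes of degree 3; for 3 taxa it is the unique star.
    """
    if negative_branch not in ("clamp", "raw"):
        raise ValueError(f"unknown negative_branch mode {negative_branch!r}")
    if isinstance(d, pd.DataFrame):
        if labels is None:
            labels = list(d.index)
        d = d.to_numpy(dtype=float)
    else:
        d = np.array(d, dtype=float)
    n = d.shape[0]
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length does not match matrix size")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    _check_distance_matrix(d)

    nodes: list[Node] = [Node(name=l) for l in labels]
    D = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> lowest (row, col) pair on ties
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if negative_branch == "clamp":
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        parent.add(nodes[i], li)
        parent.add(nodes[j], lj)
        # distances from the new node to all remaining taxa
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes: unique star with closed-form branch lengths
    a = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    if negative_branch == "clamp":
        a, b, c = max(a, 0.0), max(b, 0.0), max(c, 0.0)
    root = Node()
    root.add(nodes[0], a)
    root.add(nodes[1], b)
    root.add(nodes[2], c)
    return root


def build_expression_tree(
    joined: JoinedMatrix,
    transform: str = "one_minus_r",
    log_transform: bool = False,
    negative_branch: str = "clamp",
) -> DistanceMatrixTree:
    """Full pipeline: correlations -> distances -> NJ tree."""
    corr = pearson_matrix(joined, log_transform=log_transform)
    d = distance_matrix(corr, transform=transform)
    tree = neighbor_joining(d, negative_branch=negative_branch)
    return DistanceMatrixTree(d=d, tree=tree)


def write_phylip_distances(d: pd.DataFrame, path) -> None:
    """PHYLIP square-format distance file (names padded to 10 characters)."""
    names = list(d.index)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(names)}\n")
        for name in names:
            if len(name) > 10:
                padded = name[:10]
            else:
                padded = name.ljust(10)
            row = "  ".join(f"{d.at[name, other]:.6f}" for other in names)
            fh.write(f"{padded}{row}\n")
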