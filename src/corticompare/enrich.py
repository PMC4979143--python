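"""Gene-set overrepresentation testing.

Given a query gene list (e.g. genes at least twofold higher in one species)
and a flat term -> genes annotation with a reference gene list of size N, each
term t with K_t reference genes is tested with a binomial tail: under the
null, each of the n query genes falls in t independently with probability
p0 = K_t / N, so with k observed query genes in t,

    p_over  = P(X >= k),   p_under = P(X <= k),   X ~ Binomial(n, p0).

Tails are computed by exact summation of binomial log-probabilities (no
normal approximation), so they remain accurate at the very small p-values
that survive a Bonferroni correction over hundreds of terms.  Fold
enrichment is k / (n * p0).  A hypergeometric (Fisher's exact style,
sampling without replacement) mode is available for sensitivity analysis.

The annotation is taken as a flat mapping; ontology structure (term
hierarchies, propagation to ancestors) is the annotation provider's concern
and is not modeled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetAnnotation",
    "EnrichmentResult",
    "overrepresentation_test",
    "bonferroni_adjust",
    "binom_tail_over",
    "binom_tail_under",
    "read_gmt",
    "read_gene_list",
]


@dataclass
class GeneSetAnnotation:
    """Flat gene-set annotation: term_id -> (term_name, member genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    reference: frozenset[str]

    def __post_init__(self) -> None:
        self.reference = frozenset(g.upper() for g in self.reference)
        self.terms = {
            tid: (name, frozenset(g.upper() for g in genes))
            for tid, (name, genes) in self.terms.items()
        }

    @property
    def n_reference(self) -> int:
        return len(self.reference)

    def term_reference_genes(self, term_id: str) -> frozenset[str]:
        """A term's genes restricted to the reference list (what is tested)."""
        return self.terms[term_id][1] & self.reference


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_list: int
    k_obs: int
    expected: float
    fold_enrichment: float
    p_over: float
    p_under: float
    p_adj: float
    direction: str  # "over" | "under"


def _binom_logpmf(k: np.ndarray, n: int, p0: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p0)
        + (n - k) * np.log1p(-p0)
    )


def binom_tail_over(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), exact summation in log space."""
    if not 0 < p0 < 1:
        if p0 == 0.0:
            return 1.0 if k <= 0 else 0.0
        if p0 == 1.0:
            return 1.0 if k <= n else 0.0
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(min(1.0, np.exp(logsumexp(_binom_logpmf(ks, n, p0)))))


def binom_tail_under(k: int, n: int, p0: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p0), exact summation in log space."""
    if not 0 < p0 < 1:
        if p0 == 0.0:
            return 1.0
        if p0 == 1.0:
            return 1.0 if k >= n else 0.0
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k >= n:
        return 1.0
    if k < 0:
        return 0.0
    ks = np.arange(0, k + 1)
    return float(min(1.0, np.exp(logsumexp(_binom_logpmf(ks, n, p0)))))


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the family size m (default len(p_values)), cap at 1."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    out = []
    for x in p:
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {x}")
        out.append(min(1.0, x * m))
    return out


def overrepresentation_test(
    query,
    annotation: GeneSetAnnotation,
    method: str = "binomial",
    m: int | None = None,
) -> list[EnrichmentResult]:
    """Test every annotated term for over/underrepresentation in the query.

    Query genes absent from the reference are dropped (their number is
    logged); terms with no reference genes are skipped.  Bonferroni family
    size defaults to the number of terms actually tested.  Results come back
    sorted by adjusted p, ties by term_id.

    Parameters
    ----------
    method
        ``"binomial"`` (default; binomial tail at p0 = K_t / N) or
        ``"hypergeometric"`` (sampling without replacement, Fisher-style).
    """
    if method not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown method {method!r}")
    qset = frozenset(g.upper() for g in query)
    dropped = qset - annotation.reference
    if dropped:
        logger.warning(
            "%d query gene(s) not in the reference list were dropped", len(dropped)
        )
    qset &= annotation.reference
    if not qset:
        raise ValueError("query is empty after intersection with the reference")
    N = annotation.n_reference
    n = len(qset)

    tested: list[EnrichmentResult] = []
    for tid in sorted(annotation.terms):
        name, _ = annotation.terms[tid]
        term_ref = annotation.term_reference_genes(tid)
        K = len(term_ref)
        if K == 0:
            continue
        k = len(qset & term_ref)
        p0 = K / N
        expected = n * p0
        if method == "binomial":
            p_over = binom_tail_over(k, n, p0)
            p_under = binom_tail_under(k, n, p0)
        else:
            p_over = float(hypergeom.sf(k - 1, N, K, n))
            p_under = float(hypergeom.cdf(k, N, K, n))
        direction = "over" if k >= expected else "under"
        tested.append(
            EnrichmentResult(
                term_id=tid,
                term_name=name,
                n_list=n,
                k_obs=k,
                expected=expected,
                fold_enrichment=k / expected,
                p_over=p_over,
                p_under=p_under,
                p_adj=np.nan,  # filled below
                direction=direction,
            )
        )
    family = m if m is not None else len(tested)
    raw = [r.p_over if r.direction == "over" else r.p_under for r in tested]
    for r, adj in zip(tested, bonferroni_adjust(raw, m=family)):
        r.p_adj = adj
    tested.sort(key=lambda r: (r.p_adj, r.term_id))
    return tested


# -- annotation I/O ------------------------------------------------------------


def read_gmt(path, reference) -> GeneSetAnnotation:
    """Read GMT gene sets (term_id <tab> term_name <tab> gene...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: GMT line needs id and name")
            tid, name, *genes = parts
            if tid in terms:
                raise ValueError(f"{path}:{ln}: duplicate term id {tid!r}")
            terms[tid] = (name, frozenset(g for g in genes if g))
    return GeneSetAnnotation(terms=terms, reference=frozenset(reference))


def read_gene_list(path) -> frozenset[str]:
    """Plain-text gene list, one symbol per line; '#' lines are comments."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s.upper())
    return frozenset(out)
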