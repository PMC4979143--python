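"""Synthetic multi-species expression data with known ground truth.

The generator emulates the statistical structure a cross-species bulk brain
transcriptome comparison assumes:

* a shared ortholog symbol space quantified as RPKM per species;
* between-species correlation induced by phylogeny — each gene's log2
  expression evolves along a known species tree by Brownian motion, so the
  covariance between two species equals ``bm_sigma**2`` times their shared
  path length from the root;
* injected fold-change spikes in chosen genes for a species or a species
  group (e.g. a ~38-fold spike in the diving group);
* marker genes (GFAP-like / RBFOX3-like) whose RPKM ratio encodes a
  configured glia fraction, plus "confounded" genes whose bulk RPKM scales
  with the glia/neuron ratio while per-glial-unit expression stays constant;
* optional Poisson (or negative-binomial) count noise, with RPKM recomputed
  from the sampled counts.

Marker and confounded genes are excluded from Brownian variation and spikes
do not touch markers, so the composition signal is clean by construction.
Everything is deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .enrich import GeneSetAnnotation
from .quantify import ExpressionTable, compute_rpkm
from .trees import Node, parse_newick

__all__ = [
    "Spike",
    "MarkerConfig",
    "ConfoundedGene",
    "SyntheticConfig",
    "SyntheticTruth",
    "AnnotationTruth",
    "simulate_expression_dataset",
    "simulate_annotation",
    "load_config",
    "DEFAULT_TREE",
]

#: Default six-species tree: a seal+ferret clade, a whales+cow clade and a
#: rodent outgroup, with branch lengths loosely proportional to divergence.
DEFAULT_TREE = (
    "((seal:0.10,ferret:0.12):0.20,"
    "((minke_whale:0.05,bowhead_whale:0.05):0.12,cow:0.17):0.15,"
    "mouse:0.45);"
)


@dataclass(frozen=True)
class Spike:
    """Multiply one gene's true RPKM by `fold` in a species or group."""

    gene_symbol: str
    target: str  # a species_id or a group name from config.groups
    fold: float


@dataclass(frozen=True)
class ConfoundedGene:
    """Gene with constant per-glial-unit expression; bulk RPKM = base * ratio."""

    gene_symbol: str
    per_glial_unit_rpkm: float


@dataclass
class MarkerConfig:
    glia_symbol: str = "GFAP"
    neuron_symbol: str = "RBFOX3"
    #: species_id -> glia fraction in (0, 1); marker ratio = f / (1 - f)
    glia_fraction: dict[str, float] = field(default_factory=dict)
    #: combined marker expression budget (RPKM) split between the two markers
    total_rpkm: float = 500.0


@dataclass
class SyntheticConfig:
    tree: str = DEFAULT_TREE
    n_genes: int = 5000
    bm_sigma: float = 1.0  # log2 units per sqrt(branch length)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    spikes: tuple[Spike, ...] = ()
    markers: MarkerConfig | None = None
    confounded: tuple[ConfoundedGene, ...] = ()
    groups: dict[str, list[str]] = field(default_factory=dict)
    library_size: int = 10_000_000
    gene_length_bp: int = 1000
    count_noise: str = "poisson"  # "none" | "poisson"
    nb_dispersion: float | None = None  # Gamma-Poisson overdispersion if set
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside a simulated dataset."""

    tree_newick: str
    true_rpkm: pd.DataFrame  # genes x species, before count noise
    spikes: tuple[Spike, ...]
    marker_ratios: dict[str, float]
    config: SyntheticConfig

    @property
    def tree(self) -> Node:
        return parse_newick(self.tree_newick)


@dataclass
class AnnotationTruth:
    enriched_term_id: str
    enrichment_odds: float


def _simulate_bm_tips(
    root: Node, n_genes: int, sigma: float, baseline: np.ndarray, rng
) -> dict[str, np.ndarray]:
    """Brownian motion of per-gene log2 values from the root to each tip."""
    tips: dict[str, np.ndarray] = {}

    def descend(node: Node, value: np.ndarray) -> None:
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            if t < 0:
                raise ValueError("negative branch length in generating tree")
            step = (
                rng.normal(0.0, sigma * np.sqrt(t), size=n_genes)
                if sigma > 0 and t > 0
                else 0.0
            )
            v = value + step
            if child.is_leaf:
                if child.name is None:
                    raise ValueError("generating tree has an unlabeled leaf")
                tips[child.name] = v
            else:
                descend(child, v)

    descend(root, baseline)
    return tips


def _spike_species(spike: Spike, species: list[str], groups) -> list[str]:
    if spike.target in species:
        return [spike.target]
    if spike.target in groups:
        members = [s for s in groups[spike.target] if s in species]
        if not members:
            raise ValueError(
                f"group {spike.target!r} has no members among tree species"
            )
        return members
    raise ValueError(
        f"spike target {spike.target!r} is neither a species nor a group"
    )


def simulate_expression_dataset(
    config: SyntheticConfig,
) -> tuple[list[ExpressionTable], SyntheticTruth]:
    """Generate one ExpressionTable per tree leaf plus the ground truth."""
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if config.bm_sigma < 0:
        raise ValueError("bm_sigma must be non-negative")
    if config.count_noise not in ("none", "poisson"):
        raise ValueError(f"unknown count_noise {config.count_noise!r}")
    for spike in config.spikes:
        if spike.fold <= 0:
            raise ValueError(f"spike fold must be positive: {spike}")
    spike_genes = [s.gene_symbol.upper() for s in config.spikes]
    if len(set(spike_genes)) != len(spike_genes):
        raise ValueError("duplicate gene symbols in spikes")

    root = parse_newick(config.tree)
    species = root.leaf_names()
    if len(species) != len(set(species)):
        raise ValueError("duplicate species names in generating tree")

    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
    )
    tips = _simulate_bm_tips(root, config.n_genes, config.bm_sigma, baseline, rng)
    true = pd.DataFrame(
        {s: np.exp2(tips[s]) for s in species},
        index=pd.Index(genes, name="gene"),
    )

    # composition machinery: marker genes and confounded genes are appended
    # outside the Brownian gene set
    marker_ratios: dict[str, float] = {}
    if config.markers is not None:
        mk = config.markers
        missing = [s for s in species if s not in mk.glia_fraction]
        if missing:
            raise ValueError(f"glia_fraction missing for species: {missing}")
        for s in species:
            f = mk.glia_fraction[s]
            if not 0.0 < f < 1.0:
                raise ValueError(f"glia_fraction must be in (0,1), got {f} for {s}")
            marker_ratios[s] = f / (1.0 - f)
        glia_row = {s: mk.total_rpkm * mk.glia_fraction[s] for s in species}
        neuron_row = {
            s: mk.total_rpkm * (1.0 - mk.glia_fraction[s]) for s in species
        }
        for sym, row in (
            (mk.glia_symbol.upper(), glia_row),
            (mk.neuron_symbol.upper(), neuron_row),
        ):
            if sym in true.index:
                raise ValueError(f"marker symbol {sym!r} collides with a gene")
            true.loc[sym] = row
    for cg in config.confounded:
        if config.markers is None:
            raise ValueError("confounded genes need a marker configuration")
        sym = cg.gene_symbol.upper()
        if sym in true.index:
            raise ValueError(f"confounded symbol {sym!r} collides with a gene")
        true.loc[sym] = {
            s: cg.per_glial_unit_rpkm * marker_ratios[s] for s in species
        }

    marker_syms = set()
    if config.markers is not None:
        marker_syms = {
            config.markers.glia_symbol.upper(),
            config.markers.neuron_symbol.upper(),
        }
    for spike in config.spikes:
        sym = spike.gene_symbol.upper()
        if sym in marker_syms:
            raise ValueError(f"spikes may not target marker genes ({sym})")
        if sym not in true.index:
            raise ValueError(f"spike gene {sym!r} not in the simulated gene set")
        for s in _spike_species(spike, species, config.groups):
            true.at[sym, s] *= spike.fold

    tables: list[ExpressionTable] = []
    L = config.gene_length_bp
    N = config.library_size
    for s in species:
        rpkm = true[s].to_numpy(dtype=float)
        if config.count_noise == "none":
            tables.append(
                ExpressionTable.from_rpkm(
                    species_id=s,
                    rpkm=pd.Series(rpkm, index=true.index),
                    library_size=N,
                )
            )
            continue
        mean_counts = rpkm * N * L / 1e9
        if config.nb_dispersion:
            # Gamma-Poisson: counts ~ NB with var = mu + dispersion * mu^2
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean_counts / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mean_counts)
        df = pd.DataFrame(
            {"count": counts.astype(np.int64), "length_bp": np.int64(L)},
            index=true.index.copy(),
        )
        tables.append(ExpressionTable(species_id=s, data=df, library_size=N))

    truth = SyntheticTruth(
        tree_newick=config.tree,
        true_rpkm=true,
        spikes=tuple(config.spikes),
        marker_ratios=marker_ratios,
        config=config,
    )
    return tables, truth


def simulate_annotation(
    reference_size: int,
    n_terms: int,
    enriched_term_genes: int,
    query_size: int,
    enrichment_odds: float,
    seed: int = 0,
) -> tuple[GeneSetAnnotation, frozenset[str], AnnotationTruth]:
    """Random gene-set annotation with one designated enriched term.

    All terms draw `enriched_term_genes` members uniformly from a reference
    of `reference_size` symbols (overlaps between terms allowed).  The query
    is sampled without replacement with weight `enrichment_odds` on the
    designated term's genes and 1 elsewhere, so odds 1 is the exact null.
    """
    if not 0 < enriched_term_genes <= reference_size:
        raise ValueError("enriched_term_genes must be in (0, reference_size]")
    if not 0 < query_size <= reference_size:
        raise ValueError("query_size must be in (0, reference_size]")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")

    rng = np.random.default_rng(seed)
    reference = np.array([f"G{i + 1:05d}" for i in range(reference_size)])
    width = len(str(n_terms))
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(n_terms):
        tid = f"T{t + 1:0{width}d}"
        members = rng.choice(reference, size=enriched_term_genes, replace=False)
        terms[tid] = (f"synthetic term {tid}", frozenset(members))
    enriched_id = f"T{1:0{width}d}"

    enriched_genes = terms[enriched_id][1]
    weights = np.where(np.isin(reference, list(enriched_genes)), enrichment_odds, 1.0)
    query = rng.choice(
        reference, size=query_size, replace=False, p=weights / weights.sum()
    )
    annotation = GeneSetAnnotation(terms=terms, reference=frozenset(reference))
    truth = AnnotationTruth(
        enriched_term_id=enriched_id, enrichment_odds=enrichment_odds
    )
    return annotation, frozenset(query), truth


# -- config file ---------------------------------------------------------------


def load_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML key-value file.

    Schema (all keys optional, defaults as in :class:`SyntheticConfig`)::

        tree: "((A:0.1,B:0.1):0.2,C:0.3);"
        n_genes: 5000
        bm_sigma: 1.0
        baseline_log2_mean: 5.0
        baseline_log2_sd: 2.0
        library_size: 10000000
        gene_length_bp: 1000
        count_noise: poisson        # or none
        seed: 0
        groups:
          diving: [seal, minke_whale]
        spikes:
          - {gene: G00001, target: diving, fold: 38}
        markers:
          glia_symbol: GFAP
          neuron_symbol: RBFOX3
          total_rpkm: 500
          glia_fraction: {seal: 0.6, ferret: 0.4}
        confounded:
          - {gene: S100B, per_glial_unit_rpkm: 100}
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    simple = (
        "tree",
        "n_genes",
        "bm_sigma",
        "baseline_log2_mean",
        "baseline_log2_sd",
        "library_size",
        "gene_length_bp",
        "count_noise",
        "nb_dispersion",
        "seed",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "groups" in raw:
        kwargs["groups"] = {str(k): list(v) for k, v in raw["groups"].items()}
    if "spikes" in raw:
        kwargs["spikes"] = tuple(
            Spike(
                gene_symbol=str(s["gene"]),
                target=str(s["target"]),
                fold=float(s["fold"]),
            )
            for s in raw["spikes"]
        )
    if "markers" in raw:
        mk = raw["markers"]
        kwargs["markers"] = MarkerConfig(
            glia_symbol=str(mk.get("glia_symbol", "GFAP")),
            neuron_symbol=str(mk.get("neuron_symbol", "RBFOX3")),
            glia_fraction={
                str(k): float(v) for k, v in mk.get("glia_fraction", {}).items()
            },
            total_rpkm=float(mk.get("total_rpkm", 500.0)),
        )
    if "confounded" in raw:
        kwargs["confounded"] = tuple(
            ConfoundedGene(
                gene_symbol=str(c["gene"]),
                per_glial_unit_rpkm=float(c["per_glial_unit_rpkm"]),
            )
            for c in raw["confounded"]
        )
    return SyntheticConfig(**kwargs)
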