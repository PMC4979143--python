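import numpy as np
import pandas as pd
import pytest

from corticompare.compare import join_orthologs, signed_fold_change, round_half_up
from corticompare.composition import glia_neuron_ratio
from corticompare.enrich import overrepresentation_test
from corticompare.exprtree import pearson_matrix
from corticompare.synthetic import (
    DEFAULT_TREE,
    ConfoundedGene,
    MarkerConfig,
    Spike,
    SyntheticConfig,
    load_config,
    simulate_annotation,
    simulate_expression_dataset,
)
from corticompare.trees import leaf_path_lengths, parse_newick
from conftest import GLIA_FRACTIONS


def small_config(**kw) -> SyntheticConfig:
    base = dict(n_genes=50, seed=1)
    base.update(kw)
    return SyntheticConfig(**base)


# -- expression simulation -----------------------------------------------------


def test_same_seed_reproduces_different_seed_differs():
    t1, _ = simulate_expression_dataset(small_config())
    t2, _ = simulate_expression_dataset(small_config())
    t3, _ = simulate_expression_dataset(small_config(seed=2))
    for a, b in zip(t1, t2):
        pd.testing.assert_frame_equal(a.data, b.data)
    assert not t1[0].data.equals(t3[0].data)


def test_zero_rate_no_noise_gives_identical_columns():
    tables, _ = simulate_expression_dataset(
        small_config(bm_sigma=0.0, count_noise="none")
    )
    joined = join_orthologs(tables)
    assert (joined.values.nunique(axis=1) == 1).all()
    corr = pearson_matrix(joined)
    assert np.allclose(corr.r, 1.0)


def test_single_species_spike_recovers_configured_fold():
    tables, truth = simulate_expression_dataset(
        small_config(
            bm_sigma=0.0,
            count_noise="none",
            spikes=(Spike("G00001", "seal", 38.0),),
        )
    )
    by_id = {t.species_id: t for t in tables}
    fold = signed_fold_change(
        by_id["seal"].rpkm_of("G00001"), by_id["ferret"].rpkm_of("G00001")
    )
    assert round_half_up(fold) == 38.0
    assert truth.spikes[0].fold == 38.0


def test_group_spike_hits_all_group_members():
    groups = {"diving": ["seal", "minke_whale", "bowhead_whale"]}
    tables, truth = simulate_expression_dataset(
        small_config(
            bm_sigma=0.0,
            count_noise="none",
            groups=groups,
            spikes=(Spike("G00002", "diving", 10.0),),
        )
    )
    by_id = {t.species_id: t for t in tables}
    for s in groups["diving"]:
        assert signed_fold_change(
            by_id[s].rpkm_of("G00002"), by_id["mouse"].rpkm_of("G00002")
        ) == pytest.approx(10.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="Newick"):
        simulate_expression_dataset(small_config(tree="((A:1,B:1"))
    with pytest.raises(ValueError, match="duplicate"):
        simulate_expression_dataset(
            small_config(
                spikes=(Spike("G00001", "seal", 2.0), Spike("G00001", "ferret", 3.0))
            )
        )
    with pytest.raises(ValueError, match="neither a species nor a group"):
        simulate_expression_dataset(small_config(spikes=(Spike("G00001", "??", 2.0),)))
    with pytest.raises(ValueError, match="glia_fraction"):
        simulate_expression_dataset(
            small_config(markers=MarkerConfig(glia_fraction={"seal": 0.5}))
        )


def test_marker_ratio_round_trip_exact_without_noise():
    tables, truth = simulate_expression_dataset(
        small_config(
            count_noise="none", markers=MarkerConfig(glia_fraction=GLIA_FRACTIONS)
        )
    )
    for t in tables:
        f = GLIA_FRACTIONS[t.species_id]
        assert glia_neuron_ratio(t).ratio == pytest.approx(
            f / (1 - f), rel=1e-12
        )
        assert truth.marker_ratios[t.species_id] == pytest.approx(f / (1 - f))


def test_confounded_gene_scales_with_marker_ratio():
    tables, _ = simulate_expression_dataset(
        small_config(
            count_noise="none",
            markers=MarkerConfig(glia_fraction=GLIA_FRACTIONS),
            confounded=(ConfoundedGene("S100B", 100.0),),
        )
    )
    for t in tables:
        ratio = glia_neuron_ratio(t).ratio
        assert t.rpkm_of("S100B") == pytest.approx(100.0 * ratio, rel=1e-12)


def test_poisson_counts_conserve_rpkm_count_identity():
    tables, _ = simulate_expression_dataset(small_config(count_noise="poisson"))
    t = tables[0]
    back = (t.data["rpkm"] * t.data["length_bp"] * t.library_size / 1e9).sum()
    assert back == pytest.approx(t.data["count"].sum(), rel=1e-6)


def test_brownian_covariance_matches_shared_path_lengths():
    """With no baseline spread, cov(log2 x_a, log2 x_b) across genes equals
    bm_sigma^2 times the species' shared path length from the root."""
    cfg = SyntheticConfig(
        n_genes=20_000, baseline_log2_sd=0.0, count_noise="none", seed=3
    )
    tables, truth = simulate_expression_dataset(cfg)
    species = truth.true_rpkm.columns.tolist()
    log2 = np.log2(truth.true_rpkm.to_numpy())
    emp = np.cov(log2.T)

    tree = parse_newick(DEFAULT_TREE)
    paths = leaf_path_lengths(tree)
    depth = {}
    for leaf in tree.leaves():

        def walk(node, acc):
            if node is leaf:
                return acc
            for c in node.children:
                r = walk(c, acc + (c.length or 0.0))
                if r is not None:
                    return r
            return None

        depth[leaf.name] = walk(tree, 0.0)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i > j:
                continue
            if i == j:
                expected = cfg.bm_sigma**2 * depth[a]
            else:
                shared = 0.5 * (depth[a] + depth[b] - paths[tuple(sorted((a, b)))])
                expected = cfg.bm_sigma**2 * shared
            assert emp[i, j] == pytest.approx(expected, rel=0.10, abs=0.01)


# -- annotation simulation -----------------------------------------------------


def test_annotation_shapes_and_single_term_family():
    ann, query, truth = simulate_annotation(
        reference_size=200, n_terms=1, enriched_term_genes=20,
        query_size=30, enrichment_odds=1.0, seed=0,
    )
    assert len(ann.reference) == 200
    assert len(query) == 30
    (res,) = overrepresentation_test(query, ann)
    raw = res.p_over if res.direction == "over" else res.p_under
    assert res.p_adj == pytest.approx(raw)  # m = 1


def test_annotation_infeasible_sizes_rejected():
    with pytest.raises(ValueError):
        simulate_annotation(10, 1, 20, 5, 1.0)
    with pytest.raises(ValueError):
        simulate_annotation(10, 1, 5, 20, 1.0)
    with pytest.raises(ValueError):
        simulate_annotation(10, 1, 5, 5, -1.0)


def test_strong_enrichment_puts_designated_term_first():
    for seed in range(5):
        ann, query, truth = simulate_annotation(
            reference_size=5000, n_terms=50, enriched_term_genes=50,
            query_size=100, enrichment_odds=20.0, seed=seed,
        )
        results = overrepresentation_test(query, ann)
        assert results[0].term_id == truth.enriched_term_id
        assert results[0].direction == "over"


# -- config file ---------------------------------------------------------------


def test_yaml_config_round_trip(tmp_path):
    text = """
tree: "((A:0.1,B:0.1):0.2,C:0.3);"
n_genes: 10
bm_sigma: 0.0
count_noise: none
seed: 7
groups:
  g1: [A, B]
spikes:
  - {gene: G00001, target: g1, fold: 4}
markers:
  glia_fraction: {A: 0.5, B: 0.25, C: 0.75}
confounded:
  - {gene: TGT, per_glial_unit_rpkm: 10}
"""
    path = tmp_path / "sim.yaml"
    path.write_text(text)
    cfg = load_config(path)
    assert cfg.n_genes == 10 and cfg.seed == 7
    tables, truth = simulate_expression_dataset(cfg)
    assert {t.species_id for t in tables} == {"A", "B", "C"}
    by_id = {t.species_id: t for t in tables}
    assert by_id["A"].rpkm_of("G00001") == pytest.approx(
        4 * by_id["C"].rpkm_of("G00001")
    )
    assert by_id["B"].rpkm_of("TGT") == pytest.approx(10 * (0.25 / 0.75))
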