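import io

import dendropy
import numpy as np
import pandas as pd
import pytest

from corticompare.compare import JoinedMatrix
from corticompare.exprtree import (
    build_expression_tree,
    correlation_to_distance,
    distance_matrix,
    neighbor_joining,
    pearson_matrix,
    write_phylip_distances,
)
from corticompare.trees import (
    leaf_path_lengths,
    parse_newick,
    robinson_foulds,
    to_newick,
)


def joined_from(values: dict[str, list[float]]) -> JoinedMatrix:
    df = pd.DataFrame(values)
    df.index = [f"G{i}" for i in range(len(df))]
    return JoinedMatrix(values=df)


def random_additive_matrix(rng, n_leaves):
    """Random tree with positive branch lengths -> its path-length matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = [parse_newick(f"{l};") for l in labels]  # single-leaf trees
    lengths = rng.uniform(0.1, 2.0, size=2 * n_leaves)
    li = iter(lengths)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = type(nodes[0])()
        parent.add(nodes[j], next(li))
        parent.add(nodes[i], next(li))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = type(nodes[0])()
    for nd in nodes:
        root.add(nd, next(li))
    paths = leaf_path_lengths(root)
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in paths.items():
        d.at[a, b] = d.at[b, a] = v
    return root, d


# -- correlations --------------------------------------------------------------


def test_pearson_duplicated_and_reflected_columns():
    joined = joined_from(
        {"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0], "c": [9.0, 5.0, 1.0]}
    )
    corr = pearson_matrix(joined)
    assert corr.r.at["a", "b"] == pytest.approx(1.0)
    assert corr.r.at["a", "c"] == pytest.approx(-1.0)
    assert corr.n_genes == 3
    assert np.allclose(corr.r, corr.r.T, atol=1e-12)
    assert (np.diag(corr.r) == 1.0).all()


def test_pearson_hand_computed_value():
    joined = joined_from(
        {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 4.0], "c": [3.0, 1.0, 2.0]}
    )
    r = pearson_matrix(joined).r.at["a", "b"]
    assert r == pytest.approx(9 / np.sqrt(84), abs=1e-9)  # 0.98198...


def test_pearson_rejects_constant_column_and_tiny_inputs():
    with pytest.raises(ValueError, match="constant.*'b'"):
        pearson_matrix(
            joined_from({"a": [1, 2, 3], "b": [5, 5, 5], "c": [2, 1, 3]})
        )
    with pytest.raises(ValueError, match="species"):
        pearson_matrix(joined_from({"a": [1, 2, 3], "b": [2, 1, 3]}))


@pytest.mark.parametrize(
    "r,expected", [(1.0, 0.0), (0.0, 1.0), (-1.0, 2.0), (0.5, 0.5)]
)
def test_distance_transform_one_minus_r(r, expected):
    assert correlation_to_distance(r) == pytest.approx(expected)


def test_distance_transform_sqrt_and_range_check():
    assert correlation_to_distance(-1.0, transform="sqrt") == pytest.approx(2.0)
    assert correlation_to_distance(1.0, transform="sqrt") == 0.0
    with pytest.raises(ValueError):
        correlation_to_distance(1.5)


# -- neighbor joining ----------------------------------------------------------


def test_nj_three_taxa_closed_form():
    d = pd.DataFrame(
        [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC")
    )
    tree = neighbor_joining(d)
    assert to_newick(tree) == "(A:1.000000,B:2.000000,C:3.000000);"


def test_nj_four_taxon_additive_example():
    d = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"),
        columns=list("ABCD"),
    )
    tree = neighbor_joining(d)
    paths = leaf_path_lengths(tree)
    for (a, b), v in paths.items():
        assert v == pytest.approx(d.at[a, b], abs=1e-12)
    expected = parse_newick("((A:1,B:2):1,C:3,D:4);")
    assert robinson_foulds(tree, expected) == 0


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError, match="symmetric"):
        neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        neighbor_joining(np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0.0]]))
    with pytest.raises(ValueError, match=">= 3"):
        neighbor_joining(np.zeros((2, 2)))


def test_nj_recovers_random_additive_trees():
    """On additive matrices NJ is exact: topology and all path lengths."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        true_tree, d = random_additive_matrix(rng, n)
        est = neighbor_joining(d)
        assert robinson_foulds(est, true_tree) == 0
        paths = leaf_path_lengths(est)
        for (a, b), v in paths.items():
            assert v == pytest.approx(d.at[a, b], abs=1e-9)


def test_nj_topology_matches_dendropy_on_noisy_matrices():
    """Independent-oracle check on non-additive input."""
    rng = np.random.default_rng(21)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        _, d = random_additive_matrix(rng, n)
        noise = rng.uniform(0, 0.05, size=d.shape)
        m = d.to_numpy() + (noise + noise.T)
        np.fill_diagonal(m, 0.0)
        labels = list(d.index)
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(f"{m[i, j]:.12f}" for j in range(n))
            for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        ref = parse_newick(
            pdm.nj_tree().as_string(schema="newick", suppress_rooting=True).strip()
        )
        mine = neighbor_joining(m, labels=labels)
        assert robinson_foulds(mine, ref) == 0


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    _, d = random_additive_matrix(rng, 7)
    perm = rng.permutation(len(d))
    shuffled = d.iloc[perm, perm]
    t1 = neighbor_joining(d)
    t2 = neighbor_joining(shuffled)
    assert robinson_foulds(t1, t2) == 0


def test_nj_clamps_negative_branches_by_default():
    # strongly non-additive matrix known to give a negative NJ estimate
    m = np.array(
        [
            [0.0, 0.1, 1.0, 1.0, 1.0],
            [0.1, 0.0, 1.0, 1.0, 1.05],
            [1.0, 1.0, 0.0, 0.1, 1.0],
            [1.0, 1.0, 0.1, 0.0, 1.1],
            [1.0, 1.05, 1.0, 1.1, 0.0],
        ]
    )
    clamped = neighbor_joining(m)

    def lengths(node, acc):
        for c in node.children:
            acc.append(c.length)
            lengths(c, acc)
        return acc

    assert all(l >= 0 for l in lengths(clamped, []))


# -- pipeline + output formats -------------------------------------------------


def test_build_expression_tree_end_to_end():
    rng = np.random.default_rng(8)
    base = rng.uniform(1, 100, 200)
    joined = joined_from(
        {
            "a": list(base),
            "b": list(base * rng.uniform(0.9, 1.1, 200)),
            "c": list(base[::-1]),
            "d": list(base[::-1] * rng.uniform(0.9, 1.1, 200)),
        }
    )
    result = build_expression_tree(joined)
    assert robinson_foulds(
        result.tree, parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    ) == 0
    assert result.newick.endswith(";")


def test_phylip_distance_file_format(tmp_path):
    d = pd.DataFrame(
        np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0.0]]),
        index=["seal", "ferret", "cow", "mouse"],
        columns=["seal", "ferret", "cow", "mouse"],
    )
    path = tmp_path / "dist.phy"
    write_phylip_distances(d, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 5
    assert lines[0] == "4"
    assert lines[1].startswith("seal      ")  # name padded to 10 chars
    assert lines[1].split()[1] == "0.000000"
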