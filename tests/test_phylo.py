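"""Hamming distances, Fitch scoring (vs an independent Sankoff DP oracle),
heuristic search vs exhaustive enumeration, clustering, leaf ordering."""

import numpy as np
import pandas as pd
import pytest

from fieldmap import phylo
from fieldmap.phylo import CharacterMatrix, OrganTree


def _random_chars(rng, n, m=20, p=0.4):
    return CharacterMatrix(
        pd.DataFrame(
            rng.random((n, m)) < p,
            index=[f"F{j}" for j in range(n)],
            columns=[f"c{j}" for j in range(m)],
        )
    )


def _sankoff_score(tree: OrganTree, chars: CharacterMatrix) -> int:
    """Independent per-character minimum-change oracle (Sankoff DP)."""
    mat = chars.matrix.loc[tree.leaf_names].to_numpy()
    n = tree.n_leaves
    start = next(u for u in sorted(tree.adjacency) if u >= n)
    total = 0
    for j in range(mat.shape[1]):
        cost: dict[int, list[float]] = {}
        for node, parent in tree.postorder(start):
            if node < n:
                s = int(mat[node, j])
                cost[node] = [0 if st == s else float("inf") for st in (0, 1)]
            else:
                c = [0.0, 0.0]
                for nb in tree.adjacency[node]:
                    if nb == parent:
                        continue
                    child = cost[nb]
                    for st in (0, 1):
                        c[st] += min(child[0] + (st != 0), child[1] + (st != 1))
                cost[node] = c
        total += int(min(cost[start]))
    return total


class TestHamming:
    def test_basic_examples(self):
        m = pd.DataFrame(
            [[0, 1, 1], [0, 0, 1], [1, 0, 0]],
            index=["a", "b", "c"], columns=["x", "y", "z"],
        )
        d = phylo.hamming_matrix(CharacterMatrix(m))
        assert d.loc["a", "b"] == 1
        assert d.loc["a", "c"] == 3  # complement rows
        assert (np.diag(d) == 0).all()

    def test_metric_properties_random(self):
        rng = np.random.default_rng(0)
        d = phylo.hamming_matrix(_random_chars(rng, 8, 30)).to_numpy()
        assert (d == d.T).all()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestFitch:
    def test_three_leaf_forced_change(self):
        m = pd.DataFrame([[1], [0], [0]], index=list("abc"), columns=["x"])
        chars = CharacterMatrix(m)
        tree = OrganTree({0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}, list("abc"))
        assert phylo.fitch_score(tree, chars) == 1

    def test_constant_character_no_change(self):
        m = pd.DataFrame([[1], [1], [1], [1]], index=list("abcd"), columns=["x"])
        chars = CharacterMatrix(m)
        tree = OrganTree(
            {0: [4], 1: [4], 2: [5], 3: [5], 4: [0, 1, 5], 5: [2, 3, 4]},
            list("abcd"),
        )
        assert phylo.fitch_score(tree, chars) == 0

    def test_matches_sankoff_oracle_random(self):
        rng = np.random.default_rng(42)
        for i in range(10):
            chars = _random_chars(rng, 6, 20)
            tree = phylo.search_tree(chars, restarts=2, seed=i)
            assert phylo.fitch_score(tree, chars) == _sankoff_score(tree, chars)

    def test_leaf_mismatch_rejected(self):
        m = pd.DataFrame([[1], [0]], index=["a", "b"], columns=["x"])
        tree = OrganTree({0: [1], 1: [0]}, ["a", "zzz"])
        with pytest.raises(ValueError, match="match"):
            phylo.fitch_score(tree, CharacterMatrix(m))


class TestSearch:
    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(1)
        for i in range(8):
            chars = _random_chars(rng, int(rng.integers(5, 8)), 15)
            t = phylo.search_tree(chars, restarts=10, seed=i)
            assert t.score == phylo.exhaustive_min_score(chars)

    def test_two_fields_score_is_hamming(self):
        m = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["a", "b"],
                         columns=list("xyz"))
        chars = CharacterMatrix(m)
        t = phylo.search_tree(chars, seed=0)
        assert t.score == 2

    def test_search_never_worse_than_nj_start(self):
        rng = np.random.default_rng(2)
        for i in range(5):
            chars = _random_chars(rng, 9, 25)
            nj = phylo._nj_start(chars)
            t = phylo.search_tree(chars, restarts=3, seed=i)
            assert t.score <= phylo.fitch_score(nj, chars)

    def test_nested_clones_form_clade(self):
        # gamma footprint nested inside a beta footprint: the gamma-bearing
        # fields must come out as one clade
        fields = [f"F{j}" for j in range(10)]
        gamma_set = {"F0", "F1", "F2", "F3"}
        beta_set = gamma_set | {"F4", "F5", "F6"}
        cols = {}
        for k in range(12):
            cols[f"g{k}"] = [f in gamma_set for f in fields]
        for k in range(6):
            cols[f"b{k}"] = [f in beta_set for f in fields]
        rng = np.random.default_rng(3)
        for k in range(10):
            private = np.zeros(10, dtype=bool)
            private[rng.integers(10)] = True
            cols[f"p{k}"] = private
        chars = CharacterMatrix(pd.DataFrame(cols, index=fields))
        t = phylo.search_tree(chars, restarts=5, seed=0)
        sides = []
        for u, v in t.edges():
            comp = phylo._component_nodes(t, v, u)
            names = {t.leaf_names[x] for x in comp if x < t.n_leaves}
            sides.append(names)
            sides.append(set(fields) - names)
        assert gamma_set in sides

    def test_single_field_rejected(self):
        m = pd.DataFrame([[1]], index=["a"], columns=["x"])
        with pytest.raises(ValueError):
            phylo.search_tree(CharacterMatrix(m))


class TestClustersAndOrder:
    @pytest.fixture(scope="class")
    def planted(self):
        fields = [f"F{j}" for j in range(9)]
        clones = [set(fields[:3]), set(fields[3:6]), set(fields[6:])]
        cols = {}
        for ci, cl in enumerate(clones):
            for k in range(8):
                cols[f"c{ci}_{k}"] = [f in cl for f in fields]
        chars = CharacterMatrix(pd.DataFrame(cols, index=fields))
        tree = phylo.search_tree(chars, restarts=5, seed=0)
        d = phylo.hamming_matrix(chars)
        return fields, clones, chars, tree, d

    def test_k1_single_cluster(self, planted):
        fields, _, _, tree, d = planted
        part = phylo.branch_clusters(tree, d, k=1)
        assert set(part.values()) == {0}

    def test_kn_singletons(self, planted):
        fields, _, _, tree, d = planted
        part = phylo.branch_clusters(tree, d, k=len(fields))
        assert len(set(part.values())) == len(fields)

    def test_three_planted_clones_recovered(self, planted):
        fields, clones, _, tree, d = planted
        part = phylo.branch_clusters(tree, d, k=3)
        recovered = {}
        for f, c in part.items():
            recovered.setdefault(c, set()).add(f)
        assert sorted(map(sorted, recovered.values())) == sorted(
            map(sorted, clones)
        )

    def test_k_too_large_rejected(self, planted):
        _, _, _, tree, d = planted
        with pytest.raises(ValueError):
            phylo.branch_clusters(tree, d, k=100)

    def test_tree_order_deterministic_and_orientation_invariant(self, planted):
        _, _, chars, tree, _ = planted
        o1 = phylo.tree_order(tree)
        o2 = phylo.tree_order(tree)
        assert o1 == o2
        mirrored = tree.copy()
        for u in mirrored.adjacency:
            mirrored.adjacency[u] = list(reversed(mirrored.adjacency[u]))
        assert phylo.tree_order(mirrored) == o1
        assert sorted(o1) == sorted(tree.leaf_names)

    def test_caterpillar_path_order(self):
        # caterpillar on 5 leaves: a-b | c | d | e hanging off a backbone
        adj = {
            0: [5], 1: [5], 5: [0, 1, 6],
            2: [6], 6: [2, 5, 7],
            3: [7], 7: [3, 6, 4],
            4: [7],
        }
        tree = OrganTree({k: list(v) for k, v in adj.items()}, list("abcde"))
        order = phylo.tree_order(tree)
        pos = {name: i for i, name in enumerate(order)}
        assert abs(pos["a"] - pos["b"]) == 1  # cherry stays adjacent
        assert pos["e"] == len(order) - 1 or pos["e"] == 0


class TestRootingAndNewick:
    def test_rooted_newick_parses_with_dendropy(self, small_organ):
        import dendropy

        chars = phylo.character_matrix(small_organ.mutations)
        t = phylo.search_tree(chars, restarts=2, seed=0)
        rooted = phylo.root_at_ancestor(t, chars)
        lengths = phylo.edge_parsimony_lengths(rooted.tree, chars)
        nwk = rooted.tree.newick(lengths)
        parsed = dendropy.Tree.get(
            data=nwk, schema="newick", preserve_underscores=True
        )
        taxa = {x.taxon.label for x in parsed.leaf_node_iter() if x.taxon}
        # the planted ancestor is rendered as the "node0" root, not a leaf
        assert taxa == set(chars.field_ids)
        assert "node0" in nwk

    def test_edge_lengths_sum_to_parsimony_score(self, small_organ):
        chars = phylo.character_matrix(small_organ.mutations)
        t = phylo.search_tree(chars, restarts=2, seed=0)
        rooted = phylo.root_at_ancestor(t, chars)
        lengths = phylo.edge_parsimony_lengths(rooted.tree, chars)
        aug_score = phylo.fitch_score(
            rooted.tree,
            CharacterMatrix(
                pd.concat(
                    [
                        chars.matrix,
                        pd.DataFrame(
                            False, index=["__ancestor__"],
                            columns=chars.matrix.columns,
                        ),
                    ]
                )
            ),
        )
        assert sum(lengths.values()) == aug_score
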