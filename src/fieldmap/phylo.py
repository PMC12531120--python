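"""Maximum-parsimony tree of mucosal fields from mutation presence profiles.

Fields are leaves; characters are binary presence calls (VAF >= threshold)
over all silent and nonsilent mutations.  The search is heuristic: a
neighbour-joining start from the Hamming distance matrix followed by
nearest-neighbour-interchange hill climbing on the Fitch parsimony score,
best over random-restart stepwise-addition trees.  An exhaustive enumerator
over all unrooted topologies is provided for small instances.

The tree is unrooted for analysis; for display and timing it can be rooted
at a hypothetical all-zero ancestor ("node 0") attached to the edge where
the mutation-free state is most parsimonious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import MutationTable

__all__ = [
    "CharacterMatrix",
    "OrganTree",
    "character_matrix",
    "hamming_matrix",
    "fitch_score",
    "search_tree",
    "exhaustive_min_score",
    "branch_clusters",
    "tree_order",
    "edge_parsimony_lengths",
    "RootedTree",
    "root_at_ancestor",
]


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterMatrix:
    """Binary fields x mutations presence matrix for tree building."""

    matrix: pd.DataFrame  # bool, index=field ids, columns=mutation ids

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if vals.dtype != bool:
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("character matrix entries must be 0/1")
            object.__setattr__(self, "matrix", self.matrix.astype(bool))

    @property
    def field_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_fields(self) -> int:
        return len(self.matrix)

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique column patterns and their multiplicities (scoring cache)."""
        pats, counts = np.unique(
            self.matrix.to_numpy(dtype=np.uint8), axis=1, return_counts=True
        )
        return pats, counts


def character_matrix(
    mutations: MutationTable,
    threshold: float = 0.01,
    drop_empty_fields: bool = True,
) -> CharacterMatrix:
    """Presence characters from all (silent and nonsilent) mutations."""
    pres = (mutations.vaf >= threshold).T  # fields x mutations
    empty = ~pres.any(axis=1)
    if empty.any():
        if not drop_empty_fields:
            raise ValueError(f"fields with no mutations: {list(pres.index[empty])}")
        warnings.warn(
            f"dropping {int(empty.sum())} field(s) with no mutation present: "
            f"{list(pres.index[empty])}"
        )
        pres = pres.loc[~empty]
    return CharacterMatrix(pres)


def hamming_matrix(chars: CharacterMatrix) -> pd.DataFrame:
    """Pairwise Hamming distances (number of discordant presence calls)."""
    if chars.n_fields < 2:
        raise ValueError("need at least 2 fields")
    x = chars.matrix.to_numpy(dtype=np.int64)
    y = 1 - x
    d = x @ y.T + y @ x.T
    return pd.DataFrame(d, index=chars.field_ids, columns=chars.field_ids)


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------


@dataclass
class OrganTree:
    """Unrooted tree; leaves 0..n-1 carry ``leaf_names``, internal nodes >= n.

    ``score`` caches the Fitch parsimony score of the tree on the matrix it
    was built from; ``root`` is set when an all-zero ancestor has been
    attached (see :func:`root_at_ancestor`).
    """

    adjacency: dict[int, list[int]]
    leaf_names: list[str]
    score: int | None = None
    root: int | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def copy(self) -> "OrganTree":
        return OrganTree(
            {u: list(vs) for u, vs in self.adjacency.items()},
            list(self.leaf_names),
            self.score,
            self.root,
        )

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, vs in self.adjacency.items() for v in vs if u < v]

    def internal_edges(self) -> list[tuple[int, int]]:
        n = self.n_leaves
        return [(u, v) for u, v in self.edges() if u >= n and v >= n]

    def postorder(self, start: int) -> list[tuple[int, int]]:
        """(node, parent) pairs in postorder, rooted at ``start``."""
        out: list[tuple[int, int]] = []
        stack = [(start, -1)]
        while stack:
            node, parent = stack.pop()
            out.append((node, parent))
            for nb in self.adjacency[node]:
                if nb != parent:
                    stack.append((nb, node))
        out.reverse()
        return out

    def newick(self, lengths: dict[frozenset, int] | None = None) -> str:
        """Newick string; rooted at ``root`` when set, else at the internal
        node adjacent to the first leaf."""
        if self.root is not None:
            start = self.root
        elif self.n_leaves == 1:
            return f"{self.leaf_names[0]};"
        else:
            start = self.adjacency[0][0]

        def fmt(node: int, parent: int) -> str:
            kids = [nb for nb in self.adjacency[node] if nb != parent]
            if not kids:
                label = self.leaf_names[node] if node < self.n_leaves else f"n{node}"
            else:
                label = "(" + ",".join(fmt(k, node) for k in kids) + ")"
                if node == self.root:
                    label += "node0"
            if parent >= 0 and lengths is not None:
                label += f":{lengths.get(frozenset((node, parent)), 0)}"
            return label

        return fmt(start, -1) + ";"


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------


def _score_patterns(
    tree: OrganTree, pats: np.ndarray, counts: np.ndarray
) -> int:
    """Vectorised Fitch small-parsimony score over unique patterns.

    Leaf state sets are bitmasks (1 = absent, 2 = present); an intersection
    that comes up empty at an internal node costs one change per character.
    """
    n = tree.n_leaves
    if n == 1:
        return 0
    if len(tree.adjacency) == 2:
        u, v = sorted(tree.adjacency)
        return int((counts * (pats[u] != pats[v])).sum())
    # root at an internal node: rooting at a leaf would skip its final merge
    start = next(u for u in sorted(tree.adjacency) if u >= n)
    order = tree.postorder(start)
    masks: dict[int, np.ndarray] = {}
    changes = np.zeros(pats.shape[1], dtype=np.int64)
    for node, parent in order:
        if node < n:
            masks[node] = np.where(pats[node], 2, 1).astype(np.uint8)
        else:
            acc = None
            for nb in tree.adjacency[node]:
                if nb == parent:
                    continue
                child = masks.pop(nb)
                if acc is None:
                    acc = child
                    continue
                inter = acc & child
                empty = inter == 0
                changes += empty * 1
                acc = np.where(empty, acc | child, inter).astype(np.uint8)
            masks[node] = acc
    return int((changes * counts).sum())


def fitch_score(tree: OrganTree, chars: CharacterMatrix) -> int:
    """Total parsimony score (minimum state changes summed over characters)."""
    if tree.leaf_names != chars.field_ids:
        if sorted(tree.leaf_names) != sorted(chars.field_ids):
            raise ValueError("tree leaves do not match character-matrix fields")
        chars = CharacterMatrix(chars.matrix.loc[tree.leaf_names])
    pats, counts = chars.patterns()
    return _score_patterns(tree, pats, counts)


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------


def _tree_from_pairs(pairs: dict[int, set[int]], leaf_names: list[str]) -> OrganTree:
    adj = {u: sorted(vs) for u, vs in pairs.items()}
    return OrganTree(adj, leaf_names)


def _nj_start(chars: CharacterMatrix) -> OrganTree:
    """Neighbour-joining start topology from the Hamming matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    d = hamming_matrix(chars).to_numpy(dtype=float)
    # neighbour joining needs distinct ids and non-degenerate distances
    dm = DistanceMatrix(d, ids=chars.field_ids)
    t = skbio_nj(dm)
    name_to_id = {name: i for i, name in enumerate(chars.field_ids)}
    adj: dict[int, set[int]] = {}
    node_ids: dict[int, int] = {}
    nxt = chars.n_fields

    def get_id(node) -> int:
        nonlocal nxt
        key = id(node)
        if key not in node_ids:
            if node.name in name_to_id:
                node_ids[key] = name_to_id[node.name]
            else:
                node_ids[key] = nxt
                nxt += 1
        return node_ids[key]

    for node in t.traverse():
        u = get_id(node)
        adj.setdefault(u, set())
        for child in node.children:
            v = get_id(child)
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
    # suppress any degree-2 node (skbio may root the tree arbitrarily)
    for u in [u for u, vs in adj.items() if len(vs) == 2]:
        a, b = sorted(adj[u])
        adj[a].discard(u)
        adj[b].discard(u)
        adj[a].add(b)
        adj[b].add(a)
        del adj[u]
    # compact internal ids to n, n+1, ...
    remap = {u: u for u in sorted(adj) if u < chars.n_fields}
    for u in sorted(u for u in adj if u >= chars.n_fields):
        remap[u] = len(remap)
    adj2 = {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}
    return _tree_from_pairs(adj2, chars.field_ids)


def _greedy_stepwise(
    order: Sequence[int],
    leaf_names: list[str],
    pats: np.ndarray,
    counts: np.ndarray,
) -> OrganTree:
    """Stepwise addition placing each leaf on the most parsimonious edge."""
    n = len(leaf_names)
    if n == 2:
        return OrganTree({order[0]: [order[1]], order[1]: [order[0]]}, leaf_names)
    nxt = n
    a, b, c = order[0], order[1], order[2]
    adj: dict[int, set[int]] = {a: {nxt}, b: {nxt}, c: {nxt}, nxt: {a, b, c}}
    nxt += 1
    for leaf in order[3:]:
        best = None
        edges = [(u, v) for u, vs in adj.items() for v in vs if u < v]
        for u, v in edges:
            adj[u].discard(v)
            adj[v].discard(u)
            adj[nxt] = {u, v, leaf}
            adj[u].add(nxt)
            adj[v].add(nxt)
            adj[leaf] = {nxt}
            s = _score_patterns(_tree_from_pairs(adj, leaf_names), pats, counts)
            if best is None or s < best[0]:
                best = (s, (u, v))
            # undo
            del adj[nxt]
            del adj[leaf]
            adj[u].discard(nxt)
            adj[v].discard(nxt)
            adj[u].add(v)
            adj[v].add(u)
        u, v = best[1]
        adj[u].discard(v)
        adj[v].discard(u)
        adj[nxt] = {u, v, leaf}
        adj[u].add(nxt)
        adj[v].add(nxt)
        adj[leaf] = {nxt}
        nxt += 1
    return _tree_from_pairs(adj, leaf_names)


def _nni_neighbours(tree: OrganTree, u: int, v: int) -> Iterator[OrganTree]:
    """The two NNI rearrangements across the internal edge (u, v)."""
    a, b = [x for x in tree.adjacency[u] if x != v]
    c, d = [x for x in tree.adjacency[v] if x != u]
    for swap_u, swap_v in ((b, c), (b, d)):
        t = tree.copy()
        adj = t.adjacency
        adj[u] = [x if x != swap_u else swap_v for x in adj[u]]
        adj[v] = [x if x != swap_v else swap_u for x in adj[v]]
        adj[swap_u] = [x if x != u else v for x in adj[swap_u]]
        adj[swap_v] = [x if x != v else u for x in adj[swap_v]]
        t.score = None
        yield t


def _hill_climb(tree: OrganTree, pats: np.ndarray, counts: np.ndarray) -> OrganTree:
    best = tree
    best_score = _score_patterns(tree, pats, counts)
    improved = True
    while improved:
        improved = False
        for u, v in best.internal_edges():
            for cand in _nni_neighbours(best, u, v):
                s = _score_patterns(cand, pats, counts)
                if s < best_score:
                    best, best_score = cand, s
                    improved = True
                    break
            if improved:
                break
    best.score = best_score
    return best


def search_tree(
    chars: CharacterMatrix, restarts: int = 10, seed: int = 0
) -> OrganTree:
    """Heuristic maximum-parsimony search (NJ start + NNI, random restarts)."""
    n = chars.n_fields
    if n < 2:
        raise ValueError("need at least 2 fields to build a tree")
    pats, counts = chars.patterns()
    if n == 2:
        t = OrganTree({0: [1], 1: [0]}, chars.field_ids)
        t.score = _score_patterns(t, pats, counts)
        return t
    starts = [_nj_start(chars)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, restarts - 1)):
        order = list(rng.permutation(n))
        starts.append(_greedy_stepwise(order, chars.field_ids, pats, counts))
    best = None
    for s in starts:
        t = _hill_climb(s, pats, counts)
        if best is None or t.score < best.score:
            best = t
    return best


def _enumerate_topologies(n: int) -> Iterator[OrganTree]:
    """All unrooted binary topologies on leaves 0..n-1 by edge insertion."""
    names = [str(i) for i in range(n)]

    def grow(adj: dict[int, set[int]], leaf: int, nxt: int) -> Iterator[dict]:
        if leaf == n:
            yield adj
            return
        edges = [(u, v) for u, vs in adj.items() for v in vs if u < v]
        for u, v in edges:
            adj2 = {k: set(s) for k, s in adj.items()}
            adj2[u].discard(v)
            adj2[v].discard(u)
            adj2[nxt] = {u, v, leaf}
            adj2[u].add(nxt)
            adj2[v].add(nxt)
            adj2[leaf] = {nxt}
            yield from grow(adj2, leaf + 1, nxt + 1)

    if n == 2:
        yield OrganTree({0: [1], 1: [0]}, names)
        return
    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    for adj in grow(base, 3, n + 1):
        yield _tree_from_pairs(adj, names)


def exhaustive_min_score(chars: CharacterMatrix, max_leaves: int = 9) -> int:
    """Exact minimum parsimony score by enumerating every unrooted topology.

    Exponential; guarded to small leaf counts.  Used as the ground truth the
    heuristic search is measured against.
    """
    n = chars.n_fields
    if n > max_leaves:
        raise ValueError(f"exhaustive search limited to {max_leaves} leaves")
    pats, counts = chars.patterns()
    best = None
    for tree in _enumerate_topologies(n):
        s = _score_patterns(tree, pats, counts)
        if best is None or s < best:
            best = s
    return int(best)


# ---------------------------------------------------------------------------
# rooting, edge lengths, ordering, clusters
# ---------------------------------------------------------------------------


@dataclass
class RootedTree:
    """Rooted view with the all-zero ancestor as node 0 of the display."""

    tree: OrganTree  # includes the ancestor node (tree.root)
    parent: dict[int, int]  # node -> parent (root maps to -1)
    preorder: list[int]
    clades: dict[int, frozenset]  # node -> leaf-name set below it


def root_at_ancestor(tree: OrganTree, chars: CharacterMatrix) -> RootedTree:
    """Attach a mutation-free ancestor to the most parsimonious edge.

    Every edge is tried; the ancestor is grafted where the total score of the
    augmented tree is minimal (ties broken by the lexicographically smallest
    sorted leaf-set on the far side of the edge).
    """
    base = CharacterMatrix(chars.matrix.loc[tree.leaf_names])
    zero_row = pd.DataFrame(
        False, index=["__ancestor__"], columns=base.matrix.columns
    )
    aug = CharacterMatrix(pd.concat([base.matrix, zero_row]))
    pats, counts = aug.patterns()
    n = tree.n_leaves
    best = None
    for u, v in tree.edges():
        cand = tree.copy()
        # renumber: ancestor leaf gets id n; old internal ids shift by 1
        shift = {x: (x if x < n else x + 1) for x in cand.adjacency}
        adj = {shift[x]: {shift[y] for y in ys} for x, ys in cand.adjacency.items()}
        su, sv = shift[u], shift[v]
        mid = max(max(adj), n) + 1
        adj[su].discard(sv)
        adj[sv].discard(su)
        adj[mid] = {su, sv, n}
        adj[su].add(mid)
        adj[sv].add(mid)
        adj[n] = {mid}
        cand2 = _tree_from_pairs(adj, tree.leaf_names + ["__ancestor__"])
        s = _score_patterns(cand2, pats, counts)
        far = frozenset(
            tree.leaf_names[x] for x in _component_nodes(tree, v, u) if x < n
        )
        key = (s, tuple(sorted(far)))
        if best is None or key < best[0]:
            best = (key, cand2)
    _, rooted = best
    # the ancestor leaf is the root of the display
    rooted.root = rooted.leaf_names.index("__ancestor__")
    parent: dict[int, int] = {}
    preorder: list[int] = []
    order = rooted.postorder(rooted.root)
    for node, par in order:
        parent[node] = par
    preorder = [node for node, _ in reversed(order)]
    clades: dict[int, frozenset] = {}
    nl = rooted.n_leaves
    for node, par in order:
        if node < nl:
            name = rooted.leaf_names[node]
            clades[node] = frozenset() if name == "__ancestor__" else frozenset([name])
        else:
            clades[node] = frozenset().union(
                *(clades[nb] for nb in rooted.adjacency[node] if nb != par)
            )
    return RootedTree(rooted, parent, preorder, clades)


def _component_nodes(tree: OrganTree, side: int, other: int) -> set[int]:
    """Nodes in the component of ``side`` when edge (side, other) is cut."""
    stack = [side]
    seen = {other}
    comp: set[int] = set()
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        comp.add(x)
        stack.extend(tree.adjacency[x])
    return comp


def edge_parsimony_lengths(
    tree: OrganTree, chars: CharacterMatrix
) -> dict[frozenset, int]:
    """Per-edge change counts under a deterministic Fitch state assignment.

    The up-pass computes Fitch state sets; the down-pass resolves each node to
    a single state, preferring the parent's state when admissible and the
    absent state otherwise (the ancestor-free convention).
    """
    real = [x for x in tree.leaf_names if x != "__ancestor__"]
    base = CharacterMatrix(chars.matrix.loc[real])
    pats, counts = base.patterns()
    row_of = {name: i for i, name in enumerate(real)}
    n = tree.n_leaves
    if n < 2:
        return {}
    start = tree.root if tree.root is not None else tree.adjacency[0][0]
    order = tree.postorder(start)
    parent_of = {node: par for node, par in order}
    masks: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node < n:
            name = tree.leaf_names[node]
            if name == "__ancestor__":
                masks[node] = np.full(pats.shape[1], 1, dtype=np.uint8)
            else:
                masks[node] = np.where(pats[row_of[name]], 2, 1).astype(np.uint8)
        else:
            acc = None
            for nb in tree.adjacency[node]:
                if nb == parent:
                    continue
                child = masks[nb]
                if acc is None:
                    acc = child.copy()
                    continue
                inter = acc & child
                acc = np.where(inter == 0, acc | child, inter).astype(np.uint8)
            masks[node] = acc
    # down-pass: resolve each node to a single state (0 = absent, 1 = present)
    states: dict[int, np.ndarray] = {}
    lengths: dict[frozenset, int] = {}
    for node, _ in reversed(order):
        parent = parent_of[node]
        m = masks[node]
        if parent < 0:
            states[node] = np.where(m & 1, 0, 1).astype(np.uint8)  # prefer absent
        else:
            ps = states[parent]
            pmask = np.where(ps == 0, 1, 2).astype(np.uint8)
            keep = (m & pmask) > 0
            states[node] = np.where(keep, ps, np.where(m & 1, 0, 1)).astype(np.uint8)
            diff = states[node] != ps
            lengths[frozenset((node, parent))] = int((diff * counts).sum())
    return lengths


def tree_order(tree: OrganTree) -> list[str]:
    """Deterministic leaf ordering for distance-heatmap display.

    Traversal from the root (the planted ancestor when present, else the
    internal node next to the lexicographically smallest leaf); children are
    visited smallest-subtree first, ties broken by smallest leaf name.
    Invariant under any permutation of the stored child order.
    """
    n = tree.n_leaves
    if n == 1:
        return list(tree.leaf_names)
    if tree.root is not None:
        start = tree.root
    else:
        first = min(range(n), key=lambda i: tree.leaf_names[i])
        start = tree.adjacency[first][0]
    info: dict[int, tuple[int, str]] = {}
    for node, parent in tree.postorder(start):
        if node < n:
            info[node] = (1, tree.leaf_names[node])
        else:
            kids = [info[nb] for nb in tree.adjacency[node] if nb != parent]
            info[node] = (sum(k[0] for k in kids), min(k[1] for k in kids))

    out: list[str] = []

    def walk(node: int, parent: int) -> None:
        if node < n:
            if tree.leaf_names[node] != "__ancestor__":
                out.append(tree.leaf_names[node])
            return
        kids = sorted(
            (nb for nb in tree.adjacency[node] if nb != parent),
            key=lambda nb: info[nb],
        )
        for k in kids:
            walk(k, node)

    walk(start, -1)
    return out


def branch_clusters(
    tree: OrganTree,
    distances: pd.DataFrame,
    k: int = 3,
) -> dict[str, int]:
    """Partition fields into ``k`` branches by greedy edge removal.

    At each step the edge whose removal maximises the minimum inter-cluster
    Hamming distance is cut; ties broken by the lexicographically smallest
    sorted leaf-set of the newly split-off cluster.
    """
    leaves = [x for x in tree.leaf_names if x != "__ancestor__"]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds the number of fields ({len(leaves)})")
    n = tree.n_leaves

    def components(removed: set[frozenset]) -> list[frozenset]:
        seen: set[int] = set()
        comps = []
        for node in tree.adjacency:
            if node in seen:
                continue
            stack, comp = [node], set()
            while stack:
                x = stack.pop()
                if x in seen:
                    continue
                seen.add(x)
                comp.add(x)
                for nb in tree.adjacency[x]:
                    if frozenset((x, nb)) not in removed:
                        stack.append(nb)
            names = frozenset(
                tree.leaf_names[x]
                for x in comp
                if x < n and tree.leaf_names[x] != "__ancestor__"
            )
            comps.append(names)
        return comps

    def objective(comps: list[frozenset]) -> float:
        groups = [sorted(c) for c in comps if c]
        if len(groups) < 2:
            return float("inf")
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = distances.loc[groups[i], groups[j]].to_numpy().min()
                best = d if best is None else min(best, d)
        return float(best)

    removed: set[frozenset] = set()
    all_edges = [frozenset(e) for e in tree.edges()]
    for _ in range(k - 1):
        best_key = None
        best_edge = None
        for e in all_edges:
            if e in removed:
                continue
            comps = components(removed | {e})
            if any(not c for c in comps):
                continue  # would strand a leafless component
            score = objective(comps)
            sig = tuple(sorted(tuple(sorted(c)) for c in comps))
            key = (-score, sig)
            if best_key is None or key < best_key:
                best_key = key
                best_edge = e
        if best_edge is None:
            raise ValueError("cannot split further: no admissible edge")
        removed.add(best_edge)
    comps = [c for c in components(removed) if c]
    comps.sort(key=lambda c: sorted(c)[0])
    assignment = {}
    for ci, comp in enumerate(comps):
        for name in comp:
            assignment[name] = ci
    return assignment
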