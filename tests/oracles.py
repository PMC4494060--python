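"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exhaustive
enumeration over ancestral state assignments, over tree topologies, and over
rank splits, so the dynamic programs and closed forms in the package can be
checked against first principles on small instances.
"""

from __future__ import annotations

from itertools import product

import dendropy
import numpy as np

from archflux.geneflux import CostScheme, transition_cost


def exhaustive_sankoff_cost(
    tree: dendropy.Tree,
    leaf_states: dict[str, int],
    costs: CostScheme,
    max_state: int,
    charge_root: bool,
) -> float:
    """Global minimum cost by enumerating every internal state assignment."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = np.inf
    for assignment in product(range(max_state + 1), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assignment)}
        for leaf in tree.leaf_node_iter():
            state[id(leaf)] = leaf_states[leaf.taxon.label]
        cost = 0.0
        root = tree.seed_node
        if charge_root:
            cost += transition_cost(0, state[id(root)], costs)
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                cost += transition_cost(state[id(node)], state[id(child)], costs)
        best = min(best, cost)
    return best


def random_rooted_binary_tree(
    labels: list[str], rng: np.random.Generator
) -> dendropy.Tree:
    """Random rooted binary topology with unit-ish branch lengths."""
    items = [f"{l}:{rng.uniform(0.1, 1.0):.3f}" for l in labels]
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]}):{rng.uniform(0.1, 1.0):.3f}"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    newick = items[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# joint two-site parsimony over all unrooted topologies


def _all_unrooted_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1, as edge lists.

    Nodes 0..n-1 are leaves; internal nodes get indices >= n.
    """
    assert n >= 3
    base = [(0, n), (1, n), (2, n)]
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        new_trees = []
        for edges, next_node in trees:
            for k, (u, v) in enumerate(edges):
                ne = edges[:k] + edges[k + 1:]
                ne = ne + [(u, next_node), (v, next_node), (leaf, next_node)]
                new_trees.append((ne, next_node + 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def _parsimony_length(edges, leaf_state: dict[int, int], n_states: int) -> int:
    """Unit-cost parsimony length of one character on an edge-list tree."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = 0  # root at leaf 0; DP over the implied rooted tree
    INF = 10**6

    def dp(node: int, parent: int) -> np.ndarray:
        if node in leaf_state:
            vec = np.full(n_states, INF)
            vec[leaf_state[node]] = 0
            base = vec
        else:
            base = np.zeros(n_states, dtype=int)
        total = base.astype(int).copy()
        for nb in adj[node]:
            if nb == parent:
                continue
            child_vec = dp(nb, node)
            # unit cost: min(child_vec) + 1, or child_vec[s] if same state
            total += np.minimum(child_vec, child_vec.min() + 1)
        return total

    child = adj[root][0]
    vec = dp(child, root)
    s0 = leaf_state[root]
    return int(min(vec[s0], vec.min() + 1))


def min_joint_changes(col_i: list, col_j: list) -> int:
    """Minimum total changes for two sites on the best common topology.

    Sequences missing at either site are dropped; both characters are scored
    by unit-cost parsimony on every unrooted binary topology and the summed
    minimum over topologies is returned.
    """
    pairs = [(x, y) for x, y in zip(col_i, col_j) if x is not None and y is not None]
    n = len(pairs)
    states_i = sorted({x for x, _ in pairs})
    states_j = sorted({y for _, y in pairs})
    enc_i = {s: k for k, s in enumerate(states_i)}
    enc_j = {s: k for k, s in enumerate(states_j)}
    best = None
    for edges in _all_unrooted_topologies(n):
        li = _parsimony_length(
            edges, {k: enc_i[pairs[k][0]] for k in range(n)}, len(states_i)
        )
        lj = _parsimony_length(
            edges, {k: enc_j[pairs[k][1]] for k in range(n)}, len(states_j)
        )
        total = li + lj
        if best is None or total < best:
            best = total
    return best


def kruskal_wallis_by_formula(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook rank-sum formula."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(N)
    sorted_vals = pooled[order]
    i = 0
    while i < N:
        j = i
        while j < N and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    return H / tie
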