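"""Independent brute-force oracles used to validate the engine.

Everything here is deliberately naive pure-Python (dict recursion, explicit
enumeration) and shares no code with the package's optimized paths.
"""

from __future__ import annotations

from itertools import combinations

from morphoclad.tree_model import PhyloTree

BIG = 10**9


def sankoff_steps(tree: PhyloTree, codes_by_label: dict[str, int | None], n_states: int = 10) -> int:
    """Uniform-cost Sankoff dynamic program for one character.

    ``codes_by_label``: observed state per taxon, None for missing or
    inapplicable (any state allowed).  Handles polytomies naturally.
    """
    observed = sorted({s for s in codes_by_label.values() if s is not None})
    if len(observed) <= 1:
        return 0
    states = observed  # unobserved states never help under uniform costs

    label_of = tree.leaf_labels
    some_leaf = next(iter(label_of))

    def cost(node: int, came_from: int | None) -> dict[int, int]:
        nbrs = [v for v in tree.adj[node] if v != came_from]
        if node in label_of:
            s = codes_by_label[label_of[node]]
            leaf = {t: (0 if s is None or t == s else BIG) for t in states}
            if not nbrs:
                return leaf
            base = leaf
        else:
            base = {t: 0 for t in states}
        for child in nbrs:
            sub = cost(child, node)
            best = min(sub.values())
            base = {
                t: base[t] + min(sub[t], best + 1)
                for t in states
            }
        return base

    return min(cost(some_leaf, None).values())


def matrix_sankoff_length(tree: PhyloTree, matrix) -> int:
    """Total Sankoff length of a matrix (missing/inapplicable = None)."""
    total = 0
    for j in range(matrix.n_chars):
        codes = {
            lab: (int(c) if c >= 0 else None)
            for lab, c in zip(matrix.taxon_labels, matrix.codes[:, j])
        }
        total += sankoff_steps(tree, codes)
    return total


def all_binary_topologies(labels: list[str]):
    """Yield every unrooted binary topology over ``labels`` (n >= 4)."""
    n = len(labels)
    hub = n
    adj = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}

    def recurse(adj, next_taxon, next_node):
        if next_taxon == n:
            yield PhyloTree(
                {u: list(vs) for u, vs in adj.items()},
                {i: labels[i] for i in range(n)},
            )
            return
        edges = [(a, b) for a in sorted(adj) for b in adj[a] if a < b]
        for p, q in edges:
            m = next_node
            adj[p] = [y for y in adj[p] if y != q] + [m]
            adj[q] = [y for y in adj[q] if y != p] + [m]
            adj[m] = [p, q, next_taxon]
            adj[next_taxon] = [m]
            yield from recurse(adj, next_taxon + 1, next_node + 1)
            del adj[next_taxon]
            del adj[m]
            adj[p] = [y for y in adj[p] if y != m] + [q]
            adj[q] = [y for y in adj[q] if y != m] + [p]

    yield from recurse(adj, 3, n + 1)


def leaf_path_partition(tree: PhyloTree) -> frozenset:
    """Topology signature from quartet-style leaf separation.

    For every pair of leaves, record the multiset of leaves on each side of
    the path's internal branches via explicit component splitting: for each
    edge, split the tree and record the two leaf sets.  Equals the
    bipartition-set signature; used as an independent identity oracle.
    """
    sides = set()
    labels = tree.leaf_labels
    for u, v in tree.edges():
        # leaves reachable from u without crossing (u, v)
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in tree.adj[x]:
                if (x == u and y == v) or y in seen:
                    continue
                seen.add(y)
                stack.append(y)
        side = frozenset(labels[x] for x in seen if x in labels)
        other = frozenset(labels.values()) - side
        if 2 <= len(side) <= tree.n_leaves - 2:
            sides.add(frozenset((side, other)))
    return frozenset(sides)
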