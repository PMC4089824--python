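"""Heuristic maximum-parsimony tree search.

The strategy mirrors classic parsimony software: each replicate builds a
Wagner tree by stepwise addition in a random taxon order, then improves it
by tree-bisection-reconnection (TBR) branch swapping, holding a bounded
number of equally parsimonious trees.  Best trees pooled over replicates
are swapped to completion (every tree on the plateau gets a full TBR
neighborhood scan) up to a tree-count cap, then ambiguously supported
branches — branches on which no character change is forced in every
most-parsimonious reconstruction — are collapsed and duplicate topologies
removed.

Reconnection costs are exact, not approximate: joining two subtrees by an
edge costs ``L1 + L2 + [R1 and R2 share no state]`` per character, where
``Ri`` is the Fitch state set of subtree ``i`` rooted at its reattachment
edge.  This follows from the root-independence of Fitch lengths and makes
a full TBR scan a pair of directional-set passes per bisection plus one
vectorized pairwise comparison.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CharacterMatrix
from .parsimony_engine import EncodedMatrix, encode_matrix, edge_analysis
from .tree_model import PhyloTree
from . import _fastscan

__all__ = [
    "SearchConfig",
    "ReplicateRecord",
    "SearchResult",
    "wagner_build",
    "tbr_swap",
    "heuristic_search",
    "collapse_ambiguous",
    "exhaustive_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Replicate/hold/cap settings for :func:`heuristic_search`.

    Defaults follow the published Helopini protocol: 1000 random-addition
    replicates holding 20 trees each, final swap to completion with up to
    10000 trees, ambiguous-branch collapsing.
    """

    n_replicates: int = 1000
    hold_per_replicate: int = 20
    max_trees: int = 10000
    seed: int = 0
    collapse_rule: str = "ambiguous"  # or "none"
    final_sweep: bool = True

    def __post_init__(self) -> None:
        if min(self.n_replicates, self.hold_per_replicate, self.max_trees) < 1:
            raise ValueError("all counts must be >= 1")
        if self.hold_per_replicate > self.max_trees:
            raise ValueError("hold_per_replicate must not exceed max_trees")
        if self.collapse_rule not in ("ambiguous", "none"):
            raise ValueError("collapse_rule must be 'ambiguous' or 'none'")


@dataclass(frozen=True)
class ReplicateRecord:
    index: int
    seed: int
    addition_order: tuple[int, ...]
    best_length: int


@dataclass
class SearchResult:
    best_length: int
    trees: list[PhyloTree]
    replicate_log: list[ReplicateRecord]
    hit_max_trees: bool = False


# ---------------------------------------------------------------------------
# internal flat representation: adjacency dict, leaves 0..n-1 = matrix rows


def _to_internal(tree: PhyloTree, labels: list[str]) -> dict[int, list[int]]:
    row = {lab: i for i, lab in enumerate(labels)}
    mapping: dict[int, int] = {}
    nxt = len(labels)
    for node in tree.adj:
        if node in tree.leaf_labels:
            mapping[node] = row[tree.leaf_labels[node]]
        else:
            mapping[node] = nxt
            nxt += 1
    return {mapping[u]: [mapping[v] for v in vs] for u, vs in tree.adj.items()}


def _to_phylo(adj: dict[int, list[int]], labels: list[str]) -> PhyloTree:
    n = len(labels)
    return PhyloTree(adj, {i: labels[i] for i in range(n) if i in adj})


def _copy(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {u: list(vs) for u, vs in adj.items()}


def _fingerprint(adj: dict[int, list[int]], n: int) -> frozenset[int]:
    """Unrooted topology identity: informative splits as leaf bitmasks."""
    full = (1 << n) - 1
    root = 0
    parent = {root: -1}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    below: dict[int, int] = {}
    splits = []
    for u in reversed(order):
        mask = 1 << u if u < n else 0
        for v in adj[u]:
            if v != parent[u]:
                mask |= below[v]
        below[u] = mask
        if u != root:
            side = (full ^ mask) if (mask & 1) else mask
            c = side.bit_count()
            if 2 <= c <= n - 2:
                splits.append(side)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# Fitch kernel


class _Kernel:
    def __init__(self, enc: EncodedMatrix):
        self.masks = enc.masks  # (n_leaves, C)
        self.weights = enc.weights.astype(np.int64)
        self.n = enc.masks.shape[0]

    def length(self, adj: dict[int, list[int]]) -> int:
        _, _, L = self._edge_sets(adj, want_sets=False)
        return L

    @staticmethod
    def _postorder(adj, root):
        parent = {root: -1}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        return order, parent

    @staticmethod
    def _join(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        inter = a & b
        return np.where(inter == 0, a | b, inter)

    def _edge_sets(self, adj, want_sets=True):
        """Directional Fitch sets of every edge plus total length.

        Returns ``(edges, R, L)``: for each undirected edge the combined
        root state set one would obtain by rooting the tree on that edge.
        Works on any binary unrooted tree whose leaves are < n.
        """
        root = min(u for u in adj if u < self.n)
        order, parent = self._postorder(adj, root)
        if len(order) == 1:
            return [None], self.masks[root][None, :], 0
        up: dict[int, np.ndarray] = {}
        steps = 0
        w = self.weights
        for u in reversed(order):
            kids = [v for v in adj[u] if v != parent[u]]
            if not kids:
                up[u] = self.masks[u]
                continue
            if u == root:
                kids = kids  # root is a leaf: single child
                a = up[kids[0]]
                b = self.masks[root]
            elif len(kids) == 1:  # degree-2 artifact; should not occur
                up[u] = up[kids[0]]
                continue
            else:
                a, b = up[kids[0]], up[kids[1]]
            inter = a & b
            empty = inter == 0
            steps += int(w[empty].sum())
            merged = np.where(empty, a | b, inter)
            if u == root:
                L = steps
                root_set = merged
            else:
                up[u] = merged
        if not want_sets:
            return None, None, L
        down: dict[int, np.ndarray] = {}
        for u in order:
            kids = [v for v in adj[u] if v != parent[u]]
            if u == root:
                down[kids[0]] = self.masks[root]
                continue
            if len(kids) == 2:
                c1, c2 = kids
                down[c1] = self._join(down[u], up[c2])
                down[c2] = self._join(down[u], up[c1])
        edges = []
        rows = []
        for u in order:
            if u == root:
                continue
            edges.append((parent[u], u))
            rows.append(self._join(up[u], down[u]))
        return edges, np.stack(rows), L

    def component(self, adj, start, banned):
        """The unrooted component containing ``start`` after cutting the
        edge (banned, start); the attachment endpoint is suppressed."""
        if len(adj[start]) == 1:  # start is a leaf: single-node component
            return None, [None], self.masks[start][None, :], 0, None
        sub: dict[int, list[int]] = {}
        stack = [start]
        seen = {start}
        while stack:
            u = stack.pop()
            sub[u] = [v for v in adj[u] if v != banned]
            for v in sub[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        merged = None
        if len(sub[start]) == 2:
            a, b = sub[start]
            sub[a] = [x for x in sub[a] if x != start] + [b]
            sub[b] = [x for x in sub[b] if x != start] + [a]
            del sub[start]
            merged = (min(a, b), max(a, b))
        edges, R, L = self._edge_sets(sub)
        edges = [(min(e), max(e)) if e else None for e in edges]
        return sub, edges, R, L, merged


def _apply_tbr(adj, cut, e1, e2, n):
    """Return a new adjacency with the TBR move applied.

    ``cut=(u,v)``: the bisected edge; ``e1`` the reattachment edge on v's
    side (None when v is a leaf), ``e2`` on u's side (None when u is a
    leaf).  The endpoints u and v are reused as the inserted nodes.
    """
    new = _copy(adj)
    u, v = cut
    new[u].remove(v)
    new[v].remove(u)

    def detach_and_insert(x, e):
        if len(new[x]) == 0:  # leaf component
            return
        a, b = new[x]
        new[a] = [y for y in new[a] if y != x] + [b]
        new[b] = [y for y in new[b] if y != x] + [a]
        new[x] = []
        p, q = e
        new[p] = [y for y in new[p] if y != q] + [x]
        new[q] = [y for y in new[q] if y != p] + [x]
        new[x] = [p, q]

    detach_and_insert(v, e1)
    detach_and_insert(u, e2)
    new[u].append(v)
    new[v].append(u)
    return new


def _adj_to_nbr(adj):
    N = max(adj) + 1
    nbr = np.full((N, 3), -1, dtype=np.int64)
    for u, vs in adj.items():
        for k, v in enumerate(vs):
            nbr[u, k] = v
    return nbr


def _tbr_scan(adj, kernel: _Kernel, cur_len: int, equal_cap: int = 0):
    """One full TBR neighborhood evaluation (compiled kernel).

    Returns ``(best_len, best_moves, equal_moves)``: the shortest neighbor
    length found, moves achieving it, and (up to ``equal_cap``) moves whose
    length equals ``cur_len``.  The null reconnection that reproduces the
    current tree is excluded.
    """
    nbr = _adj_to_nbr(adj)
    best_len, bm, nb, em, ne = _fastscan.tbr_scan(
        nbr, kernel.n, kernel.masks, kernel.weights, cur_len, equal_cap
    )

    def decode(rows, k):
        out = []
        for r in rows[:k]:
            e1 = None if r[2] < 0 else (int(r[2]), int(r[3]))
            e2 = None if r[4] < 0 else (int(r[4]), int(r[5]))
            out.append(((int(r[0]), int(r[1])), e1, e2))
        return out

    if best_len >= _fastscan.BIG:
        return None, [], []
    return int(best_len), decode(bm, nb), decode(em, ne)


def _tbr_scan_reference(adj, kernel: _Kernel, cur_len: int, equal_cap: int = 0):
    """Pure-numpy TBR scan; the independent reference for the compiled path."""
    best_len = None
    best_moves: list[tuple] = []
    equal_moves: list[tuple] = []
    cut_edges = sorted(
        (min(a, b), max(a, b)) for a in adj for b in adj[a] if a < b
    )
    for u, v in cut_edges:
        if len(adj[u]) == 1 and len(adj[v]) == 1:
            continue
        _, e1s, R1, L1, merged_v = kernel.component(adj, v, u)
        _, e2s, R2, L2, merged_u = kernel.component(adj, u, v)
        disj = ((R1[:, None, :] & R2[None, :, :]) == 0) @ kernel.weights
        lengths = disj + (L1 + L2)
        # mask the null move
        i_null = e1s.index(merged_v) if merged_v is not None else 0
        j_null = e2s.index(merged_u) if merged_u is not None else 0
        lengths[i_null, j_null] = np.iinfo(lengths.dtype).max
        lmin = int(lengths.min())
        if best_len is None or lmin < best_len:
            best_len = lmin
            best_moves = []
        if lmin == best_len and len(best_moves) < 50:
            for i, j in np.argwhere(lengths == lmin)[:50]:
                best_moves.append(((u, v), e1s[i], e2s[j]))
        if equal_cap and best_len <= cur_len:
            for i, j in np.argwhere(lengths == cur_len):
                if len(equal_moves) >= equal_cap:
                    break
                equal_moves.append(((u, v), e1s[i], e2s[j]))
    return best_len, best_moves, equal_moves


def _hillclimb(adj, kernel: _Kernel):
    """Steepest-descent TBR to a local optimum; returns (length, adjacency)."""
    cur = kernel.length(adj)
    while True:
        best_len, best_moves, _ = _tbr_scan(adj, kernel, cur)
        if best_len is not None and best_len < cur:
            cut, e1, e2 = best_moves[0]
            adj = _apply_tbr(adj, cut, e1, e2, kernel.n)
            cur = best_len
        else:
            return cur, adj


# ---------------------------------------------------------------------------
# Wagner stepwise addition


def wagner_build(
    matrix: CharacterMatrix,
    addition_order,
    weights=None,
) -> PhyloTree:
    """Stepwise-addition (Wagner) starting tree.

    Starts from the first three taxa of ``addition_order`` and inserts each
    following taxon on the branch that minimizes total length; ties go to
    the first branch in a deterministic traversal.
    """
    enc = encode_matrix(matrix, weights)
    kernel = _Kernel(enc)
    order = list(addition_order)
    n = matrix.n_taxa
    if sorted(order) != list(range(n)):
        raise ValueError("addition_order must be a permutation of taxon indices")
    if n < 4:
        raise ValueError("need at least 4 taxa")
    adj = _wagner_adj(kernel, order, n)
    return _to_phylo(adj, matrix.taxon_labels)


def _wagner_adj(kernel: _Kernel, order, n):
    hub = n
    adj = {order[0]: [hub], order[1]: [hub], order[2]: [hub], hub: [order[0], order[1], order[2]]}
    nxt = n + 1
    for x in order[3:]:
        edges, R, L = kernel._edge_sets(adj)
        extra = ((R & kernel.masks[x][None, :]) == 0) @ kernel.weights
        k = int(np.argmin(extra))
        p, q = edges[k]
        m = nxt
        nxt += 1
        adj[p] = [y for y in adj[p] if y != q] + [m]
        adj[q] = [y for y in adj[q] if y != p] + [m]
        adj[m] = [p, q, x]
        adj[x] = [m]
    return adj


# ---------------------------------------------------------------------------
# public swapping / search


def tbr_swap(start: PhyloTree, matrix: CharacterMatrix, hold: int = 20, weights=None) -> list[PhyloTree]:
    """TBR-swap ``start`` to a local optimum and collect equally best trees.

    Returns up to ``hold`` topologically distinct binary trees at the best
    length found (the optimum itself included).
    """
    if not start.is_binary():
        raise ValueError("tbr_swap needs a binary start tree")
    enc = encode_matrix(matrix, weights)
    kernel = _Kernel(enc)
    labels = matrix.taxon_labels
    adj = _to_internal(start, labels)
    best_len, adj = _hillclimb(adj, kernel)
    pool = _collect_equal(adj, kernel, best_len, hold)
    return [_to_phylo(a, labels) for a in pool]


def _collect_equal(adj, kernel, best_len, hold):
    seen = {_fingerprint(adj, kernel.n): adj}
    if hold > 1:
        _, _, equal_moves = _tbr_scan(adj, kernel, best_len, equal_cap=4 * hold)
        for cut, e1, e2 in equal_moves:
            if len(seen) >= hold:
                break
            cand = _apply_tbr(adj, cut, e1, e2, kernel.n)
            fp = _fingerprint(cand, kernel.n)
            if fp not in seen:
                seen[fp] = cand
    return list(seen.values())


def heuristic_search(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    weights=None,
) -> SearchResult:
    """Random-addition Wagner + TBR replicates, pooled and swapped to closure.

    Fully seed-deterministic: replicate ``i`` draws its addition order from
    a child seed of ``config.seed``, so any replicate can be replayed
    independently.
    """
    config = config or SearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    enc = encode_matrix(matrix, weights)
    kernel = _Kernel(enc)
    n = matrix.n_taxa
    log: list[ReplicateRecord] = []
    best_len: int | None = None
    pool: dict[frozenset, dict] = {}
    for i in range(config.n_replicates):
        ss = np.random.SeedSequence([config.seed, i])
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(ss)
        order = [int(x) for x in rng.permutation(n)]
        adj = _wagner_adj(kernel, order, n)
        rep_len, adj = _hillclimb(adj, kernel)
        log.append(ReplicateRecord(i, rep_seed, tuple(order), rep_len))
        if best_len is None or rep_len < best_len:
            best_len = rep_len
            pool = {}
        if rep_len == best_len:
            for a in _collect_equal(adj, kernel, rep_len, config.hold_per_replicate):
                fp = _fingerprint(a, n)
                if fp not in pool and len(pool) < config.max_trees:
                    pool[fp] = a
    hit_max = False
    if config.final_sweep:
        best_len, pool, hit_max = _plateau_closure(pool, kernel, best_len, config.max_trees)
    labels = matrix.taxon_labels
    trees = [_to_phylo(a, labels) for a in pool.values()]
    if config.collapse_rule == "ambiguous":
        trees = [collapse_ambiguous(t, matrix, weights=weights) for t in trees]
    uniq: dict = {}
    for t in trees:
        uniq.setdefault(t.bipartitions(), t)
    trees = sorted(uniq.values(), key=lambda t: t.newick())
    return SearchResult(
        best_length=int(best_len),
        trees=trees,
        replicate_log=log,
        hit_max_trees=hit_max,
    )


def _plateau_closure(pool, kernel, best_len, max_trees):
    """TBR to completion: scan every pooled tree, absorbing equal-length
    neighbors (and restarting from scratch if anything shorter appears)."""
    queue = deque(pool.items())
    seen = dict(pool)
    hit_max = False
    while queue:
        fp, adj = queue.popleft()
        if fp not in seen:
            continue
        found_len, best_moves, equal_moves = _tbr_scan(
            adj, kernel, best_len, equal_cap=max_trees
        )
        if found_len is not None and found_len < best_len:
            cut, e1, e2 = best_moves[0]
            better = _apply_tbr(adj, cut, e1, e2, kernel.n)
            best_len = found_len
            seen = {_fingerprint(better, kernel.n): better}
            queue = deque(seen.items())
            continue
        for cut, e1, e2 in equal_moves:
            if len(seen) >= max_trees:
                hit_max = True
                break
            cand = _apply_tbr(adj, cut, e1, e2, kernel.n)
            cfp = _fingerprint(cand, kernel.n)
            if cfp not in seen:
                seen[cfp] = cand
                queue.append((cfp, cand))
    return best_len, seen, hit_max


# ---------------------------------------------------------------------------
# collapsing


def collapse_ambiguous(tree: PhyloTree, matrix: CharacterMatrix, weights=None) -> PhyloTree:
    """Collapse internal branches with no forced character change.

    A branch whose minimum length over all most-parsimonious
    reconstructions is zero is ambiguously supported; contracting all such
    branches (iterated to a fixed point, so the operation is idempotent)
    yields the collapsed tree.  On binary trees the test is cheap and
    exact: a branch is ambiguous iff the Fitch state sets of the two
    components it separates share a state for every character; polytomous
    iterations fall back to the state-by-state dynamic program.
    """
    current = tree
    while True:
        if current.is_binary() and current.n_leaves >= 4:
            to_collapse = _ambiguous_internal_edges_binary(current, matrix, weights)
        else:
            to_collapse = _ambiguous_internal_edges_general(current, matrix, weights)
        if not to_collapse:
            return current
        merge_into: dict[int, int] = {}

        def find(x: int) -> int:
            while x in merge_into:
                x = merge_into[x]
            return x

        for p, u in to_collapse:
            rp, ru = find(p), find(u)
            if rp != ru:
                merge_into[ru] = rp
        adj: dict[int, set[int]] = {}
        for a in current.adj:
            fa = find(a)
            adj.setdefault(fa, set())
            for b in current.adj[a]:
                fb = find(b)
                if fa != fb:
                    adj.setdefault(fa, set()).add(fb)
                    adj.setdefault(fb, set()).add(fa)
        current = PhyloTree(adj, dict(current.leaf_labels))


def _ambiguous_internal_edges_binary(tree, matrix, weights):
    enc = encode_matrix(matrix, weights)
    labels = matrix.taxon_labels
    row = {lab: i for i, lab in enumerate(labels)}
    to_tree_node: dict[int, int] = {}
    nxt = len(labels)
    adj: dict[int, list[int]] = {}
    mapping: dict[int, int] = {}
    for node in tree.adj:
        if node in tree.leaf_labels:
            mapping[node] = row[tree.leaf_labels[node]]
        else:
            mapping[node] = nxt
            nxt += 1
        to_tree_node[mapping[node]] = node
    for u, vs in tree.adj.items():
        adj[mapping[u]] = [mapping[v] for v in vs]
    parent, flags = _fastscan.ambiguous_edges(
        _adj_to_nbr(adj), len(labels), enc.masks, enc.weights.astype(np.int64)
    )
    n = len(labels)
    return [
        (to_tree_node[int(parent[x])], to_tree_node[x])
        for x in range(len(flags))
        if flags[x] and x >= n and parent[x] >= n
    ]


def _ambiguous_internal_edges_general(tree, matrix, weights):
    ana = edge_analysis(tree, matrix, weights=weights)
    w = ana.enc.weights
    out = []
    for e, u in enumerate(ana.edge_nodes):
        p = ana.parent[u]
        if u in tree.leaf_labels or p in tree.leaf_labels:
            continue
        if int((ana.edge_forced[e] * w).sum()) == 0:
            out.append((p, u))
    return out


# ---------------------------------------------------------------------------
# exhaustive oracle


def exhaustive_search(
    matrix: CharacterMatrix,
    weights=None,
    max_taxa: int = 9,
    prune: bool = False,
) -> SearchResult:
    """Enumerate every unrooted binary topology (small matrices only).

    With ``prune=False`` evaluates all (2n-5)!! topologies; the count of
    evaluated complete trees is recorded in the single replicate log entry.
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(f"exhaustive search refused for {n} taxa (> {max_taxa})")
    if n < 4:
        raise ValueError("need at least 4 taxa")
    enc = encode_matrix(matrix, weights)
    kernel = _Kernel(enc)
    hub = n
    adj = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    best: dict = {"len": None, "trees": {}, "count": 0}

    def recurse(adj, next_taxon, next_node):
        if next_taxon == n:
            best["count"] += 1
            L = kernel.length(adj)
            if best["len"] is None or L < best["len"]:
                best["len"] = L
                best["trees"] = {}
            if L == best["len"]:
                best["trees"][_fingerprint(adj, n)] = _copy(adj)
            return
        if prune and best["len"] is not None and kernel.length(adj) > best["len"]:
            return
        edges = [(a, b) for a in sorted(adj) for b in adj[a] if a < b]
        for p, q in edges:
            m = next_node
            adj[p] = [y for y in adj[p] if y != q] + [m]
            adj[q] = [y for y in adj[q] if y != p] + [m]
            adj[m] = [p, q, next_taxon]
            adj[next_taxon] = [m]
            recurse(adj, next_taxon + 1, next_node + 1)
            del adj[next_taxon]
            del adj[m]
            adj[p] = [y for y in adj[p] if y != m] + [q]
            adj[q] = [y for y in adj[q] if y != m] + [p]

    recurse(adj, 3, n + 1)
    labels = matrix.taxon_labels
    trees = sorted(
        (_to_phylo(a, labels) for a in best["trees"].values()), key=lambda t: t.newick()
    )
    log = [ReplicateRecord(0, 0, tuple(range(n)), int(best["len"]))]
    result = SearchResult(best_length=int(best["len"]), trees=trees, replicate_log=log)
    result.n_evaluated = best["count"]  # type: ignore[attr-defined]
    return result
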