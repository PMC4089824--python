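"""Compiled TBR neighborhood scan.

Same mathematics as the numpy scan in :mod:`morphoclad.search` (exact
reconnection costs from directional Fitch state sets), restructured as
flat-array loops for numba.  The numpy implementation remains the
reference; the two are cross-checked in the test suite.

Tree encoding: ``nbr`` is an (N, 3) int64 array of neighbor ids with -1
padding; leaves are ids < n_leaves and have one neighbor.  Components are
described to the pairwise stage by per-edge root state sets (uint16
bitmasks per character).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = np.int64(2**62)


@njit(cache=True)
def _join_into(a, b, out, C):
    for c in range(C):
        inter = a[c] & b[c]
        out[c] = inter if inter != 0 else (a[c] | b[c])


@njit(cache=True)
def _component_sets(
    nbr, n_leaves, masks, weights, start, banned,
    order, parent, up, down, edges, R,
):
    """Directional edge sets of the component containing ``start`` after
    cutting the edge (start, banned); the attachment node is suppressed.

    Fills ``edges`` (pairs) and ``R`` (per-edge root sets); returns
    (n_edges, component_length, merged_edge_index).  A single-leaf
    component returns one pseudo-edge (-1, -1) whose R is the leaf mask.
    """
    C = masks.shape[1]
    if start < n_leaves:  # leaf component
        edges[0, 0] = -1
        edges[0, 1] = -1
        for c in range(C):
            R[0, c] = masks[start, c]
        return 1, np.int64(0), 0
    # DFS from start, not crossing to banned
    n_nodes = 0
    order[n_nodes] = start
    parent[start] = banned
    n_nodes += 1
    stack_top = 0
    # reuse order as BFS queue storage: iterate with explicit index
    head = 0
    while head < n_nodes:
        x = order[head]
        head += 1
        for j in range(3):
            y = nbr[x, j]
            if y < 0 or y == parent[x]:
                continue
            parent[y] = x
            order[n_nodes] = y
            n_nodes += 1
    # start has exactly two children c_a, c_b (it had degree 3)
    c_a = np.int64(-1)
    c_b = np.int64(-1)
    for j in range(3):
        y = nbr[start, j]
        if y >= 0 and y != banned:
            if c_a < 0:
                c_a = y
            else:
                c_b = y
    # postorder up-pass (children before parents: reverse of BFS order)
    L = np.int64(0)
    for i in range(n_nodes - 1, -1, -1):
        x = order[i]
        if x < n_leaves:
            for c in range(C):
                up[x, c] = masks[x, c]
            continue
        # children of x: neighbors except parent
        k0 = np.int64(-1)
        k1 = np.int64(-1)
        for j in range(3):
            y = nbr[x, j]
            if y < 0 or y == parent[x]:
                continue
            if k0 < 0:
                k0 = y
            else:
                k1 = y
        if x == start:
            continue  # handled after the loop (suppressed node)
        for c in range(C):
            inter = up[k0, c] & up[k1, c]
            if inter == 0:
                L += weights[c]
                up[x, c] = up[k0, c] | up[k1, c]
            else:
                up[x, c] = inter
    # the merged edge joins the two halves
    for c in range(C):
        inter = up[c_a, c] & up[c_b, c]
        if inter == 0:
            L += weights[c]
    # down-pass (preorder)
    for c in range(C):
        down[c_a, c] = up[c_b, c]
        down[c_b, c] = up[c_a, c]
    for i in range(n_nodes):
        x = order[i]
        if x == start or x < n_leaves:
            continue
        k0 = np.int64(-1)
        k1 = np.int64(-1)
        for j in range(3):
            y = nbr[x, j]
            if y < 0 or y == parent[x]:
                continue
            if k0 < 0:
                k0 = y
            else:
                k1 = y
        _join_into(down[x], up[k1], down[k0], C)
        _join_into(down[x], up[k0], down[k1], C)
    # collect edges: (parent[x], x) for x != start, skipping the duplicate
    # half of the merged edge; merged edge recorded as (c_a, c_b)
    n_edges = 0
    merged_idx = -1
    for i in range(n_nodes):
        x = order[i]
        if x == start:
            continue
        if x == c_b:
            continue  # same unrooted edge as c_a's
        if x == c_a:
            edges[n_edges, 0] = c_a if c_a < c_b else c_b
            edges[n_edges, 1] = c_b if c_a < c_b else c_a
            merged_idx = n_edges
        else:
            p = parent[x]
            edges[n_edges, 0] = p if p < x else x
            edges[n_edges, 1] = x if p < x else p
        for c in range(C):
            inter = up[x, c] & down[x, c]
            R[n_edges, c] = inter if inter != 0 else (up[x, c] | down[x, c])
        n_edges += 1
    return n_edges, L, merged_idx


@njit(cache=True)
def tbr_scan(nbr, n_leaves, masks, weights, cur_len, equal_cap):
    """Evaluate the full TBR neighborhood.

    Returns (best_len, best_moves, n_best, equal_moves, n_equal) with moves
    encoded as rows (cut_u, cut_v, e1a, e1b, e2a, e2b); -1 marks a leaf
    component without a reattachment edge.
    """
    N = nbr.shape[0]
    C = masks.shape[1]
    order1 = np.empty(N, np.int64)
    parent1 = np.empty(N, np.int64)
    up1 = np.empty((N, C), np.uint16)
    down1 = np.empty((N, C), np.uint16)
    edges1 = np.empty((N, 2), np.int64)
    R1 = np.empty((N, C), np.uint16)
    order2 = np.empty(N, np.int64)
    parent2 = np.empty(N, np.int64)
    up2 = np.empty((N, C), np.uint16)
    down2 = np.empty((N, C), np.uint16)
    edges2 = np.empty((N, 2), np.int64)
    R2 = np.empty((N, C), np.uint16)

    best_len = BIG
    best_moves = np.empty((64, 6), np.int64)
    n_best = 0
    eq_cap = equal_cap if equal_cap > 0 else 1
    equal_moves = np.empty((eq_cap, 6), np.int64)
    n_equal = 0

    for u in range(N):
        for ju in range(3):
            v = nbr[u, ju]
            if v < 0 or v <= u:
                continue
            if u < n_leaves and v < n_leaves:
                continue  # two-leaf tree: no TBR
            nE1, L1, m1 = _component_sets(
                nbr, n_leaves, masks, weights, v, u,
                order1, parent1, up1, down1, edges1, R1,
            )
            nE2, L2, m2 = _component_sets(
                nbr, n_leaves, masks, weights, u, v,
                order2, parent2, up2, down2, edges2, R2,
            )
            base = L1 + L2
            for i in range(nE1):
                for j in range(nE2):
                    if i == m1 and j == m2:
                        continue  # reproduces the current tree
                    extra = np.int64(0)
                    for c in range(C):
                        if R1[i, c] & R2[j, c] == 0:
                            extra += weights[c]
                    length = base + extra
                    if length < best_len:
                        best_len = length
                        n_best = 0
                    if length == best_len and n_best < 64:
                        best_moves[n_best, 0] = u
                        best_moves[n_best, 1] = v
                        best_moves[n_best, 2] = edges1[i, 0]
                        best_moves[n_best, 3] = edges1[i, 1]
                        best_moves[n_best, 4] = edges2[j, 0]
                        best_moves[n_best, 5] = edges2[j, 1]
                        n_best += 1
                    if equal_cap > 0 and length == cur_len and n_equal < eq_cap:
                        equal_moves[n_equal, 0] = u
                        equal_moves[n_equal, 1] = v
                        equal_moves[n_equal, 2] = edges1[i, 0]
                        equal_moves[n_equal, 3] = edges1[i, 1]
                        equal_moves[n_equal, 4] = edges2[j, 0]
                        equal_moves[n_equal, 5] = edges2[j, 1]
                        n_equal += 1
    return best_len, best_moves, n_best, equal_moves, n_equal


@njit(cache=True)
def ambiguous_edges(nbr, n_leaves, masks, weights):
    """Per-node flags for collapsing on a binary tree.

    For the branch between each node and its parent (rooted at leaf 0):
    1 if no character with positive weight is forced to change there.  A
    change is forced in every most-parsimonious reconstruction exactly
    when no single state can sit at both branch endpoints at optimal total
    cost, so the test uses full uniform-cost Sankoff vectors (a state that
    is second-best on one side can still yield a change-free optimum,
    which pure Fitch state sets cannot see).

    Returns (parent, flags): flags[x] concerns the branch (parent[x], x);
    flags[root] is 0.
    """
    N = nbr.shape[0]
    C = masks.shape[1]
    S = 10
    INF = np.int32(1 << 20)
    root = 0
    parent = np.full(N, -1, np.int64)
    order = np.empty(N, np.int64)
    order[0] = root
    n_nodes = 1
    head = 0
    parent[root] = -2
    while head < n_nodes:
        x = order[head]
        head += 1
        for j in range(3):
            y = nbr[x, j]
            if y < 0 or y == parent[x]:
                continue
            parent[y] = x
            order[n_nodes] = y
            n_nodes += 1

    down = np.empty((N, C, S), np.int32)
    contrib = np.empty((N, C, S), np.int32)
    upc = np.empty((N, C, S), np.int32)
    upcontrib = np.empty((N, C, S), np.int32)

    # postorder: subtree cost vectors
    for i in range(n_nodes - 1, -1, -1):
        x = order[i]
        if x < n_leaves:
            for c in range(C):
                mk = masks[x, c]
                for t in range(S):
                    down[x, c, t] = 0 if (mk >> t) & 1 else INF
        else:
            k0 = np.int64(-1)
            k1 = np.int64(-1)
            for j in range(3):
                y = nbr[x, j]
                if y < 0 or y == parent[x]:
                    continue
                if k0 < 0:
                    k0 = y
                else:
                    k1 = y
            for c in range(C):
                for t in range(S):
                    v = contrib[k0, c, t] + contrib[k1, c, t]
                    down[x, c, t] = v if v < INF else INF
        for c in range(C):
            mn = INF
            for t in range(S):
                if down[x, c, t] < mn:
                    mn = down[x, c, t]
            cap = mn + 1
            for t in range(S):
                v = down[x, c, t]
                contrib[x, c, t] = v if v < cap else cap

    # preorder: rest-of-tree cost vectors.  upc[x][t] = cost of the
    # component containing parent(x) when the branch is cut, given the
    # parent has state t.
    for i in range(n_nodes):
        x = order[i]
        if x == root:
            continue
        p = parent[x]
        if p == root:
            for c in range(C):
                mk = masks[root, c]
                for t in range(S):
                    upc[x, c, t] = 0 if (mk >> t) & 1 else INF
        else:
            # p is internal: other child of p plus p's own upstream part
            ko = np.int64(-1)
            for j in range(3):
                y = nbr[p, j]
                if y < 0 or y == parent[p] or y == x:
                    continue
                ko = y
            for c in range(C):
                for t in range(S):
                    v = contrib[ko, c, t] + upcontrib[p, c, t]
                    upc[x, c, t] = v if v < INF else INF
        for c in range(C):
            mn = INF
            for t in range(S):
                if upc[x, c, t] < mn:
                    mn = upc[x, c, t]
            cap = mn + 1
            for t in range(S):
                v = upc[x, c, t]
                upcontrib[x, c, t] = v if v < cap else cap

    # per-character optimum from any edge; use the root's child
    Lc = np.empty(C, np.int32)
    c0 = np.int64(-1)
    for j in range(3):
        y = nbr[root, j]
        if y >= 0:
            c0 = y
    for c in range(C):
        best = INF
        for t in range(S):
            v = down[c0, c, t] + min(upc[c0, c, t], _minplus1(upc[c0, c], S))
            if v < best:
                best = v
        Lc[c] = best

    flags = np.zeros(N, np.uint8)
    for i in range(1, n_nodes):
        x = order[i]
        forced = False
        for c in range(C):
            if weights[c] <= 0:
                continue
            same_best = INF
            for t in range(S):
                v = upc[x, c, t] + down[x, c, t]
                if v < same_best:
                    same_best = v
            if same_best > Lc[c]:
                forced = True
                break
        if not forced:
            flags[x] = 1
    return parent, flags


@njit(cache=True)
def _minplus1(vec, S):
    mn = vec[0]
    for t in range(1, S):
        if vec[t] < mn:
            mn = vec[t]
    return mn + 1
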