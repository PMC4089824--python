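"""Parsimony lengths, homoplasy indices and ancestral state-set reconstruction.

All characters are unordered (any state can change into any other at cost
one).  ``?`` (missing) and ``-`` (inapplicable) cells are optimization
neutral: the leaf is assigned the full set of states observed for that
character, so it never contributes steps.  Lengths on multifurcating trees
use Hartigan's degree-general most-parsimonious assignment, which reduces
to Fitch's state-set intersection/union rule on binary trees.

Two independent code paths compute the same quantity: a fast bitmask
Hartigan pass (:func:`tree_length`) and an explicit uniform-cost dynamic
program over states (:func:`edge_analysis`) that additionally yields, for
every branch, whether a character change is *forced* (present in every
most-parsimonious reconstruction) and whether its derived state is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .matrix_io import CharacterMatrix, INAPPLICABLE, MISSING
from .tree_model import PhyloTree, TreeError

__all__ = [
    "CharacterStepBounds",
    "CharacterIndices",
    "EnsembleIndices",
    "IndexReport",
    "StateSetReconstruction",
    "BranchChange",
    "EncodedMatrix",
    "encode_matrix",
    "character_length",
    "tree_length",
    "per_character_lengths",
    "step_bounds",
    "index_report",
    "reconstruct",
    "edge_analysis",
    "round_half_up",
    "truncate2",
]

_N_STATES = 10
_INF = 10**6


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.285 -> 0.29)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (2/3 -> 0.66).

    This is how classic cladistics programs print consistency and
    retention indices, so all displayed ci/ri/CI/RI values follow it; full
    precision is kept internally.
    """
    return float(int(x * 100)) / 100.0


# ---------------------------------------------------------------------------
# encoding


@dataclass(frozen=True)
class EncodedMatrix:
    """Bitmask view of a matrix: one uint16 state-set per cell.

    Missing and inapplicable cells receive the union of the states observed
    in their column (constant and empty columns degrade to a single dummy
    state, contributing zero steps).
    """

    masks: np.ndarray  # (n_taxa, n_chars) uint16
    weights: np.ndarray  # (n_chars,) int64 column multiplicities
    n_observed: np.ndarray  # (n_chars,) distinct observed states


def encode_matrix(matrix: CharacterMatrix, weights=None) -> EncodedMatrix:
    codes = matrix.codes
    n_taxa, n_chars = codes.shape
    scored = codes >= 0
    masks = np.where(scored, (1 << np.where(scored, codes, 0)).astype(np.uint16), 0)
    universe = np.bitwise_or.reduce(masks, axis=0)
    universe = np.where(universe == 0, np.uint16(1), universe).astype(np.uint16)
    masks = np.where(scored, masks, universe)
    n_observed = np.array(
        [len(set(int(c) for c in codes[:, j] if c >= 0)) for j in range(n_chars)],
        dtype=np.int64,
    )
    if weights is None:
        w = np.ones(n_chars, dtype=np.int64)
    else:
        w = np.asarray(weights, dtype=np.int64)
        if w.shape != (n_chars,) or (w < 0).any():
            raise ValueError("weights must be one non-negative integer per character")
    return EncodedMatrix(masks=masks, weights=w, n_observed=n_observed)


# ---------------------------------------------------------------------------
# rooted traversal helper


def _rooted_order(tree: PhyloTree, root_label: str | None = None):
    """Postorder node list, parents and children for the tree rooted at a leaf."""
    label_to_node = {lab: n for n, lab in tree.leaf_labels.items()}
    if root_label is None:
        root_label = min(label_to_node)
    if root_label not in label_to_node:
        raise TreeError(f"unknown root taxon {root_label!r}")
    root = label_to_node[root_label]
    parent: dict[int, int | None] = {root: None}
    preorder = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if v != parent[u]:
                parent[v] = u
                preorder.append(v)
                stack.append(v)
    children: dict[int, list[int]] = {u: [] for u in preorder}
    for u in preorder[1:]:
        children[parent[u]].append(u)
    return preorder, parent, children, root


def _leaf_mask_rows(tree: PhyloTree, matrix: CharacterMatrix, enc: EncodedMatrix):
    row_of = {lab: i for i, lab in enumerate(matrix.taxon_labels)}
    if tree.taxa != frozenset(row_of):
        raise TreeError("tree leaf set does not match the matrix taxa")
    return {node: enc.masks[row_of[lab]] for node, lab in tree.leaf_labels.items()}


# ---------------------------------------------------------------------------
# Hartigan bitmask lengths


_BITS = (1 << np.arange(_N_STATES, dtype=np.uint16)).astype(np.uint16)


def per_character_lengths(
    tree: PhyloTree, matrix: CharacterMatrix, weights=None
) -> np.ndarray:
    """Minimum unordered steps per character (unweighted counts).

    Hartigan's algorithm: at each vertex keep the states occurring in the
    maximum number K of child state sets and add (number of children - K)
    steps.  Exact on binary and multifurcating trees.
    """
    enc = encode_matrix(matrix, weights)
    return _hartigan_steps(tree, matrix, enc)


def _hartigan_steps(tree: PhyloTree, matrix: CharacterMatrix, enc: EncodedMatrix) -> np.ndarray:
    leaf_masks = _leaf_mask_rows(tree, matrix, enc)
    if tree.n_leaves == 2:
        a, b = leaf_masks.values()
        return ((a & b) == 0).astype(np.int64)
    preorder, parent, children, root = _rooted_order(tree)
    n_chars = matrix.n_chars
    steps = np.zeros(n_chars, dtype=np.int64)
    prelim: dict[int, np.ndarray] = {}
    for u in reversed(preorder):
        if u in tree.leaf_labels and u != root:
            prelim[u] = leaf_masks[u]
            continue
        kids = children[u]
        stacked = [prelim[v] for v in kids]
        if u == root:
            stacked.append(leaf_masks[u])  # the root leaf's own constraint
        counts = (
            ((np.stack(stacked)[:, :, None] >> np.arange(_N_STATES)) & 1)
            .sum(axis=0)
            .astype(np.int16)
        )  # (C, 10)
        k_max = counts.max(axis=1)
        steps += len(stacked) - k_max
        prelim[u] = (((counts == k_max[:, None]) * _BITS).sum(axis=1)).astype(np.uint16)
        for v in kids:
            del prelim[v]
    return steps


def tree_length(tree: PhyloTree, matrix: CharacterMatrix, weights=None) -> int:
    """Total parsimony length: weighted sum of per-character minimum steps."""
    enc = encode_matrix(matrix, weights)
    return int((_hartigan_steps(tree, matrix, enc) * enc.weights).sum())


def character_length(tree: PhyloTree, matrix: CharacterMatrix, char_id: int) -> int:
    """Minimum steps of the 1-based character ``char_id`` on ``tree``."""
    if not isinstance(matrix, CharacterMatrix):
        raise TypeError("pass a CharacterMatrix and a 1-based char_id")
    steps = per_character_lengths(tree, matrix)
    return int(steps[char_id - 1])


# ---------------------------------------------------------------------------
# step bounds and indices


@dataclass(frozen=True)
class CharacterStepBounds:
    """Minimum (m) and maximum (g) conceivable steps of one character.

    ``m`` is reached on some fully resolved tree, ``g`` on the completely
    unresolved star tree; missing and inapplicable taxa are excluded.
    """

    m: int
    g: int
    observed_states: frozenset[int]


def step_bounds(column: np.ndarray) -> CharacterStepBounds:
    col = np.asarray(column)
    scored = col[col >= 0]
    if scored.size == 0:
        return CharacterStepBounds(0, 0, frozenset())
    values, counts = np.unique(scored, return_counts=True)
    m = max(0, len(values) - 1)
    g = int(scored.size - counts.max())
    return CharacterStepBounds(m, g, frozenset(int(v) for v in values))


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class CharacterIndices:
    char_id: int  # 1-based
    s: int
    m: int
    g: int
    ci: float | None  # undefined ("—") when s = 0
    ri: float | None  # undefined when g = m

    @property
    def informative(self) -> bool:
        return self.g > self.m


@dataclass(frozen=True)
class EnsembleIndices:
    S: int
    M: int
    G: int
    CI: float | None
    RI: float | None


@dataclass
class IndexReport:
    """Per-character and ensemble consistency/retention indices.

    The ensemble is reported twice: over all characters and over
    parsimony-informative characters only (g > m), because published
    ensemble values may follow either convention.
    """

    per_character: list[CharacterIndices]
    ensemble_all: EnsembleIndices
    ensemble_informative: EnsembleIndices
    tree_count: int = 1

    def to_table(self) -> str:
        lines = ["character\ts\tm\tg\tci\tri"]
        for c in self.per_character:
            ci = "—" if c.ci is None else f"{truncate2(c.ci):.2f}"
            ri = "—" if c.ri is None else f"{truncate2(c.ri):.2f}"
            lines.append(f"{c.char_id}\t{c.s}\t{c.m}\t{c.g}\t{ci}\t{ri}")
        for name, e in (("all", self.ensemble_all), ("informative", self.ensemble_informative)):
            CI = "—" if e.CI is None else f"{truncate2(e.CI):.2f}"
            RI = "—" if e.RI is None else f"{truncate2(e.RI):.2f}"
            lines.append(f"ensemble[{name}]\t{e.S}\t{e.M}\t{e.G}\t{CI}\t{RI}")
        return "\n".join(lines) + "\n"


def _ensemble(chars: list[CharacterIndices]) -> EnsembleIndices:
    S = sum(c.s for c in chars)
    M = sum(c.m for c in chars)
    G = sum(c.g for c in chars)
    CI = _safe_div(M, S)
    RI = _safe_div(G - S, G - M)
    return EnsembleIndices(S, M, G, CI, RI)


def index_report(trees, matrix: CharacterMatrix) -> IndexReport:
    """Homoplasy indices of ``matrix`` on a tree (or the first of a tree set).

    Per character: observed steps s, bounds m and g, ci = m/s and
    ri = (g-s)/(g-m).  Ensembles use the summed quantities.
    """
    if isinstance(trees, PhyloTree):
        tree, count = trees, 1
    else:
        seq = list(trees)
        if not seq:
            raise ValueError("need at least one tree")
        tree, count = seq[0], len(seq)
    steps = per_character_lengths(tree, matrix)
    chars: list[CharacterIndices] = []
    for j in range(matrix.n_chars):
        b = step_bounds(matrix.codes[:, j])
        s = int(steps[j])
        ci = _safe_div(b.m, s)
        ri = _safe_div(b.g - s, b.g - b.m)
        chars.append(CharacterIndices(j + 1, s, b.m, b.g, ci, ri))
    return IndexReport(
        per_character=chars,
        ensemble_all=_ensemble(chars),
        ensemble_informative=_ensemble([c for c in chars if c.informative]),
        tree_count=count,
    )


# ---------------------------------------------------------------------------
# exact per-branch analysis (uniform-cost dynamic program)


@dataclass(frozen=True)
class BranchChange:
    """One character-state transformation on a branch.

    ``clade`` is the leaf set on the side of the branch away from the root
    taxon (the group whose stem the change sits on).  ``forced`` means every
    most-parsimonious reconstruction places a change on this branch;
    ``unambiguous`` additionally requires a single possible derived state.
    """

    char_id: int  # 1-based
    clade: frozenset[str]
    from_states: frozenset[int]
    to_states: frozenset[int]
    forced: bool
    unambiguous: bool

    @property
    def derived_state(self) -> int | None:
        return next(iter(self.to_states)) if len(self.to_states) == 1 else None


@dataclass
class StateSetReconstruction:
    """Most-parsimonious state sets and branch changes for one character."""

    char_id: int
    length: int
    final_sets: dict[frozenset[str], frozenset[int]]  # clade -> MPR state set
    changes: list[BranchChange]


class EdgeAnalysis:
    """Batch DP results for all characters on one tree (internal workhorse)."""

    def __init__(self, tree, matrix, enc, root_label):
        leaf_masks = _leaf_mask_rows(tree, matrix, enc)
        preorder, parent, children, root = _rooted_order(tree, root_label)
        C = matrix.n_chars
        idx = {u: i for i, u in enumerate(preorder)}
        N = len(preorder)
        leafcost = np.full((N, C, _N_STATES), 0, dtype=np.int32)
        for u, mask in leaf_masks.items():
            allowed = ((mask[:, None] >> np.arange(_N_STATES)) & 1).astype(bool)
            leafcost[idx[u]] = np.where(allowed, 0, _INF)
        down = np.zeros((N, C, _N_STATES), dtype=np.int32)
        contrib = np.zeros((N, C, _N_STATES), dtype=np.int32)
        for u in reversed(preorder):
            i = idx[u]
            d = leafcost[i].copy()
            for v in children[u]:
                d += contrib[idx[v]]
            np.minimum(d, _INF, out=d)
            down[i] = d
            mins = d.min(axis=1)
            contrib[i] = np.minimum(d, (mins + 1)[:, None])
        L = down[idx[root]].min(axis=1)  # (C,)

        # up pass: upcost[u][t] = min cost of the component containing the
        # parent when the branch (parent,u) is cut, given parent state t.
        upcost = np.zeros((N, C, _N_STATES), dtype=np.int32)
        upcontrib = np.zeros((N, C, _N_STATES), dtype=np.int32)
        for u in preorder:
            i = idx[u]
            for v in children[u]:
                j = idx[v]
                base = down[i] - contrib[j]
                if parent[u] is not None:
                    base = base + upcontrib[i]
                np.minimum(base, _INF, out=base)
                upcost[j] = base
                mins = base.min(axis=1)
                upcontrib[j] = np.minimum(base, (mins + 1)[:, None])

        self.tree = tree
        self.matrix = matrix
        self.enc = enc
        self.preorder, self.parent, self.children, self.root = preorder, parent, children, root
        self.idx = idx
        self.down, self.upcost, self.L = down, upcost, L
        self._clades: dict[int, frozenset[str]] | None = None

        # per-node MPR ("final") state sets
        tot = np.zeros((N, C, _N_STATES), dtype=np.int32)
        for u in preorder:
            i = idx[u]
            if parent[u] is None:
                tot[i] = down[i]
            else:
                up = upcost[i]
                up_in = np.minimum(up, (up.min(axis=1) + 1)[:, None])
                tot[i] = down[i] + up_in
        self.final = tot <= L[None, :, None]  # (N, C, 10) bool

        # per-edge quantities (edges are (parent, u) for u != root)
        self.edge_nodes = [u for u in preorder if parent[u] is not None]
        E = len(self.edge_nodes)
        forced = np.zeros((E, C), dtype=bool)
        to_sets = np.zeros((E, C, _N_STATES), dtype=bool)
        from_sets = np.zeros((E, C, _N_STATES), dtype=bool)
        for e, u in enumerate(self.edge_nodes):
            i = idx[u]
            dwn, up = down[i], upcost[i]
            same = (dwn + up).min(axis=1)
            forced[e] = same > L
            # min over a != b of up[a], per b: via two smallest values
            part = np.partition(up, 1, axis=1)
            m1, m2 = part[:, 0], part[:, 1]
            arg1 = up.argmin(axis=1)
            excl = np.where(
                np.arange(_N_STATES)[None, :] == arg1[:, None], m2[:, None], m1[:, None]
            )
            to_sets[e] = (dwn + 1 + np.minimum(excl, _INF)) <= L[:, None]
            partd = np.partition(dwn, 1, axis=1)
            d1, d2 = partd[:, 0], partd[:, 1]
            argd = dwn.argmin(axis=1)
            excl_d = np.where(
                np.arange(_N_STATES)[None, :] == argd[:, None], d2[:, None], d1[:, None]
            )
            from_sets[e] = (up + 1 + np.minimum(excl_d, _INF)) <= L[:, None]
        self.edge_forced = forced  # (E, C)
        self.edge_to = to_sets
        self.edge_from = from_sets
        n_to = to_sets.sum(axis=2)
        self.edge_unambiguous = forced & (n_to == 1)

    def clade_of(self, u: int) -> frozenset[str]:
        if self._clades is None:
            below: dict[int, frozenset[str]] = {}
            for v in reversed(self.preorder):
                s: set[str] = set()
                if v in self.tree.leaf_labels:
                    s.add(self.tree.leaf_labels[v])
                for w in self.children[v]:
                    s |= below[w]
                below[v] = frozenset(s)
            self._clades = below
        return self._clades[u]

    def forced_edge_steps(self) -> dict[frozenset[str], int]:
        """Weighted count of forced changes per branch (its minimum length)."""
        w = self.enc.weights
        return {
            self.clade_of(u): int((self.edge_forced[e] * w).sum())
            for e, u in enumerate(self.edge_nodes)
        }


def edge_analysis(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    weights=None,
    root_taxon: str | None = None,
) -> EdgeAnalysis:
    """Run the exact uniform-cost DP for all characters on ``tree``.

    Returns per-branch forced/unambiguous change flags, derived-state sets
    and per-node most-parsimonious state sets, polarized away from
    ``root_taxon`` (lexicographically smallest leaf by default).
    """
    enc = encode_matrix(matrix, weights)
    return EdgeAnalysis(tree, matrix, enc, root_taxon)


def _states_of(mask_row: np.ndarray) -> frozenset[int]:
    return frozenset(int(s) for s in np.nonzero(mask_row)[0])


def reconstruct(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char_id: int,
    root_taxon: str | None = None,
) -> StateSetReconstruction:
    """Most-parsimonious state sets of one character and its branch changes.

    A change is recorded for a branch when at least one most-parsimonious
    reconstruction differs across it; ``forced`` marks branches where every
    reconstruction changes, and ``unambiguous`` additionally requires the
    derived state to be identical in all of them.
    """
    ana = edge_analysis(tree, matrix, root_taxon=root_taxon)
    j = char_id - 1
    final_sets = {
        ana.clade_of(u): _states_of(ana.final[ana.idx[u], j])
        for u in ana.preorder
        if ana.parent[u] is not None
    }
    changes: list[BranchChange] = []
    for e, u in enumerate(ana.edge_nodes):
        to_states = _states_of(ana.edge_to[e, j])
        if not to_states:
            continue
        changes.append(
            BranchChange(
                char_id=char_id,
                clade=ana.clade_of(u),
                from_states=_states_of(ana.edge_from[e, j]),
                to_states=to_states,
                forced=bool(ana.edge_forced[e, j]),
                unambiguous=bool(ana.edge_unambiguous[e, j]),
            )
        )
    return StateSetReconstruction(
        char_id=char_id,
        length=int(ana.L[j]),
        final_sets=final_sets,
        changes=changes,
    )
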