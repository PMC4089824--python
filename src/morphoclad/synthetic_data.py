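"""Synthetic character matrices with known generating trees.

Characters are simulated by placing a Poisson number of state changes
directly on branches of a known tree (uniform branch choice by default)
rather than by a continuous-time Markov process: this gives direct control
over homoplasy and exact bookkeeping of every simulated transformation,
which is what the downstream search/consensus/sensitivity machinery needs
for oracle-style testing.  Missing ('?') and inapplicable ('-') cells are
masked at random after simulation; the inference engine treats both as
uninformative, so no logical structure between characters is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import INAPPLICABLE, MISSING, CharacterMatrix
from .parsimony_engine import per_character_lengths, step_bounds
from .tree_model import PhyloTree

__all__ = [
    "SimulationConfig",
    "SimulatedChange",
    "SimulatedDataset",
    "random_tree",
    "simulate",
    "two_signal_matrix",
]


def random_tree(n_taxa: int, seed, labels=None) -> PhyloTree:
    """Uniform random unrooted binary topology via random sequential addition.

    Attaching each new leaf to a branch chosen uniformly at random yields
    the uniform distribution over labelled unrooted binary topologies.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i+1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("need one label per taxon")
    hub = n_taxa
    adj: dict[int, list[int]] = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    nxt = n_taxa + 1
    for x in range(3, n_taxa):
        edges = [(a, b) for a in sorted(adj) for b in adj[a] if a < b]
        p, q = edges[int(rng.integers(len(edges)))]
        m = nxt
        nxt += 1
        adj[p] = [y for y in adj[p] if y != q] + [m]
        adj[q] = [y for y in adj[q] if y != p] + [m]
        adj[m] = [p, q, x]
        adj[x] = [m]
    return PhyloTree(adj, {i: labels[i] for i in range(n_taxa)})


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated matrix.

    ``change_rate`` is the expected number of state changes per character
    (the homoplasy dial: with more changes than states can absorb,
    characters start arising repeatedly).  Fractions are cellwise masking
    probabilities.
    """

    n_taxa: int = 33
    n_chars: int = 67
    n_states: int = 3
    change_rate: float = 1.0
    missing_fraction: float = 0.0
    inapplicable_fraction: float = 0.0
    seed: int = 0
    tree: PhyloTree | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if not 2 <= self.n_states <= 10:
            raise ValueError("n_states must be in 2..10")
        if self.change_rate < 0:
            raise ValueError("change_rate must be non-negative")
        if min(self.missing_fraction, self.inapplicable_fraction) < 0 or (
            self.missing_fraction + self.inapplicable_fraction
        ) >= 1:
            raise ValueError("masking fractions must be in [0,1) and sum below 1")


@dataclass(frozen=True)
class SimulatedChange:
    char_id: int
    clade: frozenset[str]  # leaf set below the mutated branch
    from_state: int
    to_state: int


@dataclass
class SimulatedDataset:
    matrix: CharacterMatrix
    true_tree: PhyloTree
    true_changes: list[SimulatedChange]
    realized_homoplasy: list[bool]  # per character: extra steps on the true tree?


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Simulate unordered multistate characters on a (possibly given) tree."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    if tree is None:
        tree = random_tree(config.n_taxa, rng)
    labels = sorted(tree.leaf_labels.values())
    n = len(labels)
    # rooted traversal from an arbitrary leaf
    node_of = {lab: nd for nd, lab in tree.leaf_labels.items()}
    root = node_of[labels[0]]
    parent: dict[int, int | None] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    branches = order[1:]  # node below each branch
    below: dict[int, frozenset[str]] = {}
    for u in reversed(order):
        s: set[str] = set()
        if u in tree.leaf_labels:
            s.add(tree.leaf_labels[u])
        for v in tree.adj[u]:
            if parent.get(v) == u:
                s |= below[v]
        below[u] = frozenset(s)

    codes = np.zeros((n, config.n_chars), dtype=np.int8)
    row_of = {lab: i for i, lab in enumerate(labels)}
    changes: list[SimulatedChange] = []
    for j in range(config.n_chars):
        n_changes = int(rng.poisson(config.change_rate))
        hit = rng.integers(0, len(branches), size=n_changes) if n_changes else []
        per_branch: dict[int, int] = {}
        for h in hit:
            per_branch[int(h)] = per_branch.get(int(h), 0) + 1
        state: dict[int, int] = {root: 0}
        for idx, u in enumerate(order[1:]):
            s = state[parent[u]]
            for _ in range(per_branch.get(idx, 0)):
                new = int(rng.integers(config.n_states - 1))
                if new >= s:
                    new += 1
                changes.append(
                    SimulatedChange(char_id=j + 1, clade=below[u], from_state=s, to_state=new)
                )
                s = new
            state[u] = s
        for lab in labels:
            codes[row_of[lab], j] = state[node_of[lab]]

    # masking
    total_mask = config.missing_fraction + config.inapplicable_fraction
    if total_mask > 0:
        u = rng.random(codes.shape)
        codes[u < config.missing_fraction] = MISSING
        codes[(u >= config.missing_fraction) & (u < total_mask)] = INAPPLICABLE

    matrix = CharacterMatrix(labels, codes)
    steps = per_character_lengths(tree, matrix)
    homoplasy = [
        bool(steps[j] > step_bounds(codes[:, j]).m) for j in range(config.n_chars)
    ]
    return SimulatedDataset(
        matrix=matrix, true_tree=tree, true_changes=changes, realized_homoplasy=homoplasy
    )


def _splits_incompatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    ca, cb = taxa - a, taxa - b
    return all((x & y) for x in (a, ca) for y in (b, cb))


def two_signal_matrix(
    n_taxa: int, n_main: int, n_conflict: int, seed
) -> SimulatedDataset:
    """A matrix with a dominant signal and a contradicting character block.

    ``n_main`` binary characters each mark one informative clade of tree A
    (clades are used cyclically, so support per clade is n_main divided by
    the clade count).  The conflict block is ``n_conflict`` identical
    characters marking one clade of an independent tree B, chosen to clash
    with as few clades of A as possible (preferably exactly one): when the
    block's size matches the support of the clade it contradicts, the best
    trees disagree, the strict consensus loses resolution, and removing a
    single conflict character sharpens it — the phenomenon the sequential
    removal screen is designed to flag.
    """
    if not n_main > n_conflict >= 0:
        raise ValueError("need n_main > n_conflict >= 0")
    rng = np.random.default_rng(seed)
    tree_a = random_tree(n_taxa, rng)
    labels = sorted(tree_a.leaf_labels.values())
    taxa = frozenset(labels)
    splits_a = sorted(tree_a.bipartitions(), key=lambda s: (len(s), sorted(s)))
    conflict_split: frozenset | None = None
    if n_conflict:
        best_clashes = None
        for _ in range(8):  # a handful of candidate trees is plenty
            tree_b = random_tree(n_taxa, rng)
            for s in sorted(tree_b.bipartitions(), key=lambda s: (len(s), sorted(s))):
                if s in tree_a.bipartitions():
                    continue
                clashes = sum(
                    _splits_incompatible(s, a, taxa) for a in splits_a
                )
                if best_clashes is None or clashes < best_clashes:
                    best_clashes, conflict_split = clashes, s
            if best_clashes == 1:
                break
    n = len(labels)
    codes = np.zeros((n, n_main + n_conflict), dtype=np.int8)
    changes: list[SimulatedChange] = []
    for j in range(n_main):
        clade = splits_a[j % len(splits_a)]
        for i, lab in enumerate(labels):
            codes[i, j] = 1 if lab in clade else 0
        changes.append(SimulatedChange(j + 1, clade, 0, 1))
    for k in range(n_conflict):
        j = n_main + k
        for i, lab in enumerate(labels):
            codes[i, j] = 1 if lab in conflict_split else 0
        changes.append(SimulatedChange(j + 1, conflict_split, 0, 1))
    matrix = CharacterMatrix(labels, codes)
    steps = per_character_lengths(tree_a, matrix)
    homoplasy = [
        bool(steps[j] > step_bounds(codes[:, j]).m) for j in range(matrix.n_chars)
    ]
    return SimulatedDataset(
        matrix=matrix, true_tree=tree_a, true_changes=changes, realized_homoplasy=homoplasy
    )
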