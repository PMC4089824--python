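"""Consensus trees and nonparametric bootstrap clade support.

The strict consensus keeps exactly the bipartitions present in every input
tree; the majority-rule consensus keeps those in more than a cutoff
percentage (>= 50, so the retained splits are pairwise compatible).  The
bootstrap resamples characters with replacement — implemented as integer
column weights, which leaves per-tree lengths identical to materializing
duplicated columns but is much cheaper — and records how often each clade
reappears in the replicate searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CharacterMatrix
from .search import SearchConfig, heuristic_search
from .tree_model import PhyloTree, TreeError

__all__ = [
    "BootstrapConfig",
    "SupportReport",
    "strict_consensus",
    "majority_consensus",
    "bootstrap",
]


def _common_taxa(trees: list[PhyloTree]) -> frozenset[str]:
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("all trees must share an identical leaf set")
    return taxa


def build_tree_from_splits(taxa, splits) -> PhyloTree:
    """Assemble the (unique) tree displaying a compatible set of splits.

    Splits use the canonical representation of
    :meth:`PhyloTree.bipartitions`: the side excluding the smallest leaf.
    """
    taxa = sorted(taxa)
    clades = sorted(splits, key=len, reverse=True)
    next_id = iter(range(10**9)).__next__
    leaf_node = {t: next_id() for t in taxa}
    root = next_id()
    adj: dict[int, set[int]] = {v: set() for v in leaf_node.values()}
    adj[root] = set()
    clade_node = {c: next_id() for c in clades}
    for c in clades:
        adj[clade_node[c]] = set()

    def parent_of(item_contained_in) -> int:
        sup = None
        for o in clades:
            if item_contained_in(o) and (sup is None or len(o) < len(sup)):
                sup = o
        return clade_node[sup] if sup is not None else root

    for c in clades:
        p = parent_of(lambda o: c < o)
        adj[p].add(clade_node[c])
        adj[clade_node[c]].add(p)
    for t in taxa:
        p = parent_of(lambda o: t in o)
        adj[p].add(leaf_node[t])
        adj[leaf_node[t]].add(p)
    return PhyloTree(adj, {v: k for k, v in leaf_node.items()})


def strict_consensus(trees) -> PhyloTree:
    """Tree containing exactly the bipartitions shared by all input trees."""
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    taxa = _common_taxa(trees)
    splits = trees[0].bipartitions()
    for t in trees[1:]:
        splits = splits & t.bipartitions()
    return build_tree_from_splits(taxa, splits)


def majority_consensus(trees, cutoff: float = 50.0) -> PhyloTree:
    """Tree of bipartitions occurring in more than ``cutoff`` percent of trees."""
    if cutoff < 50:
        raise ValueError("cutoff below 50% can select incompatible splits")
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    taxa = _common_taxa(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    keep = {s for s, c in counts.items() if 100.0 * c / len(trees) > cutoff}
    return build_tree_from_splits(taxa, keep)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings; the defaults are the published protocol
    (1000 replicates, each searched with 100 random-addition replicates,
    hold 20, up to 1000 trees)."""

    n_replicates: int = 1000
    inner_search: SearchConfig = field(
        default_factory=lambda: SearchConfig(
            n_replicates=100, hold_per_replicate=20, max_trees=1000, collapse_rule="none"
        )
    )
    seed: int = 0
    report_threshold: float = 50.0
    vote_mode: str = "consensus"  # or "pertree"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.report_threshold <= 100:
            raise ValueError("report_threshold must be a percentage")
        if self.vote_mode not in ("consensus", "pertree"):
            raise ValueError("vote_mode must be 'consensus' or 'pertree'")


@dataclass
class SupportReport:
    """Clade frequencies from a bootstrap run.

    ``clade_frequencies`` maps canonical bipartitions to percentages in
    [0, 100]; ``annotated_tree`` carries the frequencies at or above the
    reporting threshold as branch annotations.
    """

    clade_frequencies: dict[frozenset, float]
    annotated_tree: PhyloTree
    n_replicates_effective: int
    n_failures: int = 0

    def supported_clades(self, threshold: float | None = None) -> dict[frozenset, float]:
        thr = self.annotated_threshold if threshold is None else threshold
        return {s: f for s, f in self.clade_frequencies.items() if f > thr}

    annotated_threshold: float = 50.0

    def to_table(self) -> str:
        lines = ["clade\tfrequency"]
        for s, f in sorted(
            self.clade_frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        ):
            lines.append(",".join(sorted(s)) + f"\t{f:.1f}")
        return "\n".join(lines) + "\n"


def bootstrap(
    matrix: CharacterMatrix,
    config: BootstrapConfig | None = None,
    reference_tree: PhyloTree | None = None,
) -> SupportReport:
    """Character-resampling bootstrap with clade-frequency summary.

    Each replicate draws ``n_chars`` columns with replacement (kept as
    integer weights), reruns the heuristic search, and contributes one vote
    per bipartition of the replicate's strict consensus of best trees
    (``vote_mode='pertree'`` instead averages over the replicate's trees).
    Frequencies at or above the threshold annotate ``reference_tree`` when
    given, otherwise the majority-rule consensus of replicate votes.
    """
    config = config or BootstrapConfig()
    n_chars = matrix.n_chars
    votes: dict[frozenset, float] = {}
    failures = 0
    effective = 0
    for rep in range(config.n_replicates):
        ss = np.random.SeedSequence([config.seed, rep])
        rng = np.random.default_rng(ss)
        weights = rng.multinomial(n_chars, np.full(n_chars, 1.0 / n_chars))
        inner = SearchConfig(
            n_replicates=config.inner_search.n_replicates,
            hold_per_replicate=config.inner_search.hold_per_replicate,
            max_trees=config.inner_search.max_trees,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            collapse_rule=config.inner_search.collapse_rule,
            final_sweep=config.inner_search.final_sweep,
        )
        try:
            result = heuristic_search(matrix, inner, weights=weights)
        except Exception:
            failures += 1
            continue
        effective += 1
        if config.vote_mode == "consensus":
            rep_splits = result.trees[0].bipartitions()
            for t in result.trees[1:]:
                rep_splits = rep_splits & t.bipartitions()
            for s in rep_splits:
                votes[s] = votes.get(s, 0.0) + 1.0
        else:
            k = len(result.trees)
            for t in result.trees:
                for s in t.bipartitions():
                    votes[s] = votes.get(s, 0.0) + 1.0 / k
    if effective == 0:
        raise RuntimeError("all bootstrap replicates failed")
    freqs = {s: 100.0 * v / effective for s, v in votes.items()}
    if reference_tree is not None:
        annotated = reference_tree.copy()
    else:
        keep = {s for s, f in freqs.items() if f > 50.0}
        annotated = build_tree_from_splits(matrix.taxon_labels, keep)
    annotated.branch_annotations = {
        s: round(freqs.get(s, 0.0))
        for s in annotated.bipartitions()
        if freqs.get(s, 0.0) >= config.report_threshold
    }
    return SupportReport(
        clade_frequencies=freqs,
        annotated_tree=annotated,
        n_replicates_effective=effective,
        n_failures=failures,
        annotated_threshold=config.report_threshold,
    )
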