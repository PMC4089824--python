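"""Unrooted leaf-labelled trees and the bipartition machinery built on them.

A :class:`PhyloTree` is stored unrooted (internal vertices of degree >= 3
after canonicalization); rooting is purely a display operation, since
parsimony lengths of unordered characters do not depend on root placement.
Tree identity is defined by the set of informative bipartitions, so two
newick strings describing the same unrooted topology compare equal.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = ["PhyloTree", "TreeError", "bipartitions", "rf_distance"]


class TreeError(ValueError):
    """Raised for malformed trees or mismatched leaf sets."""


class PhyloTree:
    """Unrooted, possibly multifurcating tree over named leaves.

    Nodes are integers; leaves carry labels.  ``branch_annotations`` maps a
    bipartition (see :meth:`bipartitions`) to an arbitrary payload such as a
    bootstrap percentage.
    """

    def __init__(
        self,
        adjacency: Mapping[int, Iterable[int]],
        leaf_labels: Mapping[int, str],
        branch_annotations: Mapping[frozenset, object] | None = None,
    ) -> None:
        self.adj: dict[int, list[int]] = {int(u): sorted(int(v) for v in nbrs) for u, nbrs in adjacency.items()}
        self.leaf_labels: dict[int, str] = dict(leaf_labels)
        self.branch_annotations: dict[frozenset, object] = dict(branch_annotations or {})
        self._validate()
        self._suppress_degree_two()
        self._bipartitions: frozenset[frozenset[str]] | None = None

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            raise TreeError("leaf labels must be unique")
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u not in self.adj.get(v, []):
                    raise TreeError(f"edge {u}-{v} is not symmetric")
        for u, nbrs in self.adj.items():
            if u in self.leaf_labels:
                if len(nbrs) != 1 and len(self.adj) > 1:
                    raise TreeError(f"leaf {u} must have degree 1")
            elif len(nbrs) < 2:
                raise TreeError(f"internal node {u} has degree {len(nbrs)}")
        # connectivity
        if self.adj:
            seen = {next(iter(self.adj))}
            stack = list(seen)
            while stack:
                u = stack.pop()
                for v in self.adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if len(seen) != len(self.adj):
                raise TreeError("tree is not connected")

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self.adj):
                if u not in self.leaf_labels and len(self.adj[u]) == 2:
                    a, b = self.adj[u]
                    self.adj[a] = [x for x in self.adj[a] if x != u] + [b]
                    self.adj[b] = [x for x in self.adj[b] if x != u] + [a]
                    del self.adj[u]
                    changed = True

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a newick string (rooted or unrooted; the result is unrooted)."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed newick: {exc}") from exc
        adjacency: dict[int, set[int]] = {}
        leaf_labels: dict[int, str] = {}
        ids: dict[object, int] = {}

        def nid(node) -> int:
            if node not in ids:
                ids[node] = len(ids)
                adjacency[ids[node]] = set()
            return ids[node]

        n_leaves = 0
        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            u, v = nid(edge.tail_node), nid(edge.head_node)
            adjacency[u].add(v)
            adjacency[v].add(u)
        for leaf in dtree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            if not label:
                raise TreeError("unlabelled leaf in newick input")
            leaf_labels[nid(leaf)] = label.replace(" ", "_")
            n_leaves += 1
        if n_leaves < 2:
            raise TreeError("need at least two leaves")
        return cls(adjacency, leaf_labels)

    # -- basic queries -----------------------------------------------------

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == 3 for u, nbrs in self.adj.items() if u not in self.leaf_labels
        )

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            {u: list(vs) for u, vs in self.adj.items()},
            dict(self.leaf_labels),
            dict(self.branch_annotations),
        )

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, include_trivial: bool = False) -> frozenset[frozenset[str]]:
        """One bipartition per branch, invariant under re-rooting.

        Each bipartition is represented canonically by the leaf-label set on
        the side *not* containing the lexicographically smallest leaf.  By
        default only informative bipartitions (both sides >= 2 leaves, i.e.
        internal branches) are returned.
        """
        if self._bipartitions is not None and not include_trivial:
            return self._bipartitions
        ref = min(self.leaf_labels.values())
        n = self.n_leaves
        splits: set[frozenset[str]] = set()
        # leaf sets below each directed edge via iterative postorder
        root = next(iter(self.leaf_labels))
        parent = {root: None}
        order = [root]
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    order.append(v)
                    stack.append(v)
        below: dict[int, set[str]] = {}
        for u in reversed(order):
            s: set[str] = set()
            if u in self.leaf_labels:
                s.add(self.leaf_labels[u])
            for v in self.adj[u]:
                if v != parent[u] and parent.get(v) == u:
                    s |= below[v]
            below[u] = s
        for u in order[1:]:
            side = below[u]
            if not include_trivial and not (2 <= len(side) <= n - 2):
                continue
            if ref in side:
                side = self.taxa - side
            if side:
                splits.add(frozenset(side))
        result = frozenset(splits)
        if not include_trivial:
            self._bipartitions = result
        return result

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.taxa == other.taxa and self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        return hash((self.taxa, self.bipartitions()))

    # -- newick output -----------------------------------------------------

    def newick(self, rooted_at: str | None = None) -> str:
        """Deterministic newick serialization.

        ``rooted_at`` re-roots the display on the pendant edge of the given
        leaf so it appears as the first-diverging terminal; by default the
        display root is the pendant edge of the lexicographically smallest
        leaf.  Child order is sorted by smallest descendant label, which
        makes the output canonical: equal unrooted topologies serialize to
        equal strings.
        """
        label_to_node = {lab: n for n, lab in self.leaf_labels.items()}
        if rooted_at is None:
            rooted_at = min(label_to_node)
        if rooted_at not in label_to_node:
            raise TreeError(f"unknown rooted_at label {rooted_at!r}")
        root_leaf = label_to_node[rooted_at]
        if self.n_leaves == 1:
            return f"{rooted_at};"

        annot = self._annotations_by_side()

        def render(u: int, parent_node: int) -> tuple[str, str]:
            if u in self.leaf_labels:
                return self.leaf_labels[u].replace(" ", "_"), self.leaf_labels[u]
            parts = sorted(
                (render(v, u) for v in self.adj[u] if v != parent_node),
                key=lambda p: p[1],
            )
            text = "(" + ",".join(p[0] for p in parts) + ")"
            key = min(p[1] for p in parts)
            return text, key

        inner = self.adj[root_leaf][0]
        body, _ = render(inner, root_leaf)
        return f"({rooted_at.replace(' ', '_')},{body});"

    def _annotations_by_side(self) -> dict[frozenset, object]:
        return dict(self.branch_annotations)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.newick()})"


def bipartitions(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """Informative bipartitions of ``tree`` (module-level convenience)."""
    return tree.bipartitions()


def rf_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Robinson-Foulds distance: symmetric difference of informative splits."""
    if tree_a.taxa != tree_b.taxa:
        raise TreeError("trees must share an identical leaf set")
    return len(tree_a.bipartitions() ^ tree_b.bipartitions())


def parse_newick(text: str) -> PhyloTree:
    """Parse newick text into an unrooted :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, rooted_at: str | None = None) -> str:
    """Serialize ``tree`` to canonical newick, optionally rooted for display."""
    return tree.newick(rooted_at=rooted_at)


__all__ += ["parse_newick", "write_newick"]
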