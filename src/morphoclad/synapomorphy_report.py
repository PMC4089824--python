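"""Mapping common synapomorphies onto the strict consensus.

A character-state transformation is mapped onto a consensus branch only if
its optimization there is unambiguous (every most-parsimonious
reconstruction places a change with the same derived state on that branch)
and the same unambiguous transformation occurs, on the branch with the
same bipartition, in every most parsimonious tree.  Transformations are
classified *unique* (single origin, no homoplasy: the character's observed
steps on the consensus equal its minimum conceivable steps, so ci = ri = 1)
or homoplasious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matrix_io import CharacterMatrix
from .parsimony_engine import (
    IndexReport,
    edge_analysis,
    index_report,
    step_bounds,
)
from .search import SearchResult
from .consensus_support import SupportReport, strict_consensus
from .tree_model import PhyloTree, TreeError

__all__ = [
    "Transformation",
    "SynapomorphyMap",
    "common_synapomorphies",
    "is_monophyletic",
    "render_report",
]


@dataclass(frozen=True)
class Transformation:
    char_id: int
    from_state: int | None  # None when the ancestral state is ambiguous
    derived_state: int
    unique: bool


@dataclass
class SynapomorphyMap:
    """Branch -> transformations common to the consensus and every MPT.

    Branches are keyed by the leaf set on the side away from the root taxon
    (the clade the transformation supports).  ``orphans`` lists characters
    that change unambiguously in every MPT but on no shared consensus
    branch.
    """

    by_branch: dict[frozenset, list[Transformation]]
    orphans: list[int]
    root_taxon: str

    def unique_characters(self) -> list[int]:
        return sorted(
            {t.char_id for ts in self.by_branch.values() for t in ts if t.unique}
        )

    def all_characters(self) -> list[int]:
        return sorted({t.char_id for ts in self.by_branch.values() for t in ts})


def _unambiguous_changes(tree: PhyloTree, matrix: CharacterMatrix, root_taxon: str):
    """(clade, char_id) -> derived state for every unambiguous branch change."""
    ana = edge_analysis(tree, matrix, root_taxon=root_taxon)
    out: dict[tuple[frozenset, int], tuple[int, frozenset]] = {}
    for e, u in enumerate(ana.edge_nodes):
        clade = ana.clade_of(u)
        for j in ana.edge_unambiguous[e].nonzero()[0]:
            derived = int(ana.edge_to[e, j].nonzero()[0][0])
            from_states = frozenset(int(s) for s in ana.edge_from[e, j].nonzero()[0])
            out[(clade, int(j) + 1)] = (derived, from_states)
    return out


def common_synapomorphies(
    consensus: PhyloTree,
    mpts,
    matrix: CharacterMatrix,
    root_taxon: str | None = None,
) -> SynapomorphyMap:
    """Intersect unambiguous branch changes across the consensus and all MPTs.

    ``consensus`` must be the strict consensus of ``mpts``; branches are
    matched across trees by their bipartitions (MPT branches collapsed out
    of the consensus cannot receive a mapping).
    """
    mpts = list(mpts)
    if not mpts:
        raise ValueError("need at least one most parsimonious tree")
    if strict_consensus(mpts) != consensus:
        raise TreeError("consensus is not the strict consensus of the given trees")
    if root_taxon is None:
        root_taxon = min(consensus.taxa)
    cons_changes = _unambiguous_changes(consensus, matrix, root_taxon)
    mpt_changes = [_unambiguous_changes(t, matrix, root_taxon) for t in mpts]

    cons_steps = {
        c.char_id: c for c in index_report(consensus, matrix).per_character
    }
    by_branch: dict[frozenset, list[Transformation]] = {}
    mapped_chars: set[int] = set()
    for (clade, char_id), (derived, from_states) in sorted(
        cons_changes.items(), key=lambda kv: (len(kv[0][0]), sorted(kv[0][0]), kv[0][1])
    ):
        if any(ch.get((clade, char_id), (None,))[0] != derived for ch in mpt_changes):
            continue
        ci = cons_steps[char_id]
        unique = ci.s == ci.m
        by_branch.setdefault(clade, []).append(
            Transformation(
                char_id=char_id,
                from_state=next(iter(from_states)) if len(from_states) == 1 else None,
                derived_state=derived,
                unique=unique,
            )
        )
        mapped_chars.add(char_id)
    chars_everywhere = set(range(1, matrix.n_chars + 1))
    for changes in [cons_changes] + mpt_changes:
        chars_everywhere &= {cid for (_, cid) in changes}
    orphans = sorted(chars_everywhere - mapped_chars)
    return SynapomorphyMap(by_branch=by_branch, orphans=orphans, root_taxon=root_taxon)


def is_monophyletic(tree: PhyloTree, labels, root_taxon: str | None = None) -> bool:
    """Does ``labels`` form a clade on ``tree`` rooted at ``root_taxon``?"""
    group = frozenset(labels)
    if not group <= tree.taxa:
        raise TreeError("labels are not a subset of the tree's taxa")
    if root_taxon is None:
        root_taxon = min(tree.taxa)
    if root_taxon in group:
        raise ValueError("the root taxon cannot be part of the tested group")
    if len(group) in (1, len(tree.taxa) - 1):
        return True
    # clades w.r.t. the root are the branch sides not containing it
    for side in tree.bipartitions():
        candidate = side if root_taxon not in side else tree.taxa - side
        if candidate == group:
            return True
    return False


def render_report(
    result: SearchResult,
    consensus: PhyloTree,
    indices: IndexReport,
    support: SupportReport | None,
    synmap: SynapomorphyMap,
    root_taxon: str | None = None,
) -> str:
    """Plain-text analysis report: summary block, per-character index table,
    branch table (support plus transformations), and annotated newick."""
    from .parsimony_engine import round_half_up

    root = root_taxon or synmap.root_taxon
    ens = indices.ensemble_all
    lines = ["== parsimony analysis summary =="]
    lines.append(f"most parsimonious trees: {len(result.trees)}")
    lines.append(f"best length: {result.best_length}")
    ci = "undefined" if ens.CI is None else f"{ens.CI:.4f}"
    ri = "undefined" if ens.RI is None else f"{ens.RI:.4f}"
    lines.append(f"consensus: L = {ens.S}; CI = {ci}; RI = {ri}")
    lines.append("")
    lines.append("== per-character indices ==")
    lines.append(indices.to_table().rstrip("\n"))
    lines.append("")
    lines.append("== branches ==")
    header = "clade\ttransformations"
    freqs = support.clade_frequencies if support is not None else None
    if freqs is not None:
        header += "\tsupport"
    lines.append(header)
    branches = sorted(synmap.by_branch, key=lambda c: (len(c), sorted(c)))
    for clade in branches:
        ts = synmap.by_branch[clade]
        shown = ";".join(
            f"{t.char_id}:{t.derived_state}{'*' if t.unique else ''}" for t in ts
        )
        row = ",".join(sorted(clade)) + "\t" + shown
        if freqs is not None:
            row += f"\t{freqs.get(clade, 0.0):.0f}"
        lines.append(row)
    if synmap.orphans:
        lines.append(f"# characters without a common mapping: {synmap.orphans}")
    lines.append("")
    lines.append("== consensus (rooted for display) ==")
    lines.append(consensus.newick(rooted_at=root))
    lines.append("")
    return "\n".join(lines)
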