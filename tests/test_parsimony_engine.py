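import numpy as np
import pytest

from morphoclad import (
    CharacterMatrix,
    PhyloTree,
    TreeError,
    index_report,
    parse_newick,
    per_character_lengths,
    reconstruct,
    round_half_up,
    step_bounds,
    tree_length,
    truncate2,
)
from morphoclad.synthetic_data import SimulationConfig, random_tree, simulate

from .oracles import all_binary_topologies, matrix_sankoff_length, sankoff_steps


def _random_matrix(rng, n_taxa, n_chars, n_states=4, missing=0.15):
    codes = rng.integers(0, n_states, size=(n_taxa, n_chars)).astype(np.int8)
    codes[rng.random(codes.shape) < missing / 2] = -1
    codes[rng.random(codes.shape) < missing / 2] = -2
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], codes)


def _random_polytomous(tree, rng):
    """Collapse a random subset of internal branches of a binary tree."""
    splits = list(tree.bipartitions())
    keep = [s for s in splits if rng.random() < 0.5]
    from morphoclad.consensus_support import build_tree_from_splits

    return build_tree_from_splits(tree.taxa, keep)


class TestLengths:
    def test_constant_column_zero(self):
        m = CharacterMatrix(["A", "B", "C", "D"], np.zeros((4, 2), dtype=np.int8))
        assert tree_length(parse_newick("((A,B),(C,D));"), m) == 0

    def test_star_tree_gives_g(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 10))
            m = _random_matrix(rng, n, 1)
            hub = n
            adj = {i: [hub] for i in range(n)}
            adj[hub] = list(range(n))
            star = PhyloTree(adj, {i: f"t{i}" for i in range(n)})
            assert tree_length(star, m) == step_bounds(m.codes[:, 0]).g

    def test_matches_sankoff_oracle_on_random_instances(self, rng):
        """Bitmask Hartigan == uniform-cost Sankoff DP, binary and polytomous."""
        for trial in range(200):
            n = int(rng.integers(4, 9))
            m = _random_matrix(rng, n, int(rng.integers(1, 5)))
            tree = random_tree(n, int(rng.integers(1 << 30)), labels=m.taxon_labels)
            if trial % 2:
                tree = _random_polytomous(tree, rng)
            assert tree_length(tree, m) == matrix_sankoff_length(tree, m)

    def test_length_invariant_under_rerooting_and_permutation(self, rng):
        m = _random_matrix(rng, 7, 6)
        tree = random_tree(7, 11, labels=m.taxon_labels)
        base = tree_length(tree, m)
        for taxon in m.taxon_labels:
            rerooted = parse_newick(tree.newick(rooted_at=taxon))
            assert tree_length(rerooted, m) == base
        perm = list(np.random.default_rng(0).permutation(7))
        m2 = CharacterMatrix([m.taxon_labels[i] for i in perm], m.codes[perm])
        assert tree_length(tree, m2) == base

    def test_leaf_mismatch_raises(self, rng):
        m = _random_matrix(rng, 5, 3)
        tree = random_tree(5, 1)  # labels t1..t5, matrix has t0..t4
        with pytest.raises(TreeError):
            tree_length(tree, m)

    def test_collapsing_never_shortens(self, rng):
        for _ in range(20):
            m = _random_matrix(rng, 7, 8)
            tree = random_tree(7, int(rng.integers(1 << 30)), labels=m.taxon_labels)
            poly = _random_polytomous(tree, rng)
            assert tree_length(poly, m) >= tree_length(tree, m)

    def test_weights_equal_duplicated_columns(self, rng):
        m = _random_matrix(rng, 6, 4)
        tree = random_tree(6, 9, labels=m.taxon_labels)
        w = [2, 0, 3, 1]
        expanded = CharacterMatrix(
            m.taxon_labels, np.repeat(m.codes, w, axis=1)
        )
        assert tree_length(tree, m, weights=w) == tree_length(tree, expanded)


class TestStepBounds:
    def test_even_binary_split(self):
        col = np.array([0] * 5 + [1] * 5, dtype=np.int8)
        b = step_bounds(col)
        assert (b.m, b.g) == (1, 5)

    def test_single_scored_taxon(self):
        col = np.array([3, -1, -1, -2], dtype=np.int8)
        assert (step_bounds(col).m, step_bounds(col).g) == (0, 0)

    def test_all_missing(self):
        col = np.full(6, -1, dtype=np.int8)
        assert (step_bounds(col).m, step_bounds(col).g) == (0, 0)

    def test_bounds_tight_over_all_six_taxon_trees(self, rng):
        """min/max of observed steps over every topology equals m and g."""
        labels = [f"t{i}" for i in range(6)]
        trees = list(all_binary_topologies(labels))
        assert len(trees) == 105
        star = PhyloTree(
            {**{i: [6] for i in range(6)}, 6: list(range(6))},
            {i: labels[i] for i in range(6)},
        )
        for _ in range(10):
            m = _random_matrix(rng, 6, 1)
            b = step_bounds(m.codes[:, 0])
            lengths = [tree_length(t, m) for t in trees]
            assert min(lengths) == b.m
            assert max(lengths) <= b.g  # g is attained on the star tree
            assert tree_length(star, m) == b.g
            assert all(b.m <= s <= b.g for s in lengths)


class TestIndices:
    def test_homoplasy_free_matrix_gives_unit_indices(self):
        ds = simulate(SimulationConfig(n_taxa=10, n_chars=30, change_rate=0.6, seed=5))
        keep = [j + 1 for j in range(30) if not ds.realized_homoplasy[j]]
        assert len(keep) >= 20  # at this rate most characters are clean
        clean = CharacterMatrix(
            ds.matrix.taxon_labels, ds.matrix.codes[:, [k - 1 for k in keep]]
        )
        rep = index_report(ds.true_tree, clean)
        assert rep.ensemble_all.CI == 1.0
        assert rep.ensemble_all.RI in (1.0, None)  # None if no informative characters

    def test_undefined_ci_for_constant_character(self):
        codes = np.array([[0, 0], [0, 1], [0, 1], [0, 0]], dtype=np.int8)
        m = CharacterMatrix(["A", "B", "C", "D"], codes)
        rep = index_report(parse_newick("((A,B),(C,D));"), m)
        assert rep.per_character[0].ci is None
        assert rep.per_character[0].ri is None  # g == m == 0

    def test_rounding_conventions(self):
        assert round_half_up(0.285) == 0.29
        assert truncate2(2 / 3) == 0.66
        assert truncate2(0.5915) == 0.59
        assert truncate2(0.5664) == 0.56


class TestReconstruction:
    def test_single_derived_leaf(self):
        codes = np.array([[0], [0], [0], [1]], dtype=np.int8)
        m = CharacterMatrix(["A", "B", "C", "D"], codes)
        r = reconstruct(parse_newick("((A,B),(C,D));"), m, 1, root_taxon="A")
        unamb = [c for c in r.changes if c.unambiguous]
        assert len(unamb) == 1
        assert unamb[0].clade == frozenset({"D"})
        assert unamb[0].to_states == frozenset({1})

    def test_sister_pair_change_on_stem(self):
        codes = np.array([[0], [0], [1], [1], [0]], dtype=np.int8)
        m = CharacterMatrix(["A", "B", "C", "D", "E"], codes)
        r = reconstruct(parse_newick("((A,B),((C,D),E));"), m, 1, root_taxon="A")
        unamb = [c for c in r.changes if c.unambiguous]
        assert len(unamb) == 1
        assert unamb[0].clade == frozenset({"C", "D"})
        assert unamb[0].from_states == frozenset({0})

    def test_reconstruction_length_equals_observed_steps(self, rng):
        for _ in range(20):
            m = _random_matrix(rng, 6, 3)
            tree = random_tree(6, int(rng.integers(1 << 30)), labels=m.taxon_labels)
            steps = per_character_lengths(tree, m)
            for j in range(m.n_chars):
                assert reconstruct(tree, m, j + 1).length == steps[j]

    def test_forced_and_derived_sets_match_enumeration(self, rng):
        """Brute-force all most-parsimonious labelings on small instances and
        compare forced/unambiguous branch flags with the DP."""
        from itertools import product

        for _ in range(25):
            n = 6
            m = _random_matrix(rng, n, 1, n_states=3, missing=0.1)
            tree = random_tree(n, int(rng.integers(1 << 30)), labels=m.taxon_labels)
            r = reconstruct(tree, m, 1, root_taxon=m.taxon_labels[0])
            col = {lab: (int(c) if c >= 0 else None)
                   for lab, c in zip(m.taxon_labels, m.codes[:, 0])}
            best = sankoff_steps(tree, col)
            states = sorted({s for s in col.values() if s is not None}) or [0]
            internals = [u for u in tree.adj if u not in tree.leaf_labels]
            leaf_states = {}
            for node, lab in tree.leaf_labels.items():
                leaf_states[node] = [col[lab]] if col[lab] is not None else states
            # enumerate all assignments; collect edge-change profiles of optima
            edge_list = tree.edges()
            optima = []
            leaf_nodes = list(tree.leaf_labels)
            for leaf_choice in product(*(leaf_states[n_] for n_ in leaf_nodes)):
                fixed = dict(zip(leaf_nodes, leaf_choice))
                for internal_choice in product(states, repeat=len(internals)):
                    assign = {**fixed, **dict(zip(internals, internal_choice))}
                    cost = sum(assign[a] != assign[b] for a, b in edge_list)
                    if cost == best:
                        optima.append(assign)
            # compare per-branch behaviour for every recorded change
            label = tree.leaf_labels
            clade_of = {}
            for a, b in edge_list:
                seen = {b}
                stack = [b]
                while stack:
                    x = stack.pop()
                    for y in tree.adj[x]:
                        if (x == b and y == a) or y in seen:
                            continue
                        seen.add(y)
                        stack.append(y)
                side = frozenset(label[x] for x in seen if x in label)
                root_lab = m.taxon_labels[0]
                clade_of[(a, b)] = side if root_lab not in side else frozenset(label.values()) - side
            recorded = {c.clade: c for c in r.changes}
            root_lab = m.taxon_labels[0]

            def side_of(b, a):
                seen = {b}
                stack = [b]
                while stack:
                    x = stack.pop()
                    for y in tree.adj[x]:
                        if (x == b and y == a) or y in seen:
                            continue
                        seen.add(y)
                        stack.append(y)
                return frozenset(label[x] for x in seen if x in label)

            for a, b in edge_list:
                clade = clade_of[(a, b)]
                changed_in = [assign[a] != assign[b] for assign in optima]
                forced_true = all(changed_in)
                rec = recorded.get(clade)
                if rec is None:
                    assert not any(changed_in)
                    continue
                assert rec.forced == forced_true
                if forced_true:
                    # the endpoint away from the root carries the derived state
                    away = b if root_lab not in side_of(b, a) else a
                    derived_states = {assign[away] for assign in optima}
                    assert rec.unambiguous == (len(derived_states) == 1)
                    if rec.unambiguous:
                        assert rec.to_states == frozenset(derived_states)
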