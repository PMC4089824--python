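import numpy as np
import pytest

from morphoclad import (
    BootstrapConfig,
    CharacterMatrix,
    SearchConfig,
    TreeError,
    bootstrap,
    majority_consensus,
    parse_newick,
    strict_consensus,
)
from morphoclad.synthetic_data import random_tree


class TestStrictConsensus:
    def test_singleton_identity(self):
        t = random_tree(8, 1)
        assert strict_consensus([t]) == t

    def test_fully_conflicting_quartets_give_star(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        cons = strict_consensus([a, b])
        assert cons.bipartitions() == frozenset()

    def test_leaf_set_mismatch(self):
        with pytest.raises(TreeError):
            strict_consensus([random_tree(5, 0), random_tree(6, 0)])

    def test_equals_split_intersection_on_random_sets(self, rng):
        for trial in range(30):
            k = int(rng.integers(2, 5))
            trees = [random_tree(7, int(rng.integers(1 << 30))) for _ in range(k)]
            cons = strict_consensus(trees)
            expected = trees[0].bipartitions()
            for t in trees[1:]:
                expected &= t.bipartitions()
            assert cons.bipartitions() == expected

    def test_refined_by_every_input_and_monotone(self, rng):
        trees = [random_tree(8, s) for s in (1, 2, 3)]
        cons_two = strict_consensus(trees[:2])
        cons_three = strict_consensus(trees)
        for t in trees:
            assert cons_three.bipartitions() <= t.bipartitions() | cons_three.bipartitions()
        assert cons_three.bipartitions() <= cons_two.bipartitions()


class TestMajorityConsensus:
    def test_identical_trees_any_cutoff(self):
        t = random_tree(7, 4)
        for cutoff in (50, 75, 99):
            assert majority_consensus([t, t, t], cutoff) == t

    def test_two_of_three_retained_at_fifty(self):
        a = parse_newick("((A,B),(C,(D,E)));")
        b = parse_newick("((A,B),(D,(C,E)));")
        c = parse_newick("((A,C),(B,(D,E)));")
        cons = majority_consensus([a, b, c], 50)
        # clade AB (canonical split CDE) is in a and b; DE is in a and c
        assert frozenset({"C", "D", "E"}) in cons.bipartitions()
        assert frozenset({"D", "E"}) in cons.bipartitions()

    def test_matches_direct_tally(self, rng):
        for trial in range(20):
            trees = [random_tree(6, int(rng.integers(1 << 30))) for _ in range(5)]
            cons = majority_consensus(trees, 50)
            counts = {}
            for t in trees:
                for s in t.bipartitions():
                    counts[s] = counts.get(s, 0) + 1
            expected = {s for s, c in counts.items() if 100.0 * c / 5 > 50}
            assert cons.bipartitions() == expected

    def test_low_cutoff_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus([random_tree(5, 0)], 30)


def _clade_marker_matrix(tree, chars_per_split=4):
    """Binary characters marking each informative clade of ``tree``."""
    labels = sorted(tree.taxa)
    splits = sorted(tree.bipartitions(), key=lambda s: (len(s), sorted(s)))
    cols = []
    for s in splits:
        for _ in range(chars_per_split):
            cols.append([1 if lab in s else 0 for lab in labels])
    codes = np.array(cols, dtype=np.int8).T
    return CharacterMatrix(labels, codes), splits


_FAST_INNER = SearchConfig(
    n_replicates=2, hold_per_replicate=10, max_trees=100,
    collapse_rule="none", final_sweep=False,
)


class TestBootstrap:
    def test_well_supported_splits_near_hundred(self):
        tree = random_tree(8, 31)
        matrix, splits = _clade_marker_matrix(tree, chars_per_split=4)
        report = bootstrap(
            matrix,
            BootstrapConfig(n_replicates=150, inner_search=_FAST_INNER, seed=5),
        )
        # 4 of 20 columns support each split: expected presence
        # 1-(1-4/20)^20 = 98.8% of replicates
        for s in splits:
            assert report.clade_frequencies.get(s, 0.0) > 93

    def test_single_informative_character_closed_form(self):
        # one informative column among 10: the split's expected frequency is
        # the probability the column survives resampling, 1-(1-1/10)^10 = 65.1%
        labels = [f"t{i}" for i in range(6)]
        codes = np.zeros((6, 10), dtype=np.int8)
        codes[:2, 0] = 1
        matrix = CharacterMatrix(labels, codes)
        report = bootstrap(
            matrix,
            BootstrapConfig(
                n_replicates=400,
                inner_search=SearchConfig(
                    n_replicates=1, hold_per_replicate=20, max_trees=200,
                    collapse_rule="none", final_sweep=True,
                ),
                seed=9,
            ),
        )
        split = frozenset({"t2", "t3", "t4", "t5"})  # canonical side (excludes t0)
        expected = 100 * (1 - (1 - 0.1) ** 10)
        assert abs(report.clade_frequencies.get(split, 0.0) - expected) < 5

    def test_seed_stability_within_binomial_error(self):
        tree = random_tree(7, 13)
        matrix, splits = _clade_marker_matrix(tree, chars_per_split=2)
        freqs = []
        for seed in (1, 2):
            rep = bootstrap(
                matrix,
                BootstrapConfig(n_replicates=150, inner_search=_FAST_INNER, seed=seed),
            )
            freqs.append(rep.clade_frequencies)
        for s in splits:
            assert abs(freqs[0].get(s, 0.0) - freqs[1].get(s, 0.0)) < 12

    def test_annotations_respect_threshold(self):
        tree = random_tree(6, 3)
        matrix, _ = _clade_marker_matrix(tree, chars_per_split=3)
        rep = bootstrap(
            matrix,
            BootstrapConfig(
                n_replicates=60, inner_search=_FAST_INNER, seed=3, report_threshold=50
            ),
            reference_tree=tree,
        )
        assert all(v >= 50 for v in rep.annotated_tree.branch_annotations.values())
        assert all(0 <= f <= 100 for f in rep.clade_frequencies.values())
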