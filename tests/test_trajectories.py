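"""Trajectory extraction, permutation enrichment, nested levels."""

import itertools

import numpy as np
import pytest
from scipy import stats

from clonetraj import trajectories as tj
from clonetraj.datatypes import CnvSegment
from conftest import make_tree


class TestLabels:
    @pytest.mark.parametrize("chrom,start,end,cn,loh,expected", [
        ("9", 1, 38_000_000, 1, False, "del_in_9p"),     # p-arm deletion
        ("20", 100_000, 64_000_000, 3, False, "dup20"),  # whole-chromosome gain
        ("9", 1, 38_000_000, 2, True, "LOH_in_9p"),
        ("6", 62_000_000, 169_000_000, 0, False, "del_in_6q"),
    ])
    def test_cnv_labels(self, chrom, start, end, cn, loh, expected):
        seg = CnvSegment("P", "S", 0, chrom, start, end, cn, loh)
        assert tj.cnv_event_label(seg) == expected

    def test_unknown_chromosome_errors(self):
        seg = CnvSegment("P", "S", 0, "chrZ", 1, 100, 1, False)
        with pytest.raises(KeyError):
            tj.cnv_event_label(seg)

    def test_label_events_collapses_duplicates(self):
        doc = make_tree("P", [("A", None, ["v1", "v2"], {0: 1.0})])
        out = tj.label_events(doc, {"v1": "NOTCH1", "v2": "NOTCH1"})
        assert out.node("A").events == ["NOTCH1"]


class TestExtraction:
    def test_chain_semantics(self, chain_tree):
        got = tj.extract_trajectories(chain_tree)
        assert got == {("e1", "e2"), ("e1", "e3"), ("e2", "e3"),
                       ("e1", "e2", "e3")}

    def test_star_has_no_sibling_pairs(self, star_tree):
        got = tj.extract_trajectories(star_tree)
        assert got == {("e1", "e2"), ("e1", "e3")}

    def test_same_node_order_unknowable(self):
        doc = make_tree("P", [("A", None, ["e1", "e2"], {0: 1.0}),
                              ("B", "A", ["e3"], {0: 0.4})])
        assert tj.extract_trajectories(doc) == {("e1", "e3"), ("e2", "e3")}

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_path_graph_counts(self, n):
        """A path of n single-event nodes yields C(n,2) pairs, C(n,3) triples."""
        spec = [("N0", None, ["x0"], {0: 1.0})]
        spec += [(f"N{i}", f"N{i-1}", [f"x{i}"], {0: 1.0 - 0.1 * i})
                 for i in range(1, n)]
        got = tj.extract_trajectories(make_tree("P", spec))
        pairs = [t for t in got if len(t) == 2]
        triples = [t for t in got if len(t) == 3]
        from math import comb
        assert len(pairs) == comb(n, 2) and len(triples) == comb(n, 3)


class TestFrequencies:
    def _cohort(self, n, with_pair_in=1):
        out = []
        for i in range(n):
            if i < with_pair_in:
                out.append(make_tree(f"P{i}", [("A", None, ["X"], {0: 1.0}),
                                               ("B", "A", ["Y"], {0: 0.5})]))
            else:
                out.append(make_tree(f"P{i}", [("A", None, ["Z"], {0: 1.0})]))
        return out

    def test_inclusive_boundary_len2(self):
        kept = tj.trajectory_frequencies(self._cohort(10))
        assert any(t.labels == ("X", "Y") for t in kept)  # 0.10 retained

    def test_below_boundary_dropped(self):
        kept = tj.trajectory_frequencies(self._cohort(20))
        assert not any(t.labels == ("X", "Y") for t in kept)  # 0.05 < 0.10

    def test_triple_boundary(self):
        trees = [make_tree("P0", [("A", None, ["X"], {0: 1.0}),
                                  ("B", "A", ["Y"], {0: 0.5}),
                                  ("C", "B", ["Z"], {0: 0.2})])]
        trees += [make_tree(f"P{i}", [("A", None, ["W"], {0: 1.0})])
                  for i in range(1, 20)]
        kept = tj.trajectory_frequencies(trees)
        assert any(t.labels == ("X", "Y", "Z") for t in kept)  # 1/20 = 0.05


class TestPermutationTest:
    def test_forced_pair_matches_binomial_oracle(self):
        """10 trees each with X alone in the root and Y alone in the child:
        a label shuffle keeps or swaps them with probability 1/2, so the
        null cohort support is Binomial(10, 1/2) and the exact p-value of
        the observed support 10 is 2^-10."""
        trees = [make_tree(f"P{i}", [("A", None, ["X"], {0: 1.0}),
                                     ("B", "A", ["Y"], {0: 0.5})])
                 for i in range(10)]
        n_perm = 8000
        res = tj.trajectory_permutation_test(trees, ("X", "Y"), n_perm=n_perm,
                                             seed=0)
        assert res.support == 10
        exact_tail = 2.0 ** -10
        expected_p = (1 + n_perm * exact_tail) / (1 + n_perm)
        sd = np.sqrt(n_perm * exact_tail) / (1 + n_perm)
        assert abs(res.p_value - expected_p) < 4 * sd

    def test_null_support_distribution_matches_binomial(self):
        """The permutation-null support of the forced pair is Bin(10, 1/2)
        (chi-square goodness of fit against the exact law)."""
        trees = [make_tree(f"P{i}", [("A", None, ["X"], {0: 1.0}),
                                     ("B", "A", ["Y"], {0: 0.5})])
                 for i in range(10)]
        rng = np.random.default_rng(1)
        engine = tj._PermEngine(trees, 4000, rng, with_triples=False)
        code = engine._code(("X", "Y"))
        null = engine.null_pairs[:, code]
        counts = np.bincount(null, minlength=11)
        probs = stats.binom.pmf(np.arange(11), 10, 0.5)
        chi = stats.chisquare(counts, probs * len(null))
        assert chi.pvalue > 0.001

    def test_determinism(self):
        trees = [make_tree(f"P{i}", [("A", None, ["X", "Z"], {0: 1.0}),
                                     ("B", "A", ["Y"], {0: 0.5})])
                 for i in range(6)]
        r1 = tj.trajectory_permutation_test(trees, ("X", "Y"), n_perm=500, seed=9)
        r2 = tj.trajectory_permutation_test(trees, ("X", "Y"), n_perm=500, seed=9)
        assert r1.p_value == r2.p_value

    def test_small_n_perm_refused_in_strict_mode(self, star_tree):
        with pytest.raises(ValueError, match="strict"):
            tj.trajectory_permutation_test([star_tree], ("e1", "e2"), n_perm=50)
        with pytest.warns(UserWarning):
            tj.trajectory_permutation_test([star_tree], ("e1", "e2"), n_perm=50,
                                           strict=False)

    def test_cohort_table_adjusts_within_length_class(self):
        trees = [make_tree(f"P{i}", [("A", None, ["X"], {0: 1.0}),
                                     ("B", "A", ["Y"], {0: 0.5})])
                 for i in range(10)]
        df = tj.test_cohort_trajectories(trees, "pediatric T-ALL", n_perm=500,
                                         seed=0)
        assert (df["p_adjusted"] >= df["p_value"] - 1e-15).all()
        assert set(df["subgroup"]) == {"pediatric T-ALL"}


class TestBhAdjust:
    def test_hand_computed_example(self):
        got = tj.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert tj.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_ones_stay_ones(self):
        assert np.allclose(tj.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_empty(self):
        assert len(tj.bh_adjust([])) == 0

    def test_dominates_raw_p(self, rng):
        p = rng.uniform(size=30)
        adj = tj.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestNestedLevels:
    def test_all_in_root(self):
        doc = make_tree("P", [("A", None, ["a", "b"], {0: 1.0})])
        assert tj.nested_levels(doc) == {"a": 1, "b": 1}
        assert tj.tree_nested_level(doc) == 1

    def test_chain_depth(self):
        spec = [("N0", None, ["x0"], {0: 1.0})]
        spec += [(f"N{i}", f"N{i-1}", [f"x{i}"], {0: 1.0 - 0.2 * i})
                 for i in range(1, 4)]
        doc = make_tree("P", spec)
        assert tj.tree_nested_level(doc) == 4
        assert tj.nested_levels(doc)["x2"] == 3  # grandchild of the founder

    def test_weighted_tree_scope_equal_weights(self):
        t1 = make_tree("P1", [("A", None, ["a"], {0: 1.0}),
                              ("B", "A", ["b"], {0: 0.5}),
                              ("C", "B", [], {0: 0.2})])       # depth 3, 2 events
        t2 = make_tree("P2", [("A", None, ["a"], {0: 1.0}),
                              ("B", "A", ["b"], {0: 0.5}),
                              ("C", "B", [], {0: 0.3}),
                              ("D", "C", [], {0: 0.1})])       # depth 4, 2 events
        res = tj.weighted_nested_level([t1, t2], "tree")
        assert res.value == pytest.approx(3.5)

    def test_weighted_tree_scope_event_counts(self):
        t1 = make_tree("P1", [("A", None, ["a"], {0: 1.0}),
                              ("B", "A", [], {0: 0.5})])              # depth 2, 1 event
        t2 = make_tree("P2", [("A", None, ["a", "b"], {0: 1.0}),
                              ("B", "A", ["c"], {0: 0.5}),
                              ("C", "B", [], {0: 0.3}),
                              ("D", "C", [], {0: 0.1})])              # depth 4, 3 events
        res = tj.weighted_nested_level([t1, t2], "tree")
        assert res.value == pytest.approx((2 * 1 + 4 * 3) / 4)

    def test_event_class_scope(self):
        t1 = make_tree("P1", [("A", None, ["del_in_9p"], {0: 1.0})])
        t2 = make_tree("P2", [("A", None, ["del_in_9p"], {0: 1.0})])
        res = tj.weighted_nested_level([t1, t2], "event_class",
                                       labels={"del_in_9p", "LOH_in_9p"})
        assert res.value == 1.0 and res.n == 2

    def test_missing_class_errors(self):
        t1 = make_tree("P1", [("A", None, ["NOTCH1"], {0: 1.0})])
        with pytest.raises(ValueError, match="del_in_9p"):
            tj.weighted_nested_level([t1], "event_class", labels={"del_in_9p"})
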