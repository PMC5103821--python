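"""Gold-standard and weighted-Bcubed tests, with an independent plain
extended-Bcubed oracle for the uniform-weight reduction."""

import numpy as np
import pytest

from prox3c.validate import (AlignmentRecord, GoldStandard,
                             build_gold_standard, multiplicity_pr,
                             weighted_bcubed)


def reference_extended_bcubed(memb: dict, classes: dict) -> tuple[float, float, float]:
    """Independently coded unweighted extended Bcubed (naive pair loops)."""
    objs = sorted(memb)
    p_vals, r_vals = [], []
    for oi in objs:
        d = [oj for oj in objs if memb[oi] & memb[oj]]
        h = [oj for oj in objs if classes[oi] & classes[oj]]
        p_vals.append(np.mean([min(len(memb[oi] & memb[oj]), len(classes[oi] & classes[oj]))
                               / len(memb[oi] & memb[oj]) for oj in d]))
        r_vals.append(np.mean([min(len(memb[oi] & memb[oj]), len(classes[oi] & classes[oj]))
                               / len(classes[oi] & classes[oj]) for oj in h]))
    p, r = float(np.mean(p_vals)), float(np.mean(r_vals))
    return p, r, 2 * p * r / (p + r)


def random_overlapping_instance(rng, n_obj=20):
    objs = [f"o{i}" for i in range(n_obj)]
    n_k = int(rng.integers(2, 6))
    n_t = int(rng.integers(2, 6))
    memb = {o: set(rng.choice(n_k, size=rng.integers(1, 3), replace=False).tolist())
            for o in objs}
    classes = {o: frozenset(rng.choice(n_t, size=rng.integers(1, 3), replace=False).tolist())
               for o in objs}
    return memb, classes


class TestGoldStandard:
    def test_mu_boundary_is_strict(self):
        """96 bp at identity 1.0 over a 100 bp contig: mu = 0.96 exactly -> rejected."""
        gs = build_gold_standard([AlignmentRecord("c1", "g1", 0, 96, 1.0, 50.0)],
                                 {"c1": 100})
        assert "c1" not in gs.classes and gs.rejected == ["c1"]

    def test_just_above_threshold_accepted(self):
        gs = build_gold_standard([AlignmentRecord("c1", "g1", 0, 97, 1.0, 50.0)],
                                 {"c1": 100})
        assert gs.classes["c1"] == frozenset({"g1"})

    def test_one_to_many_association(self):
        als = [AlignmentRecord("c1", "g1", 0, 100, 0.97, 60.0),
               AlignmentRecord("c1", "g2", 0, 100, 0.97, 55.0)]
        gs = build_gold_standard(als, {"c1": 100})
        assert gs.classes["c1"] == frozenset({"g1", "g2"})

    def test_descending_bitscore_occupancy_first_writer_wins(self):
        """Overlapping alignments to one genome: the higher-bitscore identity
        (0.9) occupies the shared cells; the later 1.0 cannot overwrite."""
        als = [AlignmentRecord("c1", "g1", 0, 100, 0.9, 200.0),
               AlignmentRecord("c1", "g1", 0, 100, 1.0, 100.0)]
        gs = build_gold_standard(als, {"c1": 100}, mu_threshold=0.89)
        assert gs.classes["c1"] == frozenset({"g1"})
        gs2 = build_gold_standard(als, {"c1": 100}, mu_threshold=0.95)
        assert "c1" not in gs2.classes  # mean stays 0.9, not 1.0

    def test_partial_coverage_dilutes_identity(self):
        # 50 bp at 1.0 over a 100 bp contig -> mu = 0.5
        gs = build_gold_standard([AlignmentRecord("c1", "g1", 0, 50, 1.0, 10.0)],
                                 {"c1": 100}, mu_threshold=0.49)
        assert gs.classes["c1"] == frozenset({"g1"})

    def test_weights_are_contig_lengths(self):
        gs = build_gold_standard([AlignmentRecord("c1", "g1", 0, 200, 1.0, 10.0)],
                                 {"c1": 200})
        assert gs.weights == {"c1": 200.0}


class TestMultiplicityPR:
    def test_more_shared_clusters_than_classes(self):
        p, r = multiplicity_pr("a", "b", {"a": {1, 2}, "b": {1, 2}},
                               {"a": {9}, "b": {9}})
        assert (p, r) == (0.5, 1.0)

    def test_identity_pair(self):
        assert multiplicity_pr("a", "a", {"a": {1}}, {"a": {9}}) == (1.0, 1.0)

    def test_more_shared_classes_than_clusters(self):
        p, r = multiplicity_pr("a", "b", {"a": {1}, "b": {1}},
                               {"a": {7, 8, 9}, "b": {7, 8, 9}})
        assert p == 1.0 and r == pytest.approx(1 / 3)

    def test_no_shared_cluster_is_caller_error(self):
        with pytest.raises(ValueError):
            multiplicity_pr("a", "b", {"a": {1}, "b": {2}}, {"a": {9}, "b": {9}})


class TestWeightedBcubed:
    def test_perfect_reconstruction(self):
        gold = GoldStandard({"a": frozenset("x"), "b": frozenset("x"),
                             "c": frozenset("y")}, {"a": 2.0, "b": 1.0, "c": 5.0})
        s = weighted_bcubed([{"a", "b"}, {"c"}], gold)
        assert (s.precision, s.recall, s.f) == (1.0, 1.0, 1.0)

    def test_split_class_uniform_weights(self):
        gold = GoldStandard({"o1": frozenset("g"), "o2": frozenset("g")},
                            {"o1": 1.0, "o2": 1.0})
        s = weighted_bcubed([{"o1"}, {"o2"}], gold)
        assert s.precision == pytest.approx(1.0, abs=1e-12)
        assert s.recall == pytest.approx(0.5, abs=1e-12)
        assert s.f == pytest.approx(2 / 3, abs=1e-12)

    def test_split_class_weighted_3_to_1(self):
        gold = GoldStandard({"o1": frozenset("g"), "o2": frozenset("g")},
                            {"o1": 3.0, "o2": 1.0})
        s = weighted_bcubed([{"o1"}, {"o2"}], gold)
        assert s.recall == pytest.approx(0.625, abs=1e-12)
        assert s.f == pytest.approx(10 / 13, abs=1e-12)

    def test_uniform_weights_reduce_to_extended_bcubed(self):
        """Agreement with the independent oracle on 50 random overlapping instances."""
        rng = np.random.default_rng(20240917)
        for _ in range(50):
            memb, classes = random_overlapping_instance(rng)
            gold = GoldStandard(dict(classes), {o: 1.0 for o in classes})
            s = weighted_bcubed(memb, gold)
            p, r, f = reference_extended_bcubed(memb, classes)
            assert s.precision == pytest.approx(p, abs=1e-12)
            assert s.recall == pytest.approx(r, abs=1e-12)
            assert s.f == pytest.approx(f, abs=1e-12)

    def test_invariant_under_label_permutation_and_weight_rescaling(self):
        rng = np.random.default_rng(5)
        memb, classes = random_overlapping_instance(rng)
        w = {o: float(rng.integers(1, 10)) for o in classes}
        gold = GoldStandard(dict(classes), w)
        s1 = weighted_bcubed(memb, gold)
        relabeled = {o: {k + 100 for k in ks} for o, ks in memb.items()}
        gold_scaled = GoldStandard(dict(classes), {o: 7.5 * x for o, x in w.items()})
        s2 = weighted_bcubed(relabeled, gold_scaled)
        assert s1.f == pytest.approx(s2.f, abs=1e-12)

    def test_merging_pure_clusters_never_raises_precision(self):
        gold = GoldStandard({o: frozenset("x" if o < "c" else "y") for o in "abcd"},
                            {o: 1.0 for o in "abcd"})
        split = weighted_bcubed([{"a", "b"}, {"c", "d"}], gold)
        merged = weighted_bcubed([{"a", "b", "c", "d"}], gold)
        assert merged.precision <= split.precision

    def test_splitting_a_class_never_raises_recall(self):
        gold = GoldStandard({o: frozenset("x") for o in "abcd"},
                            {o: 1.0 for o in "abcd"})
        whole = weighted_bcubed([{"a", "b", "c", "d"}], gold)
        split = weighted_bcubed([{"a", "b"}, {"c", "d"}], gold)
        assert split.recall <= whole.recall

    def test_unclustered_gold_objects_scored_as_singletons(self):
        gold = GoldStandard({"a": frozenset("x"), "b": frozenset("x")},
                            {"a": 1.0, "b": 1.0})
        s = weighted_bcubed([{"a"}], gold)
        assert s.n_unclustered == 1
        assert s.recall == pytest.approx(0.5)

    def test_objects_outside_gold_are_dropped_and_counted(self):
        gold = GoldStandard({"a": frozenset("x")}, {"a": 1.0})
        s = weighted_bcubed([{"a", "ghost"}], gold)
        assert s.n_dropped == 1 and s.f == 1.0

    def test_empty_universe_raises(self):
        gold = GoldStandard({}, {})
        with pytest.raises(ValueError):
            weighted_bcubed([], gold)
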