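"""Referrer quality, reliability score, threshold selection and RRPM decisions."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refpharm as rp


def graph_of(edges, **kw):
    return rp.ReferralGraph.from_edges(edges, **kw)


def labels_of(rogue=(), safe=()):
    d = {p: rp.ILLICIT for p in rogue}
    d.update({p: rp.LEGITIMATE for p in safe})
    return rp.LabelSet(d)


class TestReferrerQuality:
    def test_pure_illicit_referrer_scores_minus_one(self):
        g = graph_of([("i1", "j", 4), ("i2", "j", 1)])
        q = rp.fit_referrer_quality(g, labels_of(rogue=["i1", "i2"]))
        assert q["j"] == -1.0

    def test_pure_legitimate_referrer_scores_plus_one(self):
        g = graph_of([(f"s{n}", "j", 1) for n in range(4)])
        q = rp.fit_referrer_quality(g, labels_of(safe=[f"s{n}" for n in range(4)]))
        assert q["j"] == 1.0

    def test_mixed_referrer(self):
        g = graph_of([("s1", "j", 9), ("s2", "j", 1), ("s3", "j", 1), ("i1", "j", 1)])
        q = rp.fit_referrer_quality(g, labels_of(rogue=["i1"], safe=["s1", "s2", "s3"]))
        assert q["j"] == pytest.approx((3 - 1) / 4)

    def test_multiplicity_does_not_affect_quality(self):
        g1 = graph_of([("s1", "j", 1), ("i1", "j", 1)])
        g2 = graph_of([("s1", "j", 100), ("i1", "j", 1)])
        lab = labels_of(rogue=["i1"], safe=["s1"])
        assert rp.fit_referrer_quality(g1, lab).quality == rp.fit_referrer_quality(g2, lab).quality

    def test_referrer_to_unlabeled_only_is_omitted(self):
        g = graph_of([("s1", "j1", 1), ("u1", "j2", 5)])
        q = rp.fit_referrer_quality(g, labels_of(safe=["s1"]))
        assert "j2" not in q

    def test_no_training_signal_raises(self):
        g = graph_of([("u1", "j", 1)])
        with pytest.raises(rp.FitError, match="empty training signal"):
            rp.fit_referrer_quality(g, labels_of(rogue=["i1"]))

    def test_support_counts_are_consistent(self):
        g = graph_of([("s1", "j", 2), ("s2", "j", 3), ("i1", "j", 7)])
        q = rp.fit_referrer_quality(g, labels_of(rogue=["i1"], safe=["s1", "s2"]))
        s = q.support["j"]
        assert (s.n_safe, s.n_rogue, s.n_total) == (2, 1, 3)


class TestReliabilityScore:
    def test_constant_quality_one(self):
        g = graph_of([("x", "j1", 3), ("x", "j2", 5), ("s", "j1", 1), ("s", "j2", 1)])
        q = rp.fit_referrer_quality(g, labels_of(safe=["s"]))
        assert rp.reliability_score(g, "x", q).score == 1.0

    def test_symmetric_cancellation(self):
        g = graph_of([("x", "j1", 2), ("x", "j2", 2),
                      ("s", "j1", 1), ("i", "j2", 1)])
        q = rp.fit_referrer_quality(g, labels_of(rogue=["i"], safe=["s"]))
        assert rp.reliability_score(g, "x", q).score == 0.0

    def test_weighted_average(self):
        # qualities: j1 -> 0.5 (3 safe, 1 rogue), j2 -> -1
        edges = [(f"s{n}", "j1", 1) for n in range(3)] + [("i0", "j1", 1), ("i1", "j2", 1)]
        edges += [("x", "j1", 3), ("x", "j2", 1)]
        g = graph_of(edges)
        q = rp.fit_referrer_quality(
            g, labels_of(rogue=["i0", "i1"], safe=["s0", "s1", "s2"]))
        res = rp.reliability_score(g, "x", q)
        assert res.score == pytest.approx((3 * 0.5 - 1) / 4)
        assert res.total_links == 4

    def test_unseen_referrers_give_indeterminate_zero(self):
        g = graph_of([("x", "jNEW", 5), ("s", "j1", 1)])
        q = rp.fit_referrer_quality(g, labels_of(safe=["s"]))
        res = rp.reliability_score(g, "x", q)
        assert res.indeterminate and res.score == 0.0 and res.total_links == 0

    def test_no_edges_raises(self):
        g = graph_of([("s", "j1", 1)], pharmacies=["s", "empty"])
        q = rp.fit_referrer_quality(g, labels_of(safe=["s"]))
        with pytest.raises(rp.NoReferralDataError):
            rp.reliability_score(g, "empty", q)


class TestSelectThreshold:
    def test_conservative_is_max_illicit_score(self):
        scores = {"a": -0.8, "b": -0.2, "c": 0.1, "d": 0.6, "e": 0.9}
        lab = labels_of(rogue=["a", "b", "c"], safe=["d", "e"])
        assert rp.select_threshold(scores, lab, rp.CONSERVATIVE) == pytest.approx(0.1)

    def test_conservative_degenerate_all_minus_one(self):
        scores = {"a": -1.0, "b": -1.0}
        assert rp.select_threshold(scores, labels_of(rogue=["a", "b"]), rp.CONSERVATIVE) == -1.0

    def test_accuracy_max_reaches_perfect_separation(self):
        scores = {"a": -0.9, "b": -0.5, "c": 0.4, "d": 0.8}
        lab = labels_of(rogue=["a", "b"], safe=["c", "d"])
        t = rp.select_threshold(scores, lab, rp.ACCURACY_MAX)
        correct = sum(1 for p in ("a", "b") if scores[p] < t) + \
            sum(1 for p in ("c", "d") if scores[p] >= t)
        assert correct == 4
        assert -0.5 < t <= 0.4

    def test_accuracy_max_ties_break_toward_larger_t(self):
        # every cut between the two classes is perfect; the largest candidate wins
        scores = {"a": -1.0, "b": 0.0, "c": 1.0}
        lab = labels_of(rogue=["a"], safe=["b", "c"])
        t = rp.select_threshold(scores, lab, rp.ACCURACY_MAX)
        assert t == pytest.approx(0.0)  # b must stay legitimate (R >= T)

    def test_missing_class_raises(self):
        with pytest.raises(rp.FitError):
            rp.select_threshold({"a": 0.5}, labels_of(safe=["a"]), rp.CONSERVATIVE)
        with pytest.raises(rp.FitError):
            rp.select_threshold({"a": 0.5}, labels_of(rogue=["a"]), rp.ACCURACY_MAX)


class TestClassify:
    @pytest.fixture
    def fitted(self):
        edges = [("s0", "jg", 2), ("s1", "jg", 1), ("i0", "jb", 3), ("i1", "jb", 1),
                 ("i1", "jg", 1)]
        g = graph_of(edges, pharmacies=["s0", "s1", "i0", "i1", "noedges"])
        lab = labels_of(rogue=["i0", "i1"], safe=["s0", "s1"])
        return g, rp.fit_rrpm(g, lab, rp.CONSERVATIVE)

    def test_boundary_score_is_legitimate(self, fitted):
        g, model = fitted
        # i1 attains the threshold (it is the max-scoring illicit pharmacy)
        assert model.training_scores["i1"] == pytest.approx(model.threshold)
        assert rp.classify_rrpm(g, "i1", model).status == rp.LEGITIMATE

    def test_below_threshold_is_illicit(self, fitted):
        g, model = fitted
        assert rp.classify_rrpm(g, "i0", model).status == rp.ILLICIT

    def test_no_referral_data_is_unknown(self, fitted):
        g, model = fitted
        pred = rp.classify_rrpm(g, "noedges", model)
        assert pred.status == rp.UNKNOWN and pred.reliability.indeterminate

    def test_indeterminate_zero_below_positive_threshold_is_illicit(self):
        # jg has quality (2-1)/3 = 1/3, so the best illicit score (i2) is 1/3 > 0
        g = graph_of([("s0", "jg", 1), ("s1", "jg", 1), ("i2", "jg", 1),
                      ("i0", "jb", 2), ("x", "jNEW", 2)])
        lab = labels_of(rogue=["i0", "i2"], safe=["s0", "s1"])
        model = rp.fit_rrpm(g, lab, rp.CONSERVATIVE)
        assert model.threshold > 0
        pred = rp.classify_rrpm(g, "x", model)
        assert pred.reliability.indeterminate and pred.status == rp.ILLICIT


class TestProperties:
    def test_scores_bounded_on_random_graphs(self, random_labeled_graph):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g, lab = random_labeled_graph(rng)
            q = rp.fit_referrer_quality(g, lab)
            assert all(-1.0 <= m <= 1.0 for m in q.quality.values())
            for pid in g.pharmacies:
                if g.has_edges(pid):
                    assert abs(rp.reliability_score(g, pid, q).score) <= 1.0 + 1e-12

    def test_monotone_in_perfect_quality_backlinks(self):
        lab = labels_of(rogue=["i"], safe=["s"])
        base = [("s", "jg", 1), ("i", "jb", 1), ("x", "jg", 1), ("x", "jb", 2)]
        scores = []
        for extra in range(4):
            edges = base + ([("x", "jg", extra)] if extra else [])
            g = graph_of(edges)
            q = rp.fit_referrer_quality(g, lab)
            scores.append(rp.reliability_score(g, "x", q).score)
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_scale_invariance_of_quality_and_reliability(self, random_labeled_graph):
        rng = np.random.default_rng(5)
        g, lab = random_labeled_graph(rng)
        scaled = rp.ReferralGraph(
            g.pharmacies, g.referrers, {k: 7 * v for k, v in g.backlinks.items()})
        q1, q2 = rp.fit_referrer_quality(g, lab), rp.fit_referrer_quality(scaled, lab)
        assert q1.quality == q2.quality
        for pid in g.pharmacies:
            if g.has_edges(pid):
                assert rp.reliability_score(g, pid, q1).score == pytest.approx(
                    rp.reliability_score(scaled, pid, q2).score, abs=1e-12)

    def test_conservative_catches_all_strictly_subthreshold_illicit(self, random_labeled_graph):
        rng = np.random.default_rng(17)
        g, lab = random_labeled_graph(rng, n_pharm=40)
        model = rp.fit_rrpm(g, lab, rp.CONSERVATIVE)
        for pid in lab.rogue:
            score = model.training_scores.get(pid)
            if score is not None and score < model.threshold:
                assert rp.classify_rrpm(g, pid, model).status == rp.ILLICIT

    def test_sparse_score_equals_dense_double_loop(self, random_labeled_graph):
        """Independent oracle: dense brute force over all (i, j) pairs."""
        rng = np.random.default_rng(23)
        for _ in range(5):
            g, lab = random_labeled_graph(rng, n_pharm=50, n_ref=15)
            q = rp.fit_referrer_quality(g, lab)
            dense = np.zeros((len(g.pharmacies), len(g.referrers)))
            p_idx = {p: a for a, p in enumerate(g.pharmacies)}
            r_idx = {r: a for a, r in enumerate(g.referrers)}
            for (i, j), c in g.backlinks.items():
                dense[p_idx[i], r_idx[j]] = c
            for pid in g.pharmacies:
                if not g.has_edges(pid):
                    continue
                num = den = 0.0
                for j in g.referrers:
                    if j in q:
                        num += dense[p_idx[pid], r_idx[j]] * q[j]
                        den += dense[p_idx[pid], r_idx[j]]
                expected = num / den if den else 0.0
                assert rp.reliability_score(g, pid, q).score == pytest.approx(expected, abs=1e-12)


def test_model_round_trip(tmp_path, random_labeled_graph):
    g, lab = random_labeled_graph(np.random.default_rng(3))
    model = rp.fit_rrpm(g, lab, rp.ACCURACY_MAX)
    path = tmp_path / "model.json"
    rp.save_rrpm(model, path)
    loaded = rp.load_rrpm(path)
    assert loaded.threshold == model.threshold
    assert loaded.qualities.quality == model.qualities.quality
    assert loaded.training_scores == model.training_scores
    assert loaded.strategy == model.strategy
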