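import math

import numpy as np
import pandas as pd
import pytest

import strokepanel as sp
from strokepanel.ghmm import GaussianHMMSpec
from strokepanel.panelsearch import _confusion

from conftest import make_null_problem, make_panel_problem


class TestComputeMetrics:
    def test_perfect_validation_confusion(self):
        m = sp.compute_metrics(tp=51, tn=24, fp=0, fn=0)
        assert m.accuracy == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.youden_j == 1.0

    def test_high_sensitivity_with_three_false_positives(self):
        m = sp.compute_metrics(tp=6, fn=0, fp=3, tn=72)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.96
        assert np.isclose(m.accuracy, 78 / 81)

    def test_no_positives_flags_sensitivity_undefined(self):
        m = sp.compute_metrics(tp=0, fn=0, fp=0, tn=104)
        assert m.accuracy == 1.0 and m.specificity == 1.0
        assert m.sensitivity is None
        assert m.youden_j is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_metrics(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_metrics(-1, 0, 0, 5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert sp.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_concordant_pairs(self):
        # pos {3, 1}, neg {2, 0}: 3 of 4 pairs concordant
        assert sp.roc_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_ties_contribute_half(self):
        assert sp.roc_auc([1.0, 1.0], [1, 0]) == 0.5

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(41)
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        assert abs(sp.roc_auc(scores, labels) - 0.5) < 0.05

    def test_single_class_undefined(self):
        assert sp.roc_auc([0.1, 0.2], [1, 1]) is None

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        scores = rng.random(200)
        scores[::7] = scores[::3][: len(scores[::7])]  # inject ties
        labels = rng.integers(0, 2, 200)
        assert np.isclose(sp.roc_auc(scores, labels), roc_auc_score(labels, scores))


class TestOptimizeThreshold:
    def test_complete_separation_midpoint(self):
        thr, j = sp.optimize_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert thr == 0.5 and j == 1.0

    def test_identical_distributions_zero_j_smallest_midpoint(self):
        thr, j = sp.optimize_threshold([0.3, 0.7, 0.3, 0.7], [1, 1, 0, 0])
        assert np.isclose(j, 0.0)
        assert np.isclose(thr, 0.5)  # only midpoint of {0.3, 0.7}

    def test_hand_enumerated_overlap_case(self):
        thr, j = sp.optimize_threshold([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert np.isclose(thr, 0.25)
        assert np.isclose(j, 0.5)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            sp.optimize_threshold([0.4, 0.6], [1, 1])

    def test_agrees_with_brute_force_over_cutpoints(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr, j = sp.optimize_threshold(scores, labels)
            uniq = np.unique(scores)
            best = -np.inf
            if uniq.size >= 2:
                for cand in (uniq[:-1] + uniq[1:]) / 2:
                    tp, fp, fn, tn = _confusion(scores, labels, cand)
                    best = max(best, tp / (tp + fn) + tn / (tn + fp) - 1)
                assert np.isclose(j, best, atol=1e-12)


class TestEnumeration:
    def test_binomial_sums_for_eight_candidates(self):
        ids = [f"t{i}" for i in range(8)]
        assert len(sp.enumerate_panels(ids, 3, 5)) == 182  # 56 + 70 + 56

    def test_single_size_count(self):
        ids = [f"t{i}" for i in range(25)]
        assert len(sp.enumerate_panels(ids, 4, 4)) == 12650

    def test_exactly_minimum_candidates(self):
        assert sp.enumerate_panels(["a", "b", "c"], 3, 5) == [("a", "b", "c")]

    def test_closed_form_property(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            n = int(rng.integers(3, 13))
            ids = [f"t{i}" for i in range(n)]
            panels = sp.enumerate_panels(ids, 3, 5)
            expected = sum(math.comb(n, s) for s in range(3, min(5, n) + 1))
            assert len(panels) == expected
            assert len(set(panels)) == len(panels)

    def test_lexicographic_order(self):
        panels = sp.enumerate_panels(["c", "a", "b", "d"], 3, 3)
        assert panels == sorted(panels)

    def test_cap_refuses(self):
        ids = [f"t{i}" for i in range(40)]
        with pytest.raises(ValueError, match="cap"):
            sp.enumerate_panels(ids, 3, 5, cap=1000)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            sp.enumerate_panels(["a", "b"], 3, 5)


@pytest.fixture(scope="module")
def planted():
    return make_panel_problem(seed=101)


class TestScreenSingle:
    def test_planted_separating_transcripts_pass(self, planted):
        screen = sp.screen_single(
            planted["train"], planted["labels_train"],
            list(planted["train"].index), seed=0,
        )
        assert planted["planted"] <= set(screen.passing_ids)

    def test_label_independent_transcripts_do_not_pass(self):
        prob = make_null_problem(seed=55)
        screen = sp.screen_single(
            prob["train"], prob["labels_train"], list(prob["train"].index), seed=0
        )
        prevalence = max(
            prob["labels_train"].mean(), 1 - prob["labels_train"].mean()
        )
        assert len(screen.passing_ids) == 0
        assert (screen.table["accuracy"] <= prevalence + 0.25).all()

    def test_empty_candidate_list(self, planted):
        screen = sp.screen_single(
            planted["train"], planted["labels_train"], [], seed=0
        )
        assert len(screen.table) == 0

    def test_constant_transcript_flagged_degenerate(self, planted):
        train = planted["train"].copy()
        train.loc["FLAT"] = 1.0
        screen = sp.screen_single(
            train, planted["labels_train"], ["FLAT"], seed=0
        )
        assert bool(screen.table.loc["FLAT", "degenerate"])
        assert not bool(screen.table.loc["FLAT", "passed"])


class TestEvaluatePanel:
    def test_planted_panel_perfect_on_both_cohorts(self, planted):
        panel = tuple(sorted(planted["planted"]))
        ev = sp.evaluate_panel(
            panel, planted["train"], planted["valid"],
            planted["labels_train"], planted["labels_valid"], seed=0,
        )
        assert ev.metrics_train.accuracy == 1.0
        assert ev.metrics_valid.accuracy == 1.0
        assert 0.0 < ev.threshold < 1.0

    def test_noise_panel_low_validation_youden(self):
        js = []
        for seed in range(5):
            prob = make_null_problem(seed=200 + seed)
            panel = tuple(sorted(prob["train"].index[:3]))
            ev = sp.evaluate_panel(
                panel, prob["train"], prob["valid"],
                prob["labels_train"], prob["labels_valid"], seed=seed,
            )
            js.append(abs(ev.youden_j))
        assert np.median(js) < 0.3

    def test_same_seed_identical_evaluation(self, planted):
        panel = tuple(sorted(planted["planted"]))
        a = sp.evaluate_panel(
            panel, planted["train"], planted["valid"],
            planted["labels_train"], planted["labels_valid"], seed=3,
        )
        b = sp.evaluate_panel(
            panel, planted["train"], planted["valid"],
            planted["labels_train"], planted["labels_valid"], seed=3,
        )
        assert a.threshold == b.threshold
        assert np.array_equal(a.fit.means, b.fit.means)
        assert a.metrics_valid == b.metrics_valid

    def test_validation_perturbation_leaves_fit_frozen(self, planted):
        """No leakage: validation data never influence the fitted model,
        the state mapping, or the threshold."""
        panel = tuple(sorted(planted["planted"]))
        args = (planted["train"],)
        a = sp.evaluate_panel(
            panel, planted["train"], planted["valid"],
            planted["labels_train"], planted["labels_valid"], seed=5,
        )
        perturbed = planted["valid"] + np.random.default_rng(0).normal(
            0, 5, size=planted["valid"].shape
        )
        b = sp.evaluate_panel(
            panel, planted["train"], perturbed,
            planted["labels_train"], planted["labels_valid"], seed=5,
        )
        assert np.array_equal(a.fit.means, b.fit.means)
        assert np.array_equal(a.fit.variances, b.fit.variances)
        assert np.array_equal(a.fit.startprob, b.fit.startprob)
        assert a.threshold == b.threshold
        assert a.state_to_class == b.state_to_class
        assert a.metrics_train == b.metrics_train

    def test_missing_transcript_named(self, planted):
        with pytest.raises(KeyError, match="NOPE"):
            sp.evaluate_panel(
                ("NOPE", "x", "y"), planted["train"], planted["valid"],
                planted["labels_train"], planted["labels_valid"],
            )


def _fake_eval(transcripts, acc_train, acc_valid, gap):
    from strokepanel.ghmm import GaussianHMMFit, GaussianHMMSpec
    from strokepanel.panelsearch import PanelEvaluation

    spec = GaussianHMMSpec(2, len(transcripts))
    fit = GaussianHMMFit(
        spec=spec, startprob=np.array([0.5, 0.5]), transmat=np.full((2, 2), 0.5),
        means=np.zeros((2, len(transcripts))), variances=np.ones((2, len(transcripts))),
        log_likelihood=0.0, bic=0.0, n_obs=10, converged=True, n_iter=1, seed=0,
    )
    m_tr = sp.compute_metrics(5, int(round(10 * (1 - acc_train))), 0, 5)
    m_va = sp.compute_metrics(5, int(round(10 * (1 - acc_valid))), 0, 5)
    return PanelEvaluation(
        transcripts=tuple(transcripts), fit=fit, state_to_class=(0, 1),
        threshold=0.5, threshold_gap=gap, metrics_train=m_tr, metrics_valid=m_va,
        youden_j=m_va.youden_j,
    )


class TestSelectRepresentative:
    def test_single_candidate_returned(self):
        ev = _fake_eval(("a", "b", "c"), 1.0, 1.0, 0.4)
        assert sp.select_representative([ev]) is ev

    def test_wider_training_gap_preferred(self):
        narrow = _fake_eval(("a", "b", "c"), 1.0, 1.0, 0.3)
        wide = _fake_eval(("d", "e", "f"), 1.0, 1.0, 0.6)
        assert sp.select_representative([narrow, wide]) is wide

    def test_accuracy_dominates_gap(self):
        accurate = _fake_eval(("a", "b", "c"), 1.0, 1.0, 0.1)
        sloppy = _fake_eval(("d", "e", "f"), 1.0, 0.8, 0.9)
        assert sp.select_representative([accurate, sloppy]) is accurate

    def test_smaller_panel_preferred_on_ties(self):
        small = _fake_eval(("a", "b", "c"), 1.0, 1.0, 0.5)
        large = _fake_eval(("a", "b", "c", "d"), 1.0, 1.0, 0.5)
        assert sp.select_representative([large, small]) is small

    def test_fewer_mstrg_preferred_on_ties(self):
        annotated = _fake_eval(("ENST1", "ENST2", "ENST3"), 1.0, 1.0, 0.5)
        novel = _fake_eval(("MSTRG.1", "MSTRG.2", "ENST9"), 1.0, 1.0, 0.5)
        assert sp.select_representative([novel, annotated]) is annotated

    def test_full_tie_lexicographic(self):
        a = _fake_eval(("ENST1", "ENST2", "ENST3"), 1.0, 1.0, 0.5)
        b = _fake_eval(("ENST1", "ENST2", "ENST4"), 1.0, 1.0, 0.5)
        assert sp.select_representative([b, a]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.select_representative([])


def test_search_panels_recovers_planted_signature(planted):
    screen, evals, rep = sp.search_panels(
        planted["train"], planted["valid"],
        planted["labels_train"], planted["labels_valid"],
        list(planted["train"].index), seed=0,
    )
    assert set(rep.transcripts) <= set(screen.passing_ids)
    assert rep.metrics_valid.accuracy == 1.0
    assert planted["planted"] <= set(screen.passing_ids)
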