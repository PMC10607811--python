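"""AUC ranking machinery and top-k panel protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_curve

from psametab.core import FeatureTable
from psametab.select import (
    DEFAULT_K_GRID,
    PAIRS,
    ClassPair,
    ModelResult,
    auc_mann_whitney,
    build_topk_models,
    per_feature_auc,
    stratified_kfold,
    top_models_report,
)

from conftest import toy_table


def trapezoid_auc(scores, labels):
    """Independent oracle: trapezoidal area under the empirical ROC."""
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr))


def pair_counting_auc(scores, labels):
    """Second oracle: exhaustive concordant/tied pair enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def two_group_table(values, n_neg, n_pos, neg="low", pos="high"):
    """Study-only FeatureTable with a two-group design."""
    groups = [neg] * n_neg + [pos] * n_pos
    return toy_table(values, ["study"] * (n_neg + n_pos), groups=groups)


class TestAucMannWhitney:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),      # perfect separation
        ([5, 5, 5, 5], [0, 0, 1, 1], 0.5),      # all pairs tied
        ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),     # pairs: (1,2)+ (1,4)+ (3,2)- (3,4)+
        ([1, 2, 3, 4], [1, 1, 0, 0], 0.0),
    ])
    def test_known_values(self, scores, labels, expected):
        assert auc_mann_whitney(scores, labels) == pytest.approx(expected)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_mann_whitney([1.0, 2.0], [1, 1])

    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_antisymmetry(self, data):
        n = data.draw(st.integers(4, 12))
        scores = data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n))
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney([-s for s in scores], labels)
        assert a + b == pytest.approx(1.0)

    def test_matches_both_oracles_on_small_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            n_pos = int(rng.integers(1, n))
            labels = np.zeros(n, bool)
            labels[rng.choice(n, n_pos, replace=False)] = True
            # discretized scores so ties actually occur
            scores = rng.integers(0, 4, n).astype(float)
            got = auc_mann_whitney(scores, labels)
            assert got == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(trapezoid_auc(scores, labels), abs=1e-9)


class TestStratifiedKfold:
    def test_balanced_folds(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(labels, 10, seed=3)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 10
            assert labels[mask].sum() == 5

    def test_partition(self):
        labels = np.array([0] * 23 + [1] * 31)
        folds = stratified_kfold(labels, 10, seed=1)
        assert folds.min() == 0 and folds.max() == 9
        assert len(folds) == 54

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        assert np.array_equal(stratified_kfold(labels, 10, seed=5),
                              stratified_kfold(labels, 10, seed=5))

    def test_small_class_advises_fewer_folds(self):
        with pytest.raises(ValueError, match="fewer folds"):
            stratified_kfold([0] * 30 + [1] * 5, 10, seed=0)


class TestClassPair:
    def test_distinct_groups_required(self):
        with pytest.raises(ValueError):
            ClassPair("low", "low")

    def test_canonical_pairs(self):
        assert set(PAIRS) == {"low_vs_high", "moderate_vs_high", "low_vs_moderate"}
        for pair in PAIRS.values():
            assert pair.positive in (pair.negative, pair.positive)


@pytest.fixture(scope="module")
def planted_table():
    """30 log-scale features, feature 0 planted with a strong shift.

    Values mimic glog/pareto-conditioned intensities (ranking runs on the
    transformed table in the pipeline).
    """
    rng = np.random.default_rng(99)
    n_neg = n_pos = 25
    values = rng.normal(10.0, 0.5, size=(30, n_neg + n_pos))
    values[0, n_neg:] += 2.0
    values[7] = 10.0  # constant feature
    return two_group_table(values, n_neg, n_pos)


@pytest.fixture(scope="module")
def ranked_planted(planted_table):
    return per_feature_auc(planted_table, PAIRS["low_vs_high"], seed=1, rf_trees=10)


class TestPerFeatureAuc:
    def test_planted_feature_ranks_first_with_high_auc(self, ranked_planted):
        ranked = ranked_planted
        assert ranked[0].feature_id == "F0001"
        assert ranked[0].best_auc > 0.9

    def test_constant_feature_scored_half(self, ranked_planted):
        by_id = {r.feature_id: r for r in ranked_planted}
        assert all(v == 0.5 for v in by_id["F0008"].auc_by_classifier.values())
        assert by_id["F0008"].best_auc == 0.5

    def test_best_is_max_and_ranks_are_permutation(self, ranked_planted):
        ranked = ranked_planted
        for r in ranked:
            assert r.best_auc == pytest.approx(max(r.auc_by_classifier.values()))
        assert sorted(r.rank for r in ranked) == list(range(1, len(ranked) + 1))

    def test_null_features_stay_in_recomputed_envelope(self):
        """Distribution check: pure-noise best AUCs at n=50/50.

        Envelope recomputed empirically (max over five classifiers of a
        cross-validated null AUC, no orientation flipping, so values below
        0.5 occur).
        """
        rng = np.random.default_rng(5)
        values = rng.normal(10, 1, size=(40, 100))
        table = two_group_table(values, 50, 50)
        ranked = per_feature_auc(table, PAIRS["low_vs_high"], seed=2, rf_trees=10)
        best = np.array([r.best_auc for r in ranked])
        assert best.min() > 0.25 and best.max() < 0.78
        assert 0.45 < np.median(best) < 0.62

    def test_deterministic_for_fixed_seed(self, planted_table):
        a = per_feature_auc(planted_table, PAIRS["low_vs_high"],
                            classifiers=("LDA", "NaiveBayes", "SVM", "LogReg"), seed=4)
        b = per_feature_auc(planted_table, PAIRS["low_vs_high"],
                            classifiers=("LDA", "NaiveBayes", "SVM", "LogReg"), seed=4)
        for x, y in zip(a, b):
            assert x.feature_id == y.feature_id
            for k in x.auc_by_classifier:
                assert x.auc_by_classifier[k] == pytest.approx(y.auc_by_classifier[k], abs=1e-12)


@pytest.fixture(scope="module")
def ranked_models(planted_table, ranked_planted):
    pair = PAIRS["low_vs_high"]
    models = build_topk_models(planted_table, pair, ranked_planted,
                               k_grid=(1, 2, 5, 10, 20), seed=1, rf_trees=10)
    return ranked_planted, models


class TestBuildTopkModels:

    def test_grid_times_classifiers(self, ranked_models):
        _, models = ranked_models
        assert len(models) == 5 * 5
        assert DEFAULT_K_GRID == (1, 2, 5, 10, 20, 40, 80)

    def test_k1_uses_rank_one_feature(self, ranked_models):
        ranked, models = ranked_models
        for m in models:
            if m.k == 1:
                assert m.feature_ids == [ranked[0].feature_id]
            assert len(m.feature_ids) == m.k

    def test_gate_boundary_semantics(self, planted_table, ranked_models):
        """cv_auc exactly at the gate passes; just above it fails."""
        ranked, models = ranked_models
        pair = PAIRS["low_vs_high"]
        probe = models[0]
        at_gate = build_topk_models(planted_table, pair, ranked, k_grid=(probe.k,),
                                    classifiers=(probe.classifier,), seed=1,
                                    rf_trees=10, gate=probe.cv_auc)
        above = build_topk_models(planted_table, pair, ranked, k_grid=(probe.k,),
                                  classifiers=(probe.classifier,), seed=1,
                                  rf_trees=10, gate=probe.cv_auc + 1e-9)
        assert at_gate[0].passed_gate is True
        assert above[0].passed_gate is False
        for m in models:
            assert m.passed_gate == (m.cv_auc >= 0.7)

    def test_roc_endpoints_and_monotonicity(self, ranked_models):
        _, models = ranked_models
        for m in models:
            roc = np.array(m.roc)
            assert tuple(roc[-1]) == (1.0, 1.0)
            assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_oversized_k_skipped_with_warning(self, planted_table):
        pair = PAIRS["low_vs_high"]
        ranked = per_feature_auc(planted_table, pair, classifiers=("LDA",), seed=1)
        with pytest.warns(UserWarning, match="skipped"):
            models = build_topk_models(planted_table, pair, ranked,
                                       k_grid=(1, 500), classifiers=("LDA",), seed=1)
        assert [m.k for m in models] == [1]

    def test_planted_panel_passes_gate(self, ranked_models):
        _, models = ranked_models
        assert any(m.passed_gate for m in models)

    def test_nested_protocol_runs_and_is_not_better_than_leaky(self, planted_table):
        pair = PAIRS["low_vs_high"]
        ranked = per_feature_auc(planted_table, pair, classifiers=("LDA",), seed=1)
        leaky = build_topk_models(planted_table, pair, ranked, k_grid=(5,),
                                  classifiers=("LDA",), seed=1)
        nested = build_topk_models(planted_table, pair, ranked, k_grid=(5,),
                                   classifiers=("LDA",), seed=1, nested=True)
        assert 0.0 <= nested[0].cv_auc <= 1.0
        # with one strong planted feature both should do well
        assert nested[0].cv_auc > 0.7


class TestTopModelsReport:
    def mk(self, auc, k, clf="LDA"):
        return ModelResult(classifier=clf, pair=PAIRS["low_vs_high"], k=k,
                           feature_ids=["F"] * k, cv_auc=auc,
                           roc=[(0.0, 0.0), (1.0, 1.0)], passed_gate=auc >= 0.7)

    def test_sorted_descending_and_truncated(self):
        results = [self.mk(0.6, 1), self.mk(0.9, 5), self.mk(0.75, 2)]
        top = top_models_report(results, n=10)
        assert [m.cv_auc for m in top] == [0.9, 0.75, 0.6]

    def test_tie_prefers_smaller_k_then_name(self):
        results = [self.mk(0.8, 20), self.mk(0.8, 5), self.mk(0.8, 5, clf="SVM")]
        top = top_models_report(results, n=2)
        assert (top[0].k, top[0].classifier) == (5, "LDA")
        assert (top[1].k, top[1].classifier) == (5, "SVM")

    def test_output_is_submultiset_of_input(self):
        rng = np.random.default_rng(1)
        results = [self.mk(float(a), int(k)) for a, k in
                   zip(rng.uniform(0.4, 1, 20), rng.integers(1, 80, 20))]
        top = top_models_report(results, n=10)
        in_aucs = sorted((m.cv_auc for m in results), reverse=True)
        assert [m.cv_auc for m in top] == in_aucs[:10]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_models_report([])


def test_planted_auc_nondecreasing_in_effect_size():
    """Mean best AUC of planted features grows with the planted effect size."""
    import psametab as pm
    from psametab.preprocess import glog_transform, pareto_scale

    manifest = pm.generate_manifest(20, 0, 20, qc_every=10, seed=51)
    lib = pm.generate_compound_library(80, seed=52)
    means = []
    for effect in (1.0, 1.5, 2.0, 4.0):
        table, truth = pm.generate_feature_table(
            manifest, lib, n_features=30, n_informative=10, effect_size=effect,
            drift_strength=0.0, noise_cv=0.5, seed=53,
        )
        scaled = pareto_scale(glog_transform(table))
        ranked = per_feature_auc(scaled, PAIRS["low_vs_high"],
                                 classifiers=("LDA", "NaiveBayes"), seed=54)
        by_id = {r.feature_id: r.best_auc for r in ranked}
        means.append(np.mean([by_id[f] for f in truth.informative_features]))
    assert all(b >= a for a, b in zip(means, means[1:])), means
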