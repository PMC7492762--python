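"""Signature score, zero-mean constant, ROC/Youden, evaluation splits."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flimlca.cohort import Cohort
from flimlca.signature import (SignatureModel, evaluate_signature,
                               fit_signature, predict_class, roc_youden, score)
from flimlca.synthetic import coin_os_spec, simulate_cohort


def _labelled_cohort(n=300, seed=0):
    """Cohort whose class label is a noisy linear function of 3 covariates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 3))
    w_true = np.array([1.0, -0.8, 0.5])
    labels = np.where(X @ w_true + rng.normal(0, 0.5, n) > 0, 2, 1)
    table = pd.DataFrame(X, columns=["a", "b", "c"])
    table["patient_id"] = [f"P{i}" for i in range(n)]
    table["time"] = rng.exponential(500, n) * np.where(labels == 1, 3.0, 1.0)
    table["event"] = 1
    table["trt"] = rng.integers(0, 2, n)
    return Cohort(table), labels, w_true


def test_training_scores_have_exactly_zero_mean():
    cohort, labels, _ = _labelled_cohort()
    model = fit_signature(cohort, labels, ["a", "b", "c"])
    s = score(model, cohort)
    assert abs(s.mean()) < 1e-10


def test_patient_at_training_means_scores_the_constant():
    cohort, labels, _ = _labelled_cohort()
    model = fit_signature(cohort, labels, ["a", "b", "c"])
    means = cohort.table[["a", "b", "c"]].mean()
    probe = cohort.table.iloc[:1].copy()
    probe[["a", "b", "c"]] = means.to_numpy()
    s = score(model, Cohort(probe))
    assert s[0] == pytest.approx(model.constant, abs=1e-10)


def test_recovered_weight_signs_match_planted_signs():
    hits = 0
    for seed in range(10):
        cohort, labels, w_true = _labelled_cohort(seed=seed)
        model = fit_signature(cohort, labels, ["a", "b", "c"])
        hits += (np.sign(model.weights) == np.sign(w_true)).all()
    assert hits >= 9


def test_threshold_rule_sides_of_minus_0335():
    """With threshold -0.335, a score of -0.2 is class 2 and -0.4 class 1."""
    table = pd.DataFrame({"patient_id": ["P0", "P1"], "time": [100.0, 100.0],
                          "event": [1, 1], "x": [1.0, 0.0]})
    cohort = Cohort(table)
    from flimlca.preprocess import build_design
    _, info = build_design(table, ["x"])     # binary covariate: no rescaling
    model = SignatureModel(covariate_names=["x"], design_names=info.names,
                           weights=np.array([0.2]), constant=-0.4,
                           threshold=-0.335, design_info=info)
    s = score(model, cohort)
    np.testing.assert_allclose(s, [-0.2, -0.4])
    np.testing.assert_array_equal(predict_class(model, cohort), [2, 1])


def test_single_class_labels_rejected():
    cohort, labels, _ = _labelled_cohort(n=40)
    with pytest.raises(ValueError, match="two classes"):
        fit_signature(cohort, np.ones_like(labels), ["a", "b", "c"])


def test_unknown_covariate_errors_with_names():
    cohort, labels, _ = _labelled_cohort(n=40)
    model = fit_signature(cohort, labels, ["a", "b", "c"])
    bad = cohort.table.drop(columns=["b"])
    with pytest.raises(ValueError, match="b"):
        score(model, Cohort(bad))


def test_model_json_roundtrip_is_exact():
    cohort, labels, _ = _labelled_cohort(n=60)
    model = fit_signature(cohort, labels, ["a", "b", "c"])
    model.threshold = -0.1
    clone = SignatureModel.from_json(model.to_json())
    np.testing.assert_array_equal(clone.weights, model.weights)
    assert clone.constant == model.constant
    assert clone.threshold == model.threshold
    np.testing.assert_array_equal(score(clone, cohort), score(model, cohort))
    assert clone.to_json() == model.to_json()


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)
        assert r.youden_sensitivity + r.youden_specificity - 1 == pytest.approx(1.0)

    def test_independent_scores_auc_near_half(self):
        rng = np.random.default_rng(3)
        s = rng.normal(0, 1, 10_000)
        y = rng.random(10_000) < 0.3
        r = roc_youden(s, y)
        assert r.auc == pytest.approx(0.5, abs=0.02)

    def test_constant_scores_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            r = roc_youden(np.ones(20), np.arange(20) % 2)
        assert r.auc == 0.5
        assert r.degenerate

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(8)
        s = rng.normal(0, 1, 500)
        y = rng.random(500) < 1 / (1 + np.exp(-s))
        r = roc_youden(s, y)
        assert r.auc == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_youden_threshold_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        s = np.round(rng.normal(0, 1, n), 1)      # coarse grid forces ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            return
        r = roc_youden(s, y)
        best_j, best_t = -np.inf, None
        for t in np.concatenate([[s.min() - 1], np.unique(s)]):
            pred = s > t
            sens = (pred & y).sum() / y.sum()
            spec = (~pred & ~y).sum() / (~y).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        assert r.youden_threshold == best_t

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(0, 1, 60)
        y = rng.random(60) < 0.4
        if y.all() or not y.any():
            return
        r0 = roc_youden(s, y)
        r1 = roc_youden(np.exp(2 * s) + 5, y)
        assert r1.auc == pytest.approx(r0.auc, abs=1e-12)

    def test_roc_curve_monotone_along_threshold(self):
        rng = np.random.default_rng(5)
        r = roc_youden(rng.normal(0, 1, 200), rng.random(200) < 0.4)
        assert (np.diff(r.sensitivity) <= 1e-12).all()
        assert (np.diff(r.specificity) >= -1e-12).all()
        assert 0.0 <= r.auc <= 1.0


class TestEvaluate:
    def test_prognostic_split_detected_with_planted_signal(self):
        cohort, labels, _ = _labelled_cohort(n=400, seed=2)
        model = fit_signature(cohort, labels, ["a", "b", "c"])
        r = roc_youden(score(model, cohort), labels == 2)
        model.threshold = r.youden_threshold
        report = evaluate_signature(model, cohort, arm_col=None)
        assert report["prognostic"]["p"] < 0.05

    def test_single_arm_predictive_split_skipped(self):
        cohort, labels, _ = _labelled_cohort(n=200, seed=4)
        cohort.table["trt"] = 0.0
        model = fit_signature(cohort, labels, ["a", "b", "c"])
        model.threshold = float(np.median(score(model, cohort)))
        with pytest.warns(RuntimeWarning, match="single treatment arm"):
            report = evaluate_signature(model, cohort, arm_col="trt")
        assert "prognostic" in report
        assert report["predictive"] == {}
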