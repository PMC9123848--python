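import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import auc_pair_count
from rnsfc.classify import (
    bootstrap_auc_ci,
    confusion_metrics,
    evaluate_model,
    fit_logistic,
    loocv,
    optimal_threshold,
    precision_recall,
    roc_and_auc,
)
from rnsfc.outcomes import percent_reduction, responder_label


# ---------------------------------------------------------------------------
# outcome arithmetic

def test_seven_to_three_seizures_is_57_percent_reduction():
    r = percent_reduction(7.0, 3.0)
    assert r == pytest.approx(100 * 4 / 7)
    assert round(r) == 57
    assert responder_label(r)


@pytest.mark.parametrize(
    "baseline, followups, expected",
    [(5.0, 5.0, 0.0), (6.0, [2.0, 4.0], 50.0), (2.0, 3.0, -50.0)],
)
def test_percent_reduction_cases(baseline, followups, expected):
    assert percent_reduction(baseline, followups) == pytest.approx(expected)


def test_percent_reduction_rejects_zero_baseline():
    with pytest.raises(ValueError, match="> 0"):
        percent_reduction(0.0, 3.0)


@pytest.mark.parametrize("value, expected", [(57, True), (50, True),
                                             (49.999, False), (-20, False)])
def test_responder_boundary_is_inclusive_at_50(value, expected):
    assert responder_label(value) is expected


# ---------------------------------------------------------------------------
# logistic fitting

def test_single_class_labels_are_rejected():
    X = np.arange(6.0).reshape(-1, 1)
    with pytest.raises(ValueError, match="each class"):
        fit_logistic(X, np.ones(6, int))


def test_perfectly_ordered_feature_gives_monotone_scores_and_auc_one():
    X = np.arange(10.0).reshape(-1, 1)
    y = (np.arange(10) >= 5).astype(int)
    with pytest.warns(UserWarning, match="separation"):
        model = fit_logistic(X, y)
    assert np.all(np.diff(model.fitted) >= -1e-12)
    _, auc = roc_and_auc(model.fitted, y)
    assert auc == 1.0


def test_interleaved_symmetric_feature_gives_chance_auc():
    X = np.array([0, 1, 2, 3, 4, 5, 6, 7], float).reshape(-1, 1)
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    model = fit_logistic(X, y)
    _, auc = roc_and_auc(model.fitted, y)
    assert auc == pytest.approx(0.5, abs=0.15)


# ---------------------------------------------------------------------------
# ROC / AUC

def test_printed_style_four_point_fixture_has_auc_075():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1])
    _, auc = roc_and_auc(scores, labels)
    assert auc == pytest.approx(0.75)


def test_roc_is_a_step_function_from_origin_to_one_one():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=20)
    labels = rng.integers(0, 2, 20)
    labels[:2] = [0, 1]
    points, auc = roc_and_auc(scores, labels)
    assert tuple(points[0]) == (0.0, 0.0)
    assert tuple(points[-1]) == (1.0, 1.0)
    assert np.all(np.diff(points[:, 0]) >= 0)
    assert 0.0 <= auc <= 1.0


def test_degenerate_auc_values():
    assert roc_and_auc([1, 2, 3, 10, 11, 12],
                       [0, 0, 0, 1, 1, 1])[1] == 1.0
    assert roc_and_auc(np.ones(6), [0, 0, 0, 1, 1, 1])[1] == 0.5
    with pytest.raises(ValueError, match="both classes"):
        roc_and_auc([1.0, 2.0], [1, 1])


@pytest.mark.parametrize("seed", range(8))
def test_trapezoid_auc_equals_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 51))
    scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]
    _, auc = roc_and_auc(scores, labels)
    assert auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)


def test_auc_complement_identity_without_ties():
    rng = np.random.default_rng(1)
    scores = rng.permutation(30).astype(float)
    labels = (rng.random(30) < 0.4).astype(int)
    labels[:2] = [0, 1]
    _, a = roc_and_auc(scores, labels)
    _, a_neg = roc_and_auc(-scores, labels)
    assert a + a_neg == pytest.approx(1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=15)
    labels = rng.integers(0, 2, 15)
    labels[:2] = [0, 1]
    _, a = roc_and_auc(scores, labels)
    _, b = roc_and_auc(np.exp(3 * scores), labels)
    assert a == pytest.approx(b, abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap

def test_separable_scores_give_degenerate_unit_interval():
    scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
    labels = np.array([0, 0, 0, 1, 1, 1])
    lo, hi = bootstrap_auc_ci(scores, labels, n_boot=200, seed=0)
    assert (lo, hi) == (1.0, 1.0)


def test_bootstrap_is_deterministic_given_seed():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=20)
    labels = rng.integers(0, 2, 20)
    labels[:2] = [0, 1]
    ci1 = bootstrap_auc_ci(scores, labels, n_boot=300, seed=7)
    ci2 = bootstrap_auc_ci(scores, labels, n_boot=300, seed=7)
    assert ci1 == ci2
    assert ci1[0] <= ci1[1]


def test_tiny_class_triggers_small_sample_warning():
    with pytest.warns(UserWarning, match="unstable"):
        bootstrap_auc_ci([0.1, 0.9], [0, 1], n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# LOOCV

def test_loocv_builds_n_models_of_n_minus_1_samples(monkeypatch):
    import rnsfc.classify as mod

    calls = []
    orig = mod._fit_glm

    def counting_fit(X, y):
        calls.append(len(y))
        return orig(X, y)

    monkeypatch.setattr(mod, "_fit_glm", counting_fit)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(31, 1))
    y = (rng.random(31) < 0.7).astype(int)
    result = loocv(X, y)
    assert result.n_models == 31
    assert result.train_size == 30
    assert calls == [30] * 31


def test_loocv_minimum_size():
    X = np.array([[0.0], [1.0], [2.0]])
    assert loocv(X, np.array([0, 1, 1])).scores.shape == (3,)
    with pytest.raises(ValueError, match="n >= 3"):
        loocv(X[:2], np.array([0, 1]))


def test_loocv_separated_clusters_classify_accurately():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(-3, 1, (20, 1)), rng.normal(3, 1, (20, 1))])
    y = np.r_[np.zeros(20, int), np.ones(20, int)]
    scores = loocv(X, y).scores
    acc = np.mean((scores >= 0.5) == y)
    assert acc >= 0.95


def test_single_class_training_fold_is_flagged_with_prevalence_score():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([1, 0, 0, 0])
    result = loocv(X, y)
    assert result.flagged_folds == [0]
    assert result.scores[0] == 0.0  # training prevalence of positives


# ---------------------------------------------------------------------------
# thresholds and confusion metrics

def test_separable_scores_threshold_is_the_gap_midpoint():
    scores = np.array([0.1, 0.2, 0.6, 0.9])
    labels = np.array([0, 0, 1, 1])
    t = optimal_threshold(scores, labels)
    assert t == pytest.approx(0.4)  # midpoint of 0.2 and 0.6
    cm = confusion_metrics(scores, labels, t)
    assert (cm.sensitivity, cm.specificity) == (100.0, 100.0)


def test_all_tied_scores_pick_the_better_trivial_classifier():
    scores = np.ones(6)
    labels = np.array([1, 1, 1, 1, 0, 0])
    t = optimal_threshold(scores, labels)
    cm = confusion_metrics(scores, labels, t)
    # gm is 0 either way; tie broken toward higher specificity (all negative)
    assert cm.specificity == 100.0 and cm.sensitivity == 0.0


def test_single_top_positive_threshold_sits_just_below_it():
    scores = np.array([0.1, 0.3, 0.5, 0.9])
    labels = np.array([0, 0, 0, 1])
    t = optimal_threshold(scores, labels)
    assert 0.5 < t < 0.9


def test_clinical_style_confusion_counts_give_hand_ratios():
    # 22 positives (19 detected), 9 negatives (7 detected)
    scores = np.r_[np.full(19, 0.9), np.full(3, 0.1),
                   np.full(7, 0.1), np.full(2, 0.9)]
    labels = np.r_[np.ones(22, int), np.zeros(9, int)]
    cm = confusion_metrics(scores, labels, 0.5)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (19, 3, 7, 2)
    assert cm.sensitivity == pytest.approx(100 * 19 / 22)
    assert cm.specificity == pytest.approx(100 * 7 / 9)
    assert cm.accuracy == pytest.approx(100 * 26 / 31)
    assert cm.ppv == pytest.approx(100 * 19 / 21)
    assert cm.npv == pytest.approx(100 * 7 / 10)
    assert cm.rounded() == {
        "accuracy": 83.9, "sensitivity": 86.4, "specificity": 77.8,
        "ppv": 90.5, "npv": 70.0,
    }


def test_all_correct_predictions_give_all_100s():
    cm = confusion_metrics([0.9, 0.9, 0.1], [1, 1, 0], 0.5)
    assert all(
        getattr(cm, k) == 100.0
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv")
    )


def test_no_predicted_positives_flags_undefined_ppv():
    with pytest.warns(UserWarning, match="PPV"):
        cm = confusion_metrics([0.1, 0.2, 0.3], [0, 1, 1], 0.9)
    assert np.isnan(cm.ppv)


# ---------------------------------------------------------------------------
# precision-recall

def test_perfect_ranking_has_unit_precision_at_all_recalls():
    scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
    labels = np.array([1, 1, 1, 0, 0])
    points = precision_recall(scores, labels)
    assert np.allclose(points[:, 1], 1.0)
    assert points[0, 0] == 1.0  # descending recall ordering


def test_tied_scores_give_prevalence_precision_at_full_recall():
    scores = np.ones(10)
    labels = np.r_[np.ones(3, int), np.zeros(7, int)]
    points = precision_recall(scores, labels)
    at_full = points[points[:, 0] == 1.0]
    assert at_full[0, 1] == pytest.approx(0.3)


def test_single_positive_ranked_last():
    n = 6
    scores = np.arange(n, dtype=float)
    labels = np.zeros(n, int)
    labels[np.argmin(scores)] = 1
    points = precision_recall(scores, labels)
    at_full = points[points[:, 0] == 1.0]
    assert at_full[:, 1].min() == pytest.approx(1 / n)
    with pytest.raises(ValueError, match="positive"):
        precision_recall(scores, np.zeros(n, int))


# ---------------------------------------------------------------------------
# full evaluation bundle

def test_evaluate_model_bundle_is_consistent():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-1, 1, (15, 2)), rng.normal(1, 1, (10, 2))])
    y = np.r_[np.zeros(15, int), np.ones(10, int)]
    ev = evaluate_model(X, y, name="demo", features=("f1", "f2"),
                        n_boot=100, seed=0)
    assert 0.5 < ev.auc <= 1.0
    assert ev.auc_ci[0] <= ev.auc_ci[1]
    assert ev.loocv_scores.shape == (25,)
    assert np.isfinite(ev.threshold)
    d = ev.to_dict()
    assert set(d) >= {"auc", "auc_ci", "loocv_metrics", "roc_points"}
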