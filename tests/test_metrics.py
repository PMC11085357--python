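"""Metric suite: hand-computed examples, algebraic identities, and full
equivalence against a brute-force count-and-plug oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenonet import metrics as M


# ---------------------------------------------------------------------------
# brute-force oracle: literal counting and direct formula substitution


def oracle_counts(y_true, y_pred, positive):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    return tp, fp, tn, fn


def oracle_metrics(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    div = lambda a, b: a / b if b else 0.0
    sens = div(tp, tp + fn)
    prec = div(tp, tp + fp)
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity_eq3": prec,
        "fpr": div(fp, fp + tn),
        "f1": div(2 * sens * prec, sens + prec),
    }


def oracle_regression(y, yhat):
    n = len(y)
    rmse = math.sqrt(sum((b - a) ** 2 for a, b in zip(y, yhat)) / n)
    ybar = sum(y) / n
    sst = sum((a - ybar) ** 2 for a in y)
    sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
    sd = math.sqrt(sst / n)
    return rmse, 1 - sse / sst, (math.inf if rmse == 0 else sd / rmse)


def test_oracle_equivalence_on_randomised_instances():
    """1,000 random multiclass instances: every metric matches the
    brute-force oracle to 1e-12."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(2, 51))
        names = [f"c{i}" for i in range(k)]
        y_true = [names[i] for i in rng.integers(0, k, n)]
        y_pred = [names[i] for i in rng.integers(0, k, n)]
        cm = M.confusion_matrix(y_true, y_pred, names)
        for j, name in enumerate(names):
            bc = M.one_vs_rest_counts(cm, j)
            tp, fp, tn, fn = oracle_counts(y_true, y_pred, name)
            assert (bc.tp, bc.fp, bc.tn, bc.fn) == (tp, fp, tn, fn)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-denominator sentinels
                got = M.classification_metrics(bc)
            want = oracle_metrics(tp, fp, tn, fn)
            for key, val in want.items():
                assert abs(getattr(got, key) - val) < 1e-12, key
        # regression on random day vectors
        y = rng.integers(1, 23, n).astype(float)
        yhat = y + rng.normal(0, 2, n)
        if np.ptp(y) > 0:
            ormse, or2, orpd = oracle_regression(list(y), list(yhat))
            assert abs(M.rmse(y, yhat) - ormse) < 1e-12
            assert abs(M.r_squared(y, yhat) - or2) < 1e-12
            assert abs(M.rpd(y, yhat) - orpd) < 1e-12


# ---------------------------------------------------------------------------
# confusion matrix and one-vs-rest counts


def test_confusion_matrix_hand_example():
    cm = M.confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
    assert cm.counts.tolist() == [[1, 1], [0, 2]]


def test_confusion_matrix_perfect_is_diagonal():
    y = ["A", "B", "C", "B"]
    cm = M.confusion_matrix(y, y, ["A", "B", "C"])
    assert np.count_nonzero(cm.counts - np.diag(np.diag(cm.counts))) == 0


def test_confusion_matrix_empty_and_errors():
    cm = M.confusion_matrix([], [], ["A", "B"])
    assert cm.counts.sum() == 0
    with pytest.raises(ValueError):
        M.confusion_matrix(["A"], ["Z"], ["A", "B"])
    with pytest.raises(ValueError):
        M.confusion_matrix(["A", "A"], ["A"], ["A"])


def test_one_vs_rest_hand_example():
    cm = M.confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
    bc = M.one_vs_rest_counts(cm, 1)
    assert (bc.tp, bc.fn, bc.fp, bc.tn) == (2, 0, 1, 1)
    for k in range(2):
        assert M.one_vs_rest_counts(cm, k).n == 4  # conservation
    with pytest.raises(IndexError):
        M.one_vs_rest_counts(cm, 2)


def test_diagonal_matrix_has_no_errors():
    cm = M.ConfusionMatrix(np.diag([3, 5, 2]), ["a", "b", "c"])
    for k in range(3):
        bc = M.one_vs_rest_counts(cm, k)
        assert bc.fp == 0 and bc.fn == 0


# ---------------------------------------------------------------------------
# per-class metrics (Eqs as printed)


def test_classification_metrics_hand_example():
    got = M.classification_metrics(M.BinaryCounts(tp=2, fp=1, tn=1, fn=0))
    assert got.sensitivity == 1.0
    assert abs(got.specificity_eq3 - 2 / 3) < 1e-12
    assert got.fpr == 0.5
    assert got.accuracy == 0.75
    assert abs(got.f1 - 0.8) < 1e-12
    assert got.precision == got.specificity_eq3  # alias
    assert got.specificity_standard == 0.5  # TN/(TN+FP), the textbook one


def test_all_correct_positive_class():
    got = M.classification_metrics(M.BinaryCounts(tp=7, fp=0, tn=0, fn=0))
    assert got.accuracy == 1.0 and got.f1 == 1.0


def test_zero_sensitivity_and_zero_denominators():
    got = M.classification_metrics(M.BinaryCounts(tp=0, fp=0, tn=3, fn=2))
    assert got.sensitivity == 0.0
    with pytest.warns(UserWarning):
        got = M.classification_metrics(M.BinaryCounts(tp=0, fp=0, tn=5, fn=0))
    assert got.specificity_eq3 == 0.0  # no predicted positives -> sentinel 0
    with pytest.raises(ValueError):
        M.classification_metrics(M.BinaryCounts(0, 0, 0, 0))


def test_f1_is_exact_harmonic_mean():
    bc = M.BinaryCounts(tp=5, fp=3, tn=10, fn=2)
    got = M.classification_metrics(bc)
    s, p = got.sensitivity, got.specificity_eq3
    assert got.f1 == 2 * s * p / (s + p)


# ---------------------------------------------------------------------------
# macro report


def test_macro_report_hand_example():
    cm = M.confusion_matrix(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
    rep = M.macro_report(cm)
    assert abs(rep.macro_sensitivity - 0.75) < 1e-12  # (0.5 + 1.0) / 2
    assert rep.overall_accuracy == 0.75  # trace / n


def test_macro_report_diagonal_is_perfect():
    cm = M.ConfusionMatrix(np.diag([4, 4, 4]), ["a", "b", "c"])
    rep = M.macro_report(cm)
    assert rep.macro_f1 == 1.0 and rep.macro_fpr == 0.0
    assert rep.overall_accuracy == 1.0


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_micro_accuracy_equals_trace_over_n(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    counts = rng.integers(0, 10, (k, k))
    if counts.sum() == 0:
        counts[0, 0] = 1
    cm = M.ConfusionMatrix(counts, [str(i) for i in range(k)])
    assert M.macro_report(cm).overall_accuracy == np.trace(counts) / counts.sum()


# ---------------------------------------------------------------------------
# regression metrics


def test_rmse_examples_and_translation_invariance():
    assert M.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert abs(M.rmse([0, 0], [3, 4]) - math.sqrt(12.5)) < 1e-12
    y = np.array([1.0, 5.0, 9.0])
    yhat = np.array([2.0, 4.0, 8.5])
    assert abs(M.rmse(y, yhat) - M.rmse(y + 7, yhat + 7)) < 1e-12
    with pytest.raises(ValueError):
        M.rmse([1, 2], [1])


def test_r_squared_examples():
    assert M.r_squared([1, 2, 3], [1, 2, 3]) == 1.0
    y = [1.0, 2.0, 3.0]
    assert abs(M.r_squared(y, [2.0, 2.0, 2.0])) < 1e-12  # mean predictor
    assert abs(M.r_squared(y, [1, 2, 4]) - 0.5) < 1e-12
    with pytest.raises(ValueError):
        M.r_squared([2, 2, 2], [1, 2, 3])


def test_rpd_examples_and_scaling():
    assert abs(M.rpd([1, 2, 3], [2, 3, 4]) - math.sqrt(2 / 3)) < 1e-12
    assert M.rpd([1, 2, 3], [1, 2, 3]) == math.inf
    y = np.array([3.0, 8.0, 14.0, 20.0])
    res = np.array([0.5, -1.0, 1.5, -0.5])
    assert abs(M.rpd(y, y + 2 * res) - M.rpd(y, y + res) / 2) < 1e-12


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_rpd_times_rmse_is_population_sd(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 40))
    y = rng.uniform(1, 22, n)
    yhat = y + rng.normal(0, 1, n)
    if np.ptp(y) == 0 or M.rmse(y, yhat) == 0:
        return
    sd = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
    assert abs(M.rpd(y, yhat) * M.rmse(y, yhat) - sd) < 1e-9


def test_residuals_by_day():
    groups = M.residuals_by_day([1, 1, 2], [1.5, 0.5, 2.0])
    assert set(groups) == {1, 2}
    assert groups[1] == [0.5, -0.5] and groups[2] == [0.0]
    assert sum(len(v) for v in groups.values()) == 3
    perfect = M.residuals_by_day([3, 3, 3], [3, 3, 3])
    assert perfect == {3: [0.0, 0.0, 0.0]}


def test_regression_report_assembles_everything():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    yhat = y + np.array([0.5, -0.5, 0.5, -0.5])
    rep = M.regression_report(y, yhat)
    assert rep.rmse == 0.5 and rep.n == 4
    assert abs(rep.rpd * rep.rmse - np.sqrt(np.mean((y - y.mean()) ** 2))) < 1e-12
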