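"""KNN, cross-validation, metrics and confidence-interval construction."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiopanel import (CASE, CONTROL, ConfusionSummary, FoldOutcomes,
                         SyntheticConfig, balanced_loocv, blind_validate, ci95,
                         confusion_metrics, evaluate, generate_dataset,
                         knn_predict, loocv, roc_point)
from cardiopanel.datasets import plant_batches
from conftest import make_dataset


def brute_force_knn(train_x, train_labels, test_x, k):
    """Oracle: full distance list, explicit stable sort, majority vote."""
    dists = [(float(np.sqrt(((train_x[:, j] - test_x) ** 2).sum())), j)
             for j in range(train_x.shape[1])]
    dists.sort()
    votes = [train_labels[j] for _, j in dists[:k]]
    n_case = votes.count(CASE)
    return CASE if n_case > k - n_case else CONTROL


def test_knn_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(4, 21))
        p = int(rng.integers(1, 11))
        x = rng.normal(size=(p, n)).round(3)  # rounding provokes ties
        labels = [CASE if v else CONTROL for v in rng.integers(0, 2, n)]
        if labels.count(CASE) == 0 or labels.count(CONTROL) == 0:
            labels[0] = CASE
            labels[1] = CONTROL
        data = make_dataset(x, labels)
        test = rng.normal(size=p).round(3)
        k = int(rng.integers(1, min(n, 5) + 1))
        if k % 2 == 0:
            k += 1 if k < n else -1
        expected = brute_force_knn(x, labels, test, k)
        got = knn_predict(data, data.probe_ids, test, k=k)
        assert got == expected


def test_knn_trivial_cases(separable_dataset):
    first = separable_dataset.values.iloc[:, 0]
    assert knn_predict(separable_dataset, separable_dataset.probe_ids,
                       first, k=1) == CASE
    # three nearest at distances 1, 2, 10 labelled case, case, control
    data = make_dataset([[0.0, 1.0, 2.0, 10.0]],
                        [CASE, CASE, CASE, CONTROL])
    assert knn_predict(data, ["PS0"], np.array([0.0]), k=3) == CASE
    uniform = make_dataset([[0.0, 5.0, 9.0]], [CONTROL] * 3)
    assert knn_predict(uniform, ["PS0"], np.array([100.0]), k=3) == CONTROL


def test_knn_input_validation(separable_dataset):
    with pytest.raises(KeyError):
        knn_predict(separable_dataset, ["nope"], np.zeros(1))
    with pytest.raises(ValueError):
        knn_predict(separable_dataset, separable_dataset.probe_ids,
                    separable_dataset.values.iloc[:, 0], k=100)


def test_loocv_separable_is_perfect(separable_dataset):
    folds = loocv(separable_dataset, separable_dataset.probe_ids)
    assert folds.sr == 100.0
    assert folds.sr == folds.outcomes.mean()  # SR is exactly the fold mean


def test_loocv_boundary_n_equals_k_plus_one():
    data = make_dataset(np.random.default_rng(0).normal(size=(3, 4)),
                        [CASE, CASE, CONTROL, CONTROL])
    folds = loocv(data, data.probe_ids, k=3)
    assert len(folds) == 4


def test_loocv_permuted_labels_near_chance():
    rng = np.random.default_rng(31)
    srs = []
    for _ in range(50):
        x = rng.normal(size=(10, 20))
        labels = [CASE] * 10 + [CONTROL] * 10
        rng.shuffle(labels)
        srs.append(loocv(make_dataset(x, labels), [f"PS{i}" for i in range(10)]).sr)
    # chance level is below the 50% majority share because LOOCV removes
    # the held-out sample from its own class
    assert 25 < np.mean(srs) < 60


def test_blind_validation_and_batch_adjustment_rescue():
    cfg = SyntheticConfig(n_probes=100, n_de=10, effect_size=3.0, seed=23)
    train = generate_dataset(cfg)
    test = generate_dataset(cfg, sample_prefix="T")  # identical cohort
    features = list(train.truth)
    assert blind_validate(train, test, features).sr == 100.0

    # plant a strong additive shift on the test cohort only
    shifted = []
    for seed in range(10):
        merged_test = plant_batches(
            test, (("B", 3.0, 0.0),), seed=seed,
            assignment=pd.Series(["B"] * test.n_samples, index=test.sample_ids))
        off = blind_validate(train, merged_test, features, adjust_batches=False).sr
        on = blind_validate(train, merged_test, features, adjust_batches=True).sr
        shifted.append((off, on))
    assert all(on >= off for off, on in shifted)
    assert np.mean([on for _, on in shifted]) > np.mean([off for off, _ in shifted])


def test_blind_validation_requires_shared_features(separable_dataset):
    other = make_dataset(np.zeros((2, 4)), [CASE, CASE, CONTROL, CONTROL],
                         probe_prefix="OTHER")
    with pytest.raises(KeyError):
        blind_validate(separable_dataset, other, separable_dataset.probe_ids)


def test_balanced_loocv_subsamples_majority_class():
    rng = np.random.default_rng(3)
    # 28 cases vs 14 controls: every repeat must classify 14+14=28 samples
    x = np.vstack([rng.normal(3, 0.3, size=(3, 28)).T,
                   rng.normal(0, 0.3, size=(3, 14)).T]).T
    data = make_dataset(x, [CASE] * 28 + [CONTROL] * 14)
    report = balanced_loocv(data, data.probe_ids, n_repeats=3, seed=1)
    assert report.n_folds == 28
    again = balanced_loocv(data, data.probe_ids, n_repeats=3, seed=1)
    assert report.sr == again.sr and report.ci == again.ci


def test_balanced_loocv_idempotent_on_balanced_data(separable_dataset):
    one = balanced_loocv(separable_dataset, separable_dataset.probe_ids,
                         n_repeats=1, seed=0)
    many = balanced_loocv(separable_dataset, separable_dataset.probe_ids,
                          n_repeats=5, seed=0)
    assert one.sr == many.sr == 100.0


# ---------------------------------------------------------------------------
# metrics, CIs, ROC — worked examples from reference cohort compositions

def test_confusion_metrics_mi_vs_unstable_angina_cohort():
    # 18 MI + 8 unstable angina, sens 0.78 => TP=14, spec 0.88 => TN=7
    m = confusion_metrics(ConfusionSummary(tp=14, fp=1, tn=7, fn=4)).rounded()
    assert m == {"sr": 81, "sensitivity": 0.78, "specificity": 0.88,
                 "ppv": 0.93, "npv": 0.64}


def test_confusion_metrics_small_blind_cohort():
    # 11 MI + 6 controls, TP=9, TN=1
    m = confusion_metrics(ConfusionSummary(tp=9, fp=5, tn=1, fn=2)).rounded()
    assert m == {"sr": 59, "sensitivity": 0.82, "specificity": 0.17,
                 "ppv": 0.64, "npv": 0.33}


def test_confusion_metrics_perfect_and_undefined():
    m = confusion_metrics(ConfusionSummary(tp=5, fp=0, tn=5, fn=0))
    assert m.sr == 100.0 and m.sensitivity == m.specificity == 1.0
    m = confusion_metrics(ConfusionSummary(tp=0, fp=0, tn=5, fn=0))
    assert math.isnan(m.sensitivity) and math.isnan(m.ppv)  # undefined, not 0


@pytest.mark.parametrize("n_correct,n_total,expected", [
    (10, 17, (35, 83)),
    (21, 26, (65, 96)),
    (17, 26, (47, 84)),
    (17, 17, (100, 100)),
])
def test_ci95_fold_outcome_rule(n_correct, n_total, expected):
    outcomes = np.array([100.0] * n_correct + [0.0] * (n_total - n_correct))
    assert ci95(outcomes) == expected


def test_ci95_midpoint_and_shrinkage():
    out = np.array([100.0] * 6 + [0.0] * 4)
    lo, hi = ci95(out)
    assert (lo + hi) / 2 == pytest.approx(60, abs=1)
    lo4, hi4 = ci95(np.tile(out, 4))  # 4x the folds, same proportion
    assert (hi4 - lo4) == pytest.approx((hi - lo) / 2, abs=3)
    with pytest.raises(ValueError):
        ci95(np.array([100.0]))


def test_evaluate_builds_per_metric_cis():
    folds = FoldOutcomes(
        sample_ids=[f"s{i}" for i in range(6)],
        true_labels=[CASE, CASE, CASE, CONTROL, CONTROL, CONTROL],
        predicted_labels=[CASE, CASE, CONTROL, CONTROL, CONTROL, CASE])
    report = evaluate(folds)
    assert report.ci["sr"] is not None
    assert report.ci["sensitivity"] == ci95(np.array([100.0, 100.0, 0.0]))


def test_roc_points():
    m = confusion_metrics(ConfusionSummary(tp=14, fp=1, tn=7, fn=4))
    fpr, tpr = roc_point(m)
    assert (round(fpr, 2), round(tpr, 2)) == (0.12, 0.78)
    perfect = confusion_metrics(ConfusionSummary(tp=5, fp=0, tn=5, fn=0))
    assert roc_point(perfect) == (0.0, 1.0)
    half = confusion_metrics(ConfusionSummary(tp=1, fp=1, tn=1, fn=1))
    assert roc_point(half) == (0.5, 0.5)


def test_k3_binary_vote_never_ties():
    rng = np.random.default_rng(8)
    for _ in range(100):
        data = make_dataset(rng.normal(size=(2, 9)),
                            [CASE] * 5 + [CONTROL] * 4)
        label = knn_predict(data, data.probe_ids, rng.normal(size=2), k=3)
        assert label in (CASE, CONTROL)
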