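"""KNN (k=3) classification, LOOCV / blind validation, metrics and CIs.

Classification follows the evaluation protocol used throughout the panel
discovery: a k-nearest-neighbour vote (Euclidean distance over the selected
probe panel, k=3 so a binary vote never ties), leave-one-out cross-validation
on a single cohort, blind validation across cohorts (optionally batch
adjusted), and repeated balanced subsampling when classes are unbalanced.

Per-sample fold outcomes are coded 0/100 ("success" of that fold); the
success rate SR is their mean and its 95% CI is mean +/- 1.96 * sd / sqrt(n)
with the n-1 sample standard deviation, bounds rounded to integers and NOT
clipped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, ExpressionDataset


@dataclass
class FoldOutcomes:
    """Per held-out sample results of a cross-validation run."""

    sample_ids: list[str]
    true_labels: list[str]
    predicted_labels: list[str]

    @property
    def outcomes(self) -> np.ndarray:
        """0/100 success codes, 100 iff predicted == true."""
        return np.array(
            [100.0 if p == t else 0.0
             for p, t in zip(self.predicted_labels, self.true_labels)])

    @property
    def sr(self) -> float:
        """Success rate in percent: the mean of the 0/100 fold outcomes."""
        return float(self.outcomes.mean())

    def __len__(self) -> int:
        return len(self.sample_ids)

    def confusion(self, positive: str = CASE) -> "ConfusionSummary":
        tp = fp = tn = fn = 0
        for true, pred in zip(self.true_labels, self.predicted_labels):
            if true == positive:
                tp += pred == positive
                fn += pred != positive
            else:
                tn += pred != positive
                fp += pred == positive
        return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)

    def subset(self, mask: np.ndarray) -> "FoldOutcomes":
        idx = np.flatnonzero(mask)
        return FoldOutcomes(
            sample_ids=[self.sample_ids[i] for i in idx],
            true_labels=[self.true_labels[i] for i in idx],
            predicted_labels=[self.predicted_labels[i] for i in idx],
        )


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Point estimates (SR in percent, the rest proportions) plus CIs.

    A metric with a zero denominator is ``nan`` (undefined), never 0.  CI
    bounds are percent-scale integers and may fall outside [0, 100].
    """

    sr: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    n_folds: int = 0

    def rounded(self) -> dict[str, float]:
        """Display rounding: SR to integer percent, proportions to 2 dp."""
        out = {"sr": round(self.sr)}
        for k in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, k)
            out[k] = round(v, 2) if not math.isnan(v) else math.nan
        return out

    def summary(self) -> str:
        r = self.rounded()
        fmt = lambda v: "undefined" if isinstance(v, float) and math.isnan(v) else v
        lines = [f"KNN classification report ({self.n_folds} folds)",
                 f"  SR:          {r['sr']}%"]
        for k, label in (("sensitivity", "sensitivity"), ("specificity", "specificity"),
                         ("ppv", "PPV"), ("npv", "NPV")):
            line = f"  {label + ':':13s}{fmt(r[k])}"
            if self.ci.get(k):
                line += f"   95% CI [{self.ci[k][0]}, {self.ci[k][1]}]"
            lines.append(line)
        if self.ci.get("sr"):
            lines[1] += f"   95% CI [{self.ci['sr'][0]}, {self.ci['sr'][1]}]"
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the classifier

def _check_features(features: list[str], data: ExpressionDataset) -> None:
    missing = [f for f in features if f not in data.values.index]
    if missing:
        raise KeyError(f"feature(s) absent from dataset: {missing[:5]}")


def knn_predict(train: ExpressionDataset, features: list[str],
                test_column: np.ndarray | pd.Series, k: int = 3) -> str:
    """Majority label among the k nearest training samples.

    Euclidean distance over the feature subset; ties at the k-th distance
    are broken by training-sample order (stable sort), so the prediction is
    deterministic.
    """
    if len(features) == 0:
        raise ValueError("empty feature panel")
    _check_features(features, train)
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds the {train.n_samples} training samples")
    x = train.values.loc[features].to_numpy()
    if isinstance(test_column, pd.Series):
        test_column = test_column.loc[features].to_numpy()
    test_column = np.asarray(test_column, dtype=float)
    d2 = ((x - test_column[:, None]) ** 2).sum(axis=0)
    order = np.argsort(d2, kind="stable")[:k]
    labels = train.labels.to_numpy()[order]
    return _majority(labels)


def _majority(labels: np.ndarray) -> str:
    n_case = int((labels == CASE).sum())
    n_control = len(labels) - n_case
    if n_case == n_control:  # possible only for even k
        return labels[0]  # nearest neighbour breaks the vote
    return CASE if n_case > n_control else CONTROL


def _pairwise_sq_distances(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x.T @ x)
    np.maximum(d2, 0.0, out=d2)
    return d2


def loocv_from_distances(d2: np.ndarray, labels: np.ndarray,
                         sample_ids: list[str], k: int = 3) -> FoldOutcomes:
    """Leave-one-out KNN given a precomputed squared-distance matrix.

    The optimisers call this in their inner loop with incrementally updated
    distance matrices, which keeps panel search affordable.
    """
    n = len(labels)
    if n < k + 1:
        raise ValueError(f"LOOCV needs at least k+1={k + 1} samples, got {n}")
    d2 = d2.copy()
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    predicted = [_majority(labels[row]) for row in order]
    return FoldOutcomes(sample_ids=list(sample_ids),
                        true_labels=list(labels),
                        predicted_labels=predicted)


def loocv(data: ExpressionDataset, features: list[str], k: int = 3) -> FoldOutcomes:
    """Classify each sample by KNN on the remaining n-1 samples."""
    if len(features) == 0:
        raise ValueError("empty feature panel")
    _check_features(features, data)
    x = data.values.loc[features].to_numpy()
    return loocv_from_distances(_pairwise_sq_distances(x),
                                data.labels.to_numpy(), data.sample_ids, k=k)


def blind_validate(train: ExpressionDataset, test: ExpressionDataset,
                   features: list[str], k: int = 3,
                   adjust_batches: bool = False) -> FoldOutcomes:
    """Classify an independent cohort against the full training cohort.

    With ``adjust_batches`` the two cohorts are merged, batch-adjusted with
    batch = dataset of origin (class label protected as covariate), and the
    adjusted matrices used for classification — the situation where two
    experiments are merged and non-biological variation must be removed
    before distances mean anything.
    """
    shared = [f for f in features if f in train.values.index and f in test.values.index]
    if not shared:
        raise KeyError("no shared features between training and test cohorts")
    train_use, test_use = train, test
    if adjust_batches:
        if set(train.sample_ids) & set(test.sample_ids):
            raise ValueError("training and test cohorts share sample ids; "
                             "rename before merging for adjustment")
        from .batch import combat_adjust

        merged_values = pd.concat(
            [train.values.loc[shared], test.values.loc[shared]], axis=1)
        labels = pd.concat([train.labels, test.labels])
        batch = pd.Series(
            ["train"] * train.n_samples + ["test"] * test.n_samples,
            index=merged_values.columns, name="batch")
        merged = ExpressionDataset(values=merged_values, labels=labels,
                                   batch=batch, name="merged")
        adjusted = combat_adjust(merged)
        train_use = adjusted.subset_samples(train.sample_ids, name=train.name)
        test_use = adjusted.subset_samples(test.sample_ids, name=test.name)
    predictions = [
        knn_predict(train_use, shared, test_use.values.loc[shared, s], k=k)
        for s in test_use.sample_ids
    ]
    return FoldOutcomes(sample_ids=test.sample_ids,
                        true_labels=list(test.labels),
                        predicted_labels=predictions)


def balanced_loocv(data: ExpressionDataset, features: list[str], k: int = 3,
                   n_repeats: int = 15, seed: int = 0) -> MetricsReport:
    """Repeated balanced-subsample LOOCV, metrics averaged over repeats.

    Per repeat the majority class is subsampled without replacement down to
    the minority size (already-balanced data uses all samples every time),
    LOOCV is run, and the metric point estimates and CI bounds are averaged
    across repeats.  Repeat seeds derive from the master seed by index.
    """
    counts = data.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("both classes must be non-empty")
    minority = min(counts.values())
    case_ids = [s for s in data.sample_ids if data.labels[s] == CASE]
    control_ids = [s for s in data.sample_ids if data.labels[s] == CONTROL]
    reports = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        take_case = sorted(rng.choice(len(case_ids), size=minority, replace=False)) \
            if len(case_ids) > minority else range(len(case_ids))
        take_control = sorted(rng.choice(len(control_ids), size=minority, replace=False)) \
            if len(control_ids) > minority else range(len(control_ids))
        chosen = [case_ids[i] for i in take_case] + [control_ids[i] for i in take_control]
        subset = data.subset_samples([s for s in data.sample_ids if s in set(chosen)])
        reports.append(evaluate(loocv(subset, features, k=k)))
    return _average_reports(reports)


def _average_reports(reports: list[MetricsReport]) -> MetricsReport:
    def mean_of(vals):
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        return float(np.mean(vals)) if vals else math.nan

    ci = {}
    for key in ("sr", "sensitivity", "specificity", "ppv", "npv"):
        bounds = [r.ci.get(key) for r in reports]
        bounds = [b for b in bounds if b is not None]
        if bounds:
            ci[key] = (round(float(np.mean([b[0] for b in bounds]))),
                       round(float(np.mean([b[1] for b in bounds]))))
        else:
            ci[key] = None
    return MetricsReport(
        sr=mean_of([r.sr for r in reports]),
        sensitivity=mean_of([r.sensitivity for r in reports]),
        specificity=mean_of([r.specificity for r in reports]),
        ppv=mean_of([r.ppv for r in reports]),
        npv=mean_of([r.npv for r in reports]),
        ci=ci,
        n_folds=round(float(np.mean([r.n_folds for r in reports]))),
    )


# ---------------------------------------------------------------------------
# metrics

def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(c: ConfusionSummary) -> MetricsReport:
    """SR, sensitivity, specificity, PPV, NPV from a confusion summary."""
    if c.total == 0:
        raise ValueError("empty confusion summary")
    return MetricsReport(
        sr=100.0 * (c.tp + c.tn) / c.total,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        n_folds=c.total,
    )


def ci95(outcomes: FoldOutcomes | np.ndarray) -> tuple[int, int]:
    """95% CI for the SR from 0/100 fold outcomes.

    mean +/- 1.96 * sd / sqrt(n) with the sample (n-1 divisor) standard
    deviation; bounds rounded to the nearest integer, not clipped to
    [0, 100] (a small cohort with a middling SR legitimately produces a
    negative lower bound).
    """
    values = outcomes.outcomes if isinstance(outcomes, FoldOutcomes) else np.asarray(outcomes, float)
    n = values.size
    if n < 2:
        raise ValueError("CI needs at least 2 fold outcomes")
    mean = values.mean()
    half = 1.96 * values.std(ddof=1) / math.sqrt(n)
    return (round(mean - half), round(mean + half))


def evaluate(folds: FoldOutcomes, positive: str = CASE) -> MetricsReport:
    """Full metrics report for one cross-validation run.

    Each metric's CI applies the fold-outcome rule to the samples entering
    its denominator: all samples for SR, true cases for sensitivity, true
    controls for specificity, predicted positives for PPV, predicted
    negatives for NPV.
    """
    confusion = folds.confusion(positive)
    report = confusion_metrics(confusion)
    true = np.array(folds.true_labels)
    pred = np.array(folds.predicted_labels)
    masks = {
        "sr": np.ones(len(folds), dtype=bool),
        "sensitivity": true == positive,
        "specificity": true != positive,
        "ppv": pred == positive,
        "npv": pred != positive,
    }
    ci = {}
    for key, mask in masks.items():
        ci[key] = ci95(folds.subset(mask)) if mask.sum() >= 2 else None
    report.ci = ci
    return report


def roc_point(m: MetricsReport) -> tuple[float, float]:
    """(FPR, TPR) of a discrete classifier: (1 - specificity, sensitivity)."""
    if math.isnan(m.sensitivity) or math.isnan(m.specificity):
        raise ValueError("sensitivity/specificity undefined; no ROC point")
    return (1.0 - m.specificity, m.sensitivity)
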