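"""Predictive metrics, cross-validation, and age-category inference.

Predictive error is the mean over categories of the absolute difference
between the predicted probability vector and the one-hot vector of the
realised category (for 5 stages it lives in [0, 0.4]).  Predictive
accuracy is the 0/1 indicator that the most probable category is the
realised one, ties resolved towards the lowest category index.

Model comparison uses k-fold cross-validation (k = 5, repeated over 3
random shuffles): the structure search and the parameter fit are re-run on
every training split, and only test-split metrics are reported.
Out-of-dataset validation uses the same machinery with each source dataset
as a fold.  Folds split at the data-point level by default (subjects can
leak across folds); pass ``subject_level=True`` for a grouped split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesnet import fit_parameters, k2_search
from .datapoints import VARIABLE_CARDS, complete_cases
from .models import node_order

TARGETS = ("stage_t", "dur_t")


def predictive_error(predicted: np.ndarray, actual: int) -> float:
    """Mean absolute difference between the predicted probability vector
    and the one-hot encoding of the realised category."""
    p = np.asarray(predicted, float)
    if p.ndim != 1:
        raise ValueError("dimension mismatch: predicted must be a vector")
    if not 0 <= int(actual) < len(p):
        raise ValueError("actual category out of range")
    onehot = np.zeros_like(p)
    onehot[int(actual)] = 1.0
    return float(np.mean(np.abs(onehot - p)))


def predictive_accuracy(predicted: np.ndarray, actual: int) -> int:
    """1 if the most probable category (lowest index on ties) is the
    realised one, else 0."""
    p = np.asarray(predicted, float)
    if not 0 <= int(actual) < len(p):
        raise ValueError("actual category out of range")
    return int(int(np.argmax(p)) == int(actual))


def _batch_metrics(probs: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    n, k = probs.shape
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), actual] = 1.0
    err = float(np.mean(np.abs(onehot - probs).mean(axis=1)))
    acc = float(np.mean(probs.argmax(axis=1) == actual))
    return err, acc


@dataclass
class EvaluationResult:
    """Per-fold predictive error/accuracy for both targets plus summaries."""

    scope: str  # 'in-dataset' or 'out-of-dataset'
    folds: pd.DataFrame  # columns: shuffle, fold, target, error, accuracy, n_test

    def mean(self, target: str, metric: str) -> float:
        return float(self.folds.loc[self.folds["target"] == target, metric].mean())

    def sd(self, target: str, metric: str) -> float:
        return float(self.folds.loc[self.folds["target"] == target, metric].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        g = self.folds.groupby("target")[["error", "accuracy"]]
        out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
        out["scope"] = self.scope
        return out


def _eval_fold(train: pd.DataFrame, test: pd.DataFrame, variables: list[str],
               pseudo_count: float, max_parents: int | None) -> list[dict]:
    order = node_order(variables)
    structure = k2_search(train[order], order, max_parents=max_parents)
    net = fit_parameters(structure, train[order], pseudo_count=pseudo_count)
    out = []
    for target in TARGETS:
        evidence = test[[v for v in order if v != target]]
        probs = net.posterior_batch(target, evidence)
        err, acc = _batch_metrics(probs, test[target].to_numpy())
        out.append({"target": target, "error": err, "accuracy": acc,
                    "n_test": len(test)})
    return out


def _fold_indices(df: pd.DataFrame, k: int, rng: np.random.Generator,
                  subject_level: bool) -> list[np.ndarray]:
    if subject_level:
        subjects = df["subject_id"].unique()
        perm = rng.permutation(subjects)
        chunks = np.array_split(perm, k)
        pos = np.arange(len(df))
        return [pos[df["subject_id"].isin(c).to_numpy()] for c in chunks]
    return [np.asarray(c) for c in np.array_split(rng.permutation(len(df)), k)]


def kfold_cv(discrete_points: pd.DataFrame, variables: list[str],
             k: int = 5, shuffles: int = 3, seed: int = 0,
             pseudo_count: float = 1.0, max_parents: int | None = None,
             subject_level: bool = False) -> EvaluationResult:
    """k-fold cross-validated stage and duration prediction.

    Every point is tested exactly once per shuffle; the structure search
    runs afresh on each 80% training split.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("invalid k")
    data = complete_cases(discrete_points, variables).reset_index(drop=True)
    if len(data) < k:
        raise ValueError("not enough data points for k folds")
    rng = np.random.default_rng(seed)
    records = []
    for shuffle in range(shuffles):
        folds = _fold_indices(data, k, rng, subject_level)
        for fold_i, test_idx in enumerate(folds):
            if len(test_idx) == 0:
                continue
            test = data.iloc[test_idx]
            train = data.drop(index=data.index[test_idx])
            for rec in _eval_fold(train, test, variables, pseudo_count, max_parents):
                records.append({"shuffle": shuffle, "fold": fold_i, **rec})
    return EvaluationResult(scope="in-dataset", folds=pd.DataFrame(records))


def out_of_dataset_cv(discrete_points: pd.DataFrame, variables: list[str],
                      pseudo_count: float = 1.0,
                      max_parents: int | None = None) -> EvaluationResult:
    """Leave-one-dataset-out: train on all but one source, test on the
    held-out source; one fold per dataset."""
    data = complete_cases(discrete_points, variables).reset_index(drop=True)
    datasets = sorted(data["dataset_id"].unique())
    if len(datasets) < 2:
        raise ValueError("need >=2 datasets")
    records = []
    for fold_i, left_out in enumerate(datasets):
        test = data[data["dataset_id"] == left_out]
        train = data[data["dataset_id"] != left_out]
        for rec in _eval_fold(train, test, variables, pseudo_count, max_parents):
            records.append({"shuffle": 0, "fold": fold_i, "dataset_id": left_out,
                            **rec})
    return EvaluationResult(scope="out-of-dataset", folds=pd.DataFrame(records))


@dataclass
class AgePredictionResult:
    accuracy_mean: float
    accuracy_sd: float
    per_repeat: list[float]
    n_subjects_scored: int
    n_subjects_skipped: int  # zero usable data points


def age_prediction_experiment(discrete_points: pd.DataFrame,
                              variables: list[str],
                              n_holdout: int = 100, repeats: int = 3,
                              seed: int = 0, pseudo_count: float = 1.0,
                              max_parents: int | None = None
                              ) -> AgePredictionResult:
    """Generative age-group inference from sleep architecture alone.

    The network is trained on all but ``n_holdout`` subjects; for each
    held-out subject every data point yields a posterior over the age
    category given the point's sleep (and other demographic) variables, and
    the subject's prediction is the most common per-point argmax.  Repeats
    use disjoint hold-out draws.
    """
    if "age" not in variables:
        raise ValueError("model must contain the age variable")
    data = complete_cases(discrete_points, variables).reset_index(drop=True)
    subjects = np.sort(data["subject_id"].unique())
    if len(subjects) <= n_holdout:
        raise ValueError("cohort smaller than hold-out size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    order = node_order(variables)
    evidence_vars = [v for v in order if v != "age"]
    accs: list[float] = []
    skipped = scored = 0
    for r in range(repeats):
        holdout = set(perm[r * n_holdout: (r + 1) * n_holdout])
        if not holdout:
            raise ValueError("not enough subjects for disjoint repeats")
        train = data[~data["subject_id"].isin(holdout)]
        structure = k2_search(train[order], order, max_parents=max_parents)
        net = fit_parameters(structure, train[order], pseudo_count=pseudo_count)
        test = data[data["subject_id"].isin(holdout)]
        probs = net.posterior_batch("age", test[evidence_vars])
        votes = pd.Series(probs.argmax(axis=1),  # per-point argmax, ties -> lower bin
                          index=test.index)
        skipped += len(holdout) - test["subject_id"].nunique()
        correct = total = 0
        for sid, grp in test.groupby("subject_id"):
            pred = np.bincount(votes.loc[grp.index],
                               minlength=VARIABLE_CARDS["age"]).argmax()
            correct += int(pred == grp["age"].iloc[0])
            total += 1
        scored += total
        accs.append(correct / total if total else np.nan)
    arr = np.asarray(accs)
    return AgePredictionResult(
        accuracy_mean=float(np.nanmean(arr)),
        accuracy_sd=float(np.nanstd(arr, ddof=1)) if repeats > 1 else 0.0,
        per_repeat=[float(a) for a in arr],
        n_subjects_scored=scored,
        n_subjects_skipped=skipped,
    )
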