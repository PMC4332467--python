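"""Cross-validated left/right classification and the classifier-based symmetry test.

The premise: if left- and right-side gait patterns come from the same
distribution, no classifier can beat chance at telling them apart, so
above-chance cross-validated accuracy is evidence of asymmetry.  This module
provides the experiment engine around that idea:

* balanced k-fold cross-validation (default six folds, repeated ten times
  with fresh shuffles), with each fold holding the same number of right- and
  left-side patterns;
* confusion-matrix metrics (accuracy, sensitivity, specificity) with the
  right side as the positive class;
* a hyperparameter/feature-set comparison grid over the three kernels and
  the three pattern representations (all 101 values, six discrete
  parameters, PCA scores);
* a permutation-calibrated symmetry score in [0, 1] (1 = chance-level
  discrimination, i.e. symmetric).

By default each subject contributes one pattern per side (the mean of that
subject's trials) and both sides of a subject stay in the same fold, which
avoids subject-identity leakage across the train/test split; trial-level and
pattern-level modes are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._random import subseed, substream
from .errors import FoldError, GaitSymError
from .features import discrete_params_frame, fit_pca, transform_pca
from .grf import GaitDataset, subject_mean_patterns
from .svm import KernelSpec, train_svm

FEATURE_MODES = ("all_101", "six_params", "pca")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; right side (+1) is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise GaitSymError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass(frozen=True)
class EvalMetrics:
    """Accuracy / sensitivity / specificity; undefined ratios are NaN + flag."""

    accuracy: float
    sensitivity: float
    specificity: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True


def metrics_from_confusion(c: ConfusionCounts) -> EvalMetrics:
    """accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)."""
    if c.total == 0:
        raise GaitSymError("cannot compute metrics from an empty confusion table")
    accuracy = (c.tp + c.tn) / c.total
    sens_def = (c.tp + c.fn) > 0
    spec_def = (c.tn + c.fp) > 0
    sensitivity = c.tp / (c.tp + c.fn) if sens_def else float("nan")
    specificity = c.tn / (c.tn + c.fp) if spec_def else float("nan")
    return EvalMetrics(accuracy, sensitivity, specificity, sens_def, spec_def)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def _fold_assignment(
    y: np.ndarray, subjects: np.ndarray, k: int, pairing: str, rng: np.random.Generator
) -> np.ndarray:
    n = y.size
    if k < 2 or k > n:
        raise FoldError(f"k = {k} is not a usable fold count for {n} patterns")
    n_right = int(np.sum(y == 1))
    n_left = int(np.sum(y == -1))
    if n_right != n_left:
        raise FoldError(
            f"balanced folding needs equal class counts, got {n_right} right vs {n_left} left; "
            "drop unpaired patterns first"
        )
    folds = np.empty(n, dtype=int)
    if pairing == "subject_paired":
        subj_order = sorted(set(subjects))
        per_subject = [np.flatnonzero(subjects == s) for s in subj_order]
        sizes = {idx.size for idx in per_subject}
        for s, idx in zip(subj_order, per_subject):
            if np.sum(y[idx] == 1) != np.sum(y[idx] == -1):
                raise FoldError(f"subject {s!r} has unbalanced left/right patterns")
        if len(sizes) != 1:
            raise FoldError("subject-paired folding needs the same pattern count per subject")
        if len(subj_order) % k != 0:
            raise FoldError(
                f"{len(subj_order)} subjects not divisible by k = {k}; "
                "drop subjects or change k so each fold gets the same number"
            )
        perm = rng.permutation(len(subj_order))
        per_fold = len(subj_order) // k
        for pos, si in enumerate(perm):
            folds[per_subject[si]] = pos // per_fold
    elif pairing == "pattern_level":
        for cls in (1, -1):
            idx = np.flatnonzero(y == cls)
            if idx.size % k != 0:
                raise FoldError(
                    f"{idx.size} patterns of class {cls} not divisible by k = {k}; "
                    "subsample to a multiple of k"
                )
            idx = rng.permutation(idx)
            folds[idx] = np.repeat(np.arange(k), idx.size // k)
    else:
        raise FoldError(f"unknown pairing mode {pairing!r}")
    return folds


def make_balanced_folds(
    dataset: GaitDataset, k: int = 6, pairing: str = "subject_paired", seed: int = 0
) -> np.ndarray:
    """Assign each pattern of ``dataset`` to one of ``k`` balanced folds.

    Every fold receives exactly n_right/k right and n_left/k left patterns;
    in ``subject_paired`` mode (default) both sides of a subject share a
    fold.  The assignment is a deterministic function of ``seed``.
    """
    _, y, subjects = dataset.matrix()
    return _fold_assignment(y, subjects, k, pairing, substream(seed, "folds"))


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    """Outcome of repeated balanced cross-validation.

    ``records`` has one row per repeat x fold with confusion counts and
    metrics; ``predictions`` one row per test evaluation with the raw
    decision value (useful for leakage and stability checks).
    """

    records: pd.DataFrame
    predictions: pd.DataFrame
    config: dict

    @property
    def accuracy_mean(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.records["accuracy"].std(ddof=1)) if len(self.records) > 1 else 0.0

    @property
    def sensitivity_mean(self) -> float:
        return float(self.records["sensitivity"].mean())

    @property
    def specificity_mean(self) -> float:
        return float(self.records["specificity"].mean())

    def pooled_confusion(self) -> ConfusionCounts:
        r = self.records
        return ConfusionCounts(
            int(r["tp"].sum()), int(r["fp"].sum()), int(r["tn"].sum()), int(r["fn"].sum())
        )

    def summary(self) -> str:
        cfg = self.config
        return (
            f"{cfg['feature_mode']} / {cfg['kernel']} / C={cfg['penalty_c']:g}: "
            f"(ACC, SEN, SEP) = ({self.accuracy_mean:.2f}, {self.sensitivity_mean:.2f}, "
            f"{self.specificity_mean:.2f}) over {len(self.records)} fold evaluations"
        )


def _fold_features(
    X: np.ndarray,
    six: np.ndarray | None,
    feature_mode: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    variance_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the feature transform on the training fold only and apply it."""
    if feature_mode == "all_101":
        return X[train_idx], X[test_idx]
    if feature_mode == "six_params":
        assert six is not None
        return six[train_idx], six[test_idx]
    if feature_mode == "pca":
        model = fit_pca(X[train_idx], variance_fraction=variance_fraction)
        return transform_pca(model, X[train_idx]), transform_pca(model, X[test_idx])
    raise GaitSymError(f"unknown feature mode {feature_mode!r}")


def _run_cv(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    six: np.ndarray | None,
    feature_mode: str,
    kernel: KernelSpec,
    penalty_c: float,
    k: int,
    repeats: int,
    seed: int,
    variance_fraction: float,
    pairing: str,
    standardize: bool,
    tolerance: float,
) -> tuple[list[dict], list[dict]]:
    records, predictions = [], []
    for rep in range(repeats):
        folds = _fold_assignment(y, subjects, k, pairing, substream(seed, "folds", rep))
        for f in range(k):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            F_train, F_test = _fold_features(X, six, feature_mode, train_idx, test_idx, variance_fraction)
            model = train_svm(
                F_train,
                y[train_idx],
                kernel=kernel,
                penalty_c=penalty_c,
                tolerance=tolerance,
                seed=subseed(seed, "smo", rep, f),
                standardize=standardize,
            )
            decision = np.atleast_1d(model.decision_function(F_test))
            y_pred = np.where(decision >= 0, 1, -1)
            c = ConfusionCounts.from_labels(y[test_idx], y_pred)
            m = metrics_from_confusion(c)
            records.append(
                {
                    "repeat": rep,
                    "fold": f,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                }
            )
            for idx, d, p in zip(test_idx, decision, y_pred):
                predictions.append(
                    {
                        "repeat": rep,
                        "fold": f,
                        "index": int(idx),
                        "subject_id": subjects[idx],
                        "y_true": int(y[idx]),
                        "decision": float(d),
                        "y_pred": int(p),
                    }
                )
    return records, predictions


def _prepare(dataset: GaitDataset, aggregate: str) -> GaitDataset:
    if aggregate == "subject_mean":
        return subject_mean_patterns(dataset)
    if aggregate == "per_trial":
        return dataset
    raise GaitSymError(f"unknown aggregate mode {aggregate!r}")


def cross_validate(
    dataset: GaitDataset,
    feature_mode: str = "all_101",
    kernel: KernelSpec = KernelSpec("rbf", sigma=5.0),
    penalty_c: float = 1.0,
    k: int = 6,
    repeats: int = 10,
    seed: int = 0,
    variance_fraction: float = 0.95,
    pairing: str = "subject_paired",
    aggregate: str = "subject_mean",
    standardize: bool = True,
    tolerance: float = 1e-3,
) -> CvResult:
    """Repeated balanced k-fold cross-validation of left/right classification.

    Each repeat reshuffles the fold partition; within a fold, every fitted
    transform (standardization, PCA) and the SVM see training folds only.
    Returns fold-level confusion counts and metric means/SDs.
    """
    if feature_mode not in FEATURE_MODES:
        raise GaitSymError(f"feature_mode must be one of {FEATURE_MODES}, got {feature_mode!r}")
    work = _prepare(dataset, aggregate)
    X, y, subjects = work.matrix()
    six = None
    if feature_mode == "six_params":
        frame = discrete_params_frame(work)
        six = frame[["fz1", "tz1", "fz2", "tz2", "fz3", "tz3"]].to_numpy(dtype=float)
    records, predictions = _run_cv(
        X, y, subjects, six, feature_mode, kernel, penalty_c, k, repeats, seed,
        variance_fraction, pairing, standardize, tolerance,
    )
    config = {
        "feature_mode": feature_mode,
        "kernel": kernel.label(),
        "kernel_kind": kernel.kind,
        "degree": kernel.degree,
        "sigma": kernel.sigma,
        "penalty_c": penalty_c,
        "k": k,
        "repeats": repeats,
        "seed": seed,
        "variance_fraction": variance_fraction,
        "pairing": pairing,
        "aggregate": aggregate,
        "standardize": standardize,
    }
    return CvResult(pd.DataFrame(records), pd.DataFrame(predictions), config)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def grid_search(
    dataset: GaitDataset,
    kernels: Sequence[KernelSpec],
    c_grid: Sequence[float],
    feature_modes: Sequence[str] = FEATURE_MODES,
    **cv_kwargs,
) -> pd.DataFrame:
    """Exhaustive cross-validated evaluation of a configuration grid.

    Rows are ranked by mean accuracy, ties broken by sensitivity, then
    specificity, then smaller C.  ``cv_kwargs`` pass through to
    :func:`cross_validate`.
    """
    if not kernels or not c_grid or not feature_modes:
        raise GaitSymError("grids must be non-empty")
    rows = []
    for mode in feature_modes:
        for kern in kernels:
            for c in c_grid:
                res = cross_validate(dataset, feature_mode=mode, kernel=kern, penalty_c=c, **cv_kwargs)
                rows.append(
                    {
                        "feature_mode": mode,
                        "kernel": kern.label(),
                        "kernel_kind": kern.kind,
                        "degree": kern.degree,
                        "sigma": kern.sigma,
                        "penalty_c": c,
                        "accuracy": res.accuracy_mean,
                        "accuracy_sd": res.accuracy_sd,
                        "sensitivity": res.sensitivity_mean,
                        "specificity": res.specificity_mean,
                    }
                )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["accuracy", "sensitivity", "specificity", "penalty_c", "kernel", "feature_mode"],
        ascending=[False, False, False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def best_per_feature_mode(table: pd.DataFrame) -> pd.DataFrame:
    """The top-ranked configuration for each feature mode."""
    return table.loc[table.groupby("feature_mode")["rank"].idxmin()].sort_values("rank").reset_index(drop=True)


def render_comparison_table(table: pd.DataFrame) -> str:
    """Text rendering of the feature-mode x kernel comparison, '(ACC, SEN, SEP)' style."""
    lines = ["Classifier comparison  (ACC, SEN, SEP)"]
    for mode, sub in table.groupby("feature_mode", sort=True):
        lines.append(f"  {mode}:")
        best = sub.loc[sub.groupby("kernel_kind")["rank"].idxmin()].sort_values("kernel")
        for _, row in best.iterrows():
            lines.append(
                f"    {row['kernel']:<16} C={row['penalty_c']:<8g} "
                f"({row['accuracy']:.2f}, {row['sensitivity']:.2f}, {row['specificity']:.2f})"
            )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# symmetry score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryScore:
    """Classifier-based symmetry summary.

    ``score`` = 1 - 2 * max(mean_accuracy - 0.5, 0): 1 when the classifier
    is at (or below) chance, 0 when separation is perfect.
    ``permutation_p`` tests "symmetric" (chance accuracy) by re-running the
    whole cross-validation with left/right labels swapped within subjects.
    """

    mean_accuracy: float
    score: float
    permutation_p: float
    n_permutations: int
    permuted_accuracies: np.ndarray = field(default_factory=lambda: np.zeros(0), compare=False)


def score_from_accuracy(mean_accuracy: float) -> float:
    """Map mean CV accuracy to the [0, 1] symmetry score."""
    return 1.0 - 2.0 * max(mean_accuracy - 0.5, 0.0)


def symmetry_score(
    dataset: GaitDataset,
    feature_mode: str = "all_101",
    kernel: KernelSpec = KernelSpec("linear"),
    penalty_c: float = 1.0,
    k: int = 6,
    repeats: int = 1,
    n_permutations: int = 99,
    seed: int = 0,
    variance_fraction: float = 0.95,
    pairing: str = "subject_paired",
    aggregate: str = "subject_mean",
    standardize: bool = True,
    tolerance: float = 1e-3,
) -> SymmetryScore:
    """Permutation-calibrated classifier test of gait symmetry.

    The observed mean CV accuracy is compared with the accuracies obtained
    after randomly swapping the left/right labels within each subject
    (which enforces the symmetric null while preserving subject structure):
    ``permutation_p = (1 + #{permuted >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 19:
        warnings.warn(
            f"n_permutations={n_permutations} < 19 cannot resolve p <= 0.05", stacklevel=2
        )
    if feature_mode not in FEATURE_MODES:
        raise GaitSymError(f"feature_mode must be one of {FEATURE_MODES}, got {feature_mode!r}")
    work = _prepare(dataset, aggregate)
    X, y, subjects = work.matrix()
    six = None
    if feature_mode == "six_params":
        frame = discrete_params_frame(work)
        six = frame[["fz1", "tz1", "fz2", "tz2", "fz3", "tz3"]].to_numpy(dtype=float)
    cv_seed = subseed(seed, "cv")

    def accuracy_for(labels: np.ndarray) -> float:
        records, _ = _run_cv(
            X, labels, subjects, six, feature_mode, kernel, penalty_c, k, repeats,
            cv_seed, variance_fraction, pairing, standardize, tolerance,
        )
        return float(np.mean([r["accuracy"] for r in records]))

    observed = accuracy_for(y)
    subj_order = sorted(set(subjects))
    permuted = np.empty(n_permutations)
    for p in range(n_permutations):
        rng = substream(seed, "permutations", p)
        flips = {s: (-1.0 if rng.random() < 0.5 else 1.0) for s in subj_order}
        y_perm = y * np.array([flips[s] for s in subjects])
        permuted[p] = accuracy_for(y_perm)
    p_value = (1.0 + float(np.sum(permuted >= observed))) / (1.0 + n_permutations)
    return SymmetryScore(
        mean_accuracy=observed,
        score=score_from_accuracy(observed),
        permutation_p=p_value,
        n_permutations=n_permutations,
        permuted_accuracies=permuted,
    )
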