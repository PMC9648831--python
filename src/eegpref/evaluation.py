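"""Training and leave-one-subject-out evaluation.

Each fold holds one subject out for test and one for validation and trains
on the rest, so an n-subject cohort yields n*(n-1) folds (every ordered
test/validation pair).  Training runs a fixed number of epochs with no
early stopping; validation accuracy and loss are recorded every epoch and
two checkpoints are kept -- the epoch of maximum validation accuracy and
the epoch of minimum validation loss (earliest epoch on ties).  Test
predictions are median-filtered per trial over the window sequence (7
consecutive 1 s-hop windows = 7 s) before a second confusion matrix is
tabulated.

Note on baseline leakage: the upstream per-subject baseline correction uses
the test subject's own class labels (see :mod:`eegpref.dataset`), exactly
as in the protocol being reproduced.  Fold training itself is strictly
subject-disjoint and audited (:class:`eegpref.errors.LeakageError`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .dataset import POSITIVE, WindowDataset
from .errors import ConfigurationError, EmptyDatasetError, LeakageError
from .features import BAND_NAMES
from .models import ModelConfig, build_model


@dataclass(frozen=True)
class TrainingParams:
    """Optimisation settings (Adam, fixed LR, shuffled mini-batches)."""

    batch_size: int = 128
    learning_rate: float = 2e-4
    max_epochs: int = 300
    shuffle: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("batch_size", "learning_rate", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class Fold:
    test_subject: str
    validation_subject: str
    training_subjects: tuple[str, ...]


def loso_schedule(subject_ids: list[str]) -> list[Fold]:
    """Every ordered (test, validation) pair; n*(n-1) folds."""
    subjects = list(dict.fromkeys(str(s) for s in subject_ids))
    if len(subjects) < 3:
        raise ConfigurationError(
            f"LOSO with a rotating validation subject needs >= 3 subjects, got {len(subjects)}")
    folds = []
    for test in subjects:
        for val in subjects:
            if val == test:
                continue
            train = tuple(s for s in subjects if s not in (test, val))
            folds.append(Fold(test, val, train))
    return folds


def model_inputs(ds: WindowDataset, config: ModelConfig) -> np.ndarray:
    """Extract the input tensor an architecture consumes from the dataset."""
    if config.band is not None:
        b = BAND_NAMES.index(config.band)
        return ds.band_frames[:, b][:, None]
    if config.architecture == "parallel_bands":
        return ds.band_frames
    return ds.merged[:, None]


@dataclass
class TrainArtifacts:
    """Per-epoch curves and the two selected checkpoints."""

    val_accuracy: list[float]
    val_loss: list[float]
    train_loss: list[float]
    checkpoint_by_val_acc: tuple[int, list[np.ndarray]]   # (1-based epoch, weights)
    checkpoint_by_val_loss: tuple[int, list[np.ndarray]]
    trained_subjects: tuple[str, ...] = ()

    def checkpoint(self, criterion: str) -> tuple[int, list[np.ndarray]]:
        if criterion == "max_val_acc":
            return self.checkpoint_by_val_acc
        if criterion == "min_val_loss":
            return self.checkpoint_by_val_loss
        raise ConfigurationError(f"unknown criterion {criterion!r}")


def _evaluate(net: nn.Network, x: np.ndarray, y: np.ndarray,
              batch: int = 512) -> tuple[float, float]:
    """(accuracy, mean cross-entropy) without gradient bookkeeping."""
    losses, correct = [], 0
    for i in range(0, len(y), batch):
        logits = net.logits(x[i:i + batch], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[i:i + batch])
        losses.append(loss * len(y[i:i + batch]))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / len(y), float(np.sum(losses) / len(y))


def train(net: nn.Network, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, params: TrainingParams,
          seed: int = 0, trained_subjects: tuple[str, ...] = ()) -> TrainArtifacts:
    """Fixed-epoch training with per-epoch validation and running-best
    checkpoints (mathematically identical to saving every epoch and
    selecting afterwards, without materialising 300 weight sets)."""
    if len(y_train) == 0:
        raise EmptyDatasetError("empty training set")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy=seed)))
    opt = nn.Adam(net.params(), lr=params.learning_rate,
                  beta1=params.beta1, beta2=params.beta2, eps=params.eps)

    val_acc_curve: list[float] = []
    val_loss_curve: list[float] = []
    train_loss_curve: list[float] = []
    best_acc = (-np.inf, None, None)   # (acc, epoch, weights)
    best_loss = (np.inf, None, None)

    n = len(y_train)
    for epoch in range(1, params.max_epochs + 1):
        order = rng.permutation(n) if params.shuffle else np.arange(n)
        epoch_losses = []
        for i in range(0, n, params.batch_size):
            idx = order[i:i + params.batch_size]
            epoch_losses.append(net.train_step(x_train[idx], y_train[idx], opt))
        train_loss_curve.append(float(np.mean(epoch_losses)))

        acc, loss = _evaluate(net, x_val, y_val)
        val_acc_curve.append(acc)
        val_loss_curve.append(loss)
        if acc > best_acc[0]:
            best_acc = (acc, epoch, net.get_weights())
        if loss < best_loss[0]:
            best_loss = (loss, epoch, net.get_weights())

    return TrainArtifacts(
        val_accuracy=val_acc_curve,
        val_loss=val_loss_curve,
        train_loss=train_loss_curve,
        checkpoint_by_val_acc=(best_acc[1], best_acc[2]),
        checkpoint_by_val_loss=(best_loss[1], best_loss[2]),
        trained_subjects=trained_subjects,
    )


def select_checkpoint(artifacts: TrainArtifacts, criterion: str) -> int:
    """1-based epoch selected by a criterion (earliest epoch on ties)."""
    if criterion == "max_val_acc":
        return int(np.argmax(artifacts.val_accuracy)) + 1
    if criterion == "min_val_loss":
        return int(np.argmin(artifacts.val_loss)) + 1
    raise ConfigurationError(f"unknown criterion {criterion!r}")


def median_filter_labels(labels: np.ndarray, kernel: int = 7) -> np.ndarray:
    """Sliding-majority smoothing of one trial's window-ordered labels.

    Binary median over an odd-length kernel with replicated (edge) padding.
    """
    k = int(kernel)
    if k < 1 or k % 2 == 0:
        raise ConfigurationError(f"median filter kernel must be odd and >= 1, got {kernel}")
    labels = np.asarray(labels)
    if k == 1 or labels.size == 0:
        return labels.copy()
    return ndimage.median_filter(labels, size=k, mode="nearest")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    pos = y_true == POSITIVE
    return ConfusionMatrix(
        tp=int((pos & (y_pred == POSITIVE)).sum()),
        tn=int((~pos & (y_pred != POSITIVE)).sum()),
        fp=int((~pos & (y_pred == POSITIVE)).sum()),
        fn=int((pos & (y_pred != POSITIVE)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

    A ratio with an empty denominator is reported as None (excluded from
    averages) with a warning.
    """
    out: dict[str, float | None] = {}
    out["accuracy"] = (cm.tp + cm.tn) / cm.total if cm.total else None
    if cm.tp + cm.fn:
        out["sensitivity"] = cm.tp / (cm.tp + cm.fn)
    else:
        warnings.warn("no positive samples; sensitivity undefined")
        out["sensitivity"] = None
    if cm.tn + cm.fp:
        out["specificity"] = cm.tn / (cm.tn + cm.fp)
    else:
        warnings.warn("no negative samples; specificity undefined")
        out["specificity"] = None
    return out


@dataclass
class FoldResult:
    fold: Fold
    architecture: str
    checkpoint_epochs: dict[str, int]
    confusions: dict[tuple[str, bool], ConfusionMatrix]  # (criterion, filtered)

    def to_rows(self) -> list[dict]:
        rows = []
        for (criterion, filtered), cm in self.confusions.items():
            row = {
                "architecture": self.architecture,
                "test_subject": self.fold.test_subject,
                "validation_subject": self.fold.validation_subject,
                "criterion": criterion,
                "filtered": filtered,
                "checkpoint_epoch": self.checkpoint_epochs[criterion],
                "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
            }
            row.update(metrics(cm))
            rows.append(row)
        return rows


def _filtered_predictions(test: WindowDataset, y_pred: np.ndarray,
                          kernel: int) -> np.ndarray:
    """Median-filter per trial over the window sequence.

    Filtering runs on the unique (trial, window) positions in window order;
    oversampled duplicates inherit their window's filtered label.  Trial
    boundaries are never crossed.
    """
    out = y_pred.copy()
    for trial in np.unique(test.trial_ids):
        m = test.trial_ids == trial
        widx = test.window_ids[m]
        uniq = np.unique(widx)
        seq = np.empty(uniq.size, dtype=y_pred.dtype)
        for j, wi in enumerate(uniq):
            # duplicates of one window share one prediction by construction
            seq[j] = y_pred[m][widx == wi][0]
        filt = median_filter_labels(seq, kernel)
        lookup = dict(zip(uniq.tolist(), filt.tolist()))
        out[m] = [lookup[wi] for wi in widx]
    return out


def evaluate_fold(net: nn.Network, artifacts: TrainArtifacts,
                  test: WindowDataset, kernel: int = 7,
                  unbalanced_test: bool = False) -> FoldResult:
    """Confusion matrices for both checkpoint criteria, raw and filtered.

    ``unbalanced_test`` drops the oversampled duplicates from the test set
    before tabulating, so metrics reflect the subject's natural class
    balance instead of the balanced one.
    """
    if unbalanced_test:
        test = test.select(~test.augmented)
    test_subjects = set(test.subjects())
    if test_subjects & set(artifacts.trained_subjects):
        raise LeakageError(
            f"test subject(s) {sorted(test_subjects & set(artifacts.trained_subjects))} "
            "appear in the training set")
    x = model_inputs(test, net.config)
    confusions = {}
    epochs = {}
    for criterion in ("max_val_acc", "min_val_loss"):
        epoch, weights = artifacts.checkpoint(criterion)
        net.set_weights(weights)
        epochs[criterion] = epoch
        y_pred = net.predict(x)
        confusions[(criterion, False)] = confusion(test.labels, y_pred)
        y_filt = _filtered_predictions(test, y_pred, kernel)
        confusions[(criterion, True)] = confusion(test.labels, y_filt)
    fold = Fold(test_subject=sorted(test_subjects)[0], validation_subject="",
                training_subjects=artifacts.trained_subjects)
    return FoldResult(fold=fold, architecture=net.name,
                      checkpoint_epochs=epochs, confusions=confusions)


def run_fold(ds: WindowDataset, fold: Fold, config: ModelConfig,
             params: TrainingParams, kernel: int = 7, seed: int = 0
             ) -> tuple[FoldResult, TrainArtifacts]:
    """Train and evaluate one LOSO fold from the prepared dataset."""
    tr_mask = np.isin(ds.subject_ids, fold.training_subjects)
    net = build_model(config, seed=seed)
    art = train(
        net,
        model_inputs(ds.select(tr_mask), config), ds.labels[tr_mask],
        model_inputs(ds.for_subject(fold.validation_subject), config),
        ds.for_subject(fold.validation_subject).labels,
        params, seed=seed, trained_subjects=fold.training_subjects,
    )
    result = evaluate_fold(net, art, ds.for_subject(fold.test_subject), kernel)
    result.fold = fold
    return result, art


def run_loso(ds: WindowDataset, config: ModelConfig, params: TrainingParams,
             kernel: int = 7, master_seed: int = 0,
             folds: list[Fold] | None = None,
             progress: bool = False) -> list[FoldResult]:
    """All n*(n-1) folds (or a supplied subset) for one architecture."""
    folds = folds if folds is not None else loso_schedule(ds.subjects())
    results = []
    for i, fold in enumerate(folds):
        fold_seed = int(np.random.SeedSequence(
            entropy=master_seed, spawn_key=(i,)).generate_state(1)[0] % (2 ** 31))
        res, _ = run_fold(ds, fold, config, params, kernel, seed=fold_seed)
        results.append(res)
        if progress:
            acc = metrics(res.confusions[("max_val_acc", True)])["accuracy"]
            print(f"  fold {i + 1}/{len(folds)} test={fold.test_subject} "
                  f"val={fold.validation_subject} acc={acc:.3f}", flush=True)
    return results


def results_frame(fold_results: list[FoldResult]) -> pd.DataFrame:
    """One row per fold x criterion x filter state."""
    rows = [r for fr in fold_results for r in fr.to_rows()]
    return pd.DataFrame(rows)


def aggregate_report(fold_results: list[FoldResult]) -> pd.DataFrame:
    """Per-subject means, then unweighted mean +- sd across subjects.

    Grouped by architecture x criterion x filter state, mirroring how the
    per-model accuracies are reported (subject means first, then the
    cross-subject mean and standard deviation).
    """
    df = results_frame(fold_results)
    per_subject = (
        df.groupby(["architecture", "criterion", "filtered", "test_subject"],
                   as_index=False)[["accuracy", "sensitivity", "specificity"]]
        .mean()
    )
    agg = (
        per_subject
        .groupby(["architecture", "criterion", "filtered"])[
            ["accuracy", "sensitivity", "specificity"]]
        .agg(["mean", "std"])
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
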