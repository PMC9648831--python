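"""Model-ready dataset assembly.

Order of operations: label windows from the trial's 1-9 preference score
(1-4 negative, 8-9 positive, 5-7 dropped), remove subjects left with a
single class, balance classes per subject by random oversampling with
replacement, then baseline-correct per subject.

Baseline correction maps each subject's class-conditional mean power to
fixed anchors per grid cell and band:

    f' = (f - mean_neg) / (mean_pos - mean_neg)

so after correction every subject's negative-class mean is 0 and
positive-class mean is 1 at every cell, removing per-subject gain/offset
shifts.  The class-conditional means use the subject's own labels --
including when that subject later serves as the held-out test subject.
That is faithful to the evaluation protocol being reproduced but is a
label-leakage concern; reports should state it (see
:mod:`eegpref.evaluation`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateCellError, EmptyDatasetError, ShapeError,
                     SingleClassError)
from .features import merge_band_stack

NEGATIVE, POSITIVE = 0, 1
LABEL_NAMES = {NEGATIVE: "negative", POSITIVE: "positive"}

#: Relative tolerance deciding that class means coincide at a cell.
DEGENERATE_RTOL = 1e-12


def label_from_score(score: int) -> str:
    """Map a 1-9 preference score to 'negative' / 'positive' / 'excluded'."""
    s = int(score)
    if s != score or not 1 <= s <= 9:
        raise ValueError(f"score must be an integer in 1..9, got {score!r}")
    if s <= 4:
        return "negative"
    if s >= 8:
        return "positive"
    return "excluded"


@dataclass
class WindowDataset:
    """Parallel arrays of labelled per-window feature images."""

    band_frames: np.ndarray   # (N, 4, 5, 5)
    labels: np.ndarray        # (N,) int, 0=negative 1=positive
    subject_ids: np.ndarray   # (N,) str
    trial_ids: np.ndarray     # (N,) int
    window_ids: np.ndarray    # (N,) int
    scores: np.ndarray        # (N,) int
    augmented: np.ndarray     # (N,) bool

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.band_frames.shape != (n, 4, 5, 5):
            raise ShapeError(
                f"band_frames shape {self.band_frames.shape} != ({n}, 4, 5, 5)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def merged(self) -> np.ndarray:
        """(N, 10, 10) merged four-band images (derived from band_frames)."""
        return merge_band_stack(self.band_frames)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def select(self, mask_or_idx) -> "WindowDataset":
        return WindowDataset(
            band_frames=self.band_frames[mask_or_idx],
            labels=self.labels[mask_or_idx],
            subject_ids=self.subject_ids[mask_or_idx],
            trial_ids=self.trial_ids[mask_or_idx],
            window_ids=self.window_ids[mask_or_idx],
            scores=self.scores[mask_or_idx],
            augmented=self.augmented[mask_or_idx],
        )

    def for_subject(self, subject_id: str) -> "WindowDataset":
        return self.select(self.subject_ids == subject_id)

    def class_counts(self) -> pd.DataFrame:
        """Per-subject positive/negative window counts."""
        rows = []
        for s in self.subjects():
            m = self.subject_ids == s
            rows.append({
                "subject_id": s,
                "n_positive": int((self.labels[m] == POSITIVE).sum()),
                "n_negative": int((self.labels[m] == NEGATIVE).sum()),
                "n_augmented": int(self.augmented[m].sum()),
            })
        return pd.DataFrame(rows)


def from_labelled_windows(band_frames, scores, subject_ids, trial_ids,
                          window_ids) -> WindowDataset:
    """Build a dataset, dropping windows whose score maps to 'excluded'."""
    scores = np.asarray(scores, dtype=int)
    lab = np.array([label_from_score(s) for s in scores])
    keep = lab != "excluded"
    labels = np.where(lab[keep] == "positive", POSITIVE, NEGATIVE).astype(np.int64)
    return WindowDataset(
        band_frames=np.asarray(band_frames)[keep],
        labels=labels,
        subject_ids=np.asarray(subject_ids, dtype=str)[keep],
        trial_ids=np.asarray(trial_ids, dtype=int)[keep],
        window_ids=np.asarray(window_ids, dtype=int)[keep],
        scores=scores[keep],
        augmented=np.zeros(int(keep.sum()), dtype=bool),
    )


def exclude_single_class_subjects(ds: WindowDataset) -> tuple[WindowDataset, list[str]]:
    """Drop subjects whose retained windows all share one label."""
    excluded = []
    keep = np.ones(len(ds), dtype=bool)
    for s in ds.subjects():
        m = ds.subject_ids == s
        if len(np.unique(ds.labels[m])) < 2:
            excluded.append(s)
            keep[m] = False
    if not keep.any():
        raise EmptyDatasetError("every subject is single-class; nothing to analyse")
    return ds.select(keep), excluded


def balance_by_oversampling(ds: WindowDataset, seed: int = 0) -> WindowDataset:
    """Per subject, duplicate minority-class windows at random until equal.

    Originals are always retained; duplicates are flagged ``augmented``.
    Deterministic in ``seed`` (each subject draws from its own spawned
    stream, so subject order does not matter).
    """
    parts = []
    for si, s in enumerate(ds.subjects()):
        sub = ds.for_subject(s)
        n_pos = int((sub.labels == POSITIVE).sum())
        n_neg = int((sub.labels == NEGATIVE).sum())
        if n_pos == 0 or n_neg == 0:
            raise SingleClassError(f"subject {s} has a single class; exclude it first")
        parts.append(sub)
        deficit = abs(n_pos - n_neg)
        if deficit:
            minority = POSITIVE if n_pos < n_neg else NEGATIVE
            pool = np.flatnonzero(sub.labels == minority)
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence(entropy=seed, spawn_key=(si,))))
            dup = sub.select(rng.choice(pool, size=deficit, replace=True))
            dup.augmented[:] = True
            parts.append(dup)
    return concatenate(parts)


def concatenate(parts: list[WindowDataset]) -> WindowDataset:
    return WindowDataset(
        band_frames=np.concatenate([p.band_frames for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        trial_ids=np.concatenate([p.trial_ids for p in parts]),
        window_ids=np.concatenate([p.window_ids for p in parts]),
        scores=np.concatenate([p.scores for p in parts]),
        augmented=np.concatenate([p.augmented for p in parts]),
    )


@dataclass
class BaselineStats:
    """Class-conditional mean power per subject, grid cell and band."""

    subject_id: str
    mean_pos: np.ndarray  # (4, 5, 5)
    mean_neg: np.ndarray  # (4, 5, 5)

    def degenerate_cells(self) -> np.ndarray:
        """Boolean (4,5,5) mask where the class means coincide."""
        scale = np.maximum(np.maximum(np.abs(self.mean_pos), np.abs(self.mean_neg)), 1.0)
        return np.abs(self.mean_pos - self.mean_neg) < DEGENERATE_RTOL * scale


def baseline_stats(sub: WindowDataset) -> BaselineStats:
    """Class-conditional means over one subject's (balanced) windows."""
    pos = sub.labels == POSITIVE
    neg = sub.labels == NEGATIVE
    if not pos.any() or not neg.any():
        raise SingleClassError(
            f"subject {sub.subjects()} lacks a class; baseline stats undefined")
    sid = sub.subjects()[0]
    return BaselineStats(
        subject_id=sid,
        mean_pos=sub.band_frames[pos].mean(axis=0),
        mean_neg=sub.band_frames[neg].mean(axis=0),
    )


def baseline_correct(sub: WindowDataset, stats: BaselineStats,
                     degenerate_policy: str = "error") -> WindowDataset:
    """Apply f' = (f - mean_neg) / (mean_pos - mean_neg) per cell and band.

    ``degenerate_policy``: 'error' raises if class means coincide at a cell;
    'zero' writes 0 there (with a warning) and corrects the rest.
    """
    bad = stats.degenerate_cells()
    denom = stats.mean_pos - stats.mean_neg
    if bad.any():
        if degenerate_policy == "error":
            raise DegenerateCellError(
                f"{int(bad.sum())} cell(s) have coinciding class means for subject "
                f"{stats.subject_id}; pass degenerate_policy='zero' to zero them")
        if degenerate_policy != "zero":
            raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
        import warnings
        warnings.warn(f"zeroing {int(bad.sum())} degenerate baseline cell(s) "
                      f"for subject {stats.subject_id}")
    safe = np.where(bad, 1.0, denom)
    corrected = (sub.band_frames - stats.mean_neg) / safe
    corrected[:, bad] = 0.0
    return dataclasses.replace(sub, band_frames=corrected)


def apply_baseline(ds: WindowDataset, degenerate_policy: str = "error"
                   ) -> tuple[WindowDataset, dict[str, BaselineStats]]:
    """Baseline-correct every subject with its own statistics."""
    parts, stats = [], {}
    for s in ds.subjects():
        sub = ds.for_subject(s)
        st = baseline_stats(sub)
        stats[s] = st
        parts.append(baseline_correct(sub, st, degenerate_policy))
    return concatenate(parts), stats


def prepare_dataset(band_frames, scores, subject_ids, trial_ids, window_ids,
                    seed: int = 0, degenerate_policy: str = "error"
                    ) -> tuple[WindowDataset, dict]:
    """Full chain: label -> exclude -> balance -> baseline-correct."""
    ds = from_labelled_windows(band_frames, scores, subject_ids, trial_ids, window_ids)
    ds, excluded = exclude_single_class_subjects(ds)
    ds = balance_by_oversampling(ds, seed=seed)
    ds, stats = apply_baseline(ds, degenerate_policy=degenerate_policy)
    info = {"excluded_subjects": excluded, "baseline_stats": stats}
    return ds, info


# ---------------------------------------------------------------------------
# Persistence (uncompressed NPZ; deterministic bytes) + CSV manifest.

def save_dataset(ds: WindowDataset, path) -> None:
    np.savez(
        path,
        band_frames=ds.band_frames.astype(np.float32),
        frames=ds.merged.astype(np.float32),
        labels=ds.labels,
        subject_ids=ds.subject_ids.astype(str),
        trial_ids=ds.trial_ids,
        window_ids=ds.window_ids,
        scores=ds.scores,
        augmented=ds.augmented,
    )


def load_dataset(path) -> WindowDataset:
    with np.load(path, allow_pickle=False) as z:
        return WindowDataset(
            band_frames=z["band_frames"].astype(np.float64),
            labels=z["labels"],
            subject_ids=z["subject_ids"].astype(str),
            trial_ids=z["trial_ids"],
            window_ids=z["window_ids"],
            scores=z["scores"],
            augmented=z["augmented"],
        )
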