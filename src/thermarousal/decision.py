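"""Thresholding, temporal label correction and LOSO evaluation.

The network emits a per-frame probability of non-arousal.  Each test
participant is thresholded at the median of their own predicted
probability track (self-calibration on predictions only — no ground-truth
labels are consulted), then corrected by a majority vote over a 90-second
window: the physiological response to an emotional trigger persists on
the order of 90 s, so at 30 fps each frame's label is replaced by the most
frequent label among the 1350 frames before and after it (2700 in total).
Performance is the macro-average F1 over the two classes,

    F1 = TP / (TP + ½(FP + FN)) × 100,

reported per held-out participant under leave-one-subject-out
cross-validation and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .io_streams import AROUSAL, INVALID, NON_AROUSAL, LabelTrack
from .model import (BLSTMClassifier, ModelConfig, PredictionTrack,
                    WindowedDataset, make_windows, predict, train)


@dataclass(frozen=True)
class CorrectionConfig:
    """Majority-vote window: ``half_window`` frames on each side of the
    target (1350 at 30 fps ⇒ a 90-s, 2700-frame window)."""

    half_window: int = 1350

    def __post_init__(self) -> None:
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")

    @property
    def total_window(self) -> int:
        return 2 * self.half_window


@dataclass
class ConfusionCounts:
    """Per-class confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class FoldResult:
    participant_id: str
    f1_raw: float
    f1_corrected: float
    confusion_raw: dict[int, ConfusionCounts]
    confusion_corrected: dict[int, ConfusionCounts]
    threshold: float
    track: PredictionTrack | None = None


@dataclass
class CVReport:
    """Leave-one-subject-out results: one row per held-out participant."""

    folds: list[FoldResult] = field(default_factory=list)

    @property
    def mean_f1_raw(self) -> float:
        return float(np.mean([f.f1_raw for f in self.folds]))

    @property
    def mean_f1_corrected(self) -> float:
        return float(np.mean([f.f1_corrected for f in self.folds]))

    def to_frame(self) -> pd.DataFrame:
        rows = [(f.participant_id, f.f1_raw, f.f1_corrected)
                for f in self.folds]
        rows.append(("Average", self.mean_f1_raw, self.mean_f1_corrected))
        return pd.DataFrame(
            rows, columns=["participant", "f1_raw", "f1_corrected"])


# ---------------------------------------------------------------------------
# thresholding and correction
# ---------------------------------------------------------------------------

def median_threshold(prob: np.ndarray) -> float:
    """Median of the defined (non-NaN) probabilities — the participant's
    self-calibrated classification cutoff."""
    p = np.asarray(prob, dtype=float)
    defined = np.isfinite(p)
    if not defined.any():
        raise ValueError("no defined probabilities")
    return float(np.median(p[defined]))


def classify(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold probabilities: above → non-arousal (1), below → arousal
    (0); exactly at the threshold → arousal; NaN stays −1."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    p = np.asarray(prob, dtype=float)
    out = np.full(p.shape, INVALID, dtype=int)
    defined = np.isfinite(p)
    out[defined & (p > threshold)] = NON_AROUSAL
    out[defined & (p <= threshold)] = AROUSAL
    return out


def majority_correct(labels: np.ndarray,
                     cfg: CorrectionConfig | None = None) -> np.ndarray:
    """Majority-vote correction over a symmetric frame window.

    Each defined frame takes the most frequent defined label among
    ``[f − half_window, f + half_window]`` (truncated at the sequence
    bounds, −1 frames excluded from the vote); an exact tie keeps the
    original label.  A single pass over the raw labels — the vote is not
    iterated to a fixed point.
    """
    cfg = cfg or CorrectionConfig()
    lab = np.asarray(labels, dtype=int)
    n = lab.size
    out = lab.copy()
    if n == 0 or cfg.half_window == 0:
        return out
    # prefix sums of per-class indicators give each window's counts in O(1)
    c0 = np.concatenate([[0], np.cumsum(lab == AROUSAL)])
    c1 = np.concatenate([[0], np.cumsum(lab == NON_AROUSAL)])
    idx = np.arange(n)
    lo = np.maximum(idx - cfg.half_window, 0)
    hi = np.minimum(idx + cfg.half_window, n - 1)
    n0 = c0[hi + 1] - c0[lo]
    n1 = c1[hi + 1] - c1[lo]
    defined = lab != INVALID
    out[defined & (n0 > n1)] = AROUSAL
    out[defined & (n1 > n0)] = NON_AROUSAL
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def confusion_counts(true: np.ndarray, pred: np.ndarray,
                     positive: int) -> ConfusionCounts:
    t = np.asarray(true, dtype=int)
    p = np.asarray(pred, dtype=int)
    both = (t != INVALID) & (p != INVALID)
    tpos, ppos = t[both] == positive, p[both] == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)), fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)), tn=int(np.sum(~tpos & ~ppos)))


def _f1_from_counts(c: ConfusionCounts, class_absent: bool,
                    predicted_absent: bool) -> float:
    if class_absent:
        # degenerate fold: credit only if the class is also never predicted
        return 100.0 if predicted_absent else 0.0
    denom = c.tp + 0.5 * (c.fp + c.fn)
    return 100.0 * c.tp / denom if denom > 0 else 0.0


def macro_f1(true: np.ndarray, pred: np.ndarray,
             return_counts: bool = False):
    """Macro-average F1 in percent over the two classes.

    Frames where either track is −1 are excluded.  A class absent from
    both the reference and the predictions scores 100 for that class (it
    was never confused); absent from the reference but predicted, 0.
    """
    t = np.asarray(true, dtype=int)
    p = np.asarray(pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label tracks must share one length")
    both = (t != INVALID) & (p != INVALID)
    if not both.any():
        raise ValueError("no frame is defined in both tracks")
    scores, counts = [], {}
    for cls in (AROUSAL, NON_AROUSAL):
        c = confusion_counts(t, p, positive=cls)
        counts[cls] = c
        scores.append(_f1_from_counts(
            c, class_absent=not np.any(t[both] == cls),
            predicted_absent=not np.any(p[both] == cls)))
    macro = float(np.mean(scores))
    return (macro, counts) if return_counts else macro


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def evaluate_participant(model: BLSTMClassifier, features: FeatureMatrix,
                         labels: LabelTrack,
                         participant_id: str = "",
                         ccfg: CorrectionConfig | None = None,
                         keep_track: bool = False) -> FoldResult:
    """Predict, self-threshold, correct and score one held-out participant."""
    ccfg = ccfg or CorrectionConfig()
    track = predict(model, features)
    thr = median_threshold(track.prob)
    track.raw_label = classify(track.prob, thr)
    track.corrected_label = majority_correct(track.raw_label, ccfg)
    f1_raw, cm_raw = macro_f1(labels.labels, track.raw_label,
                              return_counts=True)
    f1_cor, cm_cor = macro_f1(labels.labels, track.corrected_label,
                              return_counts=True)
    return FoldResult(participant_id=participant_id, f1_raw=f1_raw,
                      f1_corrected=f1_cor, confusion_raw=cm_raw,
                      confusion_corrected=cm_cor, threshold=thr,
                      track=track if keep_track else None)


def loso_cv(cohort: list[tuple[str, FeatureMatrix, LabelTrack]],
            cfg: ModelConfig | None = None,
            ccfg: CorrectionConfig | None = None,
            train_stride: int = 1,
            keep_tracks: bool = False) -> CVReport:
    """Leave-one-subject-out cross-validation over a cohort.

    For each participant a model is trained on everyone else's windows and
    applied to the held-out track; the threshold comes from the held-out
    probabilities themselves.  ``train_stride`` thins the training windows
    (window ends every ``train_stride`` frames) for desk-scale runs; the
    held-out participant is always predicted at every frame.  Participants
    whose labelled frames do not contain both classes are skipped with a
    warning.
    """
    cfg = cfg or ModelConfig()
    ccfg = ccfg or CorrectionConfig()
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least two participants")
    datasets: dict[str, WindowedDataset] = {}
    usable = []
    for pid, feats, labs in cohort:
        ds = make_windows(feats, labs, cfg, participant_id=pid)
        if np.unique(ds.targets).size < 2:
            warnings.warn(f"participant {pid!r} lacks both classes; "
                          "fold skipped")
            continue
        if train_stride > 1:
            keep = slice(None, None, train_stride)
            ds = WindowedDataset(windows=ds.windows[keep],
                                 targets=ds.targets[keep],
                                 groups=ds.groups[keep],
                                 frame_index=ds.frame_index[keep])
        datasets[pid] = ds
        usable.append((pid, feats, labs))

    report = CVReport()
    for pid, feats, labs in usable:
        rest = [datasets[q] for q, _, _ in usable if q != pid]
        merged = WindowedDataset(
            windows=np.concatenate([d.windows for d in rest]),
            targets=np.concatenate([d.targets for d in rest]),
            groups=np.concatenate([d.groups for d in rest]),
            frame_index=np.concatenate([d.frame_index for d in rest]))
        model = train(merged, cfg, columns=tuple(feats.columns))
        report.folds.append(evaluate_participant(
            model, feats, labs, participant_id=pid, ccfg=ccfg,
            keep_track=keep_tracks))
    return report
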