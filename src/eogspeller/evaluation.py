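"""Performance evaluation: confusion/ROC, typing speed, information
transfer rate, and the yes-vs-no amplitude-decline statistic.

Feedback sessions are summarized as one point in ROC space (true
positive rate vs false positive rate, "yes" being the positive class);
points above the diagonal mean better-than-chance classification.  The
information transfer rate of the binary paradigm is one bit per
question: presenting a question every 9 s yields 60/9 = 6.7 bits/min.
Longitudinal eye-movement decline is quantified by comparing the
per-trial amplitude ranges of yes vs no trials with a two-sided
Mann-Whitney U test, starred at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .session import SessionRecord
from .signals import amplitude_range_per_trial
from .synthetic import NO, YES


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class ROCPoint:
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0 <= self.tpr <= 1 and 0 <= self.fpr <= 1):
            raise ValueError("TPR and FPR must lie in [0, 1]")

    @property
    def above_diagonal(self) -> bool:
        """True when the point beats the 50% chance diagonal."""
        return self.tpr > self.fpr


def confusion(predicted: Sequence[str], truth: Sequence[str],
              positive: str = YES) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with "yes" as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    labels = set(predicted) | set(truth)
    if not labels <= {YES, NO}:
        raise ValueError(f"labels must be binary yes/no, got {labels}")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p == positive:
            tp += t == positive
            fp += t != positive
        else:
            tn += t != positive
            fn += t == positive
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def roc_point(cm: ConfusionMatrix) -> ROCPoint:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN); requires both classes present."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("undefined rate: a class is absent from the truth")
    return ROCPoint(tpr=cm.tp / (cm.tp + cm.fn), fpr=cm.fp / (cm.fp + cm.tn))


def session_roc(record: SessionRecord) -> ROCPoint:
    """ROC point of one feedback session."""
    preds = [t.predicted_label for t in record.trials]
    truth = [t.true_label for t in record.trials]
    if any(p is None for p in preds) or any(t is None for t in truth):
        raise ValueError("record lacks predictions or true labels")
    return roc_point(confusion(preds, truth))


def typing_speed(record: SessionRecord) -> float:
    """Characters selected per minute over the session duration.

    Characters selected counts selection events: every confirmed letter
    or special character, and each accepted word proposal, as recorded in
    ``n_letters_selected``."""
    if record.duration_s <= 0:
        raise ValueError("session duration must be positive")
    return record.n_letters_selected / record.duration_min


def information_transfer_rate(trial_seconds: float = 9.0) -> float:
    """Bits per minute of the binary paradigm: one bit per question, one
    question every ``trial_seconds`` (9 s -> 6.7 bits/min)."""
    if trial_seconds <= 0:
        raise ValueError("trial_seconds must be positive")
    return 60.0 / trial_seconds


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def amplitude_decline_test(yes_ranges: Sequence[float],
                           no_ranges: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between yes- and no-trial amplitude
    ranges (µV).

    Exact null distribution for small untied samples (min n <= 8), the
    tie-corrected normal approximation otherwise.  Returns (U, p) with U
    the statistic of the first (yes) sample.
    """
    x = np.asarray(yes_ranges, dtype=float)
    y = np.asarray(no_ranges, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def decline_summary(visits: Sequence[tuple[int, object, list[str]]]) -> pd.DataFrame:
    """Per-visit decline table over longitudinal synthetic data.

    ``visits`` is the output of ``generate_longitudinal``: (visit id,
    recording, labels).  Returns one row per visit with the mean yes/no
    amplitude range, the Mann-Whitney U and p, and significance stars.
    """
    rows = []
    for visit, rec, labels in visits:
        ranges = [amplitude_range_per_trial(rec, tid) for tid in rec.trial_ids]
        yes_r = [r for r, l in zip(ranges, labels) if l == YES]
        no_r = [r for r, l in zip(ranges, labels) if l == NO]
        u, p = amplitude_decline_test(yes_r, no_r)
        rows.append({
            "visit": visit,
            "mean_yes_range_uV": float(np.mean(yes_r)),
            "mean_no_range_uV": float(np.mean(no_r)),
            "U": u,
            "p_value": p,
            "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


def evaluation_report(records: Sequence[SessionRecord],
                      path: str | Path | None = None) -> dict:
    """JSON-ready evaluation of a batch of feedback sessions."""
    sessions = []
    for r in records:
        pt = session_roc(r)
        preds = [t.predicted_label for t in r.trials]
        truth = [t.true_label for t in r.trials]
        cm = confusion(preds, truth)
        sessions.append({
            "n_trials": len(r.trials),
            "tpr": pt.tpr, "fpr": pt.fpr,
            "accuracy": cm.accuracy,
            "above_diagonal": pt.above_diagonal,
        })
    report = {"n_sessions": len(sessions), "sessions": sessions}
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report


def plot_roc_space(points: Sequence[ROCPoint], path: str | Path,
                   title: str = "Feedback sessions in ROC space") -> None:
    """Scatter feedback-session ROC points with the chance diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.scatter([p.fpr for p in points], [p.tpr for p in points],
               marker="o", zorder=3)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
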