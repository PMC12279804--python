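"""Epoch-level cleaning and restructuring ahead of decoding.

Stages, in pipeline order: baseline correction, moving-window peak-to-peak
artifact rejection (any channel, 200-ms windows sliding in 50-ms steps,
100 µV threshold by default), subsampling to the effective decoding rate
(every ``factor``-th sample, no anti-alias filtering), and the common trial
floor that makes decoding accuracy comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet, SubjectRuns

__all__ = [
    "RejectionLog",
    "FloorReport",
    "baseline_correct",
    "reject_peak_to_peak",
    "subsample",
    "required_trials",
    "apply_common_floor",
    "preprocess_subject",
]


@dataclass
class RejectionLog:
    """Per-trial outcome of peak-to-peak rejection."""

    kept: np.ndarray           # bool per input trial
    worst_p2p: np.ndarray      # µV per input trial (max over channels/windows)
    worst_channel: list[str]   # channel attaining worst_p2p
    worst_window_ms: np.ndarray  # window start (ms) attaining worst_p2p
    threshold: float

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.kept)),
                "kept": self.kept,
                "worst_p2p_uV": self.worst_p2p,
                "worst_channel": self.worst_channel,
                "worst_window_start_ms": self.worst_window_ms,
            }
        )


@dataclass
class FloorReport:
    """Common-floor subject inclusion: who has enough trials in every run."""

    required_trials: int
    counts: pd.DataFrame            # columns: subject_id, group, run, n_trials
    included: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # subject_id -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s, "included": True, "reason": ""} for s in self.included
        ] + [
            {"subject_id": s, "included": False, "reason": r}
            for s, r in self.excluded.items()
        ]
        return pd.DataFrame(rows)


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - mean)


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    """Window start indices from 0 in `step` increments; the last window is
    anchored at n - win so the epoch is fully covered."""
    starts = list(range(0, n_samples - win + 1, step))
    if starts[-1] != n_samples - win:
        starts.append(n_samples - win)
    return np.array(starts)


def reject_peak_to_peak(
    epochs: EpochSet,
    threshold: float = 100.0,
    win: float = 200.0,
    step: float = 50.0,
) -> tuple[EpochSet, RejectionLog]:
    """Drop trials whose peak-to-peak voltage exceeds `threshold` (µV) in any
    `win`-ms window (sliding by `step` ms) on any channel."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    win_s = int(round(win * epochs.srate / 1000.0))
    step_s = max(int(round(step * epochs.srate / 1000.0)), 1)
    if win_s > epochs.n_samples:
        raise ValueError("window longer than the epoch")
    starts = _window_starts(epochs.n_samples, win_s, step_s)

    # p2p per (trial, channel, window)
    p2p = np.empty((epochs.n_trials, epochs.n_channels, len(starts)))
    for k, s in enumerate(starts):
        seg = epochs.data[:, :, s : s + win_s]
        p2p[:, :, k] = seg.max(axis=2) - seg.min(axis=2)

    flat = p2p.reshape(epochs.n_trials, -1)
    worst = flat.max(axis=1)
    arg = flat.argmax(axis=1)
    ch_idx, win_idx = np.unravel_index(arg, (epochs.n_channels, len(starts)))
    kept = worst <= threshold
    log = RejectionLog(
        kept=kept,
        worst_p2p=worst,
        worst_channel=[epochs.channel_names[i] for i in ch_idx],
        worst_window_ms=epochs.times[starts[win_idx]],
        threshold=float(threshold),
    )
    return epochs.select_trials(np.flatnonzero(kept)), log


def subsample(epochs: EpochSet, factor: int = 2) -> EpochSet:
    """Keep every `factor`-th sample (indices 0, factor, 2*factor, ...).

    Plain striding, no anti-alias filtering: the decoder treats each retained
    timepoint independently, so aliasing of between-sample structure is not a
    concern, and the retained samples keep their original values.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return epochs
    return epochs.copy_with(
        data=epochs.data[:, :, ::factor],
        times=epochs.times[::factor],
        srate=epochs.srate / factor,
    )


def required_trials(n_per_avg: int, n_folds: int) -> int:
    """Minimum kept trials per run for a (trials-per-average, folds) setting."""
    if n_per_avg < 1 or n_folds < 1:
        raise ValueError("n_per_avg and n_folds must be >= 1")
    return n_per_avg * n_folds


def apply_common_floor(
    cohort: list[SubjectRuns], n_per_avg: int, n_folds: int
) -> FloorReport:
    """Decide per-subject inclusion under the common trial floor.

    A subject is included iff every run retains at least
    ``n_per_avg * n_folds`` trials after rejection.  Included subjects are
    decoded on exactly that many trials per run, re-drawn uniformly without
    replacement inside each decoding iteration (see the decoder).
    """
    if not cohort:
        raise ValueError("empty cohort")
    required = required_trials(n_per_avg, n_folds)
    rows = []
    report = FloorReport(required_trials=required, counts=pd.DataFrame())
    for subject in cohort:
        counts = subject.trial_counts()
        for run, n in sorted(counts.items()):
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "run": run,
                    "n_trials": n,
                }
            )
        short = {run: n for run, n in counts.items() if n < required}
        if short:
            worst_run = min(short, key=short.get)
            report.excluded[subject.subject_id] = (
                f"run {worst_run} has {short[worst_run]} < {required} trials"
            )
        else:
            report.included.append(subject.subject_id)
    report.counts = pd.DataFrame(rows)
    return report


def preprocess_subject(
    subject: SubjectRuns,
    baseline: tuple[float, float] = (-200.0, 0.0),
    threshold: float = 100.0,
    win: float = 200.0,
    step: float = 50.0,
    subsample_factor: int = 2,
) -> tuple[SubjectRuns, list[RejectionLog]]:
    """Baseline-correct, reject, and subsample every run of one subject."""
    runs, logs = [], []
    for run in subject.runs:
        run = baseline_correct(run, baseline)
        run, log = reject_peak_to_peak(run, threshold, win, step)
        runs.append(subsample(run, subsample_factor))
        logs.append(log)
    return SubjectRuns(subject.subject_id, subject.group, runs), logs
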