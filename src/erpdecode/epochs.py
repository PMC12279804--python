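"""Epoched EEG containers and on-disk persistence.

The package's central in-memory object is :class:`EpochSet`: one subject's
epoched multichannel EEG (trials x channels x samples, in microvolts) with a
millisecond time axis and per-trial run labels.  Cohorts are lists of
:class:`SubjectRuns`.  Epochs are persisted one subject per HDF5 file with a
CSV manifest per cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "EpochSet",
    "SubjectRuns",
    "write_epochs",
    "read_epochs",
    "write_cohort",
    "read_cohort",
]


@dataclass
class EpochSet:
    """Epoched EEG for one subject, one or more runs.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    times
        Sample times in milliseconds, strictly increasing with constant step
        ``1000 / srate``; the first entry is the epoch start.
    srate
        Sampling rate in Hz.
    channel_names
        One label per channel.
    run_labels
        Per-trial run index (1-based), same length as ``data``.
    subject_id, group
        Subject identifier and group label (e.g. ``"placebo"``/``"study"``).
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_names: list[str]
    run_labels: np.ndarray
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.run_labels = np.asarray(self.run_labels, dtype=int)
        self.channel_names = list(self.channel_names)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if self.times.shape != (n_samples,):
            raise ValueError("times length must equal the sample count")
        if self.run_labels.shape != (n_trials,):
            raise ValueError("run_labels length must equal the trial count")
        if n_samples > 1:
            steps = np.diff(self.times)
            expected = 1000.0 / self.srate
            if np.any(steps <= 0) or not np.allclose(steps, expected, rtol=1e-6):
                raise ValueError(
                    "times must increase in constant steps of 1000/srate ms"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "EpochSet":
        return replace(self, **kwargs)

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return self.copy_with(data=self.data[index], run_labels=self.run_labels[index])

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if hi <= lo:
            raise ValueError(f"empty time window {window}")
        return (self.times >= lo) & (self.times <= hi)


@dataclass
class SubjectRuns:
    """A subject's per-run epochs (one :class:`EpochSet` per run, in run order)."""

    subject_id: str
    group: str
    runs: list[EpochSet] = field(default_factory=list)

    @property
    def run_numbers(self) -> list[int]:
        return [int(r.run_labels[0]) for r in self.runs]

    def trial_counts(self) -> dict[int, int]:
        return {int(r.run_labels[0]): r.n_trials for r in self.runs}


# ---------------------------------------------------------------------------
# HDF5 persistence: /data, /times, /run_labels + attributes
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write one subject's epochs to an HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("run_labels", data=epochs.run_labels)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["group"] = epochs.group
        f.attrs["srate"] = float(epochs.srate)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
    return path


def read_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`.

    Doubles as the import adapter for externally epoched data stored in the
    same layout.
    """
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            srate=float(f.attrs["srate"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            run_labels=f["run_labels"][()],
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
        )


def _merge_runs(subject: SubjectRuns) -> EpochSet:
    first = subject.runs[0]
    data = np.concatenate([r.data for r in subject.runs], axis=0)
    labels = np.concatenate([r.run_labels for r in subject.runs])
    return first.copy_with(
        data=data, run_labels=labels, subject_id=subject.subject_id, group=subject.group
    )


def _split_runs(epochs: EpochSet) -> SubjectRuns:
    runs = []
    for run in sorted(set(epochs.run_labels.tolist())):
        runs.append(epochs.select_trials(epochs.run_labels == run))
    return SubjectRuns(epochs.subject_id, epochs.group, runs)


def write_cohort(cohort: Iterable[SubjectRuns], out_dir: str | Path) -> Path:
    """Write a cohort one-subject-per-file plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "file", "trials_per_run"])
        for subject in cohort:
            fname = f"{subject.subject_id}.h5"
            write_epochs(_merge_runs(subject), out_dir / fname)
            counts = subject.trial_counts()
            per_run = ";".join(f"{r}:{counts[r]}" for r in sorted(counts))
            writer.writerow([subject.subject_id, subject.group, fname, per_run])
    return manifest


def read_cohort(manifest: str | Path) -> list[SubjectRuns]:
    """Load a cohort from its CSV manifest."""
    manifest = Path(manifest)
    cohort: list[SubjectRuns] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            epochs = read_epochs(manifest.parent / row["file"])
            cohort.append(_split_runs(epochs))
    return cohort
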