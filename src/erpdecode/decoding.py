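"""Time-resolved multiclass decoding of epoched ERPs.

For each subject, each decoding iteration draws the floored trial set afresh,
partitions each class's trials into k folds, and averages each fold into one
exemplar (trial-averaged cross-validation).  At every timepoint the feature
vector is the instantaneous voltage across channels; one soft-margin linear
SVM per class is trained one-vs-all on the k-1 training exemplars per class,
and the held-out exemplars are labelled by the argmax of the one-vs-all
decision values (ECOC one-vs-all combination; exact ties go to the lowest
class index and are counted).  Accuracies and per-timepoint confusion
matrices are averaged over folds and iterations.

The three parameter sets of interest are named set1 (10 trials/average,
3 folds), set2 (13, 3) and set3 (10, 4); chance is 1/n_classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochSet, SubjectRuns
from .preprocess import required_trials
from .svm import decision_values, fit_linear_svm_batch

__all__ = [
    "DecodingConfig",
    "PARAMETER_SETS",
    "SubjectDecodingResult",
    "GroupDecodingResult",
    "chance_level",
    "assign_folds",
    "train_one_vs_all",
    "classify",
    "decode_subject",
    "decode_cohort",
    "window_confusion",
    "group_average",
    "write_subject_result",
    "read_subject_result",
]


@dataclass(frozen=True)
class DecodingConfig:
    """Decoding hyper-parameters (defaults mirror parameter set 1)."""

    n_per_avg: int = 10
    n_folds: int = 3
    n_iterations: int = 100
    subsample_factor: int = 2
    n_classes: int = 3
    C: float = 1.0
    zscore_features: bool = False
    seed: int = 0
    parameter_set_name: str = "set1"

    def __post_init__(self) -> None:
        if self.n_per_avg < 1:
            raise ValueError("n_per_avg must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def required_trials(self) -> int:
        return required_trials(self.n_per_avg, self.n_folds)


#: The three named parameter sets: (trials per average, folds).
PARAMETER_SETS: dict[str, DecodingConfig] = {
    "set1": DecodingConfig(n_per_avg=10, n_folds=3, parameter_set_name="set1"),
    "set2": DecodingConfig(n_per_avg=13, n_folds=3, parameter_set_name="set2"),
    "set3": DecodingConfig(n_per_avg=10, n_folds=4, parameter_set_name="set3"),
}


@dataclass
class SubjectDecodingResult:
    """Accuracy time course and confusion tensor for one subject."""

    accuracy: np.ndarray        # (n_times,) proportion correct
    confusion: np.ndarray       # (n_times, n_true, n_pred), rows sum to 1
    times: np.ndarray           # ms
    config: DecodingConfig
    subject_id: str = ""
    group: str = ""
    n_ties: int = 0

    def validate(self) -> None:
        rows = self.confusion.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        diag = np.einsum("tkk->tk", self.confusion).mean(axis=1)
        if not np.allclose(diag, self.accuracy, atol=1e-9):
            raise ValueError("accuracy must equal the confusion diagonal mean")


@dataclass
class GroupDecodingResult:
    """Subjects x timepoints accuracy matrix for one group."""

    accuracies: np.ndarray      # (n_subjects, n_times)
    times: np.ndarray
    group: str
    subject_ids: list[str]
    config: DecodingConfig
    confusion: np.ndarray | None = None  # (n_times, k, k) group mean, optional

    @property
    def chance(self) -> float:
        return chance_level(self.config.n_classes)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)


def chance_level(n_classes: int) -> float:
    """Expected accuracy with no class information: 1/n_classes."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return 1.0 / n_classes


def assign_folds(
    trials: np.ndarray, n_per_avg: int, n_folds: int, rng: np.random.Generator,
    class_name: str = "?",
) -> np.ndarray:
    """Randomly draw and partition one class's trials into averaged exemplars.

    Parameters
    ----------
    trials
        ``(n_trials, ...)`` array of one class's single-trial data.
    rng
        Source of the random draw and partition.

    Returns
    -------
    ``(n_folds, ...)`` array: exemplar f is the arithmetic mean of its
    ``n_per_avg`` assigned trials.  Exactly ``n_per_avg * n_folds`` trials are
    used, each in one exemplar.
    """
    needed = n_per_avg * n_folds
    if trials.shape[0] < needed:
        raise ValueError(
            f"class {class_name}: {trials.shape[0]} trials available but "
            f"{needed} required ({n_per_avg} per average x {n_folds} folds)"
        )
    chosen = rng.choice(trials.shape[0], size=needed, replace=False)
    grouped = trials[chosen].reshape(n_folds, n_per_avg, *trials.shape[1:])
    return grouped.mean(axis=1)


def train_one_vs_all(
    exemplars: np.ndarray, labels: np.ndarray, C: float = 1.0
) -> list[tuple[np.ndarray, float]]:
    """Fit one binary linear SVM per class (class c vs rest).

    ``exemplars`` is ``(n, d)`` feature vectors with integer ``labels``;
    returns per class the decision function as ``(w, b)``.  A degenerate
    all-identical training set still fits (all margins violated equally) but
    is flagged with a warning.
    """
    exemplars = np.asarray(exemplars, dtype=float)
    labels = np.asarray(labels)
    if np.allclose(exemplars, exemplars[0]):
        warnings.warn("degenerate training set: all exemplars identical")
    out = []
    for c in np.unique(labels):
        y = np.where(labels == c, 1.0, -1.0)
        w = fit_linear_svm_batch(exemplars[None], y, C=C)[0]
        out.append((w[:-1], float(w[-1])))
    return out


def classify(
    x: np.ndarray, decision_functions: list[tuple[np.ndarray, float]]
) -> tuple[int, bool]:
    """Combine one-vs-all decision values into a single prediction.

    Returns ``(predicted_class_index, was_tie)``; exact ties break to the
    lowest class index.
    """
    values = np.array([w @ x + b for w, b in decision_functions])
    best = int(np.argmax(values))
    tie = bool(np.sum(values == values[best]) > 1)
    return best, tie


def _stack_class_trials(runs: list[EpochSet]) -> list[np.ndarray]:
    times = runs[0].times
    for r in runs[1:]:
        if r.n_samples != runs[0].n_samples or not np.allclose(r.times, times):
            raise ValueError("runs must share the time axis")
    return [r.data for r in runs]


def decode_subject(
    runs: SubjectRuns | list[EpochSet],
    config: DecodingConfig,
    rng: np.random.Generator | None = None,
    time_range: tuple[float, float] | None = None,
) -> SubjectDecodingResult:
    """Decode run identity per timepoint for one subject.

    Per iteration the floored trials are re-drawn per class, folded into
    averaged exemplars, and each fold serves once as the test set
    (one held-out exemplar per class, so the test design is balanced and the
    overall proportion correct equals the confusion diagonal mean).

    ``time_range`` restricts decoding to timepoints inside the given ms
    window (per-timepoint decoding is independent, so results on the retained
    axis are unchanged).
    """
    if isinstance(runs, SubjectRuns):
        subject_id, group, run_list = runs.subject_id, runs.group, runs.runs
    else:
        run_list = list(runs)
        subject_id = run_list[0].subject_id
        group = run_list[0].group
    if len(run_list) != config.n_classes:
        raise ValueError(
            f"{len(run_list)} runs supplied for {config.n_classes} classes"
        )
    class_trials = _stack_class_trials(run_list)
    for r in run_list:
        if r.n_trials < config.required_trials:
            raise ValueError(
                f"subject {subject_id}: run {int(r.run_labels[0])} has "
                f"{r.n_trials} trials < floor {config.required_trials}"
            )
    times = run_list[0].times
    if time_range is not None:
        mask = (times >= time_range[0]) & (times <= time_range[1])
        if not mask.any():
            raise ValueError(f"time_range {time_range} selects no timepoints")
        class_trials = [d[:, :, mask] for d in class_trials]
        times = times[mask]
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    k, n_iter = config.n_folds, config.n_iterations
    n_cls = config.n_classes
    n_ch = class_trials[0].shape[1]
    n_t = class_trials[0].shape[2]

    # exemplars[it, cls, fold, ch, t]
    exemplars = np.empty((n_iter, n_cls, k, n_ch, n_t))
    for it in range(n_iter):
        for c in range(n_cls):
            exemplars[it, c] = assign_folds(
                class_trials[c], config.n_per_avg, config.n_folds, rng,
                class_name=f"run {c + 1}",
            )

    # Leave-one-exemplar-per-class-out rounds: fold f is the test fold.
    n_train = (k - 1) * n_cls
    train_labels = np.repeat(np.arange(n_cls), k - 1)
    confusion = np.zeros((n_t, n_cls, n_cls))
    n_ties = 0
    for f in range(k):
        train_folds = [g for g in range(k) if g != f]
        # (iter, cls, k-1, ch, t) -> samples ordered class-major
        tr = exemplars[:, :, train_folds]            # (it, cls, k-1, ch, t)
        te = exemplars[:, :, f]                      # (it, cls, ch, t)
        # batch over (iteration, timepoint)
        Xtr = tr.transpose(0, 4, 1, 2, 3).reshape(n_iter * n_t, n_train, n_ch)
        Xte = te.transpose(0, 3, 1, 2).reshape(n_iter * n_t, n_cls, n_ch)
        if config.zscore_features:
            mu = Xtr.mean(axis=1, keepdims=True)
            sd = Xtr.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        dec = np.empty((n_iter * n_t, n_cls, n_cls))  # (batch, test, classifier)
        for c in range(n_cls):
            y = np.where(train_labels == c, 1.0, -1.0)
            w = fit_linear_svm_batch(Xtr, y, C=config.C)
            dec[:, :, c] = decision_values(w, Xte)
        pred = dec.argmax(axis=2)                     # ties -> lowest index
        n_ties += int((np.sum(dec == np.max(dec, axis=2, keepdims=True), axis=2) > 1).sum())
        # accumulate confusion per timepoint
        pred = pred.reshape(n_iter, n_t, n_cls)
        for true_c in range(n_cls):
            p = pred[:, :, true_c]                    # (it, t)
            for pred_c in range(n_cls):
                confusion[:, true_c, pred_c] += (p == pred_c).sum(axis=0)

    confusion /= n_iter * k
    accuracy = np.einsum("tkk->tk", confusion).mean(axis=1)
    result = SubjectDecodingResult(
        accuracy=accuracy,
        confusion=confusion,
        times=times.copy(),
        config=config,
        subject_id=subject_id,
        group=group,
        n_ties=n_ties,
    )
    result.validate()
    return result


def decode_cohort(
    cohort: list[SubjectRuns],
    config: DecodingConfig,
    time_range: tuple[float, float] | None = None,
) -> list[SubjectDecodingResult]:
    """Decode every subject; per-subject RNG streams derive from
    (config.seed, subject index) so results do not depend on execution order."""
    results = []
    for idx, subject in enumerate(cohort):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, idx)))
        results.append(decode_subject(subject, config, rng=rng, time_range=time_range))
    return results


def window_confusion(
    confusion: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Average per-timepoint confusion matrices over a ms window (inclusive)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no decoded timepoints")
    return confusion[mask].mean(axis=0)


def group_average(
    results: list[SubjectDecodingResult], group: str
) -> GroupDecodingResult:
    """Stack per-subject accuracies for one group."""
    members = [r for r in results if r.group == group]
    if not members:
        raise ValueError(f"no subjects in group {group!r}")
    if len(members) == 1:
        warnings.warn(f"group {group!r} has a single subject; mean equals it")
    cfg = members[0].config
    times = members[0].times
    for r in members[1:]:
        if r.config != cfg:
            raise ValueError("subjects decoded with different configs")
        if not np.allclose(r.times, times):
            raise ValueError("subjects decoded on different time axes")
    return GroupDecodingResult(
        accuracies=np.stack([r.accuracy for r in members]),
        times=times.copy(),
        group=group,
        subject_ids=[r.subject_id for r in members],
        config=cfg,
        confusion=np.mean([r.confusion for r in members], axis=0),
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_subject_result(result: SubjectDecodingResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracy", data=result.accuracy)
        f.create_dataset("confusion", data=result.confusion)
        f.create_dataset("times", data=result.times)
        f.attrs["subject_id"] = result.subject_id
        f.attrs["group"] = result.group
        f.attrs["n_ties"] = result.n_ties
        for key in (
            "n_per_avg", "n_folds", "n_iterations", "subsample_factor",
            "n_classes", "C", "zscore_features", "seed", "parameter_set_name",
        ):
            f.attrs[f"config_{key}"] = getattr(result.config, key)
    return path


def read_subject_result(path: str | Path) -> SubjectDecodingResult:
    with h5py.File(path, "r") as f:
        cfg = DecodingConfig(
            n_per_avg=int(f.attrs["config_n_per_avg"]),
            n_folds=int(f.attrs["config_n_folds"]),
            n_iterations=int(f.attrs["config_n_iterations"]),
            subsample_factor=int(f.attrs["config_subsample_factor"]),
            n_classes=int(f.attrs["config_n_classes"]),
            C=float(f.attrs["config_C"]),
            zscore_features=bool(f.attrs["config_zscore_features"]),
            seed=int(f.attrs["config_seed"]),
            parameter_set_name=str(f.attrs["config_parameter_set_name"]),
        )
        return SubjectDecodingResult(
            accuracy=f["accuracy"][()],
            confusion=f["confusion"][()],
            times=f["times"][()],
            config=cfg,
            subject_id=str(f.attrs["subject_id"]),
            group=str(f.attrs["group"]),
            n_ties=int(f.attrs["n_ties"]),
        )


def group_to_frame(result: GroupDecodingResult) -> pd.DataFrame:
    """Subjects x timepoints accuracy matrix as a DataFrame (columns = ms)."""
    return pd.DataFrame(
        result.accuracies,
        index=pd.Index(result.subject_ids, name="subject_id"),
        columns=np.round(result.times, 3),
    )
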