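"""Figures: accuracy time courses with bold significant spans, windowed
confusion heatmaps, bin means with confidence intervals, and a basic
schematic topography.  Every figure writer returns the path of the file and
also writes a CSV twin containing exactly the plotted numbers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decoding import GroupDecodingResult
from .stats import PermTestResult

__all__ = ["plot_accuracy", "plot_confusion", "plot_bins", "plot_topography"]

_GROUP_COLORS = {"placebo": "tab:red", "study": "tab:blue"}


def _csv_twin(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path.with_suffix(".csv"), index=False)


def plot_accuracy(
    groups: list[GroupDecodingResult],
    perm_results: dict[str, PermTestResult] | None = None,
    out: str | Path = "accuracy.png",
    title: str = "",
) -> Path:
    """Group-mean accuracy curves; significant spans are drawn thickened,
    chance as a dashed line, stimulus onset marked at 0 ms."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    twin = {}
    for g in groups:
        color = _GROUP_COLORS.get(g.group, None)
        mean = g.mean_accuracy
        ax.plot(g.times, mean, label=g.group, color=color, lw=1.2)
        twin[f"mean_{g.group}"] = mean
        if perm_results and g.group in perm_results:
            mask = perm_results[g.group].mask
            bold = np.where(mask, mean, np.nan)
            ax.plot(g.times, bold, color=color, lw=3.2)
            twin[f"significant_{g.group}"] = mask.astype(int)
    chance = groups[0].chance
    ax.axhline(chance, color="black", ls="--", lw=1, label=f"chance ({chance:.2f})")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("decoding accuracy (proportion correct)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _csv_twin(out, pd.DataFrame({"time_ms": groups[0].times, **twin}))
    return out


def plot_confusion(
    matrix: np.ndarray,
    window_label: str = "",
    out: str | Path = "confusion.png",
    class_labels: list[str] | None = None,
) -> Path:
    """Heatmap of a windowed confusion matrix (true = x-axis, predicted =
    y-axis, cells annotated to two decimals, units proportion correct)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("confusion matrix must be square")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("confusion rows must sum to 1")
    k = matrix.shape[0]
    labels = class_labels or [f"run {i + 1}" for i in range(k)]
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3.6))
    # display[pred, true]: predicted on y, true on x
    display = matrix.T
    im = ax.imshow(display, vmin=0, vmax=1, cmap="viridis", origin="upper")
    for true_i in range(k):
        for pred_i in range(k):
            val = matrix[true_i, pred_i]
            ax.text(
                true_i, pred_i, f"{val:.2f}", ha="center", va="center",
                color="white" if val < 0.6 else "black", fontsize=9,
            )
    ax.set_xticks(range(k), labels)
    ax.set_yticks(range(k), labels)
    ax.set_xlabel("true label")
    ax.set_ylabel("predicted label")
    if window_label:
        ax.set_title(window_label)
    fig.colorbar(im, ax=ax, label="proportion")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    frame = pd.DataFrame(matrix, columns=[f"pred_{c}" for c in labels])
    frame.insert(0, "true", labels)
    _csv_twin(out, frame)
    return out


def plot_bins(
    table: pd.DataFrame, out: str | Path = "bins.png", ci: float = 0.95
) -> Path:
    """Mean bin accuracies per condition with normal-approximation CIs."""
    from scipy import stats as sps

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    z = sps.norm.ppf(0.5 + ci / 2)
    agg = (
        table.groupby(["condition", "bin_start"])["mean_accuracy"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    for cond, sub in agg.groupby("condition"):
        centers = sub["bin_start"] + 25.0
        ax.errorbar(
            centers, sub["mean"], yerr=z * sub["sem"], label=cond,
            color=_GROUP_COLORS.get(cond), marker="o", capsize=3,
        )
    ax.set_xlabel("time bin centre (ms)")
    ax.set_ylabel("mean decoding accuracy")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _csv_twin(out, agg)
    return out


def plot_topography(
    weights: np.ndarray,
    channel_names: list[str],
    out: str | Path = "topography.png",
    title: str = "",
) -> Path:
    """Schematic scalp map of per-channel weights (stylised layout, not a
    measured montage)."""
    from .simulate import channel_positions

    pos = channel_positions(channel_names)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=weights, s=250, cmap="RdBu_r",
                    vmin=-np.abs(weights).max(), vmax=np.abs(weights).max())
    for (x, y), name in zip(pos, channel_names):
        ax.text(x, y, name, ha="center", va="center", fontsize=5)
    circle = plt.Circle((0, 0), 1.05, fill=False, color="k", lw=1)
    ax.add_patch(circle)
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _csv_twin(out, pd.DataFrame({"channel": channel_names, "weight": weights}))
    return out
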