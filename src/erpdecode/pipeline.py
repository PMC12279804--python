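"""End-to-end orchestration: simulate -> preprocess -> decode (per parameter
set) -> inference -> figures, with a reproducibility manifest.

The run manifest records the config snapshot, master seed, package version,
per-stage completion timestamps and a SHA-256 hash of every output file; a
content hash over the sorted file hashes identifies the run, and re-running
with the same config and seed reproduces it exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import (
    PARAMETER_SETS,
    DecodingConfig,
    decode_cohort,
    group_average,
    group_to_frame,
    window_confusion,
    write_subject_result,
)
from .epochs import SubjectRuns, write_cohort
from .plotting import plot_accuracy, plot_bins, plot_confusion
from .preprocess import apply_common_floor, preprocess_subject
from .simulate import SynthConfig, load_synth_config, simulate_cohort
from .stats import (
    bin_accuracies,
    mixed_anova,
    perm_ttest_vs_chance,
    posthoc_all_bins,
    significant_intervals,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

#: Confusion-matrix summary windows (ms): the P2 and P3 peaks.
CONFUSION_WINDOWS = {"P2_210-260ms": (210.0, 260.0), "P3_450-550ms": (450.0, 550.0)}


class PipelineConfig:
    """Validated nested configuration with sections synth / preprocessing /
    decoding / inference / plotting."""

    _SECTIONS = ("synth", "preprocessing", "decoding", "inference", "plotting")

    def __init__(self, raw: dict):
        unknown = set(raw) - set(self._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.synth: SynthConfig = load_synth_config(raw.get("synth", {}) or {})
        pp = dict(raw.get("preprocessing", {}) or {})
        self.baseline = tuple(pp.pop("baseline", (-200.0, 0.0)))
        self.threshold = float(pp.pop("threshold", 100.0))
        self.win = float(pp.pop("win", 200.0))
        self.step = float(pp.pop("step", 50.0))
        if pp:
            raise ValueError(f"unknown preprocessing keys: {sorted(pp)}")
        dec = dict(raw.get("decoding", {}) or {})
        sets = dec.pop("parameter_sets", ["set1"])
        for s in sets:
            if s not in PARAMETER_SETS:
                raise ValueError(
                    f"invalid parameter_set name {s!r}; choose from "
                    f"{sorted(PARAMETER_SETS)}"
                )
        self.parameter_sets = list(sets)
        self.n_iterations = int(dec.pop("n_iterations", 100))
        self.subsample_factor = int(dec.pop("subsample_factor", 2))
        self.decode_seed = int(dec.pop("seed", 0))
        if dec:
            raise ValueError(f"unknown decoding keys: {sorted(dec)}")
        inf = dict(raw.get("inference", {}) or {})
        self.n_perm = int(inf.pop("n_perm", 10_000))
        self.alpha = float(inf.pop("alpha", 0.05))
        self.tail = str(inf.pop("tail", "upper"))
        if inf:
            raise ValueError(f"unknown inference keys: {sorted(inf)}")
        self.plotting = dict(raw.get("plotting", {}) or {})
        self.raw = raw

    def decoding_config(self, set_name: str) -> DecodingConfig:
        base = PARAMETER_SETS[set_name]
        return replace(
            base,
            n_iterations=self.n_iterations,
            subsample_factor=self.subsample_factor,
            seed=self.decode_seed,
        )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)
    return PipelineConfig(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig | str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
    make_figures: bool = True,
) -> dict:
    """Run all stages and return the manifest (also written as JSON).

    ``seed`` overrides both the synthesis seed and the decoding seed, making
    it the single master seed of the run.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    if seed is not None:
        config.synth = replace(config.synth, seed=int(seed))
        config.decode_seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    outputs: list[Path] = []

    def stage_done(name: str) -> None:
        stages.append({"stage": name, "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")})

    # 1. simulate
    cohort = simulate_cohort(config.synth)
    manifest_csv = write_cohort(cohort, out / "epochs")
    outputs.append(manifest_csv)
    outputs.extend(sorted((out / "epochs").glob("*.h5")))
    stage_done("simulate")

    # 2. preprocess
    clean: list[SubjectRuns] = []
    rej_rows = []
    for subject in cohort:
        cleaned, logs = preprocess_subject(
            subject,
            baseline=config.baseline,
            threshold=config.threshold,
            win=config.win,
            step=config.step,
            subsample_factor=config.subsample_factor,
        )
        clean.append(cleaned)
        for run, log in zip(cleaned.run_numbers, logs):
            rej_rows.append(
                {
                    "subject_id": subject.subject_id,
                    "run": run,
                    "kept": log.n_kept,
                    "rejected": log.n_rejected,
                }
            )
    rej_path = out / "rejection_summary.csv"
    pd.DataFrame(rej_rows).to_csv(rej_path, index=False)
    outputs.append(rej_path)
    stage_done("preprocess")

    # 3. decode each parameter set + inference
    all_groups = []
    for set_name in config.parameter_sets:
        dcfg = config.decoding_config(set_name)
        floor = apply_common_floor(clean, dcfg.n_per_avg, dcfg.n_folds)
        floor_path = out / f"floor_{set_name}.csv"
        floor.to_frame().to_csv(floor_path, index=False)
        outputs.append(floor_path)
        included = [s for s in clean if s.subject_id in floor.included]
        results = decode_cohort(included, dcfg)
        set_dir = out / f"decoding_{set_name}"
        for r in results:
            outputs.append(write_subject_result(r, set_dir / f"{r.subject_id}.h5"))
        groups = {}
        for group_name in config.synth.groups:
            if not any(r.group == group_name for r in results):
                continue
            g = group_average(results, group_name)
            groups[group_name] = g
            all_groups.append(g)
            acc_path = set_dir / f"accuracy_{group_name}.csv"
            group_to_frame(g).to_csv(acc_path)
            outputs.append(acc_path)
        # permutation inference per group
        perm = {
            name: perm_ttest_vs_chance(
                g, n_perm=config.n_perm, alpha=config.alpha, tail=config.tail,
                rng=np.random.default_rng(
                    np.random.SeedSequence(
                        (config.decode_seed, sum(set_name.encode()))
                    )
                ),
            )
            for name, g in groups.items()
        }
        interval_rows = []
        for name, res in perm.items():
            for iv in significant_intervals(res):
                interval_rows.append(
                    {
                        "group": name,
                        "start_ms": iv.start_ms,
                        "end_ms": iv.end_ms,
                        "n_samples": iv.n_samples,
                        "short": iv.short,
                    }
                )
        iv_path = set_dir / "significant_intervals.csv"
        pd.DataFrame(
            interval_rows, columns=["group", "start_ms", "end_ms", "n_samples", "short"]
        ).to_csv(iv_path, index=False)
        outputs.append(iv_path)

        if make_figures:
            outputs.append(
                plot_accuracy(
                    list(groups.values()), perm, set_dir / "accuracy.png",
                    title=f"{set_name}: 3-run decoding",
                )
            )
            outputs.append((set_dir / "accuracy.csv"))
            for name, g in groups.items():
                for label, window in CONFUSION_WINDOWS.items():
                    mat = window_confusion(g.confusion, g.times, window)
                    p = plot_confusion(
                        mat, f"{set_name} {name} {label}",
                        set_dir / f"confusion_{name}_{label}.png",
                    )
                    outputs.extend([p, p.with_suffix(".csv")])
        stage_done(f"decode_{set_name}")

    # 4. bin table, ANOVA, post-hoc
    table = bin_accuracies(all_groups)
    table_path = out / "bin_accuracies.csv"
    table.to_csv(table_path, index=False)
    outputs.append(table_path)
    anova = mixed_anova(table)
    anova.posthoc = posthoc_all_bins(table)
    anova_path = out / "anova_effects.csv"
    anova.effects.to_csv(anova_path, index=False)
    posthoc_path = out / "posthoc_bins.csv"
    anova.posthoc.to_csv(posthoc_path, index=False)
    outputs.extend([anova_path, posthoc_path])
    if make_figures:
        p = plot_bins(table, out / "bin_means.png")
        outputs.extend([p, p.with_suffix(".csv")])
    stage_done("inference")

    # 5. manifest
    file_hashes = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs)) if p.exists()
    }
    content = hashlib.sha256(
        json.dumps(file_hashes, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "master_seed": config.synth.seed,
        "parameter_sets": config.parameter_sets,
        "config": _config_snapshot(config),
        "stages": stages,
        "files": file_hashes,
        "content_hash": content,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    synth = asdict(config.synth)
    for comp in synth["components"]:
        comp["topography"] = np.asarray(comp["topography"]).round(6).tolist()
    return {
        "synth": synth,
        "preprocessing": {
            "baseline": list(config.baseline),
            "threshold": config.threshold,
            "win": config.win,
            "step": config.step,
        },
        "decoding": {
            "parameter_sets": config.parameter_sets,
            "n_iterations": config.n_iterations,
            "subsample_factor": config.subsample_factor,
            "seed": config.decode_seed,
        },
        "inference": {
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "tail": config.tail,
        },
    }
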