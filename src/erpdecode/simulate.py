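"""Synthetic ERP cohort generator.

Emulates a three-run visual oddball session: each subject contributes three
runs of target-locked epochs (trials x channels x samples, microvolts,
-200..800 ms at 256 Hz by default).  Epochs are sums of Gaussian-shaped ERP
components (P1, N1, P2, N2, P3) with schematic scalp topographies, modulated
per run and group by multiplicative gain rules, plus realistic noise: 1/f
(pink) background, an ongoing alpha oscillation, white sensor noise, and
trial-to-trial amplitude and latency jitter.

The default modulation rules encode the study condition the analysis is built
to detect: P2 and P3 amplitude grow across runs in the placebo group only
(with a larger step from run 1 to run 2 than from run 2 to run 3), while the
study group is flat.  With those rules, run identity is decodable from the
scalp pattern after ~200 ms in the placebo group and nowhere in the study
group; the pre-stimulus baseline carries no class information by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .epochs import EpochSet, SubjectRuns

__all__ = [
    "ComponentSpec",
    "ModulationRule",
    "NoiseSpec",
    "SynthConfig",
    "CHANNELS_30",
    "gaussian_topography",
    "default_components",
    "default_rules",
    "component_waveform",
    "simulate_subject",
    "simulate_cohort",
    "load_synth_config",
]

# Schematic 30-channel layout (extended 10/20 names; 2-D positions are a
# stylised head projection, x = right, y = anterior, not measured geometry).
CHANNELS_30: list[str] = [
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "POz",
    "O1", "Oz", "O2",
]

_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.90), "Fpz": (0.0, 0.95), "Fp2": (0.31, 0.90),
    "F7": (-0.80, 0.55), "F3": (-0.40, 0.55), "Fz": (0.0, 0.55),
    "F4": (0.40, 0.55), "F8": (0.80, 0.55),
    "FC5": (-0.60, 0.30), "FC1": (-0.25, 0.30), "FC2": (0.25, 0.30),
    "FC6": (0.60, 0.30),
    "T7": (-0.85, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "T8": (0.85, 0.0),
    "CP5": (-0.60, -0.30), "CP1": (-0.25, -0.30), "CP2": (0.25, -0.30),
    "CP6": (0.60, -0.30),
    "P7": (-0.80, -0.55), "P3": (-0.40, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.40, -0.55), "P8": (0.80, -0.55),
    "POz": (0.0, -0.80),
    "O1": (-0.31, -0.90), "Oz": (0.0, -0.95), "O2": (0.31, -0.90),
}


def channel_positions(channel_names: Sequence[str]) -> np.ndarray:
    """Schematic 2-D positions for the given channel labels."""
    return np.array([_POSITIONS[c] for c in channel_names])


def gaussian_topography(
    channel_names: Sequence[str], peak_channel: str, spatial_sd: float = 0.5
) -> np.ndarray:
    """Per-channel weights decaying with schematic distance from a peak channel.

    The weight at the peak channel is exactly 1; all weights are in [0, 1].
    """
    pos = channel_positions(channel_names)
    peak = np.array(_POSITIONS[peak_channel])
    d2 = np.sum((pos - peak) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * spatial_sd**2))


@dataclass
class ComponentSpec:
    """One ERP component: a Gaussian temporal kernel times a scalp topography.

    amplitude is the signed peak in microvolts at the topography's unit-weight
    channel; latency/width are the kernel's mean/SD in ms.
    """

    name: str
    latency: float
    width: float
    amplitude: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"component {self.name}: width must be > 0")
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.ndim != 1:
            raise ValueError("topography must be a per-channel vector")
        if np.any(np.abs(self.topography) > 1 + 1e-12):
            raise ValueError("topography weights must lie in [-1, 1]")


@dataclass
class ModulationRule:
    """Per-run multiplicative gain for one component in one group."""

    group: str
    component: str
    multipliers: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.multipliers = tuple(float(m) for m in self.multipliers)
        if len(self.multipliers) != 3:
            raise ValueError("multipliers must have one entry per run (3)")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be > 0")


@dataclass
class NoiseSpec:
    """Noise model for one epoch: 1/f background + alpha + white sensor noise,
    and per-trial amplitude/latency jitter of the components.

    The 1/f background is spatially *correlated*: neighbouring channels share
    their ongoing activity with a Gaussian correlation profile over the
    schematic scalp distance (``spatial_scale``), mimicking the smooth
    spatial structure volume conduction imposes on ongoing EEG, with exactly
    ``pink_sd`` RMS on every channel.  The alpha oscillation has a fixed
    posterior topography and a random phase per trial.  Only the sensor
    (white) noise is independent across channels.
    """

    pink_sd: float = 2.5        # µV, 1/f ongoing background per channel (RMS)
    alpha_amp: float = 3.0      # µV, ongoing alpha oscillation amplitude
    alpha_freq: float = 10.0    # Hz
    white_sd: float = 2.0       # µV, independent sensor noise
    amp_jitter_sd: float = 0.15  # unitless multiplicative SD per trial/component
    lat_jitter_sd: float = 15.0  # ms per trial/component
    spatial_scale: float = 0.45  # background spatial correlation scale
    alpha_peak_channel: str = "POz"  # posterior alpha focus
    alpha_spatial_sd: float = 0.6

    def __post_init__(self) -> None:
        for name in ("pink_sd", "alpha_amp", "white_sd", "amp_jitter_sd", "lat_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spatial_scale <= 0:
            raise ValueError("spatial_scale must be > 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All noise and jitter off (deterministic epochs)."""
        return cls(0.0, 0.0, 10.0, 0.0, 0.0, 0.0)


def default_components(channel_names: Sequence[str] | None = None) -> list[ComponentSpec]:
    """The default oddball target component set.

    P1/N1 are early visual components over occipital sites, P2 an anterior
    positivity (~230 ms), N2 a frontocentral negativity (~140 ms) and P3 a
    broad posterior-midline positivity centred near 450 ms whose kernel spans
    roughly 350-550 ms.
    """
    ch = list(channel_names) if channel_names is not None else CHANNELS_30
    mk = lambda peak, sd: gaussian_topography(ch, peak, sd)
    return [
        ComponentSpec("P1", latency=100.0, width=12.0, amplitude=3.0, topography=mk("Oz", 0.45)),
        ComponentSpec("N1", latency=75.0, width=12.0, amplitude=-2.0, topography=mk("Oz", 0.45)),
        ComponentSpec("N2", latency=140.0, width=18.0, amplitude=-3.0, topography=mk("Cz", 0.5)),
        ComponentSpec("P2", latency=230.0, width=25.0, amplitude=5.0, topography=mk("Fz", 0.5)),
        ComponentSpec("P3", latency=450.0, width=80.0, amplitude=10.0, topography=mk("Pz", 0.6)),
    ]


def default_rules() -> list[ModulationRule]:
    """Placebo-only run-increasing P2/P3 gain (larger step run1->2 than run2->3)."""
    return [
        ModulationRule("placebo", "P2", (1.0, 1.50, 1.65)),
        ModulationRule("placebo", "P3", (1.0, 1.30, 1.45)),
    ]


@dataclass
class SynthConfig:
    """Cohort-level generator settings; the defaults are the study conditions."""

    n_channels: int = 30
    srate: float = 256.0
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    components: list[ComponentSpec] = field(default_factory=default_components)
    rules: list[ModulationRule] = field(default_factory=default_rules)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    trials_per_run: int = 48
    n_runs: int = 3
    n_subjects_per_group: int = 12
    groups: tuple[str, str] = ("placebo", "study")
    channel_names: list[str] = field(default_factory=lambda: list(CHANNELS_30))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(self.channel_names):
            raise ValueError("n_channels must match channel_names length")
        span = self.epoch_window[1] - self.epoch_window[0]
        n = span * self.srate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch span x srate must give an integer sample count")
        if self.trials_per_run < 1:
            raise ValueError("trials_per_run must be >= 1")
        for rule in self.rules:
            if rule.group not in self.groups:
                raise ValueError(f"rule references unknown group {rule.group!r}")
            if rule.component not in {c.name for c in self.components}:
                raise ValueError(f"rule references unknown component {rule.component!r}")

    @property
    def n_samples(self) -> int:
        span = self.epoch_window[1] - self.epoch_window[0]
        return int(round(span * self.srate / 1000.0))

    @property
    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) * 1000.0 / self.srate

    def with_flat_rules(self) -> "SynthConfig":
        """A null copy: no run modulation in either group (runs exchangeable)."""
        return replace(self, rules=[])

    def multiplier(self, group: str, component: str, run: int) -> float:
        """Gain for a component in a given group and run (1-based run index)."""
        for rule in self.rules:
            if rule.group == group and rule.component == component:
                return rule.multipliers[run - 1]
        return 1.0


# ---------------------------------------------------------------------------
# Waveform and epoch generation
# ---------------------------------------------------------------------------

def component_waveform(spec: ComponentSpec, times: np.ndarray) -> np.ndarray:
    """Channels x samples signal of one component over the given time axis.

    Outer product of the topography and a Gaussian kernel
    ``A * exp(-(t - mu)^2 / (2 sigma^2))``, hard-truncated to zero beyond
    ``|t - mu| > 4 sigma`` so components peaking after stimulus onset leave
    the pre-stimulus baseline exactly clean.
    """
    times = np.asarray(times, dtype=float)
    z = (times - spec.latency) / spec.width
    kernel = np.where(np.abs(z) <= 4.0, np.exp(-0.5 * z**2), 0.0)
    return spec.amplitude * np.outer(spec.topography, kernel)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], srate: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance per series."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = np.fft.fftfreq(n, d=1.0 / srate)
    h = np.zeros(n)
    nz = freqs != 0
    h[nz] = 1.0 / np.sqrt(np.abs(freqs[nz]))
    h /= np.sqrt(np.mean(h**2))  # unit output variance for unit input
    spec = np.fft.fft(white, axis=-1) * h
    return np.fft.ifft(spec, axis=-1).real


def _noise_mixing(config: SynthConfig) -> np.ndarray:
    """Cholesky factor of the background's smooth spatial correlation.

    Channel correlation decays as a Gaussian of schematic scalp distance
    with scale ``spatial_scale``; the diagonal is exactly 1, so every channel
    keeps RMS ``pink_sd`` after mixing."""
    pos = channel_positions(config.channel_names)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    corr = np.exp(-d2 / (2.0 * config.noise.spatial_scale**2))
    corr += 1e-9 * np.eye(len(pos))
    return np.linalg.cholesky(corr)


def _simulate_run(
    config: SynthConfig,
    group: str,
    run: int,
    rng: np.random.Generator,
    mixing: np.ndarray | None = None,
) -> np.ndarray:
    times = config.times
    n_tr, n_ch, n_s = config.trials_per_run, config.n_channels, config.n_samples
    noise = config.noise
    data = np.zeros((n_tr, n_ch, n_s))

    for comp in config.components:
        gain = config.multiplier(group, comp.name, run)
        amp_j = rng.normal(0.0, noise.amp_jitter_sd, size=n_tr)
        lat_j = rng.normal(0.0, noise.lat_jitter_sd, size=n_tr)
        for t in range(n_tr):
            jittered = replace(
                comp,
                amplitude=comp.amplitude * gain * (1.0 + amp_j[t]),
                latency=comp.latency + lat_j[t],
            )
            data[t] += component_waveform(jittered, times)

    if noise.pink_sd > 0:
        if mixing is None:
            mixing = _noise_mixing(config)
        sources = _pink_noise(rng, (n_tr, n_ch, n_s), config.srate)
        data += noise.pink_sd * np.einsum("ck,tks->tcs", mixing, sources)
    if noise.alpha_amp > 0:
        topo = gaussian_topography(
            config.channel_names, noise.alpha_peak_channel, noise.alpha_spatial_sd
        )
        phase = rng.uniform(0.0, 2 * np.pi, size=n_tr)
        osc = np.sin(2 * np.pi * noise.alpha_freq * times[None, :] / 1000.0 + phase[:, None])
        data += noise.alpha_amp * topo[None, :, None] * osc[:, None, :]
    if noise.white_sd > 0:
        data += rng.normal(0.0, noise.white_sd, size=(n_tr, n_ch, n_s))
    return data


def simulate_subject(
    config: SynthConfig, group: str, subject_seed: int, subject_id: str | None = None
) -> SubjectRuns:
    """Generate one subject's runs; a pure function of (config, group, subject_seed)."""
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}; declared groups: {config.groups}")
    rng = np.random.default_rng(np.random.SeedSequence(int(subject_seed)))
    subject_id = subject_id or f"{group}_{subject_seed}"
    mixing = _noise_mixing(config) if config.noise.pink_sd > 0 else None
    runs = []
    for run in range(1, config.n_runs + 1):
        data = _simulate_run(config, group, run, rng, mixing=mixing)
        runs.append(
            EpochSet(
                data=data,
                times=config.times,
                srate=config.srate,
                channel_names=config.channel_names,
                run_labels=np.full(config.trials_per_run, run),
                subject_id=subject_id,
                group=group,
            )
        )
    return SubjectRuns(subject_id, group, runs)


def simulate_cohort(config: SynthConfig) -> list[SubjectRuns]:
    """Generate both groups; subject seeds derive deterministically from config.seed."""
    if config.n_subjects_per_group < 1:
        raise ValueError("n_subjects_per_group must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_subjects_per_group * len(config.groups)
    seeds = ss.generate_state(n_total, dtype=np.uint32)
    cohort: list[SubjectRuns] = []
    i = 0
    for group in config.groups:
        for j in range(config.n_subjects_per_group):
            cohort.append(
                simulate_subject(config, group, int(seeds[i]), f"{group}_{j + 1:02d}")
            )
            i += 1
    return cohort


# ---------------------------------------------------------------------------
# Config file loading (nested YAML, keys as field names)
# ---------------------------------------------------------------------------

def _build_components(entries: list[dict], channel_names: Sequence[str]) -> list[ComponentSpec]:
    comps = []
    for e in entries:
        e = dict(e)
        if "topography" in e:
            topo = np.asarray(e.pop("topography"), dtype=float)
        else:
            topo = gaussian_topography(
                channel_names, e.pop("peak_channel"), e.pop("spatial_sd", 0.5)
            )
        comps.append(ComponentSpec(topography=topo, **e))
    return comps


def load_synth_config(source: str | dict) -> SynthConfig:
    """Build a SynthConfig from a YAML file path or an already-parsed mapping."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = raw.get("synth", raw)
    kwargs = dict(raw)
    channel_names = kwargs.get("channel_names", list(CHANNELS_30))
    if "epoch_window" in kwargs:
        kwargs["epoch_window"] = tuple(kwargs["epoch_window"])
    if "components" in kwargs:
        kwargs["components"] = _build_components(kwargs["components"], channel_names)
    if "rules" in kwargs:
        kwargs["rules"] = [ModulationRule(**r) for r in kwargs["rules"]]
    if "noise" in kwargs:
        kwargs["noise"] = NoiseSpec(**kwargs["noise"])
    unknown = set(kwargs) - set(SynthConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
    return SynthConfig(**kwargs)
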