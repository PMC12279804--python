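"""Group-level inference on decoding accuracy time courses.

* One-sample permutation t-test against chance with max-statistic (tmax)
  family-wise error correction: subject-level sign flips of
  (accuracy - chance) are shared across timepoints, and each timepoint's
  corrected p is the proportion of permutation maxima at least as large as
  its observed t.
* Extraction of maximal runs of consecutive significant timepoints.
* 50-ms bin averaging of accuracies over 200-700 ms (ten bins).
* Split-plot ("mixed") ANOVA of bin accuracies with between factors
  condition (placebo/study) and parameter set (set1-3) and the 10-level
  within factor time, with Greenhouse-Geisser corrected p-values and partial
  eta squared.
* Per-bin post-hoc placebo-vs-study contrast with pooled-SD Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import GroupDecodingResult, chance_level

__all__ = [
    "PermTestResult",
    "SignificantInterval",
    "AnovaResult",
    "DEFAULT_BINS",
    "perm_ttest_vs_chance",
    "significant_intervals",
    "bin_accuracies",
    "mixed_anova",
    "posthoc_bin_contrast",
]


@dataclass
class PermTestResult:
    t_obs: np.ndarray       # per-timepoint one-sample t
    p_corr: np.ndarray      # per-timepoint tmax-corrected p
    p_uncorr: np.ndarray    # per-timepoint uncorrected permutation p
    mask: np.ndarray        # p_corr < alpha
    times: np.ndarray
    alpha: float
    n_perm: int
    tail: str

    def __post_init__(self) -> None:
        assert np.all((self.p_corr >= 0) & (self.p_corr <= 1))


@dataclass
class SignificantInterval:
    start_ms: float
    end_ms: float
    n_samples: int

    @property
    def short(self) -> bool:
        """Single-sample intervals are flagged: at 8 ms resolution they span
        less time than the decoder can resolve."""
        return self.n_samples < 2


def perm_ttest_vs_chance(
    group: GroupDecodingResult | np.ndarray,
    chance: float | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    tail: str = "upper",
    rng: np.random.Generator | int | None = None,
    times: np.ndarray | None = None,
) -> PermTestResult:
    """One-sample tmax permutation t-test of accuracies against chance.

    Sign flips are drawn per subject and applied across all timepoints
    jointly; the null distribution is of the maximum t (upper tail) or
    maximum |t| (two-sided) over timepoints, which controls the family-wise
    error rate.  The observed statistic is included in the null (p is never
    exactly 0).
    """
    if isinstance(group, GroupDecodingResult):
        acc = group.accuracies
        chance = group.chance if chance is None else chance
        times = group.times if times is None else times
    else:
        acc = np.asarray(group, dtype=float)
        if chance is None:
            raise ValueError("chance must be given for a bare accuracy matrix")
    n_subj, n_t = acc.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if tail not in ("upper", "two-sided"):
        raise ValueError("tail must be 'upper' or 'two-sided'")
    if n_perm < 1.0 / alpha:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} cannot resolve p-values below {1 / n_perm:.3g}"
        )
    if times is None:
        times = np.arange(n_t, dtype=float)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    x = acc - chance
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, mean / se, 0.0)

    # Sign flips only change the mean; the per-timepoint mean square is
    # flip-invariant, so each permutation t is computable from its mean alone.
    ms2 = (x**2).mean(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    perm_mean = signs @ x / n_subj                          # (n_perm, n_t)
    perm_var = (ms2[None, :] - perm_mean**2) * n_subj / (n_subj - 1)
    perm_var = np.maximum(perm_var, 0.0)
    perm_se = np.sqrt(perm_var / n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_t = np.where(perm_se > 0, perm_mean / perm_se, 0.0)

    if tail == "upper":
        stat_obs, stat_perm = t_obs, perm_t
    else:
        stat_obs, stat_perm = np.abs(t_obs), np.abs(perm_t)
    max_null = stat_perm.max(axis=1)
    # corrected: compare each timepoint to the max-statistic null
    p_corr = (1 + (max_null[:, None] >= stat_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    p_uncorr = (1 + (stat_perm >= stat_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    return PermTestResult(
        t_obs=t_obs,
        p_corr=p_corr,
        p_uncorr=p_uncorr,
        mask=p_corr < alpha,
        times=np.asarray(times, dtype=float),
        alpha=alpha,
        n_perm=n_perm,
        tail=tail,
    )


def significant_intervals(
    result: PermTestResult, times: np.ndarray | None = None
) -> list[SignificantInterval]:
    """Maximal runs of consecutive significant timepoints as [first, last] ms."""
    times = result.times if times is None else np.asarray(times, dtype=float)
    mask = result.mask
    if len(mask) != len(times):
        raise ValueError("mask and times lengths differ")
    intervals: list[SignificantInterval] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append(SignificantInterval(times[start], times[i - 1], i - start))
            start = None
    if start is not None:
        intervals.append(
            SignificantInterval(times[start], times[len(mask) - 1], len(mask) - start)
        )
    return intervals


#: The ten 50-ms bins tiling 200-700 ms.
DEFAULT_BINS: list[tuple[float, float]] = [
    (float(lo), float(lo + 50)) for lo in range(200, 700, 50)
]


def bin_accuracies(
    groups: list[GroupDecodingResult],
    bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per subject/parameter-set/bin mean accuracy table.

    Bin membership is ``bin_start <= t < bin_end``.  Columns: subject_id,
    condition, parameter_set, bin_start, bin_end, mean_accuracy.
    """
    bins = DEFAULT_BINS if bins is None else bins
    rows = []
    for g in groups:
        for lo, hi in bins:
            mask = (g.times >= lo) & (g.times < hi)
            if not mask.any():
                raise ValueError(f"bin {(lo, hi)} contains no decoded timepoints")
            means = g.accuracies[:, mask].mean(axis=1)
            for sid, m in zip(g.subject_ids, means):
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": g.group,
                        "parameter_set": g.config.parameter_set_name,
                        "bin_start": lo,
                        "bin_end": hi,
                        "mean_accuracy": m,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    effects: pd.DataFrame       # name, SS, df_num, df_den, F, p, p_GG, partial_eta_sq
    epsilon_gg: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a T x T repeated-measures covariance."""
    T = cov.shape[0]
    # double-centre
    row = cov.mean(axis=0, keepdims=True)
    grand = cov.mean()
    dc = cov - row - row.T + grand
    num = np.trace(dc) ** 2
    den = (T - 1) * np.sum(dc**2)
    return float(num / den) if den > 0 else 1.0


def mixed_anova(table: pd.DataFrame) -> AnovaResult:
    """Split-plot ANOVA of bin accuracies.

    Rows of ``table`` (one per subject x set x bin, as from
    :func:`bin_accuracies`) are grouped into independent observation units by
    (subject_id, parameter_set); condition and parameter set are between-unit
    factors (2 x 3 cells) and bin ("TIME", 10 levels) the within factor.
    Effects are Type II sums of squares; within effects use the time x unit
    interaction as error and get Greenhouse-Geisser adjusted p-values from
    the pooled within-cell covariance; partial eta squared is
    SS_effect / (SS_effect + SS_error).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = table.copy()
    df["unit"] = df["subject_id"].astype(str) + "|" + df["parameter_set"].astype(str)
    df["bin"] = df["bin_start"].astype(float)
    n_levels = df["bin"].nunique()
    counts = df.groupby("unit")["bin"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != n_levels:
        raise ValueError("unbalanced time factor: every unit needs every bin")
    wide = df.pivot_table(index=["unit", "condition", "parameter_set"],
                          columns="bin", values="mean_accuracy")
    if wide.isna().any().any():
        raise ValueError("missing cells in the subject x bin table")
    N = wide.shape[0]
    T = wide.shape[1]
    cells = wide.index.to_frame(index=False).groupby(["condition", "parameter_set"])
    n_cells = len(cells)
    if N <= n_cells:
        raise ValueError("need more units than between cells")

    # Full-model Type II SS for all factorial effects; between factors with a
    # single observed level are dropped from the model.
    between = [
        col for col in ("condition", "parameter_set") if df[col].nunique() > 1
    ]
    terms = " * ".join([f"C({col})" for col in between] + ["C(bin)"])
    full = smf.ols(f"mean_accuracy ~ {terms}", data=df).fit()
    aov = anova_lm(full, typ=2)

    # Error strata.  Row (unit) means against cell means give the
    # between-unit error; the full-model residual splits into that part
    # (scaled by T) plus the time x unit-within-cell error.
    unit_means = wide.mean(axis=1)
    cell_of_unit = unit_means.groupby(
        [wide.index.get_level_values("condition"),
         wide.index.get_level_values("parameter_set")]
    ).transform("mean")
    ss_subj = T * float(((unit_means - cell_of_unit) ** 2).sum())
    df_subj = N - n_cells
    ss_resid_full = float(aov.loc["Residual", "sum_sq"])
    ss_within_err = ss_resid_full - ss_subj
    df_within_err = df_subj * (T - 1)

    # Pooled within-cell covariance of the repeated measures -> GG epsilon.
    centred = wide.values - np.asarray(
        wide.groupby(level=["condition", "parameter_set"]).transform("mean")
    )
    pooled_cov = centred.T @ centred / df_subj
    eps = _gg_epsilon(pooled_cov)

    labels = {"condition": "CONDITION", "parameter_set": "SET", "bin": "TIME"}

    def _effect_name(key: str) -> tuple[str, str]:
        parts = [p[2:-1] for p in key.split(":")]  # strip C( )
        if "bin" in parts:
            rest = [labels[p] for p in parts if p != "bin"]
            return "x".join(["TIME"] + rest), "within"
        return "x".join(labels[p] for p in parts), "between"

    name_map = {
        key: _effect_name(key) for key in aov.index if key != "Residual"
    }
    rows = []
    for key, (name, stratum) in name_map.items():
        if key not in aov.index:
            continue
        ss = float(aov.loc[key, "sum_sq"])
        df_num = int(aov.loc[key, "df"])
        if stratum == "between":
            ss_err, df_den = ss_subj, df_subj
        else:
            ss_err, df_den = ss_within_err, df_within_err
        ms = ss / df_num
        ms_err = ss_err / df_den
        F = ms / ms_err
        p = float(sps.f.sf(F, df_num, df_den))
        if stratum == "within":
            p_gg = float(sps.f.sf(F, eps * df_num, eps * df_den))
        else:
            p_gg = p
        rows.append(
            {
                "effect": name,
                "stratum": stratum,
                "sum_sq": ss,
                "df_num": df_num,
                "df_den": df_den,
                "F": F,
                "p": p,
                "p_GG": p_gg,
                "partial_eta_sq": ss / (ss + ss_err),
            }
        )
    effects = pd.DataFrame(rows)
    return AnovaResult(effects=effects, epsilon_gg=eps)


def posthoc_bin_contrast(
    table: pd.DataFrame,
    bin_window: tuple[float, float],
    groups: tuple[str, str] = ("placebo", "study"),
) -> tuple[float, float]:
    """Two-sample contrast of per-unit bin means between the two conditions.

    Returns ``(p, cohen_d)``: pooled-variance two-sided t-test and
    Cohen's d = mean difference / pooled SD (first group minus second).
    """
    lo, hi = bin_window
    sel = table[(table["bin_start"] == lo) & (table["bin_end"] == hi)]
    a = sel.loc[sel["condition"] == groups[0], "mean_accuracy"].to_numpy()
    b = sel.loc[sel["condition"] == groups[1], "mean_accuracy"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"bin {bin_window}: a condition has no observations")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    d = (a.mean() - b.mean()) / np.sqrt(sp2) if sp2 > 0 else 0.0
    return float(p), float(d)


def posthoc_all_bins(
    table: pd.DataFrame, groups: tuple[str, str] = ("placebo", "study")
) -> pd.DataFrame:
    """Per-bin condition contrasts across all bins present in the table."""
    rows = []
    for (lo, hi), _ in table.groupby(["bin_start", "bin_end"]):
        p, d = posthoc_bin_contrast(table, (lo, hi), groups)
        rows.append(
            {"bin_start": lo, "bin_end": hi,
             "contrast": f"{groups[0]}-{groups[1]}", "p": p, "cohen_d": d}
        )
    return pd.DataFrame(rows).sort_values("bin_start").reset_index(drop=True)
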