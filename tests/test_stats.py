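"""Group-level inference: tmax permutation test, intervals, bins, split-plot
ANOVA with Greenhouse-Geisser correction, and post-hoc contrasts."""

import numpy as np
import pandas as pd
import pytest

import erpdecode as ed
from erpdecode.stats import posthoc_all_bins


def _acc_matrix(rng, n_subj=12, n_t=64, mean=1 / 3, sd=0.05, bump=None):
    acc = rng.normal(mean, sd, (n_subj, n_t))
    if bump is not None:
        lo, hi, height = bump
        acc[:, lo:hi] += height
    return acc


class TestPermTtest:
    def test_exact_chance_accuracies_give_zero_t_nothing_significant(self):
        acc = np.full((8, 20), 1 / 3)
        res = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=1000, rng=0)
        assert np.all(res.t_obs == 0)
        assert not res.mask.any()

    def test_strong_effect_window_detected(self, rng):
        acc = _acc_matrix(rng, bump=(20, 30, 0.2))
        res = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=2000, rng=1)
        assert res.mask[20:30].all()
        assert res.mask[:15].sum() == 0

    def test_corrected_p_dominates_uncorrected(self, rng):
        acc = _acc_matrix(rng, bump=(10, 25, 0.05))
        res = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=1000, rng=2)
        assert np.all(res.p_corr >= res.p_uncorr - 1e-12)

    def test_two_sided_detects_below_chance(self, rng):
        acc = _acc_matrix(rng, bump=(5, 15, -0.2))
        upper = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=1000, rng=3)
        two = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=1000, rng=3,
                                      tail="two-sided")
        assert not upper.mask[5:15].any()
        assert two.mask[5:15].all()

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            ed.perm_ttest_vs_chance(np.full((1, 10), 0.4), chance=1 / 3)

    def test_familywise_error_controlled_on_null(self, rng):
        """Null simulation: any-timepoint false-positive rate stays near alpha."""
        hits = 0
        reps = 400
        for i in range(reps):
            acc = _acc_matrix(rng, n_subj=12, n_t=64)
            res = ed.perm_ttest_vs_chance(acc, chance=1 / 3, n_perm=500,
                                          rng=np.random.default_rng(i))
            hits += res.mask.any()
        rate = hits / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestSignificantIntervals:
    def _result(self, mask, times):
        return ed.PermTestResult(
            t_obs=np.zeros(len(mask)), p_corr=np.where(mask, 0.01, 0.5),
            p_uncorr=np.where(mask, 0.01, 0.5), mask=np.asarray(mask),
            times=np.asarray(times, float), alpha=0.05, n_perm=100, tail="upper",
        )

    def test_empty_mask_gives_no_intervals(self):
        res = self._result(np.zeros(10, bool), np.arange(10) * 8.0)
        assert ed.significant_intervals(res) == []

    def test_contiguous_run_reported_with_its_time_bounds(self):
        times = np.arange(0, 512, 8.0)
        mask = (times >= 208) & (times <= 256)
        res = self._result(mask, times)
        out = ed.significant_intervals(res)
        assert len(out) == 1
        assert (out[0].start_ms, out[0].end_ms) == (208.0, 256.0)
        assert not out[0].short

    def test_all_true_mask_spans_whole_range(self):
        times = np.arange(-200, 800, 8.0)
        res = self._result(np.ones(len(times), bool), times)
        out = ed.significant_intervals(res)
        assert len(out) == 1
        assert out[0].start_ms == times[0] and out[0].end_ms == times[-1]

    def test_single_sample_interval_flagged_short(self):
        times = np.arange(10) * 8.0
        mask = np.zeros(10, bool)
        mask[4] = True
        out = ed.significant_intervals(self._result(mask, times))
        assert len(out) == 1 and out[0].short


def _group_result(rng, group, set_name="set1", n_subj=6, effect=0.0):
    times = np.arange(-200, 800, 8.0)
    acc = rng.normal(1 / 3, 0.03, (n_subj, len(times)))
    sel = (times >= 200) & (times < 700)
    acc[:, sel] += effect
    from dataclasses import replace

    cfg = replace(ed.PARAMETER_SETS[set_name], n_iterations=10)
    return ed.GroupDecodingResult(
        accuracies=acc, times=times, group=group,
        subject_ids=[f"{group}{set_name}_{i}" for i in range(n_subj)], config=cfg,
    )


class TestBinAccuracies:
    def test_ten_bins_tiling_200_700(self, rng):
        table = ed.bin_accuracies([_group_result(rng, "placebo")])
        bins = sorted(set(zip(table.bin_start, table.bin_end)))
        assert bins == [(s, s + 50.0) for s in np.arange(200.0, 700.0, 50.0)]
        assert len(table) == 6 * 10

    def test_constant_accuracy_gives_constant_bins(self, rng):
        g = _group_result(rng, "placebo")
        g.accuracies[:] = 0.4
        table = ed.bin_accuracies([g])
        assert np.allclose(table.mean_accuracy, 0.4)

    def test_bin_mean_is_arithmetic_mean_of_samples(self):
        times = np.arange(200, 300, 25.0)  # 200,225,250,275
        acc = np.array([[0.3, 0.5, 0.2, 0.6]])
        g = ed.GroupDecodingResult(
            accuracies=acc, times=times, group="placebo",
            subject_ids=["a"], config=ed.PARAMETER_SETS["set1"],
        )
        table = ed.bin_accuracies([g], bins=[(200.0, 250.0), (250.0, 300.0)])
        assert table.mean_accuracy.tolist() == [0.4, 0.4]

    def test_bin_means_commute_with_group_averaging(self, rng):
        g = _group_result(rng, "placebo", n_subj=5)
        table = ed.bin_accuracies([g])
        per_subject_then_mean = table.groupby("bin_start").mean_accuracy.mean()
        sel = lambda lo: (g.times >= lo) & (g.times < lo + 50)
        group_curve_then_bin = {
            lo: g.mean_accuracy[sel(lo)].mean() for lo in per_subject_then_mean.index
        }
        for lo, v in group_curve_then_bin.items():
            assert per_subject_then_mean[lo] == pytest.approx(v)

    def test_empty_bin_raises(self, rng):
        g = _group_result(rng, "placebo")
        with pytest.raises(ValueError):
            ed.bin_accuracies([g], bins=[(5000.0, 5050.0)])


def _full_bin_table(rng, n_per_cell=(16, 15, 12, 12, 12, 12), effect=None):
    """31 + 24 + 24 observation units across 2 x 3 between cells, 10 bins."""
    sizes = dict(zip(
        [("placebo", "set1"), ("study", "set1"), ("placebo", "set2"),
         ("study", "set2"), ("placebo", "set3"), ("study", "set3")],
        n_per_cell,
    ))
    rows = []
    for (cond, pset), n in sizes.items():
        for i in range(n):
            subj_effect = rng.normal(0, 0.02)
            for b, lo in enumerate(np.arange(200.0, 700.0, 50.0)):
                val = 1 / 3 + subj_effect + rng.normal(0, 0.02)
                if effect is not None:
                    val += effect(cond, pset, lo)
                rows.append(
                    {"subject_id": f"{cond[0]}{pset}{i}", "condition": cond,
                     "parameter_set": pset, "bin_start": lo, "bin_end": lo + 50,
                     "mean_accuracy": val}
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_error_dfs_match_design(self, rng):
        """31+24+24 units in 2x3 cells with 10 time levels -> within error df
        657 and between error df 73."""
        table = _full_bin_table(rng)
        res = ed.mixed_anova(table)
        time_row = res.effect("TIME")
        assert (time_row.df_num, time_row.df_den) == (9, 657)
        set_row = res.effect("SET")
        assert (set_row.df_num, set_row.df_den) == (2, 73)
        cond_row = res.effect("CONDITION")
        assert (cond_row.df_num, cond_row.df_den) == (1, 73)

    def test_hand_computed_toy_table(self):
        """Balanced 4-unit x 2-bin toy: compare against direct textbook sums
        of squares computed inline."""
        y = {  # unit -> (bin1, bin2); units a,b placebo; c,d study
            ("a", "placebo"): (0.40, 0.50),
            ("b", "placebo"): (0.44, 0.58),
            ("c", "study"): (0.30, 0.32),
            ("d", "study"): (0.34, 0.30),
        }
        rows = []
        for (sid, cond), (v1, v2) in y.items():
            for lo, v in [(200.0, v1), (250.0, v2)]:
                rows.append({"subject_id": sid, "condition": cond,
                             "parameter_set": "set1", "bin_start": lo,
                             "bin_end": lo + 50, "mean_accuracy": v})
        table = pd.DataFrame(rows)
        res = ed.mixed_anova(table)

        vals = np.array([[0.40, 0.50], [0.44, 0.58], [0.30, 0.32], [0.34, 0.30]])
        grand = vals.mean()
        cond_means = vals.reshape(2, 2, 2).mean(axis=(1, 2))     # placebo, study
        time_means = vals.mean(axis=0)
        unit_means = vals.mean(axis=1)
        T, N = 2, 4
        ss_cond = T * 2 * np.sum((cond_means - grand) ** 2)
        ss_time = N * np.sum((time_means - grand) ** 2)
        cell = vals.reshape(2, 2, 2).mean(axis=1)                # cond x time
        ss_inter = 2 * np.sum(
            (cell - cond_means[:, None] - time_means[None, :] + grand) ** 2
        )
        ss_subj = T * np.sum(
            (unit_means - np.repeat(cond_means, 2)) ** 2
        )
        ss_total = np.sum((vals - grand) ** 2)
        ss_within_err = ss_total - ss_cond - ss_time - ss_inter - ss_subj

        assert res.effect("CONDITION").sum_sq == pytest.approx(ss_cond)
        assert res.effect("TIME").sum_sq == pytest.approx(ss_time)
        assert res.effect("TIMExCONDITION").sum_sq == pytest.approx(ss_inter)
        f_cond = (ss_cond / 1) / (ss_subj / 2)
        assert res.effect("CONDITION").F == pytest.approx(f_cond)
        f_time = (ss_time / 1) / (ss_within_err / 2)
        assert res.effect("TIME").F == pytest.approx(f_time)
        assert res.effect("TIME").partial_eta_sq == pytest.approx(
            ss_time / (ss_time + ss_within_err)
        )

    def test_agrees_with_pingouin_single_between_factor(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for cond, n in [("placebo", 8), ("study", 8)]:
            for i in range(n):
                base = rng.normal(0, 0.03)
                for lo in np.arange(200.0, 700.0, 50.0):
                    rows.append({
                        "subject_id": f"{cond}{i}", "condition": cond,
                        "parameter_set": "set1", "bin_start": lo,
                        "bin_end": lo + 50,
                        "mean_accuracy": 1 / 3 + base + rng.normal(0, 0.03)
                        + (0.05 if (cond == "placebo" and lo >= 400) else 0),
                    })
        table = pd.DataFrame(rows)
        res = ed.mixed_anova(table)
        pg_res = pg.mixed_anova(
            data=table.assign(time=table.bin_start), dv="mean_accuracy",
            within="time", subject="subject_id", between="condition",
        ).set_index("Source")
        assert res.effect("CONDITION").F == pytest.approx(
            pg_res.loc["condition", "F"], rel=1e-6
        )
        assert res.effect("TIME").F == pytest.approx(
            pg_res.loc["time", "F"], rel=1e-6
        )
        assert res.effect("TIMExCONDITION").F == pytest.approx(
            pg_res.loc["Interaction", "F"], rel=1e-6
        )
        # epsilon: pingouin computes it from the grand subject x time pivot;
        # this package pools the covariance within cells (the mixed-design
        # convention), so compare on within-condition-centred data where the
        # two definitions coincide.
        wide = table.pivot_table(index=["subject_id", "condition"],
                                 columns="bin_start", values="mean_accuracy")
        centred = wide - wide.groupby(level="condition").transform("mean")
        eps_ref = float(pg.epsilon(pd.DataFrame(centred.values), correction="gg"))
        assert res.epsilon_gg == pytest.approx(eps_ref, rel=1e-6)

    def test_null_interaction_rejection_rate_near_alpha(self, rng):
        reps, hits = 200, 0
        for _ in range(reps):
            table = _full_bin_table(
                rng, n_per_cell=(6, 6, 6, 6, 6, 6),
                effect=lambda c, s, lo: 0.03 if lo >= 400 else 0.0,  # TIME only
            )
            res = ed.mixed_anova(table)
            hits += res.effect("TIMExCONDITION").p_GG < 0.05
        rate = hits / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_unbalanced_time_levels_raise(self, rng):
        table = _full_bin_table(rng).iloc[:-3]
        with pytest.raises(ValueError, match="unbalanced"):
            ed.mixed_anova(table)


class TestPosthoc:
    def _table(self, a_vals, b_vals, lo=200.0):
        rows = []
        for cond, vals in [("placebo", a_vals), ("study", b_vals)]:
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"{cond}{i}", "condition": cond,
                             "parameter_set": "set1", "bin_start": lo,
                             "bin_end": lo + 50, "mean_accuracy": v})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_d(self):
        vals = [0.3, 0.4, 0.5, 0.35]
        p, d = ed.posthoc_bin_contrast(self._table(vals, vals), (200.0, 250.0))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_shift_by_pooled_sd_gives_unit_d(self, rng):
        a = rng.normal(0.4, 0.05, 20)
        sp = a.std(ddof=1)
        p, d = ed.posthoc_bin_contrast(self._table(a + sp, a), (200.0, 250.0))
        assert d == pytest.approx(1.0, rel=1e-9)

    def test_d_antisymmetric_under_label_swap(self, rng):
        a = rng.normal(0.45, 0.04, 10)
        b = rng.normal(0.35, 0.04, 10)
        _, d_ab = ed.posthoc_bin_contrast(self._table(a, b), (200.0, 250.0))
        _, d_ba = ed.posthoc_bin_contrast(
            self._table(a, b), (200.0, 250.0), groups=("study", "placebo")
        )
        assert d_ab == pytest.approx(-d_ba)

    def test_missing_condition_raises(self):
        table = self._table([0.4, 0.5], [0.3, 0.35])
        with pytest.raises(ValueError):
            ed.posthoc_bin_contrast(table[table.condition == "placebo"], (200.0, 250.0))

    def test_all_bins_table_has_one_row_per_bin(self, rng):
        g1 = _group_result(rng, "placebo", effect=0.1)
        g2 = _group_result(rng, "study")
        table = ed.bin_accuracies([g1, g2])
        out = posthoc_all_bins(table)
        assert len(out) == 10
        assert (out.cohen_d > 0).sum() >= 8  # placebo above study in 200-700
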