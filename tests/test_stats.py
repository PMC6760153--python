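"""Group statistics: outlier screen, assumption checks, one-way and mixed
repeated-measures ANOVA (cross-checked against pingouin and the paired t),
Tukey HSD, and the fixed analysis pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chronopheno.stats import (StatsError, analyze_metric, exclude_outliers,
                               format_effect, mixed_rm_anova, normality_check,
                               one_way_anova, tukey_hsd, variance_homogeneity)


class TestOutlierScreen:
    def test_gross_outlier_excluded(self):
        kept, excluded = exclude_outliers(np.array([1, 1, 1, 1, 100.0]))
        assert excluded.tolist() == [100.0]
        assert kept.tolist() == [1, 1, 1, 1]

    def test_constant_group_keeps_everything(self):
        kept, excluded = exclude_outliers(np.array([5.0, 5.0, 5.0]))
        assert excluded.size == 0 and kept.size == 3

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            kept, excluded = exclude_outliers(np.array([1.0, 9.0]))
        assert excluded.size == 0

    def test_normal_exclusion_fraction_matches_two_sided_tail(self, rng):
        x = rng.normal(0, 1, 10_000)
        _, excluded = exclude_outliers(x)
        # P(|Z| > 2) = 4.55%
        assert excluded.size / x.size == pytest.approx(0.0455, abs=0.006)


class TestAssumptionChecks:
    def test_shapiro_type_one_calibration(self, rng):
        passes = sum(normality_check(rng.normal(0, 1, 50))[2] for _ in range(400))
        assert passes / 400 == pytest.approx(0.95, abs=0.035)

    def test_shapiro_rejects_exponential_samples(self, rng):
        passes = sum(normality_check(rng.exponential(1, 50))[2] for _ in range(200))
        assert passes / 200 < 0.4

    def test_shapiro_bounds_and_constant_rejected(self):
        with pytest.raises(StatsError):
            normality_check(np.array([1.0, 2.0]))
        with pytest.raises(StatsError):
            normality_check(np.full(10, 3.0))

    def test_levene_calibration_and_power(self, rng):
        rej = sum(variance_homogeneity([rng.normal(0, 1, 30), rng.normal(0, 1, 30)])[1] < 0.05
                  for _ in range(300))
        assert rej / 300 == pytest.approx(0.05, abs=0.035)
        rej = sum(variance_homogeneity([rng.normal(0, 1, 30), rng.normal(0, 4, 30)])[1] < 0.05
                  for _ in range(100))
        assert rej / 100 > 0.95

    def test_levene_identical_groups_statistic_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, _ = variance_homogeneity([g, g.copy()])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_levene_needs_two_groups(self):
        with pytest.raises(StatsError):
            variance_homogeneity([np.array([1.0, 2.0])])


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_hand_computed_three_by_five_example(self):
        groups = [np.array([3.0, 5, 4, 6, 2]), np.array([7.0, 6, 8, 9, 5]),
                  np.array([4.0, 3, 5, 2, 6])]
        # brute-force sums of squares
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(5 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / 12)
        res = one_way_anova(groups)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert res.df == (2, 12)
        assert res.p == pytest.approx(sps.f.sf(f, 2, 12), abs=1e-12)

    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = one_way_anova([g, g.copy(), g.copy()])
        assert res.F == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            one_way_anova([np.array([1.0, 2.0]), np.array([])])


def make_mixed_table(rng, n_per_cell=6, genotypes=("A", "B"), doses=(0, 10, 30),
                     geno_eff=0.0, phase_eff=0.0, inter_eff=0.0, subj_sd=1.0,
                     noise_sd=0.5):
    rows = []
    sid = 0
    for g in genotypes:
        for d in doses:
            for _ in range(n_per_cell):
                sid += 1
                base = rng.normal((g == "A") * geno_eff, subj_sd)
                for ph, shift in (("baseline", 0.0),
                                  ("treatment", phase_eff + (g == "A") * inter_eff)):
                    rows.append(dict(subject_id=f"s{sid}", genotype=g, dose=d,
                                     phase=ph,
                                     value=base + shift + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows)


class TestMixedRmAnova:
    def test_phase_f_equals_paired_t_squared(self, rng):
        df = make_mixed_table(rng, genotypes=("A",), doses=(0,), n_per_cell=12,
                              phase_eff=0.4)
        res = {r.effect: r for r in mixed_rm_anova(df, between=())}
        wide = df.pivot(index="subject_id", columns="phase", values="value")
        t, p = sps.ttest_rel(wide["treatment"], wide["baseline"])
        assert res["phase"].F == pytest.approx(t ** 2, rel=1e-10)
        assert res["phase"].p == pytest.approx(p, rel=1e-10)

    def test_matches_pingouin_for_one_between_factor_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        df = make_mixed_table(rng, doses=(0,), geno_eff=0.8, phase_eff=0.5,
                              inter_eff=0.3)
        ours = {r.effect: r for r in mixed_rm_anova(df, between=("genotype",))}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.mixed_anova(df, dv="value", within="phase",
                                 subject="subject_id", between="genotype")
        ref = ref.set_index("Source")
        assert ours["genotype"].F == pytest.approx(ref.loc["genotype", "F"], rel=1e-6)
        assert ours["phase"].F == pytest.approx(ref.loc["phase", "F"], rel=1e-6)
        assert ours["phase:genotype"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_sums_of_squares_partition_total_exactly(self, rng):
        df = make_mixed_table(rng, geno_eff=0.5, phase_eff=0.4, inter_eff=0.2)
        res = mixed_rm_anova(df)
        sstot = float(((df.value - df.value.mean()) ** 2).sum())
        assert sum(r.ss for r in res) == pytest.approx(sstot, rel=1e-10)

    def test_type_one_error_calibration_under_null(self, rng):
        effects = {}
        reps = 120
        for _ in range(reps):
            df = make_mixed_table(rng, n_per_cell=4)
            for r in mixed_rm_anova(df):
                if "subjects" not in r.effect:
                    effects.setdefault(r.effect, []).append(r.p < 0.05)
        for name, hits in effects.items():
            # loose 99% binomial band at 120 reps; tight bands in acceptance
            assert 0.0 <= np.mean(hits) <= 0.13, name

    def test_subject_missing_a_phase_dropped_with_warning(self, rng):
        df = make_mixed_table(rng, n_per_cell=4)
        df = df.drop(df[(df.subject_id == "s1") & (df.phase == "treatment")].index)
        with pytest.warns(UserWarning, match="s1"):
            res = mixed_rm_anova(df)
        assert res  # still returns a full effect table

    def test_requires_two_phase_levels(self, rng):
        df = make_mixed_table(rng)
        with pytest.raises(StatsError):
            mixed_rm_anova(df[df.phase == "baseline"])


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        g = np.array([1.0, 2, 3, 4, 5])
        for c in tukey_hsd({"a": g, "b": g.copy(), "c": g.copy()}):
            assert c.p_adjusted > 0.999

    def test_family_wise_error_under_null(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            groups = {k: rng.normal(0, 1, 8) for k in "abcd"}
            hits += any(c.p_adjusted < 0.05 for c in tukey_hsd(groups))
        assert hits / reps == pytest.approx(0.05, abs=0.045)

    def test_only_shifted_group_pairs_significant(self, rng):
        groups = {k: rng.normal(0, 0.5, 12) for k in "abc"}
        groups["d"] = rng.normal(4.0, 0.5, 12)
        comps = tukey_hsd(groups)
        for c in comps:
            involves_d = "d" in (c.group_a, c.group_b)
            assert (c.p_adjusted < 0.05) == involves_d

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_hsd({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestAnalysisPipeline:
    def test_posthoc_only_after_significant_omnibus(self, rng):
        df = make_mixed_table(rng, n_per_cell=5)
        df["metric"] = "m"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_ana = analyze_metric(make_null := df.assign(
                value=rng.normal(0, 1, len(df))), "m")
        if all(r.p >= 0.05 for r in null_ana.omnibus if "subjects" not in r.effect):
            assert null_ana.posthoc == []
        df_eff = df.copy()
        df_eff.loc[df_eff.genotype == "A", "value"] += 5.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ana = analyze_metric(df_eff, "m")
        assert ana.posthoc  # significant genotype effect triggers Tukey
        del make_null

    def test_outliers_removed_before_testing(self, rng):
        df = make_mixed_table(rng, genotypes=("A", "B"), doses=(0,), n_per_cell=8)
        df["metric"] = "m"
        idx = df.index[0]
        df.loc[idx, "value"] = 1e4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ana = analyze_metric(df, "m")
        assert any(1e4 in v for v in ana.excluded.values())

    def test_report_uses_study_f_format(self, rng):
        df = make_mixed_table(rng, geno_eff=3.0, subj_sd=0.5)
        df["metric"] = "m"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ana = analyze_metric(df, "m")
        rep = ana.report()
        assert "F(" in rep and "p <" in rep

    def test_format_effect_thresholds(self):
        from chronopheno.stats import StatsResult
        assert "p < 0.001" in format_effect(StatsResult("e", 30.0, (1, 20), 1e-5))
        assert "n.s." in format_effect(StatsResult("e", 1.0, (1, 20), 0.4))
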