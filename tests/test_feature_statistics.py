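import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from stepdyn.arx import CHANNELS
from stepdyn.feature_statistics import (
    DAY_TYPES,
    StatisticsError,
    check_normality,
    complete_cases,
    describe_features,
    friedman_by_daytype,
    heterogeneity_summary,
    pairwise_posthoc,
    rm_anova_2way,
    run_feature_statistics,
)


def long_table(cube, feature="steady_state", participants=None):
    """(n, 3, 2) cube -> long-format table."""
    n = cube.shape[0]
    participants = participants or [f"p{i:03d}" for i in range(n)]
    rows = []
    for s in range(n):
        for i, msg in enumerate(CHANNELS):
            for j, day in enumerate(DAY_TYPES):
                rows.append((participants[s], msg, day, feature, cube[s, i, j]))
    return pd.DataFrame(
        rows, columns=["participant", "message_type", "day_type", "feature", "value"]
    )


@pytest.fixture
def random_cube():
    return np.random.default_rng(42).normal(size=(12, 3, 2))


class TestDescribe:
    def test_single_participant_sd_missing(self):
        table = long_table(np.ones((1, 3, 2)))
        desc = describe_features(table)
        assert desc["n"].eq(1).all()
        assert desc["sd"].isna().all()

    def test_constant_feature(self):
        table = long_table(np.full((5, 3, 2), 7.0))
        desc = describe_features(table)
        assert (desc["sd"] == 0).all()
        assert (desc["max"] - desc["min"]).eq(0).all()

    def test_streaming_oracle(self, random_cube):
        table = long_table(random_cube)
        desc = describe_features(table)
        for i, msg in enumerate(CHANNELS):
            for j, day in enumerate(DAY_TYPES):
                vals = random_cube[:, i, j]
                # Welford streaming mean/variance as the independent route
                mean, m2 = 0.0, 0.0
                for k, x in enumerate(vals, start=1):
                    d = x - mean
                    mean += d / k
                    m2 += d * (x - mean)
                row = desc.loc[
                    (desc["message_type"] == msg) & (desc["day_type"] == day)
                ].iloc[0]
                assert row["mean"] == pytest.approx(mean)
                assert row["sd"] == pytest.approx(math.sqrt(m2 / (len(vals) - 1)))
                assert row["min"] == vals.min() and row["max"] == vals.max()


class TestNormality:
    def test_gaussian_passes(self):
        cube = np.random.default_rng(3).normal(size=(45, 3, 2))
        assert check_normality(long_table(cube), "steady_state")

    def test_boundary_point_mass_fails(self):
        rng = np.random.default_rng(4)
        cube = rng.normal(size=(45, 3, 2))
        vals = np.abs(cube[:, 0, 0])
        vals[:25] = 15.0  # point mass at the lower boundary
        cube[:, 0, 0] = vals
        assert not check_normality(long_table(cube), "steady_state")

    def test_constant_cell_flagged(self, random_cube):
        random_cube[:, 1, 1] = 3.0
        assert not check_normality(long_table(random_cube), "steady_state")

    def test_too_few_participants(self):
        with pytest.raises(StatisticsError):
            check_normality(long_table(np.ones((2, 3, 2))), "steady_state")


class TestRmAnova:
    def test_brute_force_cell_mean_oracle(self):
        # 5-subject toy grid: independently recompute every SS from scratch
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(5, 3, 2))
        res = rm_anova_2way(long_table(Y), "steady_state", correction="never")

        n, a, b = Y.shape
        gm = Y.mean()
        ss_a = sum(
            n * b * 0 + b * n * (Y[:, i, :].mean() - gm) ** 2 for i in range(a)
        )
        ss_b = sum(a * n * (Y[:, :, j].mean() - gm) ** 2 for j in range(b))
        ss_ab = 0.0
        for i in range(a):
            for j in range(b):
                dev = (
                    Y[:, i, j].mean()
                    - Y[:, i, :].mean()
                    - Y[:, :, j].mean()
                    + gm
                )
                ss_ab += n * dev**2
        ss_err_a = 0.0
        for s in range(n):
            for i in range(a):
                dev = (
                    Y[s, i, :].mean()
                    - Y[s].mean()
                    - Y[:, i, :].mean()
                    + gm
                )
                ss_err_a += b * dev**2
        assert res.message.ss == pytest.approx(ss_a)
        assert res.day.ss == pytest.approx(ss_b)
        assert res.interaction.ss == pytest.approx(ss_ab)
        assert res.message.ss_error == pytest.approx(ss_err_a)
        F_a = (ss_a / (a - 1)) / (ss_err_a / ((a - 1) * (n - 1)))
        assert res.message.F == pytest.approx(F_a)

    def test_pingouin_oracle(self, random_cube):
        import pingouin as pg

        table = long_table(random_cube)
        res = rm_anova_2way(table, "steady_state", correction="always")
        ref = pg.rm_anova(
            data=table,
            dv="value",
            subject="participant",
            within=["message_type", "day_type"],
            correction=True,
            effsize="ng2",
        ).set_index("Source")
        for src, eff in (
            ("message_type", res.message),
            ("day_type", res.day),
            ("message_type * day_type", res.interaction),
        ):
            assert eff.F == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert eff.eta2 == pytest.approx(ref.loc[src, "ng2"], rel=1e-9)
        # GG-corrected p for the 3-level factor and the interaction
        assert res.message.p == pytest.approx(
            ref.loc["message_type", "p_GG_corr"], rel=1e-6
        )
        assert res.interaction.p == pytest.approx(
            ref.loc["message_type * day_type", "p_GG_corr"], rel=1e-6
        )
        assert res.message.df1 == pytest.approx(
            2 * ref.loc["message_type", "eps"], rel=1e-9
        )

    def test_constructed_day_effect(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(scale=0.2, size=(20, 3, 2))
        Y[:, :, 1] += 5.0  # pure additive day effect
        res = rm_anova_2way(long_table(Y), "steady_state")
        assert res.day.p < 1e-6
        assert res.message.p > 0.05
        assert res.day.F > 100

    def test_eta2_bounds(self, random_cube):
        res = rm_anova_2way(long_table(random_cube), "steady_state")
        for eff in (res.message, res.day, res.interaction):
            assert 0 <= eff.eta2 <= 1
            assert eff.F >= 0

    def test_ss_decomposition_adds_up(self, random_cube):
        Y = random_cube
        res = rm_anova_2way(long_table(Y), "steady_state")
        total_within = np.sum((Y - Y.mean(axis=(1, 2), keepdims=True)) ** 2)
        parts = (
            res.message.ss
            + res.day.ss
            + res.interaction.ss
            + res.message.ss_error
            + res.day.ss_error
            + res.interaction.ss_error
        )
        assert parts == pytest.approx(total_within)

    def test_zero_error_variance(self):
        Y = np.zeros((6, 3, 2))
        Y[:, 1, :] = 1.0  # message effect with no subject variability
        with pytest.raises(StatisticsError, match="zero error variance"):
            rm_anova_2way(long_table(Y), "steady_state")

    def test_fractional_dfs_under_correction(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(15, 3, 2))
        Y[:, 0, :] *= 4.0  # heteroscedastic levels violate sphericity
        res = rm_anova_2way(long_table(Y), "steady_state", correction="always")
        assert res.message.sphericity_corrected
        assert res.message.df1 < 2.0

    def test_type_I_error_near_alpha(self):
        rng = np.random.default_rng(11)
        reject = np.zeros(3)
        reps = 400
        for _ in range(reps):
            Y = rng.normal(size=(15, 3, 2))
            res = rm_anova_2way(long_table(Y), "steady_state")
            reject += [res.message.p < 0.05, res.day.p < 0.05, res.interaction.p < 0.05]
        rates = reject / reps
        assert (np.abs(rates - 0.05) < 0.025).all()


class TestFriedman:
    def test_perfect_ordering_fixture(self):
        # 4 blocks, one treatment always ranked top, fixed order:
        # chi2 = 12/(nk(k+1)) * sum Rj^2 - 3n(k+1) = 8, W = 1
        cube = np.zeros((4, 3, 2))
        cube[:, 0, 0] = [3, 3, 3, 3]
        cube[:, 1, 0] = [2, 2, 2, 2]
        cube[:, 2, 0] = [1, 1, 1, 1]
        res = friedman_by_daytype(long_table(cube), "steady_state", "weekday")
        assert res.chi2 == pytest.approx(8.0)
        assert res.kendall_w == pytest.approx(1.0)
        assert res.df == 2

    def test_identical_treatments(self):
        cube = np.random.default_rng(1).normal(size=(6, 1, 2)).repeat(3, axis=1)
        res = friedman_by_daytype(long_table(cube), "steady_state", "weekend")
        assert res.chi2 == 0.0
        assert res.kendall_w == 0.0

    def test_kendall_w_in_unit_interval(self):
        cube = np.random.default_rng(2).normal(size=(10, 3, 2))
        for day in DAY_TYPES:
            res = friedman_by_daytype(long_table(cube), "steady_state", day)
            assert 0 <= res.kendall_w <= 1

    def test_permutation_invariance_of_null(self):
        # permuting treatment labels leaves the statistic's null set invariant
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 3))
        stats = set()
        for perm in itertools.permutations(range(3)):
            cube = np.zeros((5, 3, 2))
            cube[:, :, 0] = base[:, perm]
            res = friedman_by_daytype(long_table(cube), "steady_state", "weekday")
            stats.add(round(res.chi2, 9))
        assert len(stats) == 1

    def test_too_few_blocks(self):
        with pytest.raises(StatisticsError):
            friedman_by_daytype(long_table(np.ones((1, 3, 2))), "steady_state", "weekday")


class TestPosthoc:
    def test_identical_samples_undefined(self):
        cube = np.ones((6, 3, 2))
        results = pairwise_posthoc(long_table(cube), "steady_state", "message")
        assert all(r.test == "undefined" for r in results)

    def test_bonferroni_times_three(self):
        rng = np.random.default_rng(5)
        cube = rng.normal(size=(10, 3, 2))
        results = pairwise_posthoc(long_table(cube), "steady_state", "message")
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_textbook_paired_t_oracle(self):
        # 6-pair toy set, hand formula t = mean(d) / (sd(d)/sqrt(n))
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0, 10.0])
        y = np.array([8.0, 11.0, 9.5, 9.0, 12.0, 8.5])
        cube = np.zeros((6, 3, 2))
        cube[:, 0, :] = x[:, None]
        cube[:, 1, :] = y[:, None]
        cube[:, 2, :] = np.random.default_rng(6).normal(size=(6, 1))
        results = pairwise_posthoc(long_table(cube), "steady_state", "message")
        r01 = next(r for r in results if {r.level_a, r.level_b} == {"affective", "social_cognitive"})
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), len(d) - 1)
        assert r01.statistic == pytest.approx(t_hand)
        assert r01.p_raw == pytest.approx(p_hand)

    def test_wilcoxon_route(self):
        rng = np.random.default_rng(7)
        cube = rng.normal(size=(12, 3, 2))
        results = pairwise_posthoc(
            long_table(cube), "steady_state", "message", parametric=False,
            day_type="weekday",
        )
        assert all(r.test == "wilcoxon" for r in results)

    def test_day_effect_single_pair(self):
        cube = np.random.default_rng(8).normal(size=(8, 3, 2))
        results = pairwise_posthoc(long_table(cube), "steady_state", "day")
        assert len(results) == 1
        assert results[0].p_adjusted == pytest.approx(results[0].p_raw)


class TestHeterogeneity:
    def test_partition_exhaustive(self):
        cube = np.random.default_rng(9).normal(size=(20, 3, 2))
        summary = heterogeneity_summary(long_table(cube))
        for day in DAY_TYPES:
            fracs = summary[day]["best_fraction"]
            assert sum(fracs.values()) == pytest.approx(1.0)
            assert summary[day]["n"] == 20

    def test_reference_difference(self):
        cube = np.zeros((4, 3, 2))
        cube[:2, 0, :] = 300.0  # spread 300 > 250 for half the participants
        summary = heterogeneity_summary(long_table(cube))
        assert summary["weekday"]["fraction_spread_over_reference"] == 0.5


class TestOrchestration:
    def test_run_feature_statistics_writes_outputs(self, tmp_path):
        rng = np.random.default_rng(10)
        frames = []
        for feat in ("steady_state", "rise_time"):
            frames.append(long_table(rng.normal(size=(12, 3, 2)), feature=feat))
        # a clearly non-normal feature routed to Friedman
        et = np.abs(rng.normal(size=(12, 3, 2)))
        et[:6] = 15.0
        frames.append(long_table(et, feature="effective_time"))
        table = pd.concat(frames, ignore_index=True)
        results = run_feature_statistics(table, out_dir=tmp_path)
        assert (tmp_path / "table1.csv").exists()
        table2 = pd.read_csv(tmp_path / "table2.csv")
        assert set(table2["test"]) <= {"rm_anova", "friedman"}
        assert ("effective_time", "weekday") in results["friedman"]
        assert "steady_state" in results["anova"]
        assert (tmp_path / "heterogeneity.json").exists()

    def test_complete_cases_listwise_deletion(self):
        cube = np.random.default_rng(11).normal(size=(5, 3, 2))
        table = long_table(cube)
        table = table.drop(table.index[(table["participant"] == "p002")][0])
        out = complete_cases(table, "steady_state")
        assert out.shape == (4, 3, 2)
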