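import numpy as np
import pandas as pd
import pytest

from metacog import (TrialTable, ValidationError, corrupt_confidence,
                     dependence_report, difficulty_median_split,
                     fisher_average, icc_a1, normalize_precision,
                     precision_score, recode_bias, split_half)
from metacog import test_retest as retest  # avoid pytest name collection

from conftest import make_trials, random_trials


class TestCorruptConfidence:
    def _trials(self):
        # [(correct,3), (error,2), (correct,1), (error,4), (correct,4)], k=4
        stim = [1, 1, 1, 1, 1]
        resp = [1, 2, 1, 2, 1]     # resp==stim -> correct
        conf = [3, 2, 1, 4, 4]
        return make_trials(stim, resp, conf, 4)

    def test_hand_traced_loop(self):
        corrupted, n = corrupt_confidence(self._trials(), 0.4)
        assert n == 2
        assert list(corrupted.df["confidence"]) == [2, 3, 1, 4, 4]

    def test_zero_proportion_identity(self):
        trials = self._trials()
        out, n = corrupt_confidence(trials, 0.0)
        assert n == 0
        pd.testing.assert_frame_equal(out.df, trials.df)

    def test_nothing_corruptible_warns(self):
        trials = make_trials([1, 1], [1, 1], [1, 1], 4)  # correct, conf 1
        with pytest.warns(UserWarning, match="possible"):
            out, n = corrupt_confidence(trials, 1.0)
        assert n == 0
        pd.testing.assert_frame_equal(out.df, trials.df)

    def test_changes_exactly_n_ratings_by_one(self, rng):
        trials = random_trials(rng, 500)
        corrupted, n = corrupt_confidence(trials, 0.06)
        assert n == round(0.06 * 500)
        delta = corrupted.df["confidence"] - trials.df["confidence"]
        changed = delta != 0
        assert changed.sum() == n
        acc = trials.accuracy
        assert (delta[changed & acc] == -1).all()       # correct go down
        assert (delta[changed & ~acc] == 1).all()       # errors go up


class TestPrecision:
    def _bins_with_values(self, orig, corrupted_vals):
        """Bins whose measure is looked up by day label; corruption is
        detected through the confidence change it makes."""
        bins = []
        for i in range(len(orig)):
            # all correct, conf 3: corruption lowers some conf to 2
            b = make_trials([1] * 10, [1] * 10, [3] * 10, 4, day=[i] * 10)
            bins.append(b)
        table = {i: (orig[i], corrupted_vals[i]) for i in range(len(orig))}

        def fn(t):
            i = int(t.df["day"].iloc[0])
            pristine = (t.df["confidence"] == 3).all()
            return table[i][0] if pristine else table[i][1]
        return bins, fn

    def test_worked_example(self):
        bins, fn = self._bins_with_values([1.0, 1.2, 0.8, 1.0],
                                          [0.9, 1.1, 0.7, 0.9])
        res = precision_score("toy", bins, 0.1, fn)
        assert res.sd_orig == pytest.approx(0.16329932, abs=1e-6)
        assert res.precision == pytest.approx(0.61237244, abs=1e-6)

    def test_identical_values_give_zero(self):
        bins, fn = self._bins_with_values([1.0, 1.2, 0.8], [1.0, 1.2, 0.8])
        res = precision_score("toy", bins, 0.1, fn)
        assert res.precision == pytest.approx(0.0)

    def test_recomputable_from_stored_components(self):
        bins, fn = self._bins_with_values([1.0, 1.2, 0.8, 1.0],
                                          [0.9, 1.15, 0.75, 0.95])
        res = precision_score("toy", bins, 0.1, fn)
        again = np.mean((res.per_bin_orig - res.per_bin_corrupted) / res.sd_orig)
        assert res.precision == pytest.approx(float(again), abs=1e-12)
        assert res.sd_orig == pytest.approx(float(np.std(res.per_bin_orig, ddof=1)))

    def test_needs_two_bins(self):
        bins, fn = self._bins_with_values([1.0], [0.9])
        with pytest.raises(ValidationError):
            precision_score("toy", bins, 0.1, fn)


class TestNormalizePrecision:
    def test_reference_average_becomes_one(self):
        scores = {f"m{i}": 0.67 for i in range(16)}
        scores["meta-uncertainty"] = 0.37
        out = normalize_precision(scores)
        assert out["m0"] == pytest.approx(1.0)
        assert out["meta-uncertainty"] == pytest.approx(0.37 / 0.67)

    def test_scale_invariance(self):
        scores = {"a": 0.3, "b": 0.6, "meta-uncertainty": 0.2}
        out1 = normalize_precision(scores)
        out2 = normalize_precision({k: 2 * v for k, v in scores.items()})
        for k in scores:
            assert out1[k] == pytest.approx(out2[k])


class TestRecodeBias:
    def test_low_and_high_recodings(self):
        trials = make_trials([1] * 4, [1] * 4, [1, 2, 3, 4], 4)
        low = recode_bias(trials, "low")
        high = recode_bias(trials, "high")
        assert list(low.df["confidence"]) == [1, 1, 2, 3]
        assert list(high.df["confidence"]) == [1, 2, 3, 3]
        assert low.scale_points == high.scale_points == 3

    def test_preserves_accuracy_and_count(self, rng):
        trials = random_trials(rng, 200)
        for direction in ("low", "high"):
            out = recode_bias(trials, direction)
            assert out.n_trials == trials.n_trials
            np.testing.assert_array_equal(out.accuracy, trials.accuracy)

    def test_induced_bias_direction(self, rng):
        trials = random_trials(rng, 400)  # contains mid-scale ratings
        low = recode_bias(trials, "low").df["confidence"].mean()
        high = recode_bias(trials, "high").df["confidence"].mean()
        assert low < high


class TestIccA1:
    def test_identical_columns_give_one(self):
        x = np.column_stack([[1.0, 2, 3, 4, 5]] * 2)
        assert icc_a1(x) == pytest.approx(1.0)

    def test_against_pingouin_oracle(self):
        import pingouin as pg

        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.1, 2.9, 4.2, 4.8])   # roughly a + 1
        x = np.column_stack([a, b])
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(4), 2),
            "raters": np.tile(["r1", "r2"], 4),
            "scores": x.reshape(-1),
        })
        icc = pg.intraclass_corr(data=long, targets="targets",
                                 raters="raters", ratings="scores")
        types = icc.set_index("Type")["ICC"]
        oracle = float(types.get("ICC(A,1)", types.get("ICC2")))
        assert icc_a1(x) == pytest.approx(oracle, abs=1e-10)
        # the day-to-day mean shift is penalized: Pearson r is higher
        assert icc_a1(x) < float(np.corrcoef(a, b)[0, 1])

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10_000, 2))
        assert abs(icc_a1(x)) < 0.05

    def test_approaches_pearson_for_matched_columns(self):
        # equal column means and variances: the absolute-agreement penalty
        # shrinks at rate O(1/n)
        rng = np.random.default_rng(2)
        a = rng.normal(size=2000)
        noise = rng.normal(size=2000)
        b = 0.6 * a + 0.8 * noise
        b = (b - b.mean()) / b.std() * a.std() + a.mean()
        x = np.column_stack([a, b])
        r = float(np.corrcoef(a, b)[0, 1])
        assert icc_a1(x) == pytest.approx(r, abs=5e-3)


class TestFisherAverage:
    def test_identical_values_returned_exactly(self):
        assert fisher_average([0.42, 0.42, 0.42]) == pytest.approx(0.42, abs=1e-12)

    def test_handles_nan_and_extremes(self):
        assert fisher_average([np.nan, 0.5]) == pytest.approx(0.5, abs=1e-9)
        assert fisher_average([]) is not None  # nan, not crash


def _mean_conf(trials):
    return float(trials.df["confidence"].mean())


class TestSplitHalf:
    def _cohort(self, n_participants=60, n_trials=200, trait_sd=0.8,
                trial_sd=1.0, seed=0, k=7):
        rng = np.random.default_rng(seed)
        frames = []
        for pid in range(n_participants):
            trait = 4 + rng.normal(0, trait_sd)
            conf = np.clip(np.round(trait + rng.normal(0, trial_sd, n_trials)),
                           1, k).astype(int)
            frames.append(pd.DataFrame({
                "participant": pid, "stimulus": 1,
                "response": rng.integers(1, 3, n_trials),
                "confidence": conf}))
        return TrialTable(pd.concat(frames, ignore_index=True), k)

    def test_identical_halves_give_r_one(self):
        # duplicated trials: odd and even positions identical by construction
        frames = []
        rng = np.random.default_rng(3)
        for pid in range(6):
            conf = rng.integers(1, 5, 50)
            dup = np.repeat(conf, 2)
            frames.append(pd.DataFrame({
                "participant": pid, "stimulus": 1, "response": 1,
                "confidence": dup}))
        trials = TrialTable(pd.concat(frames, ignore_index=True), 4)
        res = split_half("mean_conf", trials, 50, _mean_conf)
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)

    def test_matches_classical_test_theory(self):
        trait_sd, trial_sd, bin_size = 0.8, 1.0, 100
        trials = self._cohort(trait_sd=trait_sd, trial_sd=trial_sd,
                              n_trials=2 * bin_size, n_participants=400)
        res = split_half("mean_conf", trials, bin_size, _mean_conf)
        half_noise_var = trial_sd ** 2 / bin_size
        expected_r = trait_sd ** 2 / (trait_sd ** 2 + half_noise_var)
        assert res.coefficient == pytest.approx(expected_r, abs=0.05)


class TestTestRetest:
    def _multi_day(self, trait_sd=1.0, day_sd=0.5, trial_sd=1.0,
                   n_participants=80, n_days=2, per_day=200, seed=4, k=9):
        rng = np.random.default_rng(seed)
        frames = []
        for pid in range(n_participants):
            trait = 5 + rng.normal(0, trait_sd)
            for day in range(1, n_days + 1):
                level = trait + rng.normal(0, day_sd)
                conf = np.clip(np.round(level + rng.normal(0, trial_sd, per_day)),
                               1, k).astype(int)
                frames.append(pd.DataFrame({
                    "participant": pid, "stimulus": 1, "response": 1,
                    "confidence": conf, "day": day}))
        return TrialTable(pd.concat(frames, ignore_index=True), k)

    def test_duplicated_day_gives_icc_one(self):
        trials = self._multi_day(n_days=1)
        df2 = trials.df.copy()
        df2["day"] = 2
        doubled = TrialTable(pd.concat([trials.df, df2], ignore_index=True), 9)
        icc, pearson = retest("mean_conf", doubled, 100, _mean_conf)
        assert icc.coefficient == pytest.approx(1.0, abs=1e-9)
        assert pearson.coefficient == pytest.approx(1.0, abs=1e-9)

    def test_recovers_trait_variance_share(self):
        trait_sd, day_sd, trial_sd, bin_size = 1.0, 0.5, 1.0, 200
        trials = self._multi_day(trait_sd, day_sd, trial_sd,
                                 per_day=bin_size, n_participants=300)
        icc, _ = retest("mean_conf", trials, bin_size, _mean_conf)
        expected = trait_sd ** 2 / (trait_sd ** 2 + day_sd ** 2
                                    + trial_sd ** 2 / bin_size)
        assert icc.coefficient == pytest.approx(expected, abs=0.07)

    def test_requires_day_labels(self, rng):
        with pytest.raises(ValidationError, match="day"):
            retest("m", random_trials(rng, 100), 50, _mean_conf)


class TestDependence:
    def test_identical_levels_give_zero_effect(self):
        rng = np.random.default_rng(5)
        base = rng.normal(1.0, 0.3, 30)
        df = pd.DataFrame({
            "participant": np.tile(np.arange(30), 2),
            "level": np.repeat(["easy", "hard"], 30),
            "value": np.concatenate([base, base]),
        })
        res = dependence_report(df, "m", "task_performance", "two_level_ttest")
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_cohens_d_arithmetic(self):
        rng = np.random.default_rng(6)
        n = 4000
        a = rng.normal(1.0, 0.5, n)
        b = rng.normal(0.5, 0.5, n)
        df = pd.DataFrame({
            "participant": np.tile(np.arange(n), 2),
            "level": np.repeat([1, 2], n),
            "value": np.concatenate([a, b]),
        })
        res = dependence_report(df, "m", "task_performance", "two_level_ttest")
        assert res.cohens_d == pytest.approx(1.0, abs=0.08)
        assert res.p_value < 1e-6

    def test_outliers_removed_before_test(self):
        values = np.concatenate([np.random.default_rng(7).normal(0, 1, 50), [40.0]])
        df = pd.DataFrame({
            "participant": np.concatenate([np.arange(51), np.arange(51)]),
            "level": np.repeat([1, 2], 51),
            "value": np.concatenate([values, values]),
        })
        res = dependence_report(df, "m", "task_performance", "two_level_ttest")
        assert res.dof == 49  # the 3-SD outlier participant dropped per level

    def test_rm_anova_partial_eta_squared(self):
        rng = np.random.default_rng(8)
        n, levels = 40, 4
        subject_effect = rng.normal(0, 1.0, n)
        rows = []
        for lvl in range(levels):
            rows.append(pd.DataFrame({
                "participant": np.arange(n),
                "level": lvl,
                "value": subject_effect + 0.5 * lvl + rng.normal(0, 0.5, n),
            }))
        df = pd.concat(rows, ignore_index=True)
        res = dependence_report(df, "c", "response_bias", "rm_anova")
        assert res.f_stat > 10
        assert 0 < res.partial_eta_sq <= 1

    def test_abs_c_correlation(self):
        rng = np.random.default_rng(9)
        rows = []
        for pid in range(12):
            c = rng.normal(0, 0.8, 7)
            value = 0.9 * np.abs(c) + rng.normal(0, 0.1, 7)
            rows.append(pd.DataFrame({"participant": pid,
                                      "level": np.arange(7),
                                      "value": value, "c": c}))
        df = pd.concat(rows, ignore_index=True)
        res = dependence_report(df, "m", "response_bias", "abs_c_correlation")
        assert res.mean_abs_c_correlation > 0.8


class TestDifficultySplit:
    def test_uniform_levels_split_evenly(self):
        trials = make_trials([1] * 70, [1] * 70, [2] * 70, 4,
                             difficulty=np.arange(1, 71))
        out = difficulty_median_split(trials)
        share = (out.df["difficulty"] == "difficult").mean()
        assert abs(share - 0.5) <= 1 / 70

    def test_constant_difficulty_rejected(self):
        trials = make_trials([1] * 10, [1] * 10, [2] * 10, 4,
                             difficulty=[3] * 10)
        with pytest.raises(ValidationError, match="constant"):
            difficulty_median_split(trials)

    def test_invariant_to_affine_rescaling(self):
        diff = np.array([1, 5, 2, 9, 7, 3, 8, 4, 6, 10])
        t1 = make_trials([1] * 10, [1] * 10, [2] * 10, 4, difficulty=diff)
        t2 = make_trials([1] * 10, [1] * 10, [2] * 10, 4,
                         difficulty=10 * diff + 3)
        out1 = difficulty_median_split(t1)
        out2 = difficulty_median_split(t2)
        assert list(out1.df["difficulty"]) == list(out2.df["difficulty"])
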