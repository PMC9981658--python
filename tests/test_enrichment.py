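import datetime as dt
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cyclewell as cw
from cyclewell.enrichment import (
    Z_CRIT_05,
    Z_CRIT_10,
    binarize_top_quintile,
    chisq_uniform_gof,
    normalized_phase_counts,
    residual_flags,
    symptom_sums,
)


def oracle_top_quintile(values, q=0.8):
    """Plain order-statistic oracle: flag iff strictly above the ceil(qn)-th value."""
    clean = sorted(v for v in values if not math.isnan(v))
    cut = clean[math.ceil(q * len(clean)) - 1]
    return [0 if math.isnan(v) else int(v > cut) for v in values]


class TestBinarizeTopQuintile:
    def test_one_to_ten_flags_nine_and_ten(self):
        values = list(range(1, 11))
        flags = binarize_top_quintile(values)
        assert [v for v, f in zip(values, flags) if f] == [9, 10]

    def test_all_identical_flags_nothing(self):
        assert binarize_top_quintile([5] * 10).sum() == 0

    def test_single_outlier_is_the_only_flag(self):
        values = [5] * 9 + [10]
        flags = binarize_top_quintile(values)
        assert flags.sum() == 1 and flags[-1] == 1

    def test_too_few_values_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            assert binarize_top_quintile([1, 2, 3, 4]) is None

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_order_statistic_oracle_on_tied_likert_data(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 11, size=rng.integers(5, 60)).astype(float)
        assert binarize_top_quintile(values).tolist() == oracle_top_quintile(values)

    @pytest.mark.parametrize("seed", range(10))
    def test_never_flags_more_than_a_fifth(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 11, size=50).astype(float)
        assert binarize_top_quintile(values).sum() <= 10


def table(athletes, phases, tops, cycles=None):
    return pd.DataFrame(
        dict(
            athlete_id=athletes,
            phase=phases,
            top=tops,
            cycle_index=cycles if cycles is not None else [1] * len(athletes),
        )
    )


class TestNormalizedPhaseCounts:
    def test_uniform_spread_gives_equal_counts(self):
        t = table(["a"] * 6, ["p1", "p1", "p2", "p2", "p3", "p3"], [1, 0, 1, 0, 1, 0])
        obs = normalized_phase_counts(t, ("p1", "p2", "p3"))
        assert np.allclose(obs, [1, 1, 1])

    def test_concentrated_tops_take_all_mass(self):
        t = table(["a"] * 6, ["p1", "p1", "p2", "p2", "p3", "p3"], [1, 1, 0, 0, 0, 0])
        obs = normalized_phase_counts(t, ("p1", "p2", "p3"))
        assert np.allclose(obs, [2, 0, 0])

    def test_exposure_invariance_across_athletes(self):
        # athlete b has twice a's exposure but identical per-phase rates:
        # the normalized distribution must match the single-athlete answer
        a = table(["a"] * 4, ["p1", "p1", "p2", "p2"], [1, 0, 0, 0])
        b = table(["b"] * 8, ["p1"] * 4 + ["p2"] * 4, [1, 1, 0, 0, 0, 0, 0, 0])
        both = pd.concat([a, b], ignore_index=True)
        obs_a = normalized_phase_counts(a, ("p1", "p2"))
        obs_both = normalized_phase_counts(both, ("p1", "p2"))
        # identical rate profiles (0.5, 0): all mass in p1 in both cases
        assert np.allclose(obs_a / obs_a.sum(), obs_both / obs_both.sum())

    def test_counts_rescale_to_raw_top_total(self):
        t = table(["a"] * 4 + ["b"] * 4, ["p1", "p2"] * 4, [1, 0, 1, 0, 0, 1, 0, 0])
        obs = normalized_phase_counts(t, ("p1", "p2"))
        assert obs.sum() == pytest.approx(3)  # 3 raw flagged days

    def test_phase_with_no_exposure_raises(self):
        t = table(["a"] * 2, ["p1", "p1"], [1, 0])
        with pytest.raises(ValueError, match="p2"):
            normalized_phase_counts(t, ("p1", "p2"))


class TestChisqUniformGof:
    def test_perfect_uniformity(self):
        chi2, df, p = chisq_uniform_gof([10] * 6)
        assert chi2 == 0 and df == 5 and p == pytest.approx(1.0)

    def test_textbook_example(self):
        chi2, df, p = chisq_uniform_gof([20, 10, 10, 10, 5, 5])
        assert chi2 == pytest.approx(15.0)
        assert df == 5
        assert p == pytest.approx(0.010362, abs=1e-6)

    def test_two_equal_cells(self):
        chi2, _, _ = chisq_uniform_gof([30, 30])
        assert chi2 == 0

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            chisq_uniform_gof([10], k=1)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        obs = rng.integers(1, 80, size=k).astype(float)
        chi2, df, p = chisq_uniform_gof(obs)
        ref_chi2, ref_p = stats.chisquare(obs)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_invariant_under_phase_relabeling(self):
        obs = np.array([20.0, 10, 10, 10, 5, 5])
        chi2_a, _, _ = chisq_uniform_gof(obs)
        rng = np.random.default_rng(0)
        for _ in range(5):
            chi2_b, _, _ = chisq_uniform_gof(rng.permutation(obs))
            assert chi2_b == pytest.approx(chi2_a)


class TestResidualFlags:
    def test_large_positive_residual(self):
        r, flags = residual_flags([20.0], [10.0], global_p=0.01)
        assert r[0] == pytest.approx((20 - 10) / np.sqrt(10))
        assert flags == ("over_05",)

    def test_threshold_bands(self):
        exp = np.ones(3)
        obs = exp + np.array([-1.8, 1.0, 2.5])  # residuals -1.8, 1.0, 2.5
        _, flags = residual_flags(obs, exp, global_p=0.01)
        assert flags == ("under_10", "none", "over_05")

    def test_gate_suppresses_flags_when_omnibus_not_significant(self):
        _, flags = residual_flags([20.0, 0.0], [10.0, 10.0], global_p=0.3)
        assert flags == ("none", "none")

    def test_printed_critical_values(self):
        assert round(Z_CRIT_05, 2) == 1.96
        assert round(Z_CRIT_10, 2) == 1.64

    def test_weighted_residual_sum_is_zero_after_normalization(self):
        rng = np.random.default_rng(3)
        obs = rng.random(6) * 30
        exp = np.full(6, obs.sum() / 6)
        r, _ = residual_flags(obs, exp, global_p=0.01)
        assert float(r @ np.sqrt(exp)) == pytest.approx(0.0, abs=1e-9)


class TestSymptomSums:
    def test_counts_follow_declarations(self):
        start = dt.date(2021, 2, 1)
        records = [
            cw.DailyRecord("A", start, True, symptoms=frozenset({"cramps"})),
            cw.DailyRecord("A", start + dt.timedelta(days=1), True, symptoms=frozenset({"cramps"})),
            cw.DailyRecord("A", start + dt.timedelta(days=25), False, symptoms=frozenset({"cramps", "headaches"})),
        ]
        labels = pd.DataFrame(
            dict(
                athlete_id=["A"] * 3,
                date=[r.date for r in records],
                cycle_index=1,
                cycle_day=[1, 2, 26],
                scheme="mc6",
                phase=["menses", "menses", "premenstrual"],
            )
        )
        out = symptom_sums(records, labels)
        assert out.loc["menses", "cramps"] == 2
        assert out.loc["premenstrual", "total"] == 2

    def test_no_symptoms_means_zero_totals(self, default_cohort):
        _, profiles, records, _ = default_cohort
        bare = [
            cw.DailyRecord(r.athlete_id, r.date, r.bleeding) for r in records
        ]
        labels = cw.label_cohort(bare, profiles, "mc6")
        out = symptom_sums(bare, labels)
        assert (out["total"] == 0).all()


class TestRunEnrichment:
    def test_planted_mid_cycle_boost_is_recovered(self, default_cohort):
        _, profiles, records, _ = default_cohort
        results = {r.variable: r for r in cw.run_enrichment(records, profiles, "mc6")}
        mood = results["mood"]
        assert mood.significant
        idx = dict(zip(mood.phase_order, range(len(mood.phase_order))))
        assert mood.flags[idx["late_follicular"]] == "over_05"
        assert mood.flags[idx["menses"]].startswith("under")

    def test_hc_scheme_uses_pill_phases(self, default_cohort):
        _, profiles, records, _ = default_cohort
        results = cw.run_enrichment(records, profiles, "hc", variables=("self_performance",))
        (res,) = results
        assert res.phase_order == ("pause", "phase1", "phase2")
        assert res.df == 2

    def test_binary_scheme_pools_cohort_for_coach_scores(self, default_cohort):
        _, profiles, records, _ = default_cohort
        (res,) = cw.run_enrichment(records, profiles, "binary", variables=("coach_performance",))
        assert res.phase_order == ("menses", "no_menses")
        assert res.k == 2

    def test_athlete_without_a_variable_drops_from_that_variable_only(self, default_cohort):
        _, profiles, records, _ = default_cohort
        blanked = [
            cw.DailyRecord(
                r.athlete_id,
                r.date,
                r.bleeding,
                sleep_quality=r.sleep_quality,
                fitness=r.fitness,
                mood=None if r.athlete_id == "MC01" else r.mood,
                self_performance=r.self_performance,
            )
            for r in records
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = {r.variable: r for r in cw.run_enrichment(blanked, profiles, "mc6")}
        assert results["mood"].n_athletes == results["fitness"].n_athletes - 1
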