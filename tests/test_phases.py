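import datetime as dt
import warnings

import numpy as np
import pytest

import cyclewell as cw
from cyclewell.phases import (
    DEFAULT_WINDOWS,
    HormonePhaseSummary,
    Mc6Phase,
    hc_phase_count,
)

START = dt.date(2021, 2, 1)


def calendar(n_days, bleed_days, athlete_id="A"):
    """Daily records with bleeding on the given 1-based day numbers."""
    return [
        cw.DailyRecord(athlete_id, START + dt.timedelta(days=i), (i + 1) in bleed_days)
        for i in range(n_days)
    ]


def brute_force_onsets(bleed_days, gap=14):
    """Independent onset scan: bleeding day with a bleed-free 14-day lookback."""
    days = sorted(bleed_days)
    return [d for d in days if all((d - g) not in bleed_days for g in range(1, gap + 1))]


class TestSegmentCycles:
    def test_two_onsets_make_one_complete_cycle(self):
        bleed = set(range(1, 6)) | set(range(29, 34))
        (cycle,) = cw.segment_cycles(calendar(40, bleed))
        assert (cycle.start_date, cycle.length, cycle.bleed_length) == (START, 28, 5)
        assert cycle.predicted_ovulation == 14

    def test_no_bleeding_yields_no_cycles(self):
        assert cw.segment_cycles(calendar(90, set())) == []

    def test_single_onset_is_incomplete(self):
        assert cw.segment_cycles(calendar(40, {1, 2, 3})) == []

    def test_one_day_gap_in_menses_does_not_split_the_onset(self):
        # days 1-2 and 4-5 bleed; day 3 missing: still one onset on day 1
        bleed = {1, 2, 4, 5} | set(range(29, 34))
        (cycle,) = cw.segment_cycles(calendar(40, bleed))
        assert cycle.start_date == START
        assert cycle.bleed_length == 4

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_onset_scan_and_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        bleed_days = set()
        day = 1
        while day < 160:
            for k in range(int(rng.integers(2, 7))):
                if day + k <= 170 and rng.random() < 0.9:  # self-report noise
                    bleed_days.add(day + k)
            day += int(rng.integers(21, 36))
        records = calendar(170, bleed_days)
        cycles = cw.segment_cycles(records)
        onsets = brute_force_onsets(bleed_days)
        starts = [START + dt.timedelta(days=o - 1) for o in onsets[:-1]]
        assert [c.start_date for c in cycles] == starts
        lengths = [b - a for a, b in zip(onsets, onsets[1:])]
        assert [c.length for c in cycles] == lengths
        assert cw.segment_cycles(records) == cycles  # idempotent


class TestPredictOvulation:
    @pytest.mark.parametrize("length,expected", [(28, 14), (35, 21), (21, 7)])
    def test_fixed_luteal_rule(self, length, expected):
        assert cw.predict_ovulation(length, bleed_length=5) == expected

    def test_short_cycle_warns_and_scales_proportionally(self):
        with pytest.warns(UserWarning, match="proportional"):
            po = cw.predict_ovulation(18, bleed_length=4)
        assert 5 <= po <= 12

    def test_clamped_above_bleeding(self):
        assert cw.predict_ovulation(21, bleed_length=7) == 8


def make_cycle(length, bleed):
    po = cw.predict_ovulation(length, bleed)
    return cw.CycleSpan("A", 1, START, length, bleed, po)


class TestClassifyMcPhase:
    @pytest.mark.parametrize(
        "day,phase",
        [
            (3, Mc6Phase.MENSES),
            (8, Mc6Phase.MID_FOLLICULAR),
            (14, Mc6Phase.LATE_FOLLICULAR),
            (16, Mc6Phase.EARLY_LUTEAL),
            (24, Mc6Phase.MID_LUTEAL),
            (28, Mc6Phase.PREMENSTRUAL),
        ],
    )
    def test_reference_28_day_cycle_anchors(self, day, phase):
        assert cw.classify_mc_phase(day, make_cycle(28, 5)) is phase

    def test_day_out_of_range_errors(self):
        with pytest.raises(ValueError):
            cw.classify_mc_phase(29, make_cycle(28, 5))

    @pytest.mark.parametrize("length", range(21, 36))
    @pytest.mark.parametrize("bleed", [1, 3, 5, 7])
    def test_phases_partition_every_cycle(self, length, bleed):
        cycle = make_cycle(length, bleed)
        labels = [cw.classify_mc_phase(d, cycle) for d in range(1, length + 1)]
        counts = {p: labels.count(p) for p in Mc6Phase}
        assert sum(counts.values()) == length
        assert counts[Mc6Phase.MENSES] == bleed
        assert counts[Mc6Phase.PREMENSTRUAL] == DEFAULT_WINDOWS.premenstrual

    @pytest.mark.parametrize("length", range(21, 36))
    @pytest.mark.parametrize("bleed", [1, 3, 5, 7])
    def test_predicted_ovulation_day_is_late_follicular(self, length, bleed):
        cycle = make_cycle(length, bleed)
        assert cw.classify_mc_phase(cycle.predicted_ovulation, cycle) is Mc6Phase.LATE_FOLLICULAR

    @pytest.mark.parametrize("length", range(26, 36))
    @pytest.mark.parametrize("bleed", [1, 3, 5, 7])
    def test_day8_is_mid_follicular_when_geometry_allows(self, length, bleed):
        # day 8 sits between menses and the late-follicular window whenever
        # P.O - 4 >= 8, i.e. cycles of 26+ days under the length-14 rule
        assert cw.classify_mc_phase(8, make_cycle(length, bleed)) is Mc6Phase.MID_FOLLICULAR

    @pytest.mark.parametrize("length", range(21, 36))
    def test_mid_luteal_peak_day(self, length):
        # 10 days after an unclamped P.O lands mid-luteal (4 days before the
        # premenstrual window for every length under the fixed-luteal rule)
        bleed = 5
        cycle = make_cycle(length, bleed)
        if cycle.predicted_ovulation == length - 14:
            day = cycle.predicted_ovulation + 10
            assert cw.classify_mc_phase(day, cycle) is Mc6Phase.MID_LUTEAL

    def test_short_cycle_scales_windows_instead_of_failing(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cycle = make_cycle(18, 3)
            labels = {cw.classify_mc_phase(d, cycle) for d in range(1, 19)}
        assert Mc6Phase.LATE_FOLLICULAR in labels and Mc6Phase.PREMENSTRUAL in labels


class TestClassifyHcPhase:
    biphasic = cw.AthleteProfile("H", cw.Group.HC_USER, cw.PillType.BIPHASIC)
    monophasic = cw.AthleteProfile("H", cw.Group.HC_USER, cw.PillType.MONOPHASIC)

    def test_pause_days(self):
        assert cw.classify_hc_phase(3, self.biphasic) is cw.HcPhase.PAUSE

    def test_monophasic_has_single_active_phase(self):
        assert cw.classify_hc_phase(12, self.monophasic) is cw.HcPhase.PHASE1
        assert cw.classify_hc_phase(28, self.monophasic) is cw.HcPhase.PHASE1
        assert hc_phase_count(self.monophasic) == 2

    def test_biphasic_splits_after_active_day_10(self):
        assert cw.classify_hc_phase(17, self.biphasic) is cw.HcPhase.PHASE1  # active day 10
        assert cw.classify_hc_phase(25, self.biphasic) is cw.HcPhase.PHASE2  # active day 18
        assert hc_phase_count(self.biphasic) == 3

    def test_regimen_day_out_of_pack_errors(self):
        with pytest.raises(ValueError):
            cw.classify_hc_phase(29, self.biphasic)


class TestClassifyBinary:
    def test_bleeding_flag_decides(self):
        rec = cw.DailyRecord("A", START, True)
        assert cw.classify_binary(rec) is cw.BinaryPhase.MENSES
        rec = cw.DailyRecord("A", START, False)
        assert cw.classify_binary(rec) is cw.BinaryPhase.NO_MENSES

    def test_hc_withdrawal_bleeding_counts_as_menses(self):
        # the binary scheme ignores contraception status entirely
        rec = cw.DailyRecord("H", START, True)
        assert cw.classify_binary(rec) is cw.BinaryPhase.MENSES


class TestLabelCohort:
    def test_binary_labels_equal_bleeding_days(self, default_cohort):
        _, profiles, records, _ = default_cohort
        labels = cw.label_cohort(records, profiles, "binary")
        assert len(labels) == len(records)
        n_menses = (labels["phase"] == "menses").sum()
        assert n_menses == sum(r.bleeding for r in records)

    def test_mc6_labels_partition_each_complete_cycle(self, default_cohort):
        _, profiles, records, _ = default_cohort
        labels = cw.label_cohort(records, profiles, "mc6")
        assert set(labels["athlete_id"]).issubset({f"MC{i:02d}" for i in range(1, 7)})
        assert set(labels["phase"]) <= set(p.value for p in Mc6Phase)

    def test_hc_bleeding_days_fall_in_pause(self, default_cohort):
        _, profiles, records, _ = default_cohort
        labels = cw.label_cohort(records, profiles, "hc")
        bleeding = {(r.athlete_id, r.date) for r in records if r.bleeding}
        in_cycles = labels.set_index(["athlete_id", "date"])["phase"]
        phases = [in_cycles.get(k) for k in bleeding if k in in_cycles.index]
        assert phases and all(p == "pause" for p in phases)


def summary(phase, e_mean, p_mean):
    return HormonePhaseSummary(phase, e_mean, 1.0, p_mean, 1.0, 25)


class TestHormoneOrdering:
    def test_published_style_means_pass_all_checks(self):
        summaries = {
            Mc6Phase.MID_FOLLICULAR: summary(Mc6Phase.MID_FOLLICULAR, 2.5, 38.1),
            Mc6Phase.LATE_FOLLICULAR: summary(Mc6Phase.LATE_FOLLICULAR, 6.9, 42.8),
            Mc6Phase.MID_LUTEAL: summary(Mc6Phase.MID_LUTEAL, 6.0, 81.85),
        }
        check = cw.check_hormone_ordering(summaries)
        assert check.all_pass

    def test_tied_estradiol_fails_strict_peak(self):
        summaries = {
            Mc6Phase.MID_FOLLICULAR: summary(Mc6Phase.MID_FOLLICULAR, 5.0, 38.1),
            Mc6Phase.LATE_FOLLICULAR: summary(Mc6Phase.LATE_FOLLICULAR, 5.0, 42.8),
            Mc6Phase.MID_LUTEAL: summary(Mc6Phase.MID_LUTEAL, 5.0, 81.85),
        }
        check = cw.check_hormone_ordering(summaries)
        assert check.estradiol_peak_late_follicular is False

    def test_missing_phase_is_indeterminate(self):
        summaries = {Mc6Phase.MID_LUTEAL: summary(Mc6Phase.MID_LUTEAL, 6.0, 81.85)}
        check = cw.check_hormone_ordering(summaries)
        assert check.progesterone_peak_mid_luteal is None
        assert check.estradiol_peak_late_follicular is None
        assert not check.all_pass
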