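"""Coverage timelines, combination/switch rules, belatacept algorithm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ktxclaims as k
from ktxclaims.config import (ANTIMETABOLITE, BELATACEPT, CNI, CORTICOSTEROID,
                              MTORI, group_of)
from ktxclaims.exposure import (detect_belatacept, detect_combinations,
                                detect_switches, initial_regimen, merge_covers,
                                _group_intervals)
import oracles


def deliveries_frame(rows):
    """rows: list of (day, drug_class)."""
    return pd.DataFrame(rows, columns=["day", "drug_class"])


def stays_frame(rows):
    """rows: list of (day, is_chemo, principal, associated)."""
    return pd.DataFrame(rows, columns=[
        "day", "is_chemo_delivery", "principal_diagnosis", "associated_diagnoses"])


class TestBuildTimeline:
    def test_abutting_deliveries_merge_to_single_interval(self, code_config):
        tl = k.build_timeline(
            deliveries_frame([(0, "tacrolimus"), (30, "tacrolimus"), (60, "tacrolimus")]),
            code_config)
        assert tl.intervals["tacrolimus"] == [(0, 90)]

    def test_long_gap_splits_intervals(self, code_config):
        tl = k.build_timeline(
            deliveries_frame([(0, "tacrolimus"), (200, "tacrolimus")]), code_config)
        assert tl.intervals["tacrolimus"] == [(0, 30), (200, 230)]

    def test_unknown_class_ignored(self, code_config):
        tl = k.build_timeline(deliveries_frame([(0, "other")]), code_config)
        assert tl.intervals == {}

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=30))
    def test_matches_bitmap_oracle(self, days):
        config = k.default_config()
        w = config.windows
        got = merge_covers(np.array(days), w.coverage_days, w.merge_gap_days)
        assert got == oracles.coverage_bruteforce(days, w.coverage_days, w.merge_gap_days)

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=25))
    def test_every_delivery_lies_in_exactly_one_interval(self, days):
        config = k.default_config()
        tl = k.build_timeline(
            deliveries_frame([(d, "everolimus") for d in days]), config)
        for d in days:
            containing = [iv for iv in tl.intervals["everolimus"]
                          if iv[0] <= d < iv[1]]
            assert len(containing) == 1


class TestDetectCombinations:
    def test_full_year_dual_therapy_is_recognized_combination(self, code_config):
        tl = k.build_timeline(deliveries_frame(
            [(d, "tacrolimus") for d in range(0, 365, 30)]
            + [(d, "mycophenolic_acid") for d in range(0, 365, 30)]), code_config)
        periods = detect_combinations(tl, code_config)
        assert len(periods) == 1
        p = periods[0]
        assert p.classes == frozenset({CNI, ANTIMETABOLITE})
        assert p.recognized and (p.end - p.start) >= 365

    def test_short_terminal_overlap_is_not_a_combination(self, code_config):
        """A 25-day overlap at a transition is slack, not a combination."""
        tl = k.ExposureTimeline("x", {"tacrolimus": [(0, 365)],
                                      "everolimus": [(340, 365)]})
        periods = detect_combinations(tl, code_config)
        assert [p.classes for p in periods] == [frozenset({CNI})]
        assert periods[0].start == 0 and periods[0].end == 365

    def test_unrecognized_long_overlap_flagged_not_recognized(self, code_config):
        tl = k.ExposureTimeline("x", {"tacrolimus": [(0, 200)],
                                      "belatacept": [(0, 200)]})
        periods = detect_combinations(tl, code_config)
        assert len(periods) == 1
        assert not periods[0].recognized

    @given(st.data())
    def test_matches_per_day_scan_oracle(self, data):
        config = k.default_config()
        classes = ["tacrolimus", "everolimus", "mycophenolic_acid", "corticosteroid"]
        rows = []
        for c in classes:
            days = data.draw(st.lists(st.integers(0, 300), max_size=12))
            rows += [(d, c) for d in days]
        if not rows:
            return
        tl = k.build_timeline(deliveries_frame(rows), config)
        got = [(p.start, p.end, p.classes) for p in detect_combinations(tl, config)]
        expected = oracles.regimen_periods_bruteforce(
            _group_intervals(tl), config.windows.combination_min_days,
            lambda s: {g for g in s if g != CORTICOSTEROID})
        assert got == expected

    def test_steroid_coverage_never_affects_backbone_recognition(self, code_config):
        """Toggling corticosteroid deliveries must not change the non-steroid
        backbone of any recognized period."""
        base = [(d, "tacrolimus") for d in range(0, 365, 30)] + \
               [(d, "mycophenolic_acid") for d in range(0, 365, 30)]
        steroids = [(d, "corticosteroid") for d in range(15, 200, 30)]
        without = detect_combinations(k.build_timeline(deliveries_frame(base), code_config),
                                      code_config)
        with_s = detect_combinations(
            k.build_timeline(deliveries_frame(base + steroids), code_config), code_config)
        backbone = lambda periods: [
            (frozenset(g for g in p.classes if g != CORTICOSTEROID), p.recognized)
            for p in periods]
        assert {b for b, _ in backbone(with_s)} >= {b for b, _ in backbone(without)}
        assert all(rec for _, rec in backbone(with_s))


class TestDetectBelatacept:
    DX = "Z940"

    def test_three_stays_companion_and_no_cni_is_positive(self, code_config):
        stays = stays_frame([(0, 1, "", self.DX), (30, 1, "", self.DX),
                             (60, 1, "", self.DX)])
        deliv = deliveries_frame([(10, "mycophenolic_acid")])
        call = detect_belatacept(stays, deliv, code_config)
        assert call.positive and call.source == "algorithm"
        assert call.index_hospitalization_day == 0

    def test_two_stays_only_is_negative(self, code_config):
        stays = stays_frame([(0, 1, "", self.DX), (30, 1, "", self.DX)])
        deliv = deliveries_frame([(10, "mycophenolic_acid")])
        call = detect_belatacept(stays, deliv, code_config)
        assert not call.positive and not call.three_stays_90d

    def test_cni_in_fourth_month_is_negative(self, code_config):
        stays = stays_frame([(0, 1, "", self.DX), (30, 1, "", self.DX),
                             (60, 1, "", self.DX)])
        deliv = deliveries_frame([(10, "mycophenolic_acid"), (100, "tacrolimus")])
        call = detect_belatacept(stays, deliv, code_config)
        assert not call.positive and not call.no_cni_fourth_month

    def test_chemo_stay_without_transplant_code_does_not_qualify(self, code_config):
        stays = stays_frame([(0, 1, "C64", ""), (30, 1, "C64", ""),
                             (60, 1, "", self.DX)])
        deliv = deliveries_frame([(10, "mycophenolic_acid")])
        assert not detect_belatacept(stays, deliv, code_config).positive

    def test_direct_retrocession_delivery_short_circuits(self, code_config):
        call = detect_belatacept(stays_frame([]),
                                 deliveries_frame([(400, "belatacept")]), code_config)
        assert call.positive and call.source == "direct_retrocession"

    @given(st.data())
    def test_matches_exhaustive_triple_enumeration(self, data):
        """Randomized streams of up to 20 stays against the enumeration oracle."""
        config = k.default_config()
        n_stays = data.draw(st.integers(0, 20))
        stays = [(data.draw(st.integers(0, 360)),
                  data.draw(st.booleans()),
                  "", self.DX if data.draw(st.booleans()) else "C64")
                 for _ in range(n_stays)]
        classes = ["tacrolimus", "mycophenolic_acid", "everolimus",
                   "corticosteroid", "belatacept", "other"]
        n_deliv = data.draw(st.integers(0, 10))
        deliv = [(data.draw(st.integers(0, 360)), classes[data.draw(st.integers(0, 5))])
                 for _ in range(n_deliv)]
        call = detect_belatacept(
            stays_frame([(d, int(c), p, a) for d, c, p, a in stays]),
            deliveries_frame(deliv), config)
        positive, h, c1, c2, c3, direct = oracles.belatacept_bruteforce(
            [(d, c, [p, a]) for d, c, p, a in stays], deliv, config)
        assert call.positive == positive
        assert call.index_hospitalization_day == h
        assert call.three_stays_90d == c1
        if c1:
            assert call.companion_delivery_90d == c2
            assert call.no_cni_fourth_month == c3


class TestDetectSwitches:
    def test_relay_after_coverage_end_is_a_switch(self, code_config):
        rows = [(d, "tacrolimus") for d in range(0, 181, 30)] + \
               [(d, "everolimus") for d in range(200, 400, 30)]
        tl = k.build_timeline(deliveries_frame(rows), code_config)
        events = detect_switches(tl, code_config)
        assert len(events) == 1
        e = events[0]
        assert e.kind == "switch" and e.day == 200
        assert e.from_classes == frozenset({"tacrolimus"})
        assert e.to_classes == frozenset({"everolimus"})

    def test_single_class_stream_has_no_events(self, code_config):
        tl = k.build_timeline(
            deliveries_frame([(d, "tacrolimus") for d in range(0, 400, 30)]), code_config)
        assert detect_switches(tl, code_config) == []

    def test_continuing_old_class_makes_add_on(self, code_config):
        rows = [(d, "tacrolimus") for d in range(0, 400, 30)] + \
               [(d, "everolimus") for d in range(200, 400, 30)]
        tl = k.build_timeline(deliveries_frame(rows), code_config)
        events = detect_switches(tl, code_config)
        assert len(events) == 1
        e = events[0]
        assert e.kind == "add_on"
        assert e.to_classes > e.from_classes

    def test_exactly_30_days_residual_coverage_is_add_on(self, code_config):
        """Tie rule: >=30 days of residual coverage counts as continuing."""
        tl = k.ExposureTimeline("x", {"tacrolimus": [(0, 230)],
                                      "everolimus": [(200, 400)]})
        events = detect_switches(tl, code_config)
        assert events[0].kind == "add_on"

    def test_corticosteroids_never_trigger_events(self, code_config):
        rows = [(d, "tacrolimus") for d in range(0, 400, 30)] + \
               [(d, "corticosteroid") for d in range(200, 400, 30)]
        tl = k.build_timeline(deliveries_frame(rows), code_config)
        assert detect_switches(tl, code_config) == []


class TestInitialRegimen:
    def test_first_month_triple_therapy(self, code_config):
        rows = [(0, "tacrolimus"), (0, "mycophenolic_acid"), (0, "corticosteroid"),
                (30, "tacrolimus")]
        tl = k.build_timeline(deliveries_frame(rows), code_config)
        assert initial_regimen(tl, None, code_config) == frozenset(
            {CNI, ANTIMETABOLITE, CORTICOSTEROID})

    def test_no_deliveries_and_negative_call_is_empty(self, code_config):
        tl = k.ExposureTimeline("x", {})
        call = detect_belatacept(stays_frame([]), deliveries_frame([]), code_config)
        assert initial_regimen(tl, call, code_config) == frozenset()

    def test_positive_belatacept_call_adds_group(self, code_config):
        tl = k.build_timeline(
            deliveries_frame([(0, "mycophenolic_acid")]), code_config)
        stays = stays_frame([(0, 1, "", "Z940"), (30, 1, "", "Z940"),
                             (60, 1, "", "Z940")])
        call = detect_belatacept(stays, deliveries_frame([(0, "mycophenolic_acid")]),
                                 code_config)
        assert BELATACEPT in initial_regimen(tl, call, code_config)

    def test_matches_ground_truth_first_state(self, pipeline800):
        from ktxclaims.config import groups_of
        tp = pipeline800["truth"].patients.set_index("patient_id")
        for pid, got in pipeline800["exposure"].initial_regimens.items():
            expected = groups_of(tp.loc[pid, "initial_regimen"].split("|"))
            assert got == expected
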