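"""Asynchrony rules: pairing, per-breath labels, scenario-level scoring.

The brute-force oracles here re-implement the bedside definitions as direct,
unoptimized predicates over small timelines and must agree with the labeler.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsim.labeler import (
    LABEL_PRECEDENCE,
    LabeledBreath,
    LabelerConfig,
    associate,
    label_breaths,
    scenario_label,
)
from pvsim.waveform import BreathEvent, EffortEpisode


def ep(onset, peak, amp, end):
    return EffortEpisode(onset, peak, amp, end)


def ev(trig, off, kind="patient", bid=1):
    return BreathEvent(trig, off, kind, bid)


def brute_force_pairing(efforts, events, window=0.3, pre=0.1):
    """Globally optimal assignment oracle: among all feasible breath->effort
    maps (efforts may own several breaths), lexicographically minimize
    (#unpaired breaths, #entrained pairings, total |trigger-onset| delay).
    Effort-initiated pairings are preferred over entrained ones because an
    effort that began before the trigger plausibly caused it; entrainment is
    the fallback for machine breaths that precede their effort."""
    def candidates(e):
        out = [(None, None)]
        for i, epi in enumerate(efforts):
            if epi.onset_time - pre <= e.trigger_time <= epi.end_time + window:
                out.append((i, "initiated"))
            elif e.trigger_time < epi.onset_time <= e.cycleoff_time:
                out.append((i, "entrained"))
        return out

    best, best_cost = None, None
    for combo in itertools.product(*[candidates(e) for e in events]):
        unpaired = sum(c is None for c, _ in combo)
        n_entrained = sum(kind == "entrained" for _, kind in combo)
        delay = sum(
            abs(events[b].trigger_time - efforts[c].onset_time)
            for b, (c, _) in enumerate(combo) if c is not None
        )
        cost = (unpaired, n_entrained, delay)
        if best_cost is None or cost < best_cost:
            best, best_cost = combo, cost
    return [c for c, _ in best]


class TestAssociate:
    def test_trigger_shortly_after_onset_pairs(self):
        efforts = [ep(1.0, 1.4, 8.0, 1.8)]
        events = [ev(1.08, 1.9)]
        got = associate(efforts, events)
        assert got[0].effort_index == 0
        assert got[0].kind == "initiated"

    def test_trigger_long_after_effort_unpaired(self):
        got = associate([ep(1.0, 1.4, 8.0, 1.8)], [ev(3.8, 4.5)])
        assert got[0].effort_index is None

    def test_one_effort_two_triggers_both_paired(self):
        efforts = [ep(1.0, 1.9, 12.0, 2.8)]
        events = [ev(1.05, 1.45), ev(1.8, 2.3)]
        got = associate(efforts, events)
        assert [p.effort_index for p in got] == [0, 0]

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_global_assignment_oracle(self, data):
        n_eff = data.draw(st.integers(0, 3))
        n_ev = data.draw(st.integers(0, 4))
        efforts = []
        t = 0.5
        for _ in range(n_eff):
            t += data.draw(st.floats(0.3, 3.0))
            dur = data.draw(st.floats(0.3, 1.5))
            efforts.append(ep(t, t + dur / 2, 8.0, t + dur))
            t += dur
        events = []
        t = 0.3
        for _ in range(n_ev):
            t += data.draw(st.floats(0.3, 3.0))
            off = t + data.draw(st.floats(0.2, 1.2))
            events.append(ev(t, off))
            t = off
        got = [p.effort_index for p in associate(efforts, events)]
        want = brute_force_pairing(efforts, events)
        assert got == want


class TestLabelRules:
    def test_synchronous_breath(self):
        # trigger just after onset, cycle-off between peak and end of effort
        efforts = [ep(1.0, 1.5, 8.0, 2.0)]
        events = [ev(1.08, 1.8)]
        labeled, unpaired = label_breaths(events, efforts)
        assert labeled[0].label == "synchronous"
        assert unpaired == []

    def test_ineffective_effort(self):
        labeled, unpaired = label_breaths([], [ep(1.0, 1.4, 2.0, 1.8)])
        assert labeled == []
        assert unpaired == ["ineffective_effort"]

    def test_premature_cycling_before_peak(self):
        efforts = [ep(0.5, 1.2, 8.0, 1.9)]
        events = [ev(0.55, 0.9)]  # cycle-off 0.9 < gold peak 1.2
        labeled, _ = label_breaths(events, efforts)
        assert labeled[0].label == "premature_cycling"

    def test_delayed_cycling_after_end(self):
        efforts = [ep(0.5, 0.9, 8.0, 1.3)]
        events = [ev(0.55, 1.6)]  # cycle-off 1.6 > end 1.3 + 0.1 grace
        labeled, _ = label_breaths(events, efforts)
        assert labeled[0].label == "delayed_cycling"

    def test_cycleoff_within_grace_not_delayed(self):
        efforts = [ep(0.5, 0.9, 8.0, 1.3)]
        events = [ev(0.55, 1.38)]
        labeled, _ = label_breaths(events, efforts)
        assert labeled[0].label == "synchronous"

    def test_auto_triggering(self):
        labeled, _ = label_breaths([ev(2.0, 2.8, kind="artifact")], [])
        assert labeled[0].label == "auto_triggering"

    def test_machine_breath_without_effort_is_not_auto(self):
        labeled, _ = label_breaths([ev(2.0, 2.8, kind="machine")], [])
        assert labeled[0].label == "synchronous"

    def test_double_triggering_two_cycles_one_effort(self):
        efforts = [ep(1.0, 1.9, 12.0, 2.8)]
        events = [ev(1.05, 1.45, bid=1), ev(1.8, 2.3, bid=2)]
        labeled, _ = label_breaths(events, efforts)
        assert [lb.label for lb in labeled] == ["double_triggering", "double_triggering"]

    def test_reverse_triggering_stable_delay_over_three_machine_breaths(self):
        events, efforts = [], []
        for i, t0 in enumerate((0.0, 4.0, 8.0)):
            events.append(ev(t0, t0 + 1.2, kind="machine", bid=i + 1))
            efforts.append(ep(t0 + 0.30, t0 + 0.7, 6.0, t0 + 1.1))
        labeled, _ = label_breaths(events, efforts)
        assert [lb.label for lb in labeled] == ["reverse_triggering"] * 3

    def test_unstable_delay_is_not_reverse_triggering(self):
        events, efforts = [], []
        for i, (t0, d) in enumerate(zip((0.0, 4.0, 8.0), (0.2, 0.55, 0.9))):
            events.append(ev(t0, t0 + 1.2, kind="machine", bid=i + 1))
            efforts.append(ep(t0 + d, t0 + d + 0.4, 6.0, t0 + d + 0.8))
        labeled, _ = label_breaths(events, efforts)
        assert "reverse_triggering" not in {lb.label for lb in labeled}

    def test_reverse_triggering_with_stacked_breath(self):
        events, efforts = [], []
        bid = 0
        for t0 in (0.0, 5.0, 10.0):
            bid += 1
            events.append(ev(t0, t0 + 0.8, kind="machine", bid=bid))
            efforts.append(ep(t0 + 0.5, t0 + 1.25, 12.0, t0 + 2.0))
            bid += 1
            events.append(ev(t0 + 1.1, t0 + 1.9, kind="patient", bid=bid))
        labeled, _ = label_breaths(events, efforts)
        assert {lb.label for lb in labeled} == {"reverse_triggering_double_cycling"}

    def test_determinism(self):
        efforts = [ep(1.0, 1.5, 8.0, 2.0), ep(5.0, 5.4, 2.0, 5.8)]
        events = [ev(1.05, 1.8, bid=1), ev(9.0, 9.5, kind="artifact", bid=2)]
        a = label_breaths(events, efforts)
        b = label_breaths(events, efforts)
        assert [x.label for x in a[0]] == [x.label for x in b[0]] and a[1] == b[1]


class TestScenarioLabel:
    def _mk(self, labels):
        return [LabeledBreath(breath_id=i, label=l) for i, l in enumerate(labels)]

    def test_all_synchronous(self):
        primary, full = scenario_label(self._mk(["synchronous"] * 8))
        assert primary == "synchronous"
        assert full == {"synchronous"}

    def test_most_frequent_nonsynchronous_wins(self):
        labeled = self._mk(["synchronous"] * 6)
        primary, _ = scenario_label(labeled, ["ineffective_effort"] * 3)
        assert primary == "ineffective_effort"

    def test_tie_broken_by_precedence(self):
        labeled = self._mk(["premature_cycling", "delayed_cycling"])
        primary, _ = scenario_label(labeled)
        assert primary == "premature_cycling"
        assert LABEL_PRECEDENCE.index("premature_cycling") < LABEL_PRECEDENCE.index("delayed_cycling")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scenario_label([])
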