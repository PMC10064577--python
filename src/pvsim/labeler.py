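"""Rule-based per-breath and per-scenario asynchrony classification.

Implements the standard bedside definitions as executable predicates over
paired effort episodes (from the gold or estimated Pmus channel) and
ventilator breath events:

- ineffective effort: a patient effort with no ventilator breath,
- double triggering: two ventilator cycles triggered by a single effort,
- auto-triggering: a non-patient (artifact) trigger with no effort,
- reverse triggering (+/- double cycling): the effort follows a machine
  (controlled or auto-triggered) cycle with a fixed delay across consecutive
  mandatory breaths, optionally stacking a second breath,
- premature cycling: expiratory switch before the Pmus peak,
- delayed cycling: expiratory switch after the end of the effort,
- synchronous otherwise.

Trigger-phase rules (which are about effort <-> breath cardinality) take
precedence over the cycling-phase timing rules; within a breath the first
matching rule wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .waveform import BreathEvent, BreathSignals, EffortEpisode, detect_effort_episodes

__all__ = [
    "LABELS",
    "ASYNCHRONY_LABELS",
    "LABEL_PRECEDENCE",
    "LabelerConfig",
    "Pairing",
    "LabeledBreath",
    "associate",
    "label_breaths",
    "scenario_label",
]

#: The eight per-breath categories (seven asynchronies + synchronous).
SYNCHRONOUS = "synchronous"
ASYNCHRONY_LABELS = (
    "ineffective_effort",
    "double_triggering",
    "auto_triggering",
    "reverse_triggering",
    "reverse_triggering_double_cycling",
    "premature_cycling",
    "delayed_cycling",
)
LABELS = ASYNCHRONY_LABELS + (SYNCHRONOUS,)

#: Tie-break order for scenario-level labels: rule-evaluation order.
LABEL_PRECEDENCE = (
    "ineffective_effort",
    "double_triggering",
    "auto_triggering",
    "reverse_triggering",
    "reverse_triggering_double_cycling",
    "premature_cycling",
    "delayed_cycling",
    SYNCHRONOUS,
)


@dataclass
class LabelerConfig:
    """Tolerances of the labeling rules (display-resolution scale).

    association_window_s : how long after the end of an effort a trigger may
        still be attributed to it
    association_pre_s : how much a trigger may precede the detected effort
        onset and still count as initiated by it (detection latency allowance)
    entrain_min_breaths : minimum consecutive machine breaths with entrained
        efforts for the reverse-triggering rule
    entrain_delay_sd_s : maximum standard deviation of the trigger->effort
        delay across those breaths ("fixed frequency and delay")
    delayed_grace_s : grace period after the end of effort before cycling
        counts as delayed
    """

    association_window_s: float = 0.3
    association_pre_s: float = 0.1
    entrain_min_breaths: int = 3
    entrain_delay_sd_s: float = 0.1
    delayed_grace_s: float = 0.1


@dataclass
class Pairing:
    """Association of one breath to (at most) one effort."""

    breath_index: int
    effort_index: Optional[int]
    kind: Optional[str] = None  # initiated | entrained | None


@dataclass
class LabeledBreath:
    breath_id: int
    label: str
    effort_index: Optional[int] = None
    trigger_delay_s: Optional[float] = None  # trigger - effort onset
    cycleoff_minus_peak_s: Optional[float] = None
    cycleoff_minus_end_s: Optional[float] = None


def associate(
    efforts: Sequence[EffortEpisode],
    events: Sequence[BreathEvent],
    window_s: float = 0.3,
    pre_s: float = 0.1,
) -> list[Pairing]:
    """Pair each breath to at most one effort; efforts may own several breaths.

    Two association modes:

    - ``initiated``: the trigger falls in [onset - pre_s, end + window_s] —
      the effort plausibly caused the trigger; among candidates the one with
      the smallest |trigger - onset| wins.
    - ``entrained``: no initiating effort, but an effort *onset* falls inside
      the breath's inspiratory phase (trigger, cycleoff] — the machine breath
      precedes and entrains the effort (reverse-triggering substrate).
    """
    pairings: list[Pairing] = []
    for bi, ev in enumerate(events):
        chosen: Optional[int] = None
        kind: Optional[str] = None
        best = np.inf
        for ei, ep in enumerate(efforts):
            if ep.onset_time - pre_s <= ev.trigger_time <= ep.end_time + window_s:
                d = abs(ev.trigger_time - ep.onset_time)
                if d < best:
                    best, chosen, kind = d, ei, "initiated"
        if chosen is None:
            for ei, ep in enumerate(efforts):
                if ev.trigger_time < ep.onset_time <= ev.cycleoff_time:
                    chosen, kind = ei, "entrained"
                    break
        pairings.append(Pairing(breath_index=bi, effort_index=chosen, kind=kind))
    return pairings


def label_breaths(
    events: Sequence[BreathEvent],
    efforts: Sequence[EffortEpisode],
    config: Optional[LabelerConfig] = None,
    signals: Optional[BreathSignals] = None,
) -> tuple[list[LabeledBreath], list[str]]:
    """Apply the asynchrony rules; return per-breath labels and labels for
    unpaired efforts (one ``ineffective_effort`` per effort with no breath).

    ``signals`` is accepted for API symmetry (efforts may be detected from its
    Pmus channel upstream) but the rules operate on the timing primitives.
    """
    cfg = config or LabelerConfig()
    events = sorted(events, key=lambda e: e.trigger_time)
    efforts = sorted(efforts, key=lambda e: e.onset_time)
    pairings = associate(
        efforts, events, window_s=cfg.association_window_s, pre_s=cfg.association_pre_s
    )

    effort_to_breaths: dict[int, list[int]] = {}
    for p in pairings:
        if p.effort_index is not None:
            effort_to_breaths.setdefault(p.effort_index, []).append(p.breath_index)

    # Rule 1 — ineffective effort: efforts that own no breath.
    unpaired_labels = [
        "ineffective_effort" for ei in range(len(efforts)) if ei not in effort_to_breaths
    ]

    labels: dict[int, str] = {}

    # Rule 2 — double triggering: one effort *initiating* >= 2 breaths whose
    # inter-trigger gap is shorter than the effort duration + window.
    for ei, bis in effort_to_breaths.items():
        initiated = [bi for bi in bis if pairings[bi].kind == "initiated"]
        if len(initiated) < 2:
            continue
        ep = efforts[ei]
        trig = [events[bi].trigger_time for bi in initiated]
        gaps = np.diff(sorted(trig))
        if np.all(gaps < ep.duration + cfg.association_window_s):
            for bi in initiated:
                labels.setdefault(bi, "double_triggering")

    # Rule 3 — auto-triggering: patient/artifact-triggered breath, no effort.
    for p in pairings:
        ev = events[p.breath_index]
        if p.effort_index is None and ev.trigger_kind in ("patient", "artifact"):
            labels.setdefault(p.breath_index, "auto_triggering")

    # Rule 4 — reverse triggering: machine-triggered breaths whose entrained
    # effort follows the trigger with a stable delay over >= entrain_min
    # consecutive machine breaths.
    machine_idx = [bi for bi, ev in enumerate(events) if ev.trigger_kind == "machine"]
    delays: list[Optional[float]] = []
    for bi in machine_idx:
        p = pairings[bi]
        if p.effort_index is not None and efforts[p.effort_index].onset_time > events[
            bi
        ].trigger_time:
            delays.append(efforts[p.effort_index].onset_time - events[bi].trigger_time)
        else:
            delays.append(None)
    m = cfg.entrain_min_breaths
    entrained_flags = [False] * len(machine_idx)
    for s in range(0, len(machine_idx) - m + 1):
        win = delays[s : s + m]
        if all(d is not None for d in win) and float(np.std(win)) < cfg.entrain_delay_sd_s:
            for j in range(s, s + m):
                entrained_flags[j] = True
    for j, bi in enumerate(machine_idx):
        if not entrained_flags[j] or bi in labels:
            continue
        ei = pairings[bi].effort_index
        stacked = [b for b in effort_to_breaths.get(ei, []) if b != bi]
        lab = "reverse_triggering_double_cycling" if stacked else "reverse_triggering"
        labels[bi] = lab
        for b in stacked:
            labels.setdefault(b, "reverse_triggering_double_cycling")

    # Rules 5/6 — cycling-phase timing on breaths with an associated effort.
    out: list[LabeledBreath] = []
    for p in pairings:
        ev = events[p.breath_index]
        lb = LabeledBreath(breath_id=ev.breath_id, label=SYNCHRONOUS)
        if p.effort_index is not None:
            ep = efforts[p.effort_index]
            lb.effort_index = p.effort_index
            lb.trigger_delay_s = ev.trigger_time - ep.onset_time
            lb.cycleoff_minus_peak_s = ev.cycleoff_time - ep.peak_time
            lb.cycleoff_minus_end_s = ev.cycleoff_time - ep.end_time
        if p.breath_index in labels:
            lb.label = labels[p.breath_index]
        elif p.effort_index is not None:
            ep = efforts[p.effort_index]
            if ev.cycleoff_time < ep.peak_time:
                lb.label = "premature_cycling"
            elif ev.cycleoff_time > ep.end_time + cfg.delayed_grace_s:
                lb.label = "delayed_cycling"
        out.append(lb)
    return out, unpaired_labels


def scenario_label(
    labeled: Sequence[LabeledBreath], unpaired_labels: Sequence[str] = ()
) -> tuple[str, set[str]]:
    """Scenario-level primary label: the most frequent non-synchronous label
    (ties broken by rule precedence); ``synchronous`` only if nothing fired.
    """
    all_labels = [lb.label for lb in labeled] + list(unpaired_labels)
    if not all_labels:
        raise ValueError("scenario_label requires at least one labeled unit")
    counts = Counter(lab for lab in all_labels if lab != SYNCHRONOUS)
    full = set(all_labels)
    if not counts:
        return SYNCHRONOUS, full
    best = max(counts.items(), key=lambda kv: (kv[1], -LABEL_PRECEDENCE.index(kv[0])))
    return best[0], full


def label_signals(
    signals: BreathSignals,
    events: Sequence[BreathEvent],
    efforts: Optional[Sequence[EffortEpisode]] = None,
    config: Optional[LabelerConfig] = None,
    effort_threshold: float = 0.5,
    effort_min_duration_s: float = 0.1,
) -> tuple[list[LabeledBreath], list[str]]:
    """Convenience wrapper: detect efforts from the record's Pmus channel
    (gold or estimated) unless an explicit effort list is supplied, then label.
    """
    if efforts is None:
        if signals.pmus_true is None:
            efforts = []
        else:
            efforts = detect_effort_episodes(
                signals.pmus_true,
                signals.time,
                threshold=effort_threshold,
                min_duration_s=effort_min_duration_s,
            )
    return label_breaths(events, efforts, config=config, signals=signals)
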