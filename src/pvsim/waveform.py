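"""Shared time-series containers and signal primitives.

All waveform modules operate on :class:`BreathSignals`, a uniformly sampled
multichannel record of one ventilation epoch: airway pressure (Paw, cmH2O),
flow at the airway opening (L/s, inspiratory positive), volume above the
end-expiratory baseline (L), and — when available — the inspiratory muscle
pressure Pmus (cmH2O, stored nonnegative; it *subtracts* from airway pressure
in the single-compartment equation of motion, since muscle effort lowers
alveolar pressure).

The detection primitives here are deliberately simple and exhaustively
testable: effort episodes are maximal threshold runs on the Pmus channel, and
breath events are read off the ventilator phase log (or re-derived from flow
for imported records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PHASE_EXP",
    "PHASE_INSP",
    "PHASE_NAMES",
    "BreathSignals",
    "EffortEpisode",
    "BreathEvent",
    "integrate_flow",
    "detect_effort_episodes",
    "detect_breath_events",
]

#: Integer phase codes used in the ``phase`` channel.
PHASE_EXP = 0
PHASE_INSP = 1
PHASE_NAMES = {PHASE_EXP: "expiration", PHASE_INSP: "inspiration"}

#: Default effort-detection threshold (cmH2O) and minimum episode duration (s).
#: Chosen at ventilator-display resolution to suppress numerical chatter.
EFFORT_THRESHOLD_CMH2O = 0.5
EFFORT_MIN_DURATION_S = 0.1

_TIME_GRID_TOL_S = 1e-9


@dataclass
class EffortEpisode:
    """One patient inspiratory effort: a contiguous excursion of Pmus.

    ``onset_time`` is the first threshold crossing, ``end_time`` the last
    sample still at/above threshold (the decay below threshold marks the end
    of the effort, which the delayed-cycling rule compares against).
    """

    onset_time: float
    peak_time: float
    peak_amplitude: float
    end_time: float

    def __post_init__(self) -> None:
        if not (self.onset_time <= self.peak_time <= self.end_time):
            raise ValueError(
                f"effort episode times out of order: onset={self.onset_time}, "
                f"peak={self.peak_time}, end={self.end_time}"
            )
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")

    @property
    def duration(self) -> float:
        return self.end_time - self.onset_time


@dataclass
class BreathEvent:
    """One ventilator cycle: trigger (inspiration onset) and cycle-off.

    ``trigger_kind`` records what initiated the breath: ``patient`` (flow or
    pressure deflection from muscle effort), ``machine`` (time-based mandatory
    breath), or ``artifact`` (circuit disturbance crossing the trigger, as in
    auto-triggering).
    """

    trigger_time: float
    cycleoff_time: float
    trigger_kind: str  # patient | machine | artifact
    breath_id: int

    def __post_init__(self) -> None:
        if self.trigger_time >= self.cycleoff_time:
            raise ValueError("trigger_time must precede cycleoff_time")
        if self.trigger_kind not in ("patient", "machine", "artifact"):
            raise ValueError(f"unknown trigger_kind {self.trigger_kind!r}")

    @property
    def insp_time(self) -> float:
        return self.cycleoff_time - self.trigger_time


@dataclass
class BreathSignals:
    """Uniformly sampled multichannel ventilation record.

    Channels
    --------
    time : s, strictly increasing, constant step (default 100 Hz)
    paw : airway pressure, cmH2O
    flow : L/s, inspiratory positive
    volume : L above end-expiratory baseline
    pmus_true : cmH2O, >= 0, or None when the record carries no Pmus channel
        (the "control-group" view)
    phase : per-sample ventilator phase, PHASE_INSP / PHASE_EXP
    breath_id : integer per ventilator cycle, incremented at each
        expiration->inspiration transition
    effort_id : integer index of the active effort episode, -1 outside efforts
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    pmus_true: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    breath_id: Optional[np.ndarray] = None
    effort_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.pmus_true is not None:
            self.pmus_true = np.asarray(self.pmus_true, dtype=float)
        for name in ("phase", "breath_id", "effort_id"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=int))
        n = self.time.size
        for name in ("paw", "flow", "volume", "pmus_true", "phase", "breath_id", "effort_id"):
            v = getattr(self, name)
            if v is not None and v.size != n:
                raise ValueError(f"channel {name} has length {v.size}, expected {n}")
        _check_uniform_grid(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def has_pmus(self) -> bool:
        return self.pmus_true is not None

    def validate(self, check_volume: bool = True, volume_tol_l: float = 1e-3) -> None:
        """Check the container invariants; raise ``ValueError`` on violation.

        ``check_volume`` verifies volume == cumulative trapezoid of flow at
        every sample; this holds exactly on noiseless exports and must be
        switched off for records whose flow channel carries measurement
        noise (the volume channel stays clean by convention).
        """
        _check_uniform_grid(self.time)
        if check_volume:
            vref = integrate_flow(self.flow, self.dt)
            err = np.max(np.abs(self.volume - (self.volume[0] + vref)))
            if err > volume_tol_l:
                raise ValueError(
                    f"volume-flow inconsistency: max |volume - cumtrapz(flow)| = {err:.4g} L"
                )
        if self.pmus_true is not None and np.any(self.pmus_true < -1e-9):
            raise ValueError("pmus_true must be nonnegative")
        if self.phase is not None:
            ph = self.phase
            bad = ~np.isin(ph, [PHASE_EXP, PHASE_INSP])
            if np.any(bad):
                raise ValueError("phase contains values outside {inspiration, expiration}")
            if self.breath_id is not None:
                d = np.diff(self.breath_id)
                if np.any(d < 0) or np.any(d > 1):
                    raise ValueError("breath_id must be nondecreasing in unit steps")
                # breath_id increments exactly at expiration->inspiration transitions
                starts = (ph[1:] == PHASE_INSP) & (ph[:-1] == PHASE_EXP)
                if not np.array_equal(starts.astype(int), d):
                    raise ValueError(
                        "breath_id increments must coincide with expiration->inspiration transitions"
                    )


def _check_uniform_grid(time: np.ndarray) -> None:
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid must be 1-D with at least two samples")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise ValueError("time must be strictly increasing")
    if np.max(steps) - np.min(steps) > _TIME_GRID_TOL_S:
        raise ValueError(
            "non-uniform time grid: step varies by "
            f"{np.max(steps) - np.min(steps):.3g} s (tolerance {_TIME_GRID_TOL_S} s)"
        )


def integrate_flow(
    flow: Sequence[float], dt: Optional[float] = None, time: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Cumulative trapezoidal integral of flow (L/s) -> volume (L).

    Either ``dt`` (uniform step, s) or ``time`` must be given; a non-uniform
    ``time`` grid is rejected. The first sample of the result is 0.
    """
    flow = np.asarray(flow, dtype=float)
    if time is not None:
        _check_uniform_grid(np.asarray(time, dtype=float))
        dt = float(time[1] - time[0])
    if dt is None or dt <= 0:
        raise ValueError("dt must be positive (or pass a uniform time grid)")
    return cumulative_trapezoid(flow, dx=dt, initial=0.0)


def detect_effort_episodes(
    pmus: Sequence[float],
    time: Optional[Sequence[float]] = None,
    *,
    fs: Optional[float] = None,
    threshold: float = EFFORT_THRESHOLD_CMH2O,
    min_duration_s: float = EFFORT_MIN_DURATION_S,
) -> list[EffortEpisode]:
    """Detect effort episodes as maximal runs of ``pmus >= threshold``.

    Onset is the first sample at/above threshold, end the last sample of the
    run, peak the within-run argmax. Runs shorter than ``min_duration_s`` are
    discarded (numerical chatter / sub-physiological blips). Returns an empty
    list for passive records.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pmus = np.asarray(pmus, dtype=float)
    if time is None:
        if fs is None:
            raise ValueError("pass either time or fs")
        time = np.arange(pmus.size) / float(fs)
    else:
        time = np.asarray(time, dtype=float)
    above = pmus >= threshold
    episodes: list[EffortEpisode] = []
    if not np.any(above):
        return episodes
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[0::2], edges[1::2]):  # [start, stop) sample runs
        last = stop - 1
        if time[last] - time[start] < min_duration_s:
            continue
        k_peak = start + int(np.argmax(pmus[start:stop]))
        episodes.append(
            EffortEpisode(
                onset_time=float(time[start]),
                peak_time=float(time[k_peak]),
                peak_amplitude=float(pmus[k_peak]),
                end_time=float(time[last]),
            )
        )
    return episodes


def detect_breath_events(
    signals: BreathSignals,
    *,
    flow_upcross_lps: float = 0.05,
    sustain_s: float = 0.05,
) -> list[BreathEvent]:
    """Extract one :class:`BreathEvent` per ventilator cycle.

    If the record carries the simulator's phase/breath_id log, events are read
    off it directly. Otherwise inspiration onsets are re-derived from flow
    (upcross of ``flow_upcross_lps`` sustained for ``sustain_s``) and cycle-off
    as the subsequent downcross below zero. Trigger kind is inferred only
    heuristically on re-derived events (``patient`` when a Pmus effort onset
    shortly precedes the trigger, else ``machine``); pipelines that need exact
    kinds should carry the simulator event log.
    """
    t = signals.time
    if signals.phase is not None:
        ph = signals.phase
        events: list[BreathEvent] = []
        starts = np.flatnonzero((ph[1:] == PHASE_INSP) & (ph[:-1] == PHASE_EXP)) + 1
        if ph[0] == PHASE_INSP:
            starts = np.concatenate([[0], starts])
        stops = np.flatnonzero((ph[1:] == PHASE_EXP) & (ph[:-1] == PHASE_INSP)) + 1
        for i, k0 in enumerate(starts):
            later = stops[stops > k0]
            k1 = later[0] if later.size else t.size - 1
            if k1 <= k0:
                continue
            bid = int(signals.breath_id[k0]) if signals.breath_id is not None else i + 1
            events.append(
                BreathEvent(
                    trigger_time=float(t[k0]),
                    cycleoff_time=float(t[k1]),
                    trigger_kind=_infer_kind(signals, float(t[k0])),
                    breath_id=bid,
                )
            )
        if not events:
            warnings.warn("no ventilator cycles detected in record", stacklevel=2)
        return events

    # Re-derivation from flow for imported records without a phase log.
    flow = signals.flow
    n_sustain = max(1, int(round(sustain_s * signals.fs)))
    above = flow >= flow_upcross_lps
    events = []
    k = 1
    bid = 0
    n = flow.size
    while k < n:
        if above[k] and not above[k - 1] and np.all(above[k : min(n, k + n_sustain)]):
            k_off = k + n_sustain
            while k_off < n and flow[k_off] >= 0:
                k_off += 1
            k_off = min(k_off, n - 1)
            bid += 1
            events.append(
                BreathEvent(
                    trigger_time=float(t[k]),
                    cycleoff_time=float(t[k_off]),
                    trigger_kind=_infer_kind(signals, float(t[k])),
                    breath_id=bid,
                )
            )
            k = k_off + 1
        else:
            k += 1
    if not events:
        warnings.warn("no ventilator cycles detected in record", stacklevel=2)
    return events


def _infer_kind(signals: BreathSignals, trigger_time: float, lookback_s: float = 0.35) -> str:
    if signals.pmus_true is None:
        return "machine"
    episodes = detect_effort_episodes(signals.pmus_true, signals.time)
    for ep in episodes:
        if trigger_time - lookback_s <= ep.onset_time <= trigger_time + 0.02:
            return "patient"
    return "machine"
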