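"""Closed-loop simulation of an active single-compartment respiratory system
coupled to a ventilator with trigger, pressurization, and cycling logic.

Model
-----
The lung is a single compartment with resistance R (cmH2O.s/L) and compliance
C (mL/cmH2O) obeying the equation of motion

    Paw(t) = R * V'(t) + V(t)/C + PEEP_total - Pmus(t)

with Pmus >= 0 by convention (muscle effort lowers alveolar pressure). The
ventilator imposes the boundary condition: during inspiration Paw follows a
first-order rise to the pressure target (PSV/PCV) or flow is the set square
wave (VCV); during expiration Paw = PEEP_set and the compartment relaxes
passively with time constant R*C.

Numerics
--------
The loop advances at the sampling rate (default 100 Hz) with a trapezoidal
(Crank-Nicolson) volume update. For this linear ODE the update is A-stable at
any clinically plausible time constant, and it makes two contracts hold
*exactly* at every sample: the exported volume equals the cumulative
trapezoidal integral of the exported flow, and the equation-of-motion residual
is zero (float precision) on artifact-free samples. Trigger and cycling
decisions are taken at sample resolution (10 ms).

Auto-trigger artifacts are modeled as brief biphasic flow disturbances on the
*measured* flow channel (circuit noise such as condensate oscillation): they
can cross the flow trigger with Pmus identically zero, carry no net volume,
and do not enter the lung dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .waveform import (
    PHASE_EXP,
    PHASE_INSP,
    BreathEvent,
    BreathSignals,
    EffortEpisode,
)

__all__ = [
    "RespiratoryMechanics",
    "EffortProfile",
    "EffortTrain",
    "VentilatorSettings",
    "ArtifactSpec",
    "SimulationResult",
    "pmus_waveform",
    "inject_autotrigger_artifact",
    "simulate",
    "MECHANICS_PRESETS",
]


@dataclass
class RespiratoryMechanics:
    """Single-compartment mechanics.

    resistance : cmH2O.s/L
    compliance : mL/cmH2O
    peep_total : cmH2O, baseline alveolar pressure at zero volume
    """

    resistance: float
    compliance: float
    peep_total: float = 5.0

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.compliance <= 0:
            raise ValueError("resistance and compliance must be positive")

    @property
    def elastance(self) -> float:
        """cmH2O/L."""
        return 1000.0 / self.compliance

    @property
    def time_constant(self) -> float:
        """R*C in seconds."""
        return self.resistance * self.compliance / 1000.0


#: Conventional teaching-range mechanics presets (R cmH2O.s/L, C mL/cmH2O).
MECHANICS_PRESETS = {
    "normal": RespiratoryMechanics(resistance=10.0, compliance=50.0),
    "obstructive": RespiratoryMechanics(resistance=20.0, compliance=60.0),
    "restrictive": RespiratoryMechanics(resistance=10.0, compliance=25.0),
}


@dataclass
class EffortProfile:
    """Shape of one inspiratory effort.

    ``half_sine``: amplitude * sin(pi * t / T) on [0, T] where
    T = rise_s + hold_s + release_s. ``ramp_hold_release``: linear rise over
    rise_s, plateau hold_s, linear release release_s.
    """

    shape: str = "half_sine"  # half_sine | ramp_hold_release
    amplitude: float = 8.0
    rise_s: float = 0.5
    hold_s: float = 0.0
    release_s: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("half_sine", "ramp_hold_release"):
            raise ValueError(f"unknown effort shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if min(self.rise_s, self.hold_s, self.release_s) < 0:
            raise ValueError("durations must be nonnegative")
        if self.amplitude > 0 and self.duration_s <= 0:
            raise ValueError("total duration must be positive for a nonzero effort")

    @property
    def duration_s(self) -> float:
        return self.rise_s + self.hold_s + self.release_s

    @property
    def peak_offset_s(self) -> float:
        """Time from onset to peak amplitude."""
        if self.shape == "half_sine":
            return self.duration_s / 2.0
        return self.rise_s


def pmus_waveform(profile: EffortProfile, t_since_onset: float) -> float:
    """Pmus value (cmH2O) of one effort at ``t_since_onset`` seconds."""
    t = t_since_onset
    if t < 0:
        raise ValueError("t_since_onset must be nonnegative")
    T = profile.duration_s
    a = profile.amplitude
    if a == 0.0 or t > T:
        return 0.0
    if profile.shape == "half_sine":
        return a * math.sin(math.pi * t / T)
    if t < profile.rise_s:
        return a * t / profile.rise_s
    if t <= profile.rise_s + profile.hold_s:
        return a
    rel = t - profile.rise_s - profile.hold_s
    return a * max(0.0, 1.0 - rel / profile.release_s) if profile.release_s > 0 else 0.0


@dataclass
class EffortTrain:
    """Sequence of patient efforts.

    Either explicit absolute ``onsets`` (s), or — when ``entrain_to_machine``
    is set — efforts fire at each machine/artifact insufflation onset plus
    ``entrain_delay_s`` (the reverse-triggering entrainment mechanism: Pmus
    follows the controlled or auto-triggered cycle with fixed delay).
    """

    onsets: Sequence[float] = field(default_factory=tuple)
    profile: EffortProfile = field(default_factory=EffortProfile)
    entrain_to_machine: bool = False
    entrain_delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.onsets = tuple(float(o) for o in self.onsets)
        if any(b <= a for a, b in zip(self.onsets, self.onsets[1:])):
            raise ValueError("onsets must be strictly increasing")

    @classmethod
    def passive(cls) -> "EffortTrain":
        return cls(onsets=(), profile=EffortProfile(amplitude=0.0))

    @classmethod
    def periodic(
        cls, start_s: float, period_s: float, duration_s: float, profile: EffortProfile
    ) -> "EffortTrain":
        n = max(0, int(math.floor((duration_s - start_s) / period_s)) + 1)
        return cls(onsets=tuple(start_s + k * period_s for k in range(n)), profile=profile)


@dataclass
class VentilatorSettings:
    """Ventilator mode and timing parameters.

    trigger_threshold is in L/min for flow triggering and cmH2O for pressure
    triggering. ``pressure_above_peep`` is the support (PSV) or control (PCV)
    pressure above PEEP. VCV uses the set square-wave ``insp_flow_lps`` for
    ``insp_time_s``. PSV cycles at ``cycling_flow_fraction`` of the peak
    inspiratory flow or at ``max_insp_time_s``; PCV/VCV cycle at
    ``insp_time_s``. ``set_rate_bpm`` > 0 enables time-based mandatory breaths
    (the PCV/VCV rate, or a backup rate in PSV). The trigger is armed only in
    expiration after ``refractory_s``.
    """

    mode: str = "PSV"  # PSV | PCV | VCV
    trigger_kind: str = "flow"  # flow | pressure
    trigger_threshold: float = 2.0
    pressure_above_peep: float = 12.0
    insp_flow_lps: float = 0.5
    rise_time_s: float = 0.1
    cycling_flow_fraction: float = 0.25
    insp_time_s: float = 1.0
    set_rate_bpm: float = 0.0
    peep_set: float = 5.0
    max_insp_time_s: float = 3.0
    refractory_s: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("PSV", "PCV", "VCV"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.trigger_kind not in ("flow", "pressure"):
            raise ValueError(f"unknown trigger_kind {self.trigger_kind!r}")
        if not (0.0 < self.cycling_flow_fraction < 1.0):
            raise ValueError("cycling_flow_fraction must be in (0, 1)")
        if self.set_rate_bpm < 0:
            raise ValueError("set_rate_bpm must be >= 0")
        if self.trigger_threshold <= 0:
            raise ValueError("trigger_threshold must be positive in magnitude")

    @property
    def trigger_threshold_lps(self) -> float:
        return self.trigger_threshold / 60.0


@dataclass
class ArtifactSpec:
    """Exogenous trigger-noise events on the measured flow channel.

    Each event is one biphasic sine period of total ``duration_s`` and peak
    ``flow_lps``: the positive lobe can cross a flow trigger during expiration
    with Pmus identically zero; net injected volume is zero.
    """

    times: Sequence[float] = field(default_factory=tuple)
    flow_lps: float = 0.1
    duration_s: float = 0.15

    def __post_init__(self) -> None:
        self.times = tuple(float(t) for t in self.times)

    def flow_at(self, t: float) -> float:
        for t0 in self.times:
            if t0 <= t < t0 + self.duration_s:
                return self.flow_lps * math.sin(2.0 * math.pi * (t - t0) / self.duration_s)
        return 0.0


def inject_autotrigger_artifact(
    times: Sequence[float], artifact_flow_lps: float, duration_s: float = 0.15
) -> ArtifactSpec:
    """Build the artifact injection spec passed to :func:`simulate`."""
    return ArtifactSpec(times=times, flow_lps=artifact_flow_lps, duration_s=duration_s)


@dataclass
class SimulationResult:
    signals: BreathSignals
    events: list[BreathEvent]
    gold_efforts: list[EffortEpisode]


class _EffortSchedule:
    """Evaluates total Pmus(t) over scheduled onsets; supports entrainment."""

    def __init__(self, train: EffortTrain):
        self.profile = train.profile
        self.entrain = train.entrain_to_machine
        self.delay = train.entrain_delay_s
        self.onsets: list[float] = [] if self.entrain else list(train.onsets)

    def on_machine_trigger(self, t: float) -> None:
        if self.entrain and self.profile.amplitude > 0:
            onset = t + self.delay
            if not self.onsets or onset > self.onsets[-1]:
                self.onsets.append(onset)

    def pmus(self, t: float) -> float:
        total = 0.0
        T = self.profile.duration_s
        for o in reversed(self.onsets):
            if o > t:
                continue
            if t - o > T:
                break
            total += pmus_waveform(self.profile, t - o)
        return total

    def gold_episodes(self, duration_s: float) -> list[EffortEpisode]:
        eps = []
        for o in self.onsets:
            if self.profile.amplitude <= 0 or o >= duration_s:
                continue
            eps.append(
                EffortEpisode(
                    onset_time=o,
                    peak_time=o + self.profile.peak_offset_s,
                    peak_amplitude=self.profile.amplitude,
                    end_time=o + self.profile.duration_s,
                )
            )
        return eps


def simulate(
    mechanics: RespiratoryMechanics,
    settings: VentilatorSettings,
    efforts: Optional[EffortTrain] = None,
    duration_s: float = 30.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    fs: float = 100.0,
    artifacts: Optional[ArtifactSpec] = None,
) -> SimulationResult:
    """Run the closed patient-ventilator loop and return signals + logs.

    Measurement noise (Gaussian, sd ``noise_sd`` cmH2O on paw and
    ``noise_sd``/10 L/s on flow) is added to the exported paw and flow
    channels only; volume and the gold Pmus channel stay noiseless (the Pmus
    channel is the answer key).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if efforts is None:
        efforts = EffortTrain.passive()
    dt = 1.0 / fs
    tau = mechanics.time_constant
    if tau <= 2.0 * dt / 10.0 or not np.isfinite(tau):
        raise ValueError(
            f"unstable parameter combination: time constant {tau:.4g} s too small"
        )

    R = mechanics.resistance
    E = mechanics.elastance
    peep_tot = mechanics.peep_total
    peep = settings.peep_set
    n = int(round(duration_s * fs))
    time = np.arange(n) * dt

    sched = _EffortSchedule(efforts)
    art = artifacts if artifacts is not None else ArtifactSpec(times=())

    paw_out = np.empty(n)
    flow_out = np.empty(n)
    pmus_out = np.empty(n)
    phase_out = np.empty(n, dtype=int)
    bid_out = np.empty(n, dtype=int)

    V = 0.0  # lung volume above baseline at the previous sample
    flow_prev = 0.0
    phase = PHASE_EXP
    breath_id = 0
    t_trigger = -math.inf
    t_last_trigger = -math.inf  # resets the mandatory-rate timer
    t_cycleoff = -settings.refractory_s  # armed at t=0
    peak_insp_flow = 0.0
    period = 60.0 / settings.set_rate_bpm if settings.set_rate_bpm > 0 else math.inf
    events: list[BreathEvent] = []
    pending: Optional[dict] = None  # current breath being assembled

    def paw_insp(t_insp: float) -> float:
        target = settings.pressure_above_peep
        if settings.rise_time_s > 0:
            return peep + target * (1.0 - math.exp(-t_insp / settings.rise_time_s))
        return peep + target

    # PSV cycling lockout: ignore the flow-fraction criterion in the first
    # 150 ms of pressurization while flow is still rising.
    psv_lockout_s = max(0.15, settings.rise_time_s)
    cn = dt * E / (2.0 * R)  # Crank-Nicolson coefficient for pressure regimes

    for k in range(n):
        t = time[k]
        pmus_t = sched.pmus(t)
        # Predictor flow at t under the regime in force (previous-sample volume);
        # used only for trigger/cycling decisions at sample resolution.
        if phase == PHASE_EXP:
            f_pred = (peep - peep_tot - E * V + pmus_t) / R
        elif settings.mode == "VCV":
            f_pred = settings.insp_flow_lps
        else:
            f_pred = (paw_insp(t - t_trigger) - peep_tot - E * V + pmus_t) / R

        # --- regime transitions, decided before the volume update for step k ---
        if phase == PHASE_EXP:
            armed = (t - t_cycleoff) >= settings.refractory_s
            fired = None  # patient | machine | artifact
            if settings.set_rate_bpm > 0 and (t - t_last_trigger) >= period:
                fired = "machine"
            elif armed:
                if settings.trigger_kind == "flow":
                    if f_pred + art.flow_at(t) >= settings.trigger_threshold_lps:
                        fired = "artifact" if art.flow_at(t) > 0 else "patient"
                else:
                    p_alv = E * V + peep_tot - pmus_t
                    if (peep - p_alv) >= settings.trigger_threshold:
                        fired = "patient"
            if fired is not None:
                phase = PHASE_INSP
                breath_id += 1
                t_trigger = t
                t_last_trigger = t
                peak_insp_flow = 0.0
                pending = {"trigger_time": t, "kind": fired, "breath_id": breath_id}
                if fired in ("machine", "artifact"):
                    sched.on_machine_trigger(t)
                    pmus_t = sched.pmus(t)  # entrainment with zero delay edge case
        else:
            t_insp = t - t_trigger
            cycled = False
            if settings.mode in ("PCV", "VCV"):
                cycled = t_insp >= settings.insp_time_s
            else:  # PSV
                if t_insp >= settings.max_insp_time_s:
                    cycled = True
                elif t_insp >= psv_lockout_s and peak_insp_flow > 0.05:
                    if f_pred <= settings.cycling_flow_fraction * peak_insp_flow:
                        cycled = True
            if cycled:
                phase = PHASE_EXP
                t_cycleoff = t
                if pending is not None:
                    events.append(
                        BreathEvent(
                            trigger_time=pending["trigger_time"],
                            cycleoff_time=t,
                            trigger_kind=pending["kind"],
                            breath_id=pending["breath_id"],
                        )
                    )
                    pending = None

        # --- joint (paw, flow, V) solve at sample k under the final regime ---
        # The trapezoidal update V_k = V_{k-1} + dt/2 (flow_{k-1} + flow_k)
        # holds exactly, so exported volume == cumtrapz(exported lung flow).
        if phase == PHASE_INSP and settings.mode == "VCV":
            flow_k = settings.insp_flow_lps
            if k > 0:
                V = V + 0.5 * dt * (flow_prev + flow_k)
            paw_k = R * flow_k + E * V + peep_tot - pmus_t
        else:
            paw_k = paw_insp(t - t_trigger) if phase == PHASE_INSP else peep
            if k > 0:
                V = (V + 0.5 * dt * (flow_prev + (paw_k - peep_tot + pmus_t) / R)) / (1.0 + cn)
            flow_k = (paw_k - peep_tot - E * V + pmus_t) / R

        if phase == PHASE_INSP:
            peak_insp_flow = max(peak_insp_flow, flow_k)

        paw_out[k] = paw_k
        flow_out[k] = flow_k
        pmus_out[k] = pmus_t
        phase_out[k] = phase
        bid_out[k] = breath_id
        flow_prev = flow_k

    if pending is not None:
        # breath still open at the end of the record
        if time[-1] > pending["trigger_time"]:
            events.append(
                BreathEvent(
                    trigger_time=pending["trigger_time"],
                    cycleoff_time=float(time[-1]),
                    trigger_kind=pending["kind"],
                    breath_id=pending["breath_id"],
                )
            )

    # Measured flow = lung flow + artifact disturbance (sensor-level).
    if art.times:
        flow_out = flow_out + np.array([art.flow_at(t) for t in time])

    # Exported volume: cumulative trapezoid of the exported (noiseless) flow,
    # so the volume-flow invariant holds exactly on the export.
    from .waveform import integrate_flow  # local import to avoid cycle at module load

    volume_out = integrate_flow(flow_out, dt)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        paw_out = paw_out + rng.normal(0.0, noise_sd, n)
        flow_out = flow_out + rng.normal(0.0, noise_sd / 10.0, n)

    gold = sched.gold_episodes(duration_s)
    effort_id = np.full(n, -1, dtype=int)
    for i, ep in enumerate(gold):
        mask = (time >= ep.onset_time) & (time <= ep.end_time)
        effort_id[mask] = i

    signals = BreathSignals(
        time=time,
        paw=paw_out,
        flow=flow_out,
        volume=volume_out,
        pmus_true=pmus_out,
        phase=phase_out,
        breath_id=bid_out,
        effort_id=effort_id,
    )
    return SimulationResult(signals=signals, events=events, gold_efforts=gold)
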