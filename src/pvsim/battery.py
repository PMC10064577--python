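"""The default battery of 49 labeled scenarios.

Seven asynchrony categories plus synchronous cycles, each rendered as a 30-s
closed-loop recording with the programmed (gold) Pmus as the answer key. The
composition is deterministic: 6 scenarios per asynchrony category spanning the
three mechanics presets (normal / obstructive / restrictive) at two effort
intensities, plus 7 synchronous scenarios — 49 in total. Category recipes
construct each asynchrony mechanistically:

- ineffective effort: effort too weak to cross the (pressure) trigger,
- auto-triggering: biphasic circuit-flow artifacts crossing the flow trigger
  with zero Pmus,
- double triggering: a long strong effort against a short inspiratory time,
  retriggering after cycle-off,
- reverse triggering (+/- double cycling): efforts entrained to mandatory PCV
  breaths at a fixed delay, with amplitude high enough (or not) to stack a
  second cycle,
- premature cycling: inspiratory time ending before the Pmus peak,
- delayed cycling: a low PSV cycling threshold holding inspiration past the
  end of effort.

A documented minority of scenarios carry a secondary label (the stacked-cycle
and short-inspiration recipes necessarily exhibit a second asynchrony).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .engine import (
    MECHANICS_PRESETS,
    ArtifactSpec,
    EffortProfile,
    EffortTrain,
    RespiratoryMechanics,
    SimulationResult,
    VentilatorSettings,
    simulate,
)

__all__ = ["Scenario", "AnswerKey", "build_default_battery", "render_scenario"]

DURATION_S = 30.0


@dataclass
class Scenario:
    """One battery entry: mechanics + settings + effort train + answer."""

    scenario_id: int
    mechanics_preset: str
    mechanics: RespiratoryMechanics
    settings: VentilatorSettings
    efforts: EffortTrain
    artifacts: Optional[ArtifactSpec]
    injected_labels: tuple[str, ...]  # primary first
    duration_s: float = DURATION_S

    def __post_init__(self) -> None:
        if not self.injected_labels:
            raise ValueError("injected_labels must be nonempty")

    @property
    def primary_label(self) -> str:
        return self.injected_labels[0]

    def to_dict(self) -> dict:
        d = {
            "scenario_id": self.scenario_id,
            "mechanics_preset": self.mechanics_preset,
            "mechanics": asdict(self.mechanics),
            "settings": asdict(self.settings),
            "efforts": {
                "onsets": list(self.efforts.onsets),
                "profile": asdict(self.efforts.profile),
                "entrain_to_machine": self.efforts.entrain_to_machine,
                "entrain_delay_s": self.efforts.entrain_delay_s,
            },
            "artifacts": None
            if self.artifacts is None
            else {
                "times": list(self.artifacts.times),
                "flow_lps": self.artifacts.flow_lps,
                "duration_s": self.artifacts.duration_s,
            },
            "injected_labels": list(self.injected_labels),
            "duration_s": self.duration_s,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        eff = d["efforts"]
        art = d.get("artifacts")
        return cls(
            scenario_id=int(d["scenario_id"]),
            mechanics_preset=d["mechanics_preset"],
            mechanics=RespiratoryMechanics(**d["mechanics"]),
            settings=VentilatorSettings(**d["settings"]),
            efforts=EffortTrain(
                onsets=tuple(eff["onsets"]),
                profile=EffortProfile(**eff["profile"]),
                entrain_to_machine=eff["entrain_to_machine"],
                entrain_delay_s=eff["entrain_delay_s"],
            ),
            artifacts=None if art is None else ArtifactSpec(**art),
            injected_labels=tuple(d["injected_labels"]),
            duration_s=float(d.get("duration_s", DURATION_S)),
        )


@dataclass
class AnswerKey:
    """scenario_id -> primary label (+ full injected label set)."""

    entries: dict[int, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_battery(cls, battery: Sequence[Scenario]) -> "AnswerKey":
        key = cls()
        for s in battery:
            if s.scenario_id in key.entries:
                raise ValueError(f"duplicate scenario_id {s.scenario_id}")
            key.entries[s.scenario_id] = tuple(s.injected_labels)
        return key

    def primary(self, scenario_id: int) -> str:
        return self.entries[scenario_id][0]

    def __len__(self) -> int:
        return len(self.entries)


def _half_sine(amplitude: float, duration: float) -> EffortProfile:
    return EffortProfile(
        shape="half_sine", amplitude=amplitude, rise_s=duration / 2, hold_s=0.0, release_s=duration / 2
    )


# Each recipe yields 6 variants over (mechanics preset x effort intensity);
# the synchronous recipe yields 7. The parameter choices realize the category's
# defining timing relation under the three mechanics presets.

_PRESETS = ("normal", "obstructive", "restrictive")


def _synchronous_variants() -> list[dict]:
    out = []
    for preset in _PRESETS:
        for amp in (8.0, 12.0):
            out.append(dict(preset=preset, amp=amp))
    out.append(dict(preset="normal", amp=10.0))
    return out


def _make_synchronous(preset: str, amp: float) -> dict:
    return dict(
        settings=VentilatorSettings(
            mode="PSV",
            trigger_kind="flow",
            trigger_threshold=2.0,
            pressure_above_peep=12.0,
            cycling_flow_fraction=0.3,
            max_insp_time_s=2.5,
        ),
        efforts=EffortTrain.periodic(1.0, 4.0, DURATION_S, _half_sine(amp, 1.0)),
        artifacts=None,
        labels=("synchronous",),
    )


def _make_ineffective(preset: str, amp: float) -> dict:
    # Machine PCV breaths at 0, 5, 10, ... s; weak efforts mid-expiration that
    # never overcome the pressure trigger.
    return dict(
        settings=VentilatorSettings(
            mode="PCV",
            trigger_kind="pressure",
            trigger_threshold=2.5,
            pressure_above_peep=12.0,
            insp_time_s=1.0,
            set_rate_bpm=12.0,
        ),
        efforts=EffortTrain.periodic(2.5, 5.0, DURATION_S, _half_sine(amp, 0.8)),
        artifacts=None,
        labels=("ineffective_effort",),
    )


def _make_autotrigger(preset: str, amp: float) -> dict:
    times = tuple(2.0 + 3.5 * k for k in range(8))
    return dict(
        settings=VentilatorSettings(
            mode="PSV",
            trigger_kind="flow",
            trigger_threshold=2.0,
            pressure_above_peep=10.0,
            cycling_flow_fraction=0.3,
            max_insp_time_s=2.0,
        ),
        efforts=EffortTrain.passive(),
        artifacts=ArtifactSpec(times=times, flow_lps=amp, duration_s=0.15),
        labels=("auto_triggering",),
    )


def _make_double(preset: str, amp: float) -> dict:
    # Long strong effort against a very short maximum inspiratory time: the
    # first cycle ends while the effort is still rising, so the still-rising
    # Pmus retriggers a second (stacked) cycle. Cycle-off necessarily precedes
    # the Pmus peak, hence the secondary premature label.
    return dict(
        settings=VentilatorSettings(
            mode="PSV",
            trigger_kind="flow",
            trigger_threshold=2.0,
            pressure_above_peep=12.0,
            cycling_flow_fraction=0.3,
            max_insp_time_s=0.4,
            refractory_s=0.15,
        ),
        efforts=EffortTrain.periodic(1.0, 5.0, DURATION_S, _half_sine(amp, 1.8)),
        artifacts=None,
        labels=("double_triggering", "premature_cycling"),
    )


def _make_reverse(preset: str, amp: float) -> dict:
    return dict(
        settings=VentilatorSettings(
            mode="PCV",
            trigger_kind="pressure",
            trigger_threshold=3.0,
            pressure_above_peep=12.0,
            insp_time_s=1.2,
            set_rate_bpm=15.0,
        ),
        efforts=EffortTrain(
            onsets=(), profile=_half_sine(amp, 0.9), entrain_to_machine=True, entrain_delay_s=0.3
        ),
        artifacts=None,
        labels=("reverse_triggering",),
    )


def _make_reverse_double(preset: str, amp: float) -> dict:
    # Entrained effort starting late in the mandatory inspiration and strong
    # enough that its rising phase retriggers a stacked cycle after cycle-off.
    return dict(
        settings=VentilatorSettings(
            mode="PCV",
            trigger_kind="flow",
            trigger_threshold=2.5,
            pressure_above_peep=12.0,
            insp_time_s=0.8,
            set_rate_bpm=12.0,
            refractory_s=0.2,
        ),
        efforts=EffortTrain(
            onsets=(), profile=_half_sine(amp, 1.5), entrain_to_machine=True, entrain_delay_s=0.65
        ),
        artifacts=None,
        labels=("reverse_triggering_double_cycling", "reverse_triggering"),
    )


def _make_premature(preset: str, amp: float) -> dict:
    # Patient-triggered PCV with a short set inspiratory time: cycling lands
    # well before the Pmus peak. The long refractory period outlasts the
    # effort tail so the tail cannot retrigger a stacked cycle.
    return dict(
        settings=VentilatorSettings(
            mode="PCV",
            trigger_kind="flow",
            trigger_threshold=2.0,
            pressure_above_peep=12.0,
            insp_time_s=0.5,
            set_rate_bpm=0.0,
            refractory_s=0.85,
        ),
        efforts=EffortTrain.periodic(1.0, 4.0, DURATION_S, _half_sine(amp, 1.3)),
        artifacts=None,
        labels=("premature_cycling",),
    )


def _make_delayed(preset: str, amp: float) -> dict:
    # Patient-triggered VCV with a set inspiratory time far longer than the
    # neural inspiratory time: the expiratory switch follows the end of the
    # effort by design, under every mechanics preset.
    return dict(
        settings=VentilatorSettings(
            mode="VCV",
            trigger_kind="flow",
            trigger_threshold=2.0,
            insp_flow_lps=0.4,
            insp_time_s=1.5,
            set_rate_bpm=0.0,
            refractory_s=0.2,
        ),
        efforts=EffortTrain.periodic(1.0, 5.0, DURATION_S, _half_sine(amp, 0.8)),
        artifacts=None,
        labels=("delayed_cycling",),
    )


_CATEGORY_BUILDERS = (
    ("synchronous", _make_synchronous, _synchronous_variants()),
    ("ineffective_effort", _make_ineffective, None),
    ("auto_triggering", _make_autotrigger, None),
    ("double_triggering", _make_double, None),
    ("reverse_triggering", _make_reverse, None),
    ("reverse_triggering_double_cycling", _make_reverse_double, None),
    ("premature_cycling", _make_premature, None),
    ("delayed_cycling", _make_delayed, None),
)

#: Effort-intensity pairs per category (amplitude cmH2O, or artifact peak L/s
#: for auto-triggering where Pmus is identically zero).
_CATEGORY_AMPLITUDES = {
    "ineffective_effort": (1.0, 1.8),
    "auto_triggering": (0.08, 0.12),
    "double_triggering": (10.0, 14.0),
    "reverse_triggering": (5.0, 8.0),
    "reverse_triggering_double_cycling": (12.0, 16.0),
    "premature_cycling": (6.0, 9.0),
    "delayed_cycling": (8.0, 12.0),
}


def build_default_battery() -> list[Scenario]:
    """The deterministic 49-scenario battery (no randomness in composition)."""
    scenarios: list[Scenario] = []
    sid = 1
    for category, builder, variants in _CATEGORY_BUILDERS:
        if variants is None:
            variants = [
                dict(preset=p, amp=a)
                for p in _PRESETS
                for a in _CATEGORY_AMPLITUDES[category]
            ]
        for var in variants:
            spec = builder(var["preset"], var["amp"])
            scenarios.append(
                Scenario(
                    scenario_id=sid,
                    mechanics_preset=var["preset"],
                    mechanics=MECHANICS_PRESETS[var["preset"]],
                    settings=spec["settings"],
                    efforts=spec["efforts"],
                    artifacts=spec["artifacts"],
                    injected_labels=spec["labels"],
                )
            )
            sid += 1
    assert len(scenarios) == 49
    return scenarios


def render_scenario(
    scenario: Scenario, seed: int = 0, noise_sd: float = 0.0
) -> SimulationResult:
    """Render one scenario to signals + event/effort logs (deterministic for
    a given seed)."""
    return simulate(
        mechanics=scenario.mechanics,
        settings=scenario.settings,
        efforts=scenario.efforts,
        duration_s=scenario.duration_s,
        seed=seed + scenario.scenario_id,
        noise_sd=noise_sd,
        artifacts=scenario.artifacts,
    )


def recover_labels(
    battery: Optional[Sequence[Scenario]] = None,
    seed: int = 0,
    source: str = "gold",
    noise_sd: float = 0.0,
) -> list[dict]:
    """Run the closed loop battery -> labeler and compare against the key.

    ``source`` selects the Pmus the labeler sees: ``gold`` (the programmed
    effort train, the answer-key construction), ``gold_channel`` (efforts
    re-detected from the exported Pmus channel), or ``estimate`` (robust
    mechanics fit + model-based inversion, the fully noninvasive path).
    Returns one dict per scenario with the injected and recovered primary
    label; estimator error is included on the estimate path.
    """
    from .estimator import (
        ESTIMATE_MIN_EFFORT_DURATION_S,
        estimate_pmus_model_based,
        fit_mechanics,
    )
    from .labeler import label_breaths, scenario_label
    from .waveform import detect_effort_episodes

    if battery is None:
        battery = build_default_battery()
    rows = []
    for sc in battery:
        r = render_scenario(sc, seed=seed, noise_sd=noise_sd)
        rms = None
        if source == "gold":
            efforts = r.gold_efforts
        elif source == "gold_channel":
            efforts = detect_effort_episodes(r.signals.pmus_true, r.signals.time)
        elif source == "estimate":
            mech = fit_mechanics(r.signals, robust=True)
            est = estimate_pmus_model_based(r.signals, mech)
            rms = est.rms_error_vs_gold
            efforts = detect_effort_episodes(
                est.series,
                r.signals.time,
                min_duration_s=ESTIMATE_MIN_EFFORT_DURATION_S,
            )
        else:
            raise ValueError(f"unknown source {source!r}")
        labeled, unpaired = label_breaths(r.events, efforts)
        primary, full = scenario_label(labeled, unpaired)
        rows.append(
            {
                "scenario_id": sc.scenario_id,
                "injected": sc.primary_label,
                "recovered": primary,
                "match": primary == sc.primary_label,
                "rms_error_cmh2o": rms,
                "recovered_all": sorted(full),
            }
        )
    return rows
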