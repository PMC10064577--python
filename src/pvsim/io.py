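"""File formats and provenance plumbing.

Waveforms travel as plain CSV with a fixed header
(``time_s, paw_cmh2o, flow_lps, volume_l, pmus_cmh2o, phase, breath_id,
effort_id``); the Pmus column is omitted for the "control-group" view that
shows only conventional pressure and flow. Every artifact file carries a
provenance comment header (tool version, seed, config hash) so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import AnswerKey, Scenario
from .waveform import PHASE_NAMES, BreathEvent, BreathSignals, EffortEpisode

__all__ = [
    "RunConfig",
    "read_waveform",
    "write_waveform",
    "write_events",
    "read_events",
    "write_answer_key",
    "read_answer_key",
    "write_manifest",
    "read_manifest",
]

WAVEFORM_COLUMNS = [
    "time_s",
    "paw_cmh2o",
    "flow_lps",
    "volume_l",
    "pmus_cmh2o",
    "phase",
    "breath_id",
    "effort_id",
]
_PHASE_CODES = {name: code for code, name in PHASE_NAMES.items()}


@dataclass
class RunConfig:
    """Run-level knobs recorded in every output's provenance header."""

    seed: int = 0
    sampling_hz: float = 100.0
    noise_sd: float = 0.0
    association_window_s: float = 0.3
    entrain_delay_sd_s: float = 0.1
    delayed_grace_s: float = 0.1

    def __post_init__(self) -> None:
        for name in ("association_window_s", "entrain_delay_sd_s", "delayed_grace_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: Optional[RunConfig]) -> list[str]:
    cfg = config or RunConfig()
    return [
        f"# pvsim {__version__}",
        f"# seed={cfg.seed} config_hash={cfg.config_hash()}",
    ]


def write_waveform(
    signals: BreathSignals,
    path: str | Path,
    include_pmus: bool = True,
    config: Optional[RunConfig] = None,
) -> None:
    """Write a record as CSV (lossless round-trip; %.10g floats)."""
    cols: dict[str, object] = {
        "time_s": signals.time,
        "paw_cmh2o": signals.paw,
        "flow_lps": signals.flow,
        "volume_l": signals.volume,
    }
    if include_pmus and signals.pmus_true is not None:
        cols["pmus_cmh2o"] = signals.pmus_true
    if signals.phase is not None:
        cols["phase"] = [PHASE_NAMES[p] for p in signals.phase]
    if signals.breath_id is not None:
        cols["breath_id"] = signals.breath_id
    if signals.effort_id is not None:
        cols["effort_id"] = signals.effort_id
    df = pd.DataFrame(cols)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text("\n".join(_provenance(config)) + "\n" + buf.getvalue())


def read_waveform(path: str | Path) -> BreathSignals:
    """Read a waveform CSV; header and monotone time grid are validated."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    unknown = [c for c in df.columns if c not in WAVEFORM_COLUMNS]
    if unknown:
        raise ValueError(f"{path}: unknown waveform columns {unknown}")
    required = ["time_s", "paw_cmh2o", "flow_lps", "volume_l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2 for the header row, +1 for 1-based numbering
        raise ValueError(
            f"{path}: time not strictly increasing at data line {int(bad[0]) + 2}"
        )
    phase = None
    if "phase" in df.columns:
        try:
            phase = np.array([_PHASE_CODES[str(v)] for v in df["phase"]])
        except KeyError as e:
            raise ValueError(f"{path}: unknown phase value {e}") from None
    return BreathSignals(
        time=t,
        paw=df["paw_cmh2o"].to_numpy(dtype=float),
        flow=df["flow_lps"].to_numpy(dtype=float),
        volume=df["volume_l"].to_numpy(dtype=float),
        pmus_true=df["pmus_cmh2o"].to_numpy(dtype=float) if "pmus_cmh2o" in df.columns else None,
        phase=phase,
        breath_id=df["breath_id"].to_numpy(dtype=int) if "breath_id" in df.columns else None,
        effort_id=df["effort_id"].to_numpy(dtype=int) if "effort_id" in df.columns else None,
    )


def write_events(
    events: Sequence[BreathEvent],
    path: str | Path,
    efforts: Sequence[EffortEpisode] = (),
    config: Optional[RunConfig] = None,
) -> None:
    """Write the breath-event log (and optional gold effort-onset markers)."""
    df = pd.DataFrame(
        {
            "breath_id": [e.breath_id for e in events],
            "trigger_time_s": [e.trigger_time for e in events],
            "cycleoff_time_s": [e.cycleoff_time for e in events],
            "trigger_kind": [e.trigger_kind for e in events],
        }
    )
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.10g")
    header = _provenance(config)
    if efforts:
        onsets = ",".join(f"{e.onset_time:.4f}" for e in efforts)
        header.append(f"# effort_onsets_s={onsets}")
    Path(path).write_text("\n".join(header) + "\n" + buf.getvalue())


def read_events(path: str | Path) -> list[BreathEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        BreathEvent(
            trigger_time=float(r.trigger_time_s),
            cycleoff_time=float(r.cycleoff_time_s),
            trigger_kind=str(r.trigger_kind),
            breath_id=int(r.breath_id),
        )
        for r in df.itertuples()
    ]


def write_answer_key(key: AnswerKey, path: str | Path, config: Optional[RunConfig] = None) -> None:
    df = pd.DataFrame(
        {
            "scenario_id": sorted(key.entries),
            "primary_label": [key.entries[s][0] for s in sorted(key.entries)],
            "all_labels": ["|".join(key.entries[s]) for s in sorted(key.entries)],
        }
    )
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    Path(path).write_text("\n".join(_provenance(config)) + "\n" + buf.getvalue())


def read_answer_key(path: str | Path) -> AnswerKey:
    df = pd.read_csv(path, comment="#")
    key = AnswerKey()
    for r in df.itertuples():
        key.entries[int(r.scenario_id)] = tuple(str(r.all_labels).split("|"))
    return key


def write_manifest(
    battery: Sequence[Scenario], path: str | Path, config: Optional[RunConfig] = None
) -> None:
    """Pin the battery composition as YAML (configs are the ground truth for
    re-rendering)."""
    payload = {
        "pvsim_version": __version__,
        "config_hash": (config or RunConfig()).config_hash(),
        "scenarios": [s.to_dict() for s in battery],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_manifest(path: str | Path) -> list[Scenario]:
    payload = yaml.safe_load(Path(path).read_text())
    return [Scenario.from_dict(d) for d in payload["scenarios"]]
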