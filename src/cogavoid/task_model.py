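"""Declarative paradigm model: room, stimuli, US field, phases and trial schedules.

The paradigm is a desk-scale re-implementation of a room-scale VR avoidance
conditioning task.  Two conditioned stimuli (CS+ / CS-) appear on a pedestal in
a square virtual room; on a fraction of CS+ trials an aversive sound (the US)
plays from the pedestal, its loudness decaying linearly with distance so that
walking away is an effective avoidance response.  This module holds the
configuration types (validated with pydantic), the US intensity field, ITI
sampling, and the generation of concrete per-participant trial schedules from
phase definitions or from JSON/CSV config files.

Coordinate convention: Unity-style left-handed, y-up frame; the room floor is
the x-z plane centred on the origin, and the pedestal sits at the origin by
default.  All lengths are meters, times seconds, sound levels dB.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CS_PLUS",
    "CS_MINUS",
    "PhaseKind",
    "RoomSpec",
    "USFieldSpec",
    "StimulusSpec",
    "SearchTaskSpec",
    "PhaseSpec",
    "TrialSpec",
    "ExperimentSpec",
    "PhaseSchedule",
    "SessionSchedule",
    "ConfigError",
    "us_intensity",
    "sample_iti",
    "build_phase_schedule",
    "build_experiment",
    "load_experiment_config",
    "save_experiment_config",
    "load_template",
    "available_templates",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"

PhaseKind = Literal[
    "practice",
    "pavlovian_acquisition",
    "avoidance_learning",
    "transfer",
    "instructed_extinction",
    "extinction_recall",
    "reinstatement",
]


class ConfigError(ValueError):
    """Raised for invalid experiment configuration."""


class RoomSpec(BaseModel):
    """Square virtual room; wall colour is a per-trial RGB triple."""

    width: float = 8.0
    depth: float = 8.0
    height: float = 3.0
    wall_color: tuple[int, int, int] = (200, 200, 200)

    @field_validator("width", "depth", "height")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("room dimensions must be positive")
        return v

    def contains_xz(self, x: float, z: float, margin: float = 0.0) -> bool:
        return (abs(x) <= self.width / 2 - margin) and (abs(z) <= self.depth / 2 - margin)


class USFieldSpec(BaseModel):
    """Aversive sound source with linear distance decay.

    ``decay_fraction_per_meter`` is the fraction of the source intensity lost
    per meter; the sound is inaudible beyond ``1/decay_fraction_per_meter``
    (the audible radius, 4 m at the default 25 %/m).
    """

    intensity_at_source: float = 80.0
    decay_fraction_per_meter: float = 0.25
    duration: float = 1.0
    source_position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @field_validator("intensity_at_source")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("intensity_at_source must be >= 0")
        return v

    @field_validator("decay_fraction_per_meter")
    @classmethod
    def _decay_range(cls, v: float) -> float:
        if not (0 < v <= 1):
            raise ValueError("decay_fraction_per_meter must be in (0, 1]")
        return v

    @property
    def audible_radius(self) -> float:
        return 1.0 / self.decay_fraction_per_meter


class StimulusSpec(BaseModel):
    """One CS object (coloured shape on the pedestal)."""

    cs_label: Literal["CS+", "CS-"]
    shape: str = "cube"
    color: tuple[int, int, int] = (46, 61, 124)
    size: tuple[float, float, float] = (0.2, 0.2, 0.2)
    pedestal_position: tuple[float, float, float] = (0.0, 0.0, 0.0)


class SearchTaskSpec(BaseModel):
    """Incidental coin-collection task shown during transfer trials."""

    coin_lifetime: float = 1.0
    spawn_ellipse_width: float = 2.0
    spawn_ellipse_depth: float = 2.0
    spawn_height: float = 1.0
    ellipse_center_offset: float = 1.0
    collection_radius: float = 0.15


class PhaseSpec(BaseModel):
    """One experimental phase: trial counts, reinforcement and timing."""

    phase_kind: PhaseKind
    n_trials_per_condition: int = 8
    reinforcement_rate: float = 0.0
    cs_duration: float = 9.0
    us_onset: Optional[float] = 8.0
    start_distance: float = 1.0
    iti_range: tuple[float, float] = (9.0, 15.0)
    movement_allowed: bool = True
    instructed_approach: bool = False
    pre_phase_us: int = 0
    free_duration: float = 0.0  # practice-only free-walk period

    @field_validator("reinforcement_rate")
    @classmethod
    def _rate_range(cls, v: float) -> float:
        if not (0 <= v <= 1):
            raise ValueError("reinforcement_rate must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check(self) -> "PhaseSpec":
        lo, hi = self.iti_range
        if lo > hi:
            raise ValueError(f"iti_range lo > hi: {self.iti_range}")
        if self.n_trials_per_condition < 0:
            raise ValueError("n_trials_per_condition must be >= 0")
        return self


#: Per-phase defaults reproducing the published task sequence: the seated
#: conditioning phase (2 m, no movement), free avoidance (start 1 m),
#: transfer search task (21-s CS, start 2.5 m), instructed approach
#: extinction (start 4 m), extinction recall and reinstatement (start 1 m).
_PHASE_DEFAULTS: dict[str, dict] = {
    "practice": dict(n_trials_per_condition=0, reinforcement_rate=0.0, cs_duration=0.0,
                     us_onset=None, start_distance=2.0, movement_allowed=True,
                     free_duration=40.0),
    "pavlovian_acquisition": dict(n_trials_per_condition=8, reinforcement_rate=0.75,
                                  cs_duration=9.0, us_onset=8.0, start_distance=2.0,
                                  movement_allowed=False),
    "avoidance_learning": dict(n_trials_per_condition=8, reinforcement_rate=0.75,
                               cs_duration=9.0, us_onset=8.0, start_distance=1.0),
    "transfer": dict(n_trials_per_condition=2, reinforcement_rate=0.0,
                     cs_duration=21.0, us_onset=None, start_distance=2.5),
    "instructed_extinction": dict(n_trials_per_condition=8, reinforcement_rate=0.0,
                                  cs_duration=9.0, us_onset=8.0, start_distance=4.0,
                                  instructed_approach=True),
    "extinction_recall": dict(n_trials_per_condition=2, reinforcement_rate=0.0,
                              cs_duration=9.0, us_onset=8.0, start_distance=1.0),
    "reinstatement": dict(n_trials_per_condition=8, reinforcement_rate=0.0,
                          cs_duration=9.0, us_onset=8.0, start_distance=1.0,
                          pre_phase_us=1),
}


def default_phase(kind: PhaseKind, **overrides) -> PhaseSpec:
    """A PhaseSpec with the published defaults for ``kind``, overridable."""
    params = dict(_PHASE_DEFAULTS[kind])
    params.update(overrides)
    return PhaseSpec(phase_kind=kind, **params)


class TrialSpec(BaseModel):
    """One concrete trial within a phase schedule.

    ``scheduled_us_onset`` is present iff the trial is reinforced; the phase's
    nominal ``us_onset`` still defines the analysis window for unreinforced
    trials.  ``condition`` may be ``"none"`` for the unsignalled reinstatement
    US events, which carry a US but no CS.
    """

    trial_number: int
    condition: Literal["CS+", "CS-", "none"]
    reinforced: bool = False
    iti: float = 12.0
    cs_duration: float = 9.0
    scheduled_us_onset: Optional[float] = None
    phase_kind: PhaseKind
    start_position: tuple[float, float, float] = (0.0, 0.0, -1.0)

    @model_validator(mode="after")
    def _check(self) -> "TrialSpec":
        if self.condition == CS_MINUS and self.reinforced:
            raise ValueError("CS- trials are never reinforced")
        if self.reinforced and self.scheduled_us_onset is None:
            raise ValueError("reinforced trial needs scheduled_us_onset")
        return self


class ExperimentSpec(BaseModel):
    """Fixed features of one experiment: room, US field, CS pair, phase order."""

    name: str = "experiment"
    room: RoomSpec = Field(default_factory=RoomSpec)
    us: USFieldSpec = Field(default_factory=USFieldSpec)
    stimuli: tuple[StimulusSpec, StimulusSpec] = (
        StimulusSpec(cs_label=CS_PLUS, shape="cube", color=(46, 61, 124)),
        StimulusSpec(cs_label=CS_MINUS, shape="cube", color=(5, 31, 32)),
    )
    phases: list[PhaseSpec]
    search_task: SearchTaskSpec = Field(default_factory=SearchTaskSpec)
    tracker_rate: float = 90.0
    pedestal_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cs_height: float = 1.0
    #: speaker-vibration cue under the pedestal: when on, US occurrence is
    #: perceivable at any distance (used from the second experiment onwards)
    us_visual_cue: bool = True
    #: explicit per-trial features from a trial CSV; overrides generated
    #: schedules when present (not serialized)
    explicit_trials: Optional[list[TrialSpec]] = Field(default=None, exclude=True)

    @model_validator(mode="after")
    def _check(self) -> "ExperimentSpec":
        if not self.phases:
            raise ValueError("phases must be nonempty")
        if not (1 <= self.tracker_rate <= 1000):
            raise ValueError("tracker_rate out of range")
        return self

    @property
    def cs_position(self) -> tuple[float, float, float]:
        px, py, pz = self.pedestal_position
        return (px, py + self.cs_height, pz)


@dataclass
class PhaseSchedule:
    """Concrete trials of one phase for one participant."""

    phase: PhaseSpec
    trials: list[TrialSpec]
    pre_phase_us: list[TrialSpec] = field(default_factory=list)


@dataclass
class SessionSchedule:
    """Full schedule for one participant, with CS-identity counterbalancing."""

    participant_index: int
    experiment_name: str
    phases: list[PhaseSchedule]
    #: condition -> StimulusSpec identity shown for that condition
    cs_assignment: dict = field(default_factory=dict)

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for ph in self.phases for t in ph.trials]

    def n_trials(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# operations


def us_intensity(field_spec: USFieldSpec, distance: float) -> float:
    """Sound level (dB) of the US at ``distance`` meters from its source.

    Linear decay: ``I0 * (1 - decay * distance)``, clipped at zero, so the
    sound is exactly inaudible at and beyond the audible radius.
    """
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    return field_spec.intensity_at_source * max(
        0.0, 1.0 - field_spec.decay_fraction_per_meter * distance
    )


def sample_iti(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Draw one inter-trial interval from Uniform(lo, hi) seconds."""
    if lo > hi:
        raise ConfigError(f"ITI range lo > hi: ({lo}, {hi})")
    return float(rng.uniform(lo, hi))


def _start_position(phase: PhaseSpec, cs_ground: Sequence[float]) -> tuple[float, float, float]:
    # starting point on the floor, start_distance meters in front (-z) of the pedestal
    return (float(cs_ground[0]), 0.0, float(cs_ground[2]) - phase.start_distance)


def build_phase_schedule(
    phase: PhaseSpec,
    rng: np.random.Generator,
    cs_ground: Sequence[float] = (0.0, 0.0, 0.0),
    max_run_length: Optional[int] = None,
) -> list[TrialSpec]:
    """Generate the trial list for one phase.

    Equal numbers of CS+ and CS- trials in a uniformly random order; exactly
    ``reinforcement_rate * n_trials_per_condition`` CS+ trials (which must be
    an integer) carry the US, chosen uniformly at random.  ``max_run_length``
    optionally rejects orders with longer same-condition runs
    (pseudo-randomisation; off by default).
    """
    n = phase.n_trials_per_condition
    if n == 0:
        return []
    n_reinforced_f = phase.reinforcement_rate * n
    n_reinforced = round(n_reinforced_f)
    if abs(n_reinforced_f - n_reinforced) > 1e-9:
        raise ConfigError(
            f"reinforcement_rate {phase.reinforcement_rate} times "
            f"{n} trials per condition is not an integer"
        )

    conditions = np.array([CS_PLUS] * n + [CS_MINUS] * n)
    while True:
        order = rng.permutation(2 * n)
        seq = conditions[order]
        if max_run_length is None:
            break
        runs = np.diff(np.flatnonzero(np.concatenate(([True], seq[1:] != seq[:-1], [True]))))
        if runs.max() <= max_run_length:
            break

    plus_positions = np.flatnonzero(seq == CS_PLUS)
    reinforced_at = set(rng.choice(plus_positions, size=n_reinforced, replace=False).tolist())

    start = _start_position(phase, cs_ground)
    trials = []
    for i, cond in enumerate(seq):
        reinforced = i in reinforced_at
        trials.append(
            TrialSpec(
                trial_number=i + 1,
                condition=str(cond),
                reinforced=reinforced,
                iti=sample_iti(rng, *phase.iti_range),
                cs_duration=phase.cs_duration,
                scheduled_us_onset=phase.us_onset if reinforced else None,
                phase_kind=phase.phase_kind,
                start_position=start,
            )
        )
    return trials


def _unsignalled_us(phase: PhaseSpec, rng: np.random.Generator,
                    us_duration: float, cs_ground: Sequence[float]) -> TrialSpec:
    # US alone at the pedestal, after a sampled ITI; logged with condition "none"
    return TrialSpec(
        trial_number=0,
        condition="none",
        reinforced=True,
        iti=sample_iti(rng, *phase.iti_range),
        cs_duration=us_duration,
        scheduled_us_onset=0.0,
        phase_kind=phase.phase_kind,
        start_position=_start_position(phase, cs_ground),
    )


def build_experiment(
    spec: ExperimentSpec,
    participant_index: int,
    rng: np.random.Generator,
    max_run_length: Optional[int] = None,
) -> SessionSchedule:
    """Concrete session schedule for one participant.

    Phase schedules are concatenated in spec order; the CS-identity-to-
    condition mapping alternates with participant parity (deterministic
    counterbalancing); reinstatement phases are preceded by their unsignalled
    US events.
    """
    if participant_index < 1:
        raise ValueError("participant_index must be >= 1")
    cs_ground = spec.pedestal_position
    explicit: dict[str, list[TrialSpec]] = {}
    if spec.explicit_trials:
        for t in spec.explicit_trials:
            explicit.setdefault(t.phase_kind, []).append(t)
    phases = []
    for phase in spec.phases:
        pre = [
            _unsignalled_us(phase, rng, spec.us.duration, cs_ground)
            for _ in range(phase.pre_phase_us)
        ]
        if phase.phase_kind in explicit:
            trials = explicit[phase.phase_kind]
        else:
            trials = build_phase_schedule(phase, rng, cs_ground, max_run_length)
        phases.append(PhaseSchedule(phase=phase, trials=trials, pre_phase_us=pre))

    stim_by_label = {s.cs_label: s for s in spec.stimuli}
    if participant_index % 2 == 1:
        assignment = {CS_PLUS: stim_by_label[CS_PLUS], CS_MINUS: stim_by_label[CS_MINUS]}
    else:  # swap the physical stimuli between conditions
        assignment = {CS_PLUS: stim_by_label[CS_MINUS], CS_MINUS: stim_by_label[CS_PLUS]}
    return SessionSchedule(
        participant_index=participant_index,
        experiment_name=spec.name,
        phases=phases,
        cs_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# config I/O

_KNOWN_TOP_KEYS = {
    "name", "room", "us", "stimuli", "phases", "search_task", "tracker_rate",
    "pedestal_position", "cs_height", "us_visual_cue",
}

_TRIAL_CSV_COLUMNS = [
    "trial_number", "phase", "condition", "reinforced", "iti_s",
    "cs_duration_s", "us_onset_s", "wall_color_r", "wall_color_g",
    "wall_color_b", "start_x", "start_z",
]


def load_experiment_config(json_path, trial_csv_path=None) -> ExperimentSpec:
    """Read a fixed-features JSON file (and optional trial-features CSV).

    Unknown top-level keys are reported as warnings; missing required fields
    raise a validation error naming the field.  When a trial CSV is given its
    rows are validated and attached to the spec as ``explicit_trials`` (a list
    of TrialSpec grouped by phase) for use by the simulator.
    """
    path = Path(json_path)
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        warnings.warn(f"unknown config keys ignored: {sorted(unknown)}", stacklevel=2)
        raw = {k: v for k, v in raw.items() if k in _KNOWN_TOP_KEYS}
    if "phases" not in raw:
        raise ConfigError("missing required field: phases")
    try:
        spec = ExperimentSpec(**raw)
    except Exception as exc:  # pydantic error — re-raise with config context
        raise ConfigError(f"invalid experiment config {path.name}: {exc}") from exc

    if trial_csv_path is not None:
        spec.explicit_trials = load_trial_csv(trial_csv_path)
    return spec


def load_trial_csv(trial_csv_path) -> list[TrialSpec]:
    """Parse a per-trial features CSV into TrialSpecs (row errors carry row numbers)."""
    trials = []
    with open(trial_csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigError(f"trial CSV {trial_csv_path} is empty")
        missing = {"trial_number", "phase", "condition"} - set(reader.fieldnames)
        if missing:
            raise ConfigError(f"trial CSV missing columns: {sorted(missing)}")
        n_rows = 0
        for i, row in enumerate(reader, start=2):  # header is line 1
            n_rows += 1
            try:
                reinforced = str(row.get("reinforced", "")).strip().lower() in ("1", "true", "yes")
                trials.append(
                    TrialSpec(
                        trial_number=int(row["trial_number"]),
                        condition=row["condition"],
                        reinforced=reinforced,
                        iti=float(row.get("iti_s") or 12.0),
                        cs_duration=float(row.get("cs_duration_s") or 9.0),
                        scheduled_us_onset=(
                            float(row["us_onset_s"]) if row.get("us_onset_s") else None
                        ),
                        phase_kind=row["phase"],
                        start_position=(
                            float(row.get("start_x") or 0.0),
                            0.0,
                            float(row.get("start_z") or -1.0),
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"malformed trial CSV row {i}: {exc}") from exc
        if n_rows == 0:
            raise ConfigError(f"trial CSV {trial_csv_path} has no trial rows")
    return trials


def save_experiment_config(spec: ExperimentSpec, json_path) -> None:
    """Write a spec back to a fixed-features JSON file (round-trips with load)."""
    with open(json_path, "w") as fh:
        json.dump(spec.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# packaged experiment templates


def _template_dir() -> Path:
    return Path(__file__).parent / "templates"


def available_templates() -> list[str]:
    return sorted(p.stem for p in _template_dir().glob("*.json"))


def load_template(name: str) -> ExperimentSpec:
    """Load one of the packaged experiment templates (exp1 … exp5)."""
    path = _template_dir() / f"{name}.json"
    if not path.exists():
        raise ConfigError(
            f"unknown template {name!r}; available: {available_templates()}"
        )
    return load_experiment_config(path)
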