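"""Headless session simulation: parametric agents stand in for participants.

Each agent carries a per-condition CS-US association updated once per trial by
the delta rule ``V <- V + alpha * (outcome - V)``, where the outcome is the
*perceived* US (a delivered US is only perceived when the agent is inside the
audible radius of the sound field, unless the experiment uses the
speaker-vibration cue that signals US occurrence at any distance).  Movement
is a simple distance-regulating policy: when the effective association for the
current CS exceeds an avoidance threshold the agent walks away from the CS
toward its preferred safe distance; under the instructed-approach prompt a
compliant agent walks toward the CS instead; otherwise it drifts around its
position with Gaussian noise.  Head yaw tracks the movement direction (or the
CS bearing when idle) plus heading noise.

The simulator writes sessions exclusively through the containers of
:mod:`cogavoid.uxf_io`; traces cover the CS period at the tracker rate, with
inter-trial intervals advancing the session clock only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .task_model import (
    CS_MINUS,
    CS_PLUS,
    ExperimentSpec,
    SessionSchedule,
    TrialSpec,
    build_experiment,
    us_intensity,
)
from .uxf_io import SessionLog, TrackerTrace, TrialRecord

__all__ = [
    "AgentParams",
    "AgentState",
    "TrialContext",
    "update_association",
    "agent_policy_step",
    "run_trial",
    "run_session",
    "run_cohort",
    "null_agent_params",
    "avoider_agent_params",
]

EYE_HEIGHT = 1.7  # meters; head tracker height for a standing agent
ROOM_MARGIN = 0.3  # meters kept clear of the walls


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one simulated participant.

    ``learning_rate`` (alpha) and ``avoidance_threshold`` (theta) govern the
    delta-rule acquisition and when avoidance kicks in;
    ``generalisation_weight`` leaks a fraction of the CS+ association into the
    CS- drive (condition generalisation); ``reinstatement_strength`` is the
    fraction of the historical peak association restored by an unsignalled US.
    """

    learning_rate: float = 0.25
    avoidance_threshold: float = 0.4
    preferred_safe_distance: float = 4.0
    walk_speed: float = 1.0
    heading_noise_sd: float = 5.0  # degrees
    position_noise_sd: float = 0.05  # meters of drift per second (1 SD)
    extinction_learning: bool = True
    approach_compliance: float = 0.9
    generalisation_weight: float = 0.1
    reinstatement_strength: float = 0.9
    stand_close_distance: float = 0.3  # approach stops this close to the CS
    #: starting CS+ association (pre-conditioned agent); 0 = naive
    initial_cs_plus_association: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in [0, 1]")
        if not (0.0 <= self.generalisation_weight <= 1.0):
            raise ValueError("generalisation_weight must be in [0, 1]")
        if self.walk_speed < 0:
            raise ValueError("walk_speed must be >= 0")
        if not (0.0 <= self.approach_compliance <= 1.0):
            raise ValueError("approach_compliance must be in [0, 1]")


def null_agent_params(**overrides) -> AgentParams:
    """A non-learning agent (alpha = 0): pure drift, no CS differentiation."""
    return AgentParams(**{"learning_rate": 0.0, **overrides})


def avoider_agent_params(**overrides) -> AgentParams:
    """The default learning/avoiding agent."""
    return AgentParams(**overrides)


@dataclass
class AgentState:
    """Mutable agent state: pose plus per-condition associations."""

    position: np.ndarray = field(
        default_factory=lambda: np.array([0.0, EYE_HEIGHT, -1.0])
    )
    yaw: float = 0.0
    associations: dict = field(default_factory=lambda: {CS_PLUS: 0.0, CS_MINUS: 0.0})
    peak_associations: dict = field(default_factory=lambda: {CS_PLUS: 0.0, CS_MINUS: 0.0})

    def effective_association(self, condition: str, params: AgentParams) -> float:
        v = self.associations.get(condition, 0.0)
        if condition == CS_MINUS:
            v += params.generalisation_weight * self.associations.get(CS_PLUS, 0.0)
        return min(v, 1.0)


@dataclass
class TrialContext:
    """Static per-trial context handed to the movement policy."""

    condition: str
    cs_position: tuple[float, float, float]
    movement_allowed: bool
    instructed_approach: bool
    compliant: bool
    tracker_rate: float
    room_half_width: float
    room_half_depth: float
    target: Optional[tuple[float, float]] = None  # e.g. current coin (x, z)


def update_association(v: float, outcome: float, alpha: float) -> float:
    """Delta-rule update ``v + alpha * (outcome - v)``, kept inside [0, 1]."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if not (0.0 <= v <= 1.0) or outcome not in (0, 1, 0.0, 1.0):
        raise ValueError("association and outcome must be in [0, 1]")
    return min(1.0, max(0.0, v + alpha * (outcome - v)))


def _drive_direction(
    x: float, z: float, ctx: TrialContext, params: AgentParams, v_eff: float
) -> tuple[float, float, float]:
    """Unit horizontal drive direction and the remaining distance to the
    movement target; (0, 0, 0) when the agent has no drive this step."""
    if not ctx.movement_allowed:
        return 0.0, 0.0, 0.0
    cx, _, cz = ctx.cs_position
    dx, dz = x - cx, z - cz
    dist = math.hypot(dx, dz)
    if ctx.instructed_approach and ctx.compliant:
        if dist > params.stand_close_distance and dist > 1e-9:
            return -dx / dist, -dz / dist, dist - params.stand_close_distance
        return 0.0, 0.0, 0.0
    if v_eff > params.avoidance_threshold:
        if dist < params.preferred_safe_distance:
            if dist < 1e-9:  # directly on the CS: pick -z arbitrarily
                return 0.0, -1.0, params.preferred_safe_distance
            return dx / dist, dz / dist, params.preferred_safe_distance - dist
        return 0.0, 0.0, 0.0
    if ctx.target is not None:
        tx, tz = ctx.target
        ddx, ddz = tx - x, tz - z
        tdist = math.hypot(ddx, ddz)
        if tdist > 1e-9:
            return ddx / tdist, ddz / tdist, tdist
    return 0.0, 0.0, 0.0


def agent_policy_step(
    state: AgentState,
    params: AgentParams,
    ctx: TrialContext,
    dt: float,
    rng: np.random.Generator,
) -> AgentState:
    """Advance the agent by one time step (returns a new state).

    Drive (away from / toward the CS, or toward a search-task target) moves at
    ``walk_speed`` without overshooting the target distance; positional noise
    adds Gaussian drift with a 1-second standard deviation of
    ``position_noise_sd`` per horizontal axis; the position is clipped to the
    room; yaw follows the movement direction (or the CS bearing when idle)
    plus heading noise.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x, y, z = state.position
    v_eff = state.effective_association(ctx.condition, params)
    ux, uz, remaining = _drive_direction(x, z, ctx, params, v_eff)
    step = min(params.walk_speed * dt, remaining)
    nx, nz = rng.normal(0.0, params.position_noise_sd * math.sqrt(dt), size=2)
    x_new = x + ux * step + nx
    z_new = z + uz * step + nz
    hw = ctx.room_half_width - ROOM_MARGIN
    hd = ctx.room_half_depth - ROOM_MARGIN
    x_new = min(hw, max(-hw, x_new))
    z_new = min(hd, max(-hd, z_new))

    if ux or uz:
        heading = math.degrees(math.atan2(ux, uz))  # Unity yaw: 0 = +z, clockwise
    else:
        cx, _, cz = ctx.cs_position
        heading = math.degrees(math.atan2(cx - x_new, cz - z_new))
    yaw = heading + rng.normal(0.0, params.heading_noise_sd)

    return AgentState(
        position=np.array([x_new, y, z_new]),
        yaw=yaw,
        associations=state.associations,
        peak_associations=state.peak_associations,
    )


# ---------------------------------------------------------------------------
# trial simulation


def _has_drive(ctx: TrialContext, params: AgentParams, v_eff: float) -> bool:
    if not ctx.movement_allowed:
        return False
    if ctx.instructed_approach and ctx.compliant:
        return True
    if v_eff > params.avoidance_threshold:
        return True
    return ctx.target is not None


def _simulate_drift(
    start: np.ndarray,
    yaw_to: tuple[float, float, float],
    n_steps: int,
    dt: float,
    params: AgentParams,
    half_w: float,
    half_d: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised no-drive trajectory (pure positional noise).

    Identical in distribution to iterating :func:`agent_policy_step` with zero
    drive; falls back to nothing here — the caller re-runs the scalar stepper
    if the unclipped walk would leave the room (it essentially never does in
    an 8 m room over a 9 s trial).
    """
    incr = rng.normal(0.0, params.position_noise_sd * math.sqrt(dt), size=(n_steps, 2))
    xz = start[[0, 2]] + np.cumsum(incr, axis=0)
    hw, hd = half_w - ROOM_MARGIN, half_d - ROOM_MARGIN
    if np.any(np.abs(xz[:, 0]) > hw) or np.any(np.abs(xz[:, 1]) > hd):
        return None, None  # caller falls back to the scalar loop
    positions = np.empty((n_steps, 3))
    positions[:, 0] = xz[:, 0]
    positions[:, 1] = start[1]
    positions[:, 2] = xz[:, 1]
    cx, _, cz = yaw_to
    heading = np.degrees(np.arctan2(cx - positions[:, 0], cz - positions[:, 2]))
    yaw = heading + rng.normal(0.0, params.heading_noise_sd, size=n_steps)
    return positions, yaw


def run_trial(
    trial: TrialSpec,
    ctx: TrialContext,
    state: AgentState,
    params: AgentParams,
    rng: np.random.Generator,
    us_field=None,
    us_visual_cue: bool = True,
    search_task=None,
    t0: float = 0.0,
) -> tuple[TrackerTrace, list[dict], AgentState]:
    """Simulate one CS period and return (trace, event markers, new state).

    Trial time 0 is CS onset; the trace covers ``[0, cs_duration)`` at the
    tracker rate.  Events carry session-relative timestamps offset by ``t0``.
    The association for the trial's condition is updated once at the end with
    the perceived-US outcome.
    """
    rate = ctx.tracker_rate
    dt = 1.0 / rate
    n_steps = int(round(trial.cs_duration * rate))
    events: list[dict] = [
        {"time_s": t0, "event": "trial_start",
         "payload": {"condition": trial.condition, "phase": trial.phase_kind}},
        {"time_s": t0, "event": "cs_on", "payload": {"condition": trial.condition}},
    ]

    us_onset = trial.scheduled_us_onset
    us_onset_idx = None
    if trial.reinforced and us_onset is not None:
        us_onset_idx = int(round(us_onset * rate))
        us_dur = us_field.duration if us_field is not None else 1.0
        events.append({"time_s": t0 + us_onset, "event": "us_on",
                       "payload": {"condition": trial.condition}})
        events.append({"time_s": t0 + min(us_onset + us_dur, trial.cs_duration),
                       "event": "us_off", "payload": {}})
    events.append({"time_s": t0 + trial.cs_duration, "event": "cs_off", "payload": {}})
    events.sort(key=lambda e: e["time_s"])

    cs_pos = ctx.cs_position
    half_w, half_d = ctx.room_half_width, ctx.room_half_depth
    v_eff = state.effective_association(ctx.condition, params)

    positions = yaw = None
    coin_events: list[dict] = []
    if search_task is None and not _has_drive(ctx, params, v_eff):
        positions, yaw = _simulate_drift(
            state.position, cs_pos, n_steps, dt, params, half_w, half_d, rng
        )

    if positions is None:
        # scalar stepper: inlined equivalent of iterating agent_policy_step,
        # with noise pre-drawn in bulk; handles the search-task coins
        positions = np.empty((n_steps, 3))
        yaw = np.empty(n_steps)
        pos_noise = rng.normal(
            0.0, params.position_noise_sd * math.sqrt(dt), size=(n_steps, 2)
        )
        yaw_noise = rng.normal(0.0, params.heading_noise_sd, size=n_steps)
        x, y, z = state.position
        cx, _, cz = cs_pos
        hw = half_w - ROOM_MARGIN
        hd = half_d - ROOM_MARGIN
        walk_dt = params.walk_speed * dt
        coin: Optional[tuple[float, float, float]] = None
        coin_deadline = -1.0
        ellipse_center = None
        if search_task is not None:
            sx, _, sz = trial.start_position
            d = math.hypot(cx - sx, cz - sz)
            f = search_task.ellipse_center_offset / d if d > 1e-9 else 0.0
            ellipse_center = (sx + f * (cx - sx), sz + f * (cz - sz))
        for k in range(n_steps):
            t = k * dt
            if search_task is not None:
                if coin is None or t >= coin_deadline:
                    u, ang = rng.uniform(), rng.uniform(0, 2 * math.pi)
                    r = math.sqrt(u)
                    coin = (
                        ellipse_center[0] + r * math.cos(ang) * search_task.spawn_ellipse_width / 2,
                        search_task.spawn_height,
                        ellipse_center[1] + r * math.sin(ang) * search_task.spawn_ellipse_depth / 2,
                    )
                    coin_deadline = t + search_task.coin_lifetime
                    coin_events.append({"time_s": t0 + t, "event": "coin_spawn",
                                        "payload": {"x": round(coin[0], 4), "z": round(coin[2], 4)}})
                ctx.target = (coin[0], coin[2])
            ux, uz, remaining = _drive_direction(x, z, ctx, params, v_eff)
            step = walk_dt if walk_dt < remaining else remaining
            x = x + ux * step + pos_noise[k, 0]
            z = z + uz * step + pos_noise[k, 1]
            x = hw if x > hw else (-hw if x < -hw else x)
            z = hd if z > hd else (-hd if z < -hd else z)
            if ux or uz:
                heading = math.degrees(math.atan2(ux, uz))
            else:
                heading = math.degrees(math.atan2(cx - x, cz - z))
            yk = heading + yaw_noise[k]
            if search_task is not None and coin is not None:
                # hand reach approximated 0.4 m ahead of the head
                hx = x + 0.4 * math.sin(math.radians(yk))
                hz = z + 0.4 * math.cos(math.radians(yk))
                if math.hypot(hx - coin[0], hz - coin[2]) <= search_task.collection_radius + 0.4:
                    coin_events.append({"time_s": t0 + t, "event": "coin_collect", "payload": {}})
                    coin = None
            positions[k, 0] = x
            positions[k, 1] = y
            positions[k, 2] = z
            yaw[k] = yk
        ctx.target = None

    times = np.arange(n_steps) * dt
    trace = TrackerTrace(
        tracker_id="head", times=times, positions=positions, yaw=yaw,
        nominal_rate=rate,
    )
    if len(trace) != n_steps:
        raise RuntimeError("trace duration mismatch vs trial spec")
    events.extend(coin_events)
    events.sort(key=lambda e: e["time_s"])

    # one delta-rule update per trial with the perceived-US outcome
    new_assoc = dict(state.associations)
    new_peaks = dict(state.peak_associations)
    if trial.condition in new_assoc:
        outcome = 0.0
        if trial.reinforced and us_onset_idx is not None:
            idx = min(us_onset_idx, n_steps - 1)
            px, pz = positions[idx, 0], positions[idx, 2]
            d_us = math.hypot(px - cs_pos[0], pz - cs_pos[2])
            if us_visual_cue or us_field is None or us_intensity(us_field, d_us) > 0:
                outcome = 1.0
        if outcome == 1.0 or params.extinction_learning:
            new_assoc[trial.condition] = update_association(
                new_assoc[trial.condition], outcome, params.learning_rate
            )
            new_peaks[trial.condition] = max(
                new_peaks[trial.condition], new_assoc[trial.condition]
            )
    final_state = AgentState(
        position=positions[-1].copy(),
        yaw=float(yaw[-1]),
        associations=new_assoc,
        peak_associations=new_peaks,
    )
    return trace, events, final_state


# ---------------------------------------------------------------------------
# session and cohort simulation


def run_session(
    schedule: SessionSchedule,
    agent_params: AgentParams,
    rng: np.random.Generator,
    spec: ExperimentSpec,
    ppid: Optional[str] = None,
) -> SessionLog:
    """Simulate a full session from a schedule; returns a SessionLog.

    The session clock accrues ITIs and CS periods; between trials the agent is
    repositioned on the phase's starting point (the return walk is not
    instrumented).  Unsignalled pre-phase US events (reinstatement) are logged
    as ``us_on`` rows with condition ``none`` and partially restore each
    condition's association toward its historical peak.
    """
    ppid = ppid or f"P{schedule.participant_index:03d}"
    v0 = agent_params.initial_cs_plus_association
    state = AgentState(
        associations={CS_PLUS: v0, CS_MINUS: 0.0},
        peak_associations={CS_PLUS: v0, CS_MINUS: 0.0},
    )
    events: list[dict] = []
    records: list[TrialRecord] = []
    clock = 0.0
    cs_pos = spec.cs_position

    for ph in schedule.phases:
        phase = ph.phase
        events.append({"time_s": clock, "event": "phase_start",
                       "payload": {"phase": phase.phase_kind}})
        if phase.phase_kind == "practice":
            clock += phase.free_duration
            events.append({"time_s": clock, "event": "phase_end",
                           "payload": {"phase": phase.phase_kind}})
            continue

        for us_trial in ph.pre_phase_us:
            clock += us_trial.iti
            events.append({"time_s": clock, "event": "us_on",
                           "payload": {"condition": "none"}})
            events.append({"time_s": clock + spec.us.duration, "event": "us_off",
                           "payload": {}})
            clock += spec.us.duration
            # unsignalled US reactivates prior learning toward its peak
            for cond in state.associations:
                v, peak = state.associations[cond], state.peak_associations[cond]
                state.associations[cond] = v + agent_params.reinstatement_strength * (peak - v)

        for trial in ph.trials:
            clock += trial.iti
            sx, _, sz = trial.start_position
            state = AgentState(
                position=np.array([sx, EYE_HEIGHT, sz]),
                yaw=state.yaw,
                associations=state.associations,
                peak_associations=state.peak_associations,
            )
            compliant = bool(rng.uniform() < agent_params.approach_compliance)
            ctx = TrialContext(
                condition=trial.condition,
                cs_position=cs_pos,
                movement_allowed=phase.movement_allowed,
                instructed_approach=phase.instructed_approach,
                compliant=compliant,
                tracker_rate=spec.tracker_rate,
                room_half_width=spec.room.width / 2,
                room_half_depth=spec.room.depth / 2,
            )
            search = spec.search_task if phase.phase_kind == "transfer" else None
            trace, trial_events, state = run_trial(
                trial, ctx, state, agent_params, rng,
                us_field=spec.us, us_visual_cue=spec.us_visual_cue,
                search_task=search, t0=clock,
            )
            events.extend(trial_events)
            records.append(
                TrialRecord(
                    ppid=ppid,
                    phase=phase.phase_kind,
                    trial_num=trial.trial_number,
                    condition=trial.condition,
                    reinforced=trial.reinforced,
                    iti=trial.iti,
                    cs_on_time=clock,
                    us_on_time=(clock + trial.scheduled_us_onset)
                    if trial.reinforced and trial.scheduled_us_onset is not None
                    else None,
                    traces={"head": trace},
                )
            )
            clock += trial.cs_duration
        events.append({"time_s": clock, "event": "phase_end",
                       "payload": {"phase": phase.phase_kind}})

    import json as _json

    ev = pd.DataFrame(
        {
            "time_s": [e["time_s"] for e in events],
            "event": [e["event"] for e in events],
            "payload_json": [_json.dumps(e["payload"]) for e in events],
        }
    )
    return SessionLog(
        participant_id=ppid,
        experiment_name=schedule.experiment_name,
        trials=records,
        events=ev,
        spec=spec,
    )


ParamsLike = Union[AgentParams, Callable[[np.random.Generator], AgentParams]]


def run_cohort(
    spec: ExperimentSpec,
    agent_params: ParamsLike,
    n_participants: int,
    seed: int,
) -> list[SessionLog]:
    """Simulate a cohort; reproducible given ``seed`` and stable under resizing.

    Each participant gets an independent random stream derived from the master
    seed and their 1-based index, and the CS-identity counterbalancing follows
    index parity.  ``agent_params`` is either a shared AgentParams or a
    callable drawing per-participant parameters from the stream.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    sessions = []
    for idx in range(1, n_participants + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), idx]))
        params = agent_params(rng) if callable(agent_params) else agent_params
        schedule = build_experiment(spec, idx, rng)
        session = run_session(schedule, params, rng, spec)
        session.seed = int(seed)
        sessions.append(session)
    return sessions
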