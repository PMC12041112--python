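"""Trial-level kinematic summaries of the head trajectory.

Seven statistics are computed from the head tracker over the analysis window
(CS onset to scheduled US onset by default): mean, maximum and minimum
distance to the CS location; overall path length; maximum speed; mean
absolute head angle relative to the CS bearing; and the reaction time of the
first move away, defined as the first time the head is displaced at least
0.7 m from its position at CS onset (censored when never reached).

Distances use the horizontal (x, z) projection by default — avoidance in
this paradigm is locomotor and the pedestal height is constant — with a
3-D option for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .uxf_io import SessionLog, TrackerTrace, read_session

__all__ = [
    "AnalysisWindow",
    "AnalysisOptions",
    "KinematicSummary",
    "WindowError",
    "extract_window",
    "distance_to_cs",
    "head_angle",
    "reaction_time",
    "summarize_trial",
    "summarize_session",
    "augment_trial_table",
]

RT_THRESHOLD_DEFAULT = 0.7  # meters of head displacement from CS onset


class WindowError(ValueError):
    """No samples fall inside the requested analysis window."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open trial-time window [t0, t1); defaults to CS onset → US onset."""

    t0: float = 0.0
    t1: float = 8.0

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"window requires t0 < t1, got ({self.t0}, {self.t1})")


@dataclass(frozen=True)
class AnalysisOptions:
    """Pipeline options: distance projection, RT threshold, window policy.

    ``transfer_full_window`` keeps the whole 21-s CS period for transfer
    trials (they have no US onset); unreinforced conditioning trials always
    use the phase's scheduled US-onset time as the window end.
    """

    distance_mode: str = "2d"  # or "3d"
    rt_threshold: float = RT_THRESHOLD_DEFAULT
    transfer_full_window: bool = True
    window_override: Optional[AnalysisWindow] = None
    smooth_speed: bool = False  # optional 3-sample moving average before speeds

    def __post_init__(self) -> None:
        if self.distance_mode not in ("2d", "3d"):
            raise ValueError("distance_mode must be '2d' or '3d'")


@dataclass
class KinematicSummary:
    mean_dist: float
    max_dist: float
    min_dist: float
    path_length: float
    max_speed: float
    mean_head_angle: Optional[float]  # degrees in [0, 180]; None if yaw missing
    reaction_time: Optional[float]  # seconds; None when censored

    def as_row(self) -> dict:
        return {
            "mean_dist_m": self.mean_dist,
            "max_dist_m": self.max_dist,
            "min_dist_m": self.min_dist,
            "path_len_m": self.path_length,
            "max_speed_mps": self.max_speed,
            "head_angle_deg": self.mean_head_angle,
            "rt_s": self.reaction_time,
        }


def extract_window(trace: TrackerTrace, window: AnalysisWindow) -> TrackerTrace:
    """Samples with ``t0 <= time < t1``, order preserved."""
    mask = (trace.times >= window.t0) & (trace.times < window.t1)
    if not mask.any():
        raise WindowError(
            f"no samples in window [{window.t0}, {window.t1}) for tracker "
            f"{trace.tracker_id}"
        )
    return TrackerTrace(
        tracker_id=trace.tracker_id,
        times=trace.times[mask],
        positions=trace.positions[mask],
        yaw=None if trace.yaw is None else trace.yaw[mask],
        nominal_rate=trace.nominal_rate,
        handedness=trace.handedness,
    )


def distance_to_cs(
    position: Sequence[float], cs_position: Sequence[float], mode: str = "2d"
) -> float:
    """Distance (m) from a head position to the CS, horizontal by default."""
    dx = position[0] - cs_position[0]
    dz = position[2] - cs_position[2]
    if mode == "3d":
        dy = position[1] - cs_position[1]
        return math.sqrt(dx * dx + dy * dy + dz * dz)
    return math.hypot(dx, dz)


def head_angle(
    position: Sequence[float], yaw_deg: float, cs_position: Sequence[float]
) -> float:
    """Absolute angle (deg, 0–180) between heading and the bearing to the CS.

    Yaw follows the Unity convention (0 = +z, clockwise positive about the
    vertical axis); 0 means facing the CS directly.
    """
    bx = cs_position[0] - position[0]
    bz = cs_position[2] - position[2]
    if math.hypot(bx, bz) < 1e-12:
        raise ValueError("head exactly at the CS ground point: bearing undefined")
    bearing = math.degrees(math.atan2(bx, bz))
    diff = (yaw_deg - bearing) % 360.0
    if diff > 180.0:
        diff = 360.0 - diff
    return diff


def reaction_time(
    trace: TrackerTrace,
    window: AnalysisWindow,
    threshold: float = RT_THRESHOLD_DEFAULT,
    mode: str = "2d",
) -> Optional[float]:
    """First time (s) the head is displaced >= ``threshold`` from its position
    at the window's first sample; None (censored) when never reached.

    Displacement is from the onset *position*, not distance to the CS, so a
    move toward the CS counts too.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    sub = extract_window(trace, window)
    origin = sub.positions[0]
    d = sub.positions - origin
    if mode == "3d":
        disp = np.sqrt((d ** 2).sum(axis=1))
    else:
        disp = np.hypot(d[:, 0], d[:, 2])
    hits = np.flatnonzero(disp >= threshold)
    if hits.size == 0:
        return None
    return float(sub.times[hits[0]])


def _distances(positions: np.ndarray, cs_position, mode: str) -> np.ndarray:
    d = positions - np.asarray(cs_position, dtype=float)
    if mode == "3d":
        return np.sqrt((d ** 2).sum(axis=1))
    return np.hypot(d[:, 0], d[:, 2])


def summarize_trial(
    trace: TrackerTrace,
    cs_position: Sequence[float],
    window: AnalysisWindow,
    options: AnalysisOptions = AnalysisOptions(),
) -> KinematicSummary:
    """The seven summary statistics over the analysis window."""
    sub = extract_window(trace, window)
    if len(sub) < 2:
        raise ValueError("need at least 2 samples in the analysis window")
    mode = options.distance_mode
    dist = _distances(sub.positions, cs_position, mode)

    pos = sub.positions
    if options.smooth_speed and len(sub) >= 3:
        sm = pos.copy()
        sm[1:-1] = (pos[:-2] + pos[1:-1] + pos[2:]) / 3.0
        pos_speed = sm
    else:
        pos_speed = pos
    step = np.diff(pos_speed, axis=0)
    if mode == "3d":
        seg = np.sqrt((step ** 2).sum(axis=1))
    else:
        seg = np.hypot(step[:, 0], step[:, 2])
    dt = np.diff(sub.times)
    speeds = seg / dt

    if sub.yaw is None:
        mean_angle = None
    else:
        angles = [
            head_angle(pos[k], sub.yaw[k], cs_position) for k in range(len(sub))
        ]
        mean_angle = float(np.mean(angles))

    return KinematicSummary(
        mean_dist=float(dist.mean()),
        max_dist=float(dist.max()),
        min_dist=float(dist.min()),
        path_length=float(seg.sum()),
        max_speed=float(speeds.max()),
        mean_head_angle=mean_angle,
        reaction_time=reaction_time(trace, window, options.rt_threshold, mode),
    )


def _trial_window(phase: str, cs_duration: float, us_onset: Optional[float],
                  options: AnalysisOptions) -> AnalysisWindow:
    if options.window_override is not None:
        return options.window_override
    if phase == "transfer" and options.transfer_full_window:
        return AnalysisWindow(0.0, cs_duration)
    if us_onset is not None:
        return AnalysisWindow(0.0, us_onset)
    return AnalysisWindow(0.0, cs_duration)


def summarize_session(
    session: SessionLog, options: AnalysisOptions = AnalysisOptions()
) -> SessionLog:
    """Fill each trial record's KinematicSummary in place; returns the session.

    The window end is the scheduled US onset of the trial's phase (8 s for
    the 9-s conditioning phases, whether or not the trial was reinforced) and
    the full CS period for transfer trials.
    """
    spec = session.spec
    cs_position = spec.cs_position if spec is not None else (0.0, 1.0, 0.0)
    phase_us_onset: dict[str, Optional[float]] = {}
    if spec is not None:
        phase_us_onset = {p.phase_kind: p.us_onset for p in spec.phases}

    for trial in session.trials:
        trace = trial.traces.get("head")
        if trace is None:
            continue
        cs_duration = float(trace.times[-1]) + 1.0 / trace.nominal_rate
        us_onset = phase_us_onset.get(trial.phase, 8.0 if cs_duration <= 10 else None)
        window = _trial_window(trial.phase, cs_duration, us_onset, options)
        summary = summarize_trial(trace, cs_position, window, options)
        trial.summary = summary.as_row()
    return session


def augment_trial_table(
    session_dir, options: AnalysisOptions = AnalysisOptions(), write: bool = True
) -> pd.DataFrame:
    """Batch entry point: read a session directory, append the seven summary
    columns to its trial_results.csv, and return the augmented table."""
    session = read_session(session_dir)
    summarize_session(session, options)
    table = session.trial_table()
    if write:
        table.to_csv(Path(session_dir) / "trial_results.csv", index=False,
                     float_format="%.8g")
    return table
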