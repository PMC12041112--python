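"""UXF-style session logging: one trial-results table per session, one
movement CSV per tracker per trial, plus an event-marker table.

Layout written by :func:`write_session`::

    <dir>/trial_results.csv      one row per trial
    <dir>/trackers/<tracker>_T<trial>.csv
    <dir>/events.csv             TTL-style event markers (one row per event)
    <dir>/spec.json              snapshot of the experiment spec

Positions are meters in a Unity-style left-handed y-up frame; tracker files
store time relative to trial start (CS onset), session-relative offsets live
in trial_results.csv.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .task_model import ExperimentSpec

__all__ = [
    "TrackerTrace",
    "TrialRecord",
    "SessionLog",
    "SessionFormatError",
    "write_session",
    "read_session",
    "convert_handedness",
]

SUMMARY_COLUMNS = [
    "mean_dist_m", "max_dist_m", "min_dist_m", "path_len_m",
    "max_speed_mps", "head_angle_deg", "rt_s",
]

_TRACKER_COLUMNS = ["time_s", "pos_x", "pos_y", "pos_z", "yaw_deg"]

#: best-effort shim for common UXF-style column spellings
_COLUMN_ALIASES = {
    "time": "time_s",
    "t": "time_s",
    "pos_x_m": "pos_x",
    "pos_y_m": "pos_y",
    "pos_z_m": "pos_z",
    "x": "pos_x",
    "y": "pos_y",
    "z": "pos_z",
    "yaw": "yaw_deg",
    "rot_y": "yaw_deg",
}


class SessionFormatError(ValueError):
    """Raised when a session directory does not match the expected layout."""


@dataclass
class TrackerTrace:
    """Timestamped 3-D pose samples for one tracker on one trial."""

    tracker_id: str  # head, left_hand, right_hand
    times: np.ndarray  # seconds from trial start, strictly increasing
    positions: np.ndarray  # (n, 3) meters
    yaw: Optional[np.ndarray] = None  # degrees about the vertical axis
    nominal_rate: float = 90.0
    handedness: str = "left_y_up"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.yaw is not None:
            self.yaw = np.asarray(self.yaw, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        yaw = self.yaw if self.yaw is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pos_x": self.positions[:, 0],
                "pos_y": self.positions[:, 1],
                "pos_z": self.positions[:, 2],
                "yaw_deg": yaw,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, tracker_id: str, nominal_rate: float = 90.0,
        source: str = "<dataframe>",
    ) -> "TrackerTrace":
        df = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})
        missing = [c for c in ("time_s", "pos_x", "pos_y", "pos_z") if c not in df.columns]
        if missing:
            raise SessionFormatError(f"{source}: missing tracker columns {missing}")
        times = df["time_s"].to_numpy(float)
        if len(times) >= 2:
            bad = np.flatnonzero(np.diff(times) <= 0)
            if bad.size:
                raise SessionFormatError(
                    f"{source}: non-monotone timestamps at row {int(bad[0]) + 2}"
                )
        yaw = df["yaw_deg"].to_numpy(float) if "yaw_deg" in df.columns else None
        if yaw is not None and np.all(np.isnan(yaw)):
            yaw = None
        return cls(
            tracker_id=tracker_id,
            times=times,
            positions=df[["pos_x", "pos_y", "pos_z"]].to_numpy(float),
            yaw=yaw,
            nominal_rate=nominal_rate,
        )


@dataclass
class TrialRecord:
    """One row of the trial-results table, plus the attached tracker traces."""

    ppid: str
    phase: str
    trial_num: int  # within-phase index across conditions (1-based)
    condition: str
    reinforced: bool
    iti: float
    cs_on_time: float  # session-relative, seconds
    us_on_time: Optional[float] = None  # session-relative, absent if unreinforced
    traces: dict[str, TrackerTrace] = field(default_factory=dict)
    summary: dict[str, float] = field(default_factory=dict)
    tracker_files: dict[str, str] = field(default_factory=dict)


@dataclass
class SessionLog:
    """One simulated or recorded participant session."""

    participant_id: str
    experiment_name: str
    trials: list[TrialRecord]
    events: pd.DataFrame  # columns time_s, event, payload_json
    spec: Optional[ExperimentSpec] = None
    seed: Optional[int] = None

    def trial_table(self) -> pd.DataFrame:
        """Trial-results table (one row per trial, summary columns if present)."""
        if not self.trials:
            return _empty_trial_table()
        rows = []
        for i, t in enumerate(self.trials, start=1):
            row = {
                "ppid": t.ppid,
                "phase": t.phase,
                "trial_num": t.trial_num,
                "condition": t.condition,
                "reinforced": t.reinforced,
                "iti_s": t.iti,
                "cs_on_s": t.cs_on_time,
                "us_on_s": t.us_on_time if t.us_on_time is not None else np.nan,
            }
            for tracker_id in t.traces:
                row[f"{tracker_id}_file"] = t.tracker_files.get(
                    tracker_id, f"trackers/{tracker_id}_T{i:03d}.csv"
                )
            for k in SUMMARY_COLUMNS:
                if k in t.summary:
                    v = t.summary[k]
                    row[k] = np.nan if v is None else v
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def write_session(session: SessionLog, directory) -> dict[str, int]:
    """Write a session in the UXF-style layout; returns {file: row count}."""
    directory = Path(directory)
    (directory / "trackers").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    for i, trial in enumerate(session.trials, start=1):
        for tracker_id, trace in trial.traces.items():
            rel = f"trackers/{tracker_id}_T{i:03d}.csv"
            trial.tracker_files[tracker_id] = rel
            df = trace.to_dataframe()
            df.to_csv(directory / rel, index=False, float_format="%.8g")
            manifest[rel] = len(df)

    table = session.trial_table()
    table.to_csv(directory / "trial_results.csv", index=False, float_format="%.8g")
    manifest["trial_results.csv"] = len(table)

    events = session.events if session.events is not None else pd.DataFrame(
        columns=["time_s", "event", "payload_json"]
    )
    events.to_csv(directory / "events.csv", index=False, float_format="%.8g")
    manifest["events.csv"] = len(events)

    meta = {
        "participant_id": session.participant_id,
        "experiment_name": session.experiment_name,
        "seed": session.seed,
        "spec": session.spec.model_dump(mode="json") if session.spec is not None else None,
    }
    with open(directory / "spec.json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    manifest["spec.json"] = 1
    return manifest


def _empty_trial_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["ppid", "phase", "trial_num", "condition", "reinforced",
                 "iti_s", "cs_on_s", "us_on_s"]
    )


def read_session(directory) -> SessionLog:
    """Read a session directory written by :func:`write_session`."""
    directory = Path(directory)
    results_path = directory / "trial_results.csv"
    if not results_path.exists():
        raise SessionFormatError(f"{directory}: no trial_results.csv")
    table = pd.read_csv(results_path) if results_path.stat().st_size else _empty_trial_table()

    spec = None
    participant_id, experiment_name, seed = "unknown", "unknown", None
    meta_path = directory / "spec.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        participant_id = meta.get("participant_id", participant_id)
        experiment_name = meta.get("experiment_name", experiment_name)
        seed = meta.get("seed")
        if meta.get("spec") is not None:
            spec = ExperimentSpec(**meta["spec"])
    nominal_rate = spec.tracker_rate if spec is not None else 90.0

    tracker_cols = [c for c in table.columns if c.endswith("_file")]
    trials = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        row_d = row._asdict()
        traces: dict[str, TrackerTrace] = {}
        files: dict[str, str] = {}
        for col in tracker_cols:
            rel = row_d.get(col)
            if not isinstance(rel, str) or not rel:
                continue
            tracker_id = col[: -len("_file")]
            path = directory / rel
            if not path.exists():
                raise SessionFormatError(
                    f"trial {i}: referenced tracker file {rel} is missing"
                )
            df = pd.read_csv(path)
            traces[tracker_id] = TrackerTrace.from_dataframe(
                df, tracker_id, nominal_rate, source=rel
            )
            files[tracker_id] = rel
        us_on = row_d.get("us_on_s")
        summary = {
            k: row_d[k] for k in SUMMARY_COLUMNS if k in row_d and row_d[k] is not None
        }
        trials.append(
            TrialRecord(
                ppid=str(row_d["ppid"]),
                phase=str(row_d["phase"]),
                trial_num=int(row_d["trial_num"]),
                condition=str(row_d["condition"]),
                reinforced=bool(row_d["reinforced"]),
                iti=float(row_d["iti_s"]),
                cs_on_time=float(row_d["cs_on_s"]),
                us_on_time=None if us_on is None or (isinstance(us_on, float) and math.isnan(us_on)) else float(us_on),
                traces=traces,
                summary=summary,
                tracker_files=files,
            )
        )

    events_path = directory / "events.csv"
    if events_path.exists() and events_path.stat().st_size:
        events = pd.read_csv(events_path)
    else:
        events = pd.DataFrame(columns=["time_s", "event", "payload_json"])
    return SessionLog(
        participant_id=participant_id,
        experiment_name=experiment_name,
        trials=trials,
        events=events,
        spec=spec,
        seed=seed,
    )


def convert_handedness(trace: TrackerTrace, target: str) -> TrackerTrace:
    """Re-express a trace in the other handedness convention.

    Switching between the left-handed and right-handed y-up frames negates the
    z axis and maps yaw to 180 - yaw (the heading vector's z component flips).
    Applying the conversion twice is the identity.
    """
    if target not in ("left_y_up", "right_y_up"):
        raise ValueError(f"unknown handedness target {target!r}")
    if target == trace.handedness:
        return trace
    positions = trace.positions.copy()
    positions[:, 2] = -positions[:, 2]
    yaw = None if trace.yaw is None else (180.0 - trace.yaw)
    return TrackerTrace(
        tracker_id=trace.tracker_id,
        times=trace.times.copy(),
        positions=positions,
        yaw=yaw,
        nominal_rate=trace.nominal_rate,
        handedness=target,
    )
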