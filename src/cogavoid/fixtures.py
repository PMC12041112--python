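"""Hand-checkable fixture traces with closed-form kinematic summaries.

Three deterministic head trajectories, each 9 s at 90 Hz with the CS at
(0, 1, 0) and the analysis window (0, 8):

``stationary``
    standing still 2 m from the CS, facing it.  All three distance summaries
    are 2 m, path length and maximum speed are 0, the head angle is 0 and
    the reaction time is censored.

``straight_walk``
    walking away from 1 m to 4 m at 1 m/s, then standing still.  Mean
    distance 3.435417 m (the discrete mean of the piecewise-linear distance
    profile), max 4, min 1, path length 3, max speed 1, head angle 180,
    reaction time 0.7 s.

``loop``
    the straight walk with an inserted detour loop: longer path, same
    maximum distance.
"""

from __future__ import annotations

import numpy as np

from .uxf_io import TrackerTrace

__all__ = ["CS_POSITION", "FIXTURE_NAMES", "make_fixture", "expected_summaries"]

CS_POSITION = (0.0, 1.0, 0.0)
FIXTURE_NAMES = ("stationary", "straight_walk", "loop")

_RATE = 90.0
_DURATION = 9.0


def _times() -> np.ndarray:
    n = int(round(_DURATION * _RATE))
    return np.arange(n) / _RATE


def make_fixture(name: str) -> TrackerTrace:
    """Build one of the named deterministic fixture traces."""
    t = _times()
    n = len(t)
    pos = np.zeros((n, 3))
    pos[:, 1] = 1.7
    if name == "stationary":
        pos[:, 2] = -2.0
        yaw = np.zeros(n)  # facing +z, i.e. toward the CS
    elif name == "straight_walk":
        pos[:, 2] = -(1.0 + np.minimum(t, 3.0))  # 1 m -> 4 m at 1 m/s
        yaw = np.full(n, 180.0)  # facing -z, directly away from the CS
    elif name == "loop":
        pos[:, 2] = -(1.0 + np.minimum(t, 3.0))
        # inward detour between 4 s and 6 s: 1 m toward the CS and back,
        # adding 2 m of path without changing the maximum distance
        seg = (t >= 4.0) & (t < 6.0)
        u = (t[seg] - 4.0) / 2.0  # 0..1 over the detour
        pos[seg, 2] = -(3.0 + np.abs(2.0 * u - 1.0))
        yaw = np.full(n, 180.0)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return TrackerTrace(tracker_id="head", times=t, positions=pos, yaw=yaw,
                        nominal_rate=_RATE)


def expected_summaries() -> dict[str, dict]:
    """Closed-form summary values over the (0, 8) window, frozen by hand.

    straight_walk mean distance: 720 samples at 90 Hz; the first 270 ramp
    1 + k/90 and the remaining 450 sit at 4 m, so the mean is
    (270 + 269*270/(2*90) + 450*4) / 720 = 2473.5 / 720.
    """
    return {
        "stationary": dict(mean_dist=2.0, max_dist=2.0, min_dist=2.0,
                           path_length=0.0, max_speed=0.0,
                           mean_head_angle=0.0, reaction_time=None),
        "straight_walk": dict(mean_dist=2473.5 / 720.0, max_dist=4.0,
                              min_dist=1.0, path_length=3.0, max_speed=1.0,
                              mean_head_angle=180.0, reaction_time=0.7),
    }
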