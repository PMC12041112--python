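"""Independent brute-force per-sample kinematics oracle.

Deliberately written with plain Python loops and no shared code with
``cogavoid.kinematics``: every quantity is recomputed sample by sample from
first principles so the package implementation can be checked against it.
"""

import math


def brute_force_summary(times, positions, yaw, cs_position, t0, t1,
                        rt_threshold=0.7):
    idx = [k for k in range(len(times)) if t0 <= times[k] < t1]
    assert len(idx) >= 2

    dists = []
    for k in idx:
        dx = positions[k][0] - cs_position[0]
        dz = positions[k][2] - cs_position[2]
        dists.append(math.sqrt(dx * dx + dz * dz))

    path = 0.0
    max_speed = 0.0
    for a, b in zip(idx[:-1], idx[1:]):
        dx = positions[b][0] - positions[a][0]
        dz = positions[b][2] - positions[a][2]
        seg = math.sqrt(dx * dx + dz * dz)
        path += seg
        sp = seg / (times[b] - times[a])
        if sp > max_speed:
            max_speed = sp

    angles = None
    if yaw is not None:
        angles = []
        for k in idx:
            bx = cs_position[0] - positions[k][0]
            bz = cs_position[2] - positions[k][2]
            bearing = math.degrees(math.atan2(bx, bz))
            diff = abs((yaw[k] - bearing) % 360.0)
            if diff > 180.0:
                diff = 360.0 - diff
            angles.append(diff)

    ox, oz = positions[idx[0]][0], positions[idx[0]][2]
    rt = None
    for k in idx:
        dx = positions[k][0] - ox
        dz = positions[k][2] - oz
        if math.sqrt(dx * dx + dz * dz) >= rt_threshold:
            rt = times[k]
            break

    return {
        "mean_dist": sum(dists) / len(dists),
        "max_dist": max(dists),
        "min_dist": min(dists),
        "path_length": path,
        "max_speed": max_speed,
        "mean_head_angle": None if angles is None else sum(angles) / len(angles),
        "reaction_time": rt,
    }
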