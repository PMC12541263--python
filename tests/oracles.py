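"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive (plain Python loops, scipy.spatial for the
hull) and share no code with the package's feature paths.
"""

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError

DEVICE_ORDER = ("head", "left_hand", "right_hand")


def _dist(a, b):
    return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))


def steps(track):
    return [_dist(track[k], track[k + 1]) for k in range(len(track) - 1)]


def average_speed(tracks, dt):
    per_device = []
    for dev in DEVICE_ORDER:
        ds = steps(tracks[dev])
        per_device.append(sum(d / dt for d in ds) / len(ds))
    return sum(per_device) / 3.0


def acceleration(tracks, dt):
    per_device = []
    for dev in DEVICE_ORDER:
        v = [d / dt for d in steps(tracks[dev])]
        changes = [abs(v[i + 1] - v[i]) / dt for i in range(len(v) - 1)]
        per_device.append(sum(changes) / len(changes))
    return sum(per_device) / 3.0


def total_distance(tracks, dt):
    return sum(sum(steps(tracks[dev])) for dev in DEVICE_ORDER)


def area_occupied(tracks, dt):
    pts = np.unique(np.asarray(tracks["head"])[:, [0, 2]], axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D "volume" is the area
    except QhullError:
        return 0.0


def hand_head_distance(tracks, dt):
    head = tracks["head"]
    total = 0.0
    for k in range(len(head)):
        d_l = _dist(tracks["left_hand"][k], head[k])
        d_r = _dist(tracks["right_hand"][k], head[k])
        total += (d_l + d_r) / 2.0
    return total / len(head)


def _max_steps(tracks):
    per_device = [steps(tracks[dev]) for dev in DEVICE_ORDER]
    return [max(col) for col in zip(*per_device)]


def movement_frequency(tracks, dt, threshold_1=0.05):
    moving = [d > threshold_1 for d in _max_steps(tracks)]
    events = 0
    prev = False
    for m in moving:
        if m and not prev:
            events += 1
        prev = m
    minutes = len(moving) * dt / 60.0
    return events / minutes


def time_spent_still(tracks, dt, threshold_2=0.02):
    return dt * sum(1 for d in _max_steps(tracks) if d <= threshold_2)


ALL = {
    "average_speed": average_speed,
    "acceleration": acceleration,
    "total_distance": total_distance,
    "area_occupied": area_occupied,
    "hand_head_distance": hand_head_distance,
    "movement_frequency": movement_frequency,
    "time_spent_still": time_spent_still,
}


def pearson_r(x, y):
    """Direct covariance/SD computation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    return cov / (sx * sy)


def ols_normal_equations(X, y):
    """(intercept, betas) from the normal equations."""
    X = np.asarray(X, float)
    A = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))
    return beta[0], beta[1:]
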