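"""Per-frame kinematics and locomotor endpoints.

A calibrated single-fish trajectory is reduced to a step series (speed,
heading, absolute turn angle, movement state) and then to the endpoint set
reported for every assay: average speed, total distance, the three movement
time ratios (freezing / swimming / rapid), average angular velocity and
meandering.

Movement states are assigned by speed thresholds. The field convention for
small fish is a near-zero cut-off for freezing and a burst cut-off for rapid
swimming; the defaults (1 and 10 cm/s) are configurable per species and every
endpoint report should record the thresholds used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FREEZING, SWIMMING, RAPID, INVALID = "freezing", "swimming", "rapid", "invalid"

#: steps shorter than this (cm) carry no usable heading: positional jitter at
#: rest otherwise produces spurious 180-degree turns that dominate meandering
JITTER_FLOOR_CM = 0.05


@dataclass(frozen=True)
class MovementThresholds:
    """Speed cut-offs (cm/s) separating freezing / swimming / rapid."""

    freeze_max_cm_s: float = 1.0
    rapid_min_cm_s: float = 10.0

    def __post_init__(self):
        if not (0 < self.freeze_max_cm_s < self.rapid_min_cm_s):
            raise ValueError("need 0 < freeze_max < rapid_min")


@dataclass
class KinematicSeries:
    """Step-wise kinematics: one entry per frame interval (length frames-1)."""

    speed_cm_s: np.ndarray
    heading_deg: np.ndarray      # NaN where the step is invalid or sub-jitter
    turn_deg: np.ndarray         # absolute turn in [0, 180]; NaN if undefined
    step_cm: np.ndarray
    state: np.ndarray            # object array of state labels
    fps: float
    empty: bool = False

    @property
    def valid(self) -> np.ndarray:
        return self.state != INVALID

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def kinematic_series(traj: pd.DataFrame,
                     thresholds: MovementThresholds = MovementThresholds(),
                     fps: float | None = None) -> KinematicSeries:
    """Differentiate a calibrated single-fish trajectory.

    Step i joins frame i to frame i+1: ``speed_i = ||p_{i+1} - p_i|| * fps``.
    Heading is the direction of the step vector; the turn at step i is the
    absolute angular difference to the previous usable heading, wrapped to
    [0, 180] degrees. A step is invalid when either of its endpoint frames is
    invalid. Fewer than two valid frames yields an empty, flagged series.
    """
    traj = traj.sort_values("frame")
    if fps is None:
        t = traj["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        fps = 1.0 / np.median(dt) if len(dt) else 30.0
    x = traj["x_cm"].to_numpy(dtype=float)
    y = traj["y_cm"].to_numpy(dtype=float)
    ok = traj["valid"].to_numpy(dtype=bool)
    n = len(x)
    if ok.sum() < 2 or n < 2:
        z = np.zeros(0)
        return KinematicSeries(z, z, z, z, np.array([], dtype=object), fps, empty=True)

    dx, dy = np.diff(x), np.diff(y)
    step = np.hypot(dx, dy)
    step_ok = ok[:-1] & ok[1:]
    speed = np.where(step_ok, step * fps, np.nan)

    heading = np.degrees(np.arctan2(dy, dx))
    heading[~step_ok | (step < JITTER_FLOOR_CM)] = np.nan

    # turn at step i: difference to the most recent preceding usable heading,
    # but only across contiguous valid data (an invalid step breaks the chain)
    turn = np.full(n - 1, np.nan)
    last_heading = np.nan
    for i in range(n - 1):
        if not step_ok[i]:
            last_heading = np.nan
            continue
        h = heading[i]
        if np.isnan(h):
            continue
        if not np.isnan(last_heading):
            d = abs((h - last_heading + 180.0) % 360.0 - 180.0)
            turn[i] = d
        last_heading = h

    state = np.empty(n - 1, dtype=object)
    state[:] = INVALID
    sw = step_ok.copy()
    state[sw & (speed <= thresholds.freeze_max_cm_s)] = FREEZING
    state[sw & (speed > thresholds.freeze_max_cm_s)
          & (speed < thresholds.rapid_min_cm_s)] = SWIMMING
    state[sw & (speed >= thresholds.rapid_min_cm_s)] = RAPID

    return KinematicSeries(speed, heading, turn, np.where(step_ok, step, np.nan),
                           state, fps)


def locomotor_endpoints(series: KinematicSeries) -> dict:
    """Average speed, total distance, and the three movement time ratios.

    average_speed = total valid distance / total valid time; each ratio is the
    share of valid steps in that state, so the three ratios sum to one.
    """
    out = {"average_speed_cm_s": np.nan, "total_distance_cm": np.nan,
           "freezing_ratio": np.nan, "swimming_ratio": np.nan,
           "rapid_ratio": np.nan}
    if series.empty or series.n_valid == 0:
        return out
    v = series.valid
    dist = float(np.nansum(series.step_cm[v]))
    t = series.n_valid / series.fps
    out["average_speed_cm_s"] = dist / t
    out["total_distance_cm"] = dist
    nv = series.n_valid
    out["freezing_ratio"] = float((series.state == FREEZING).sum()) / nv
    out["swimming_ratio"] = float((series.state == SWIMMING).sum()) / nv
    out["rapid_ratio"] = float((series.state == RAPID).sum()) / nv
    return out


def angular_endpoints(series: KinematicSeries) -> dict:
    """Average angular velocity (deg/s) and meandering (deg/cm).

    Both are computed over steps with a defined turn, i.e. consecutive usable
    headings; steps below the jitter floor are excluded so stationary noise
    cannot masquerade as turning. Meandering is total absolute turning per
    unit distance along the same steps; if no step carries a turn the
    endpoints are undefined (NaN) and ``defined`` is False.
    """
    out = {"angular_velocity_deg_s": np.nan, "meandering_deg_cm": np.nan,
           "defined": False}
    if series.empty:
        return out
    has_turn = ~np.isnan(series.turn_deg)
    if not has_turn.any():
        return out
    out["angular_velocity_deg_s"] = float(series.turn_deg[has_turn].mean()) * series.fps
    # denominator: every usable step (valid, above jitter floor), including
    # the chain-starting step whose own turn is undefined
    usable = series.valid & ~np.isnan(series.heading_deg)
    total_turn = float(np.nansum(series.turn_deg[usable]))
    total_len = float(series.step_cm[usable].sum())
    if total_len > 0:
        out["meandering_deg_cm"] = total_turn / total_len
        out["defined"] = True
    return out
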