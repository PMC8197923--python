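"""Zone-based endpoints for the tank assays.

Covers the four single-fish arena tests:

* novel tank — vertical exploration (time in top, entries, latency, distance
  in top) plus thigmotaxis proxied by mean distance to the water-area
  centroid, on a schedule of 1-min bins recorded every 5 min for 31 min;
* mirror biting — time in a thin contact strip against the mirror wall;
* predator avoidance — occupancy near the transparent predator separator and
  mean distance to it;
* conspecific social interaction — same geometry against the conspecific
  separator.

Zone membership is evaluated per frame; entry counting uses a two-frame
hysteresis so single-frame boundary chatter does not inflate entry counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinematics as kin
from ._geometry import (
    point_segment_distance,
    points_in_convex_polygon,
    polygon_centroid,
)
from .trajio import ArenaSpec, ConfigError, single_fish

#: a crossing counts only after this many consecutive frames on the new side
ENTRY_HYSTERESIS_FRAMES = 2


@dataclass(frozen=True)
class ZoneSpec:
    """A named region of the arena.

    kind 'region' is a convex polygon; kind 'wall-strip' additionally carries
    the wall segment it hugs (for perpendicular-distance endpoints); kind
    'point' is a reference point (distance-to-point endpoints).
    """

    name: str
    polygon_cm: tuple = ()
    kind: str = "region"
    wall_segment: tuple = ()   # ((x0,y0),(x1,y1)) for wall-strips
    point_cm: tuple = ()       # (x, y) for kind 'point'

    @property
    def polygon(self) -> np.ndarray:
        return np.asarray(self.polygon_cm, dtype=float)


@dataclass(frozen=True)
class SessionSchedule:
    """Recording bins (start, end) in seconds from session start."""

    assay: str
    bins_s: tuple

    def __post_init__(self):
        prev_end = -np.inf
        for a, b in self.bins_s:
            if b <= a or a < prev_end:
                raise ConfigError("schedule bins must be ordered and non-overlapping")
            prev_end = b


def novel_tank_schedule() -> SessionSchedule:
    """One-minute bins at 0, 5, 10, 15, 20, 25 and 30 min."""
    return SessionSchedule("novel_tank",
                           tuple((300.0 * k, 300.0 * k + 60.0) for k in range(7)))


def single_bin_schedule(assay: str, duration_s: float = 300.0) -> SessionSchedule:
    """One 5-min recording bin, used by the mirror/predator/social assays."""
    return SessionSchedule(assay, ((0.0, duration_s),))


def top_zone(arena: ArenaSpec, fraction: float = 0.5) -> ZoneSpec:
    """Upper ``fraction`` of the water column, clipped to the arena polygon."""
    poly = arena.polygon
    y_cut = arena.water_level_cm * (1.0 - fraction)
    clipped = _clip_polygon_above(poly, y_cut)
    return ZoneSpec("top", tuple(map(tuple, clipped)), kind="region")


def _clip_polygon_above(poly: np.ndarray, y_cut: float) -> np.ndarray:
    """Sutherland–Hodgman clip of a convex polygon to the half-plane y >= y_cut."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        a_in, b_in = a[1] >= y_cut, b[1] >= y_cut
        if a_in:
            out.append(a)
        if a_in != b_in:
            t = (y_cut - a[1]) / (b[1] - a[1])
            out.append(a + t * (b - a))
    return np.array(out)


def wall_strip_zone(name: str, wall_segment, width_cm: float,
                    inward) -> ZoneSpec:
    """Rectangular contact strip of ``width_cm`` hugging a wall segment.

    ``inward`` is the unit-ish direction from the wall into the arena.
    """
    (x0, y0), (x1, y1) = wall_segment
    a = np.array([x0, y0], dtype=float)
    b = np.array([x1, y1], dtype=float)
    d = np.asarray(inward, dtype=float)
    d = d / np.linalg.norm(d) * width_cm
    poly = (tuple(a), tuple(b), tuple(b + d), tuple(a + d))
    return ZoneSpec(name, poly, kind="wall-strip",
                    wall_segment=((x0, y0), (x1, y1)))


def in_zone_mask(traj: pd.DataFrame, zone: ZoneSpec) -> np.ndarray:
    pts = traj[["x_cm", "y_cm"]].to_numpy(dtype=float)
    return points_in_convex_polygon(pts, zone.polygon)


def zone_occupancy(traj: pd.DataFrame, zone: ZoneSpec, fps: float) -> dict:
    """Occupancy summary for one fish against one zone.

    Returns time_fraction (of valid frames), entries (outside-to-inside
    transitions with hysteresis; starting inside counts as the first entry at
    t = 0), latency_s (censored at session end if the zone is never entered,
    with ``latency_censored`` True), distance_in_zone_cm (steps fully inside)
    and longest_bout_s.
    """
    traj = traj.sort_values("frame")
    valid = traj["valid"].to_numpy(dtype=bool)
    inside_raw = in_zone_mask(traj, zone)
    n = len(traj)
    session_s = n / fps
    out = {"time_fraction": np.nan, "entries": 0, "latency_s": session_s,
           "latency_censored": True, "distance_in_zone_cm": 0.0,
           "longest_bout_s": 0.0}
    if valid.sum() == 0:
        return out

    inside = inside_raw & valid
    out["time_fraction"] = float(inside.sum()) / float(valid.sum())

    # hysteresis state machine over valid frames: a side change is accepted
    # only after ENTRY_HYSTERESIS_FRAMES consecutive frames on the new side;
    # an invalid frame breaks a pending streak
    times = traj["time_s"].to_numpy(dtype=float)
    t0 = times[np.argmax(valid)]
    entries = 0
    latency = None
    cur = None            # debounced side: True inside / False outside
    pend = 0              # consecutive frames on the side opposite to cur
    pend_t = 0.0
    for i in range(n):
        if not valid[i]:
            pend = 0
            continue
        side = bool(inside[i])
        if cur is None:
            cur = side
            if side:
                entries += 1
                latency = times[i] - t0
            continue
        if side == cur:
            pend = 0
            continue
        if pend == 0:
            pend_t = times[i]
        pend += 1
        if pend >= ENTRY_HYSTERESIS_FRAMES:
            cur = side
            pend = 0
            if side:
                entries += 1
                if latency is None:
                    latency = pend_t - t0
    out["entries"] = entries
    if latency is not None:
        out["latency_s"] = float(latency)
        out["latency_censored"] = False

    x = traj["x_cm"].to_numpy(dtype=float)
    y = traj["y_cm"].to_numpy(dtype=float)
    step = np.hypot(np.diff(x), np.diff(y))
    step_in = inside[:-1] & inside[1:]
    out["distance_in_zone_cm"] = float(step[step_in].sum())

    best = run = 0
    for i in range(n):
        if inside[i]:
            run += 1
            best = max(best, run)
        else:
            run = 0
    out["longest_bout_s"] = best / fps
    return out


def mean_distance_to_point(traj: pd.DataFrame, point) -> float:
    """Mean distance of valid frames to a reference point (cm)."""
    pts = traj.loc[traj["valid"], ["x_cm", "y_cm"]].to_numpy(dtype=float)
    if not len(pts):
        return np.nan
    return float(np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1).mean())


def novel_tank_endpoints(traj: pd.DataFrame, arena: ArenaSpec,
                         thresholds: kin.MovementThresholds = kin.MovementThresholds(),
                         schedule: SessionSchedule | None = None,
                         top_fraction: float = 0.5) -> pd.DataFrame:
    """Per-bin endpoint matrix for the novel tank test.

    Each 1-min bin yields the four locomotor endpoints plus time-in-top
    fraction, entries to top, latency to top (bin-wise, censored at bin end),
    distance travelled in the top and mean distance to the water centroid.
    Bins without valid frames are flagged via ``bin_missing``.
    """
    if schedule is None:
        schedule = novel_tank_schedule()
    zone = top_zone(arena, fraction=top_fraction)
    centroid = polygon_centroid(arena.polygon)
    fps = arena.fps
    fish = single_fish(traj, int(traj["fish_id"].iloc[0]))
    rows = []
    for b, (t0, t1) in enumerate(schedule.bins_s):
        t = fish["time_s"].to_numpy(dtype=float)
        sub = fish[(t >= t0 - 1e-9) & (t < t1 - 1e-9)]
        row = {"bin": b, "bin_start_s": t0, "bin_missing": sub["valid"].sum() == 0}
        series = kin.kinematic_series(sub, thresholds, fps=fps) if len(sub) else None
        loco = (kin.locomotor_endpoints(series) if series is not None
                else {k: np.nan for k in ("average_speed_cm_s", "total_distance_cm",
                                          "freezing_ratio", "swimming_ratio",
                                          "rapid_ratio")})
        row.update(loco)
        if len(sub):
            occ = zone_occupancy(sub, zone, fps)
            row.update({
                "time_in_top_fraction": occ["time_fraction"],
                "entries_to_top": occ["entries"],
                "latency_to_top_s": occ["latency_s"],
                "latency_censored": occ["latency_censored"],
                "distance_in_top_cm": occ["distance_in_zone_cm"],
                "mean_distance_to_center_cm": mean_distance_to_point(sub, centroid),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def side_preference_endpoints(traj: pd.DataFrame, wall_zone: ZoneSpec,
                              side_zone: ZoneSpec, fps: float) -> dict:
    """Contact-strip endpoints for the mirror / predator / social assays.

    contact_time_pct — % of valid time in the contact strip (mirror-biting,
    approaching-predator or conspecific-interaction time); side_time_pct — %
    in the near half of the tank; longest_side_bout_pct — longest continuous
    bout in the contact strip as % of session length; mean_distance_to_wall_cm
    — mean perpendicular distance of valid frames to the wall segment.
    """
    if wall_zone.kind != "wall-strip" or not wall_zone.wall_segment:
        raise ConfigError("wall_zone must be a wall-strip with a wall segment")
    a, b = (np.asarray(p, dtype=float) for p in wall_zone.wall_segment)
    if np.allclose(a, b):
        raise ConfigError("degenerate wall segment")
    traj = traj.sort_values("frame")
    valid = traj["valid"].to_numpy(dtype=bool)
    n_valid = int(valid.sum())
    session_s = len(traj) / fps
    if n_valid == 0:
        return {"contact_time_pct": np.nan, "side_time_pct": np.nan,
                "longest_side_bout_pct": np.nan, "mean_distance_to_wall_cm": np.nan}
    occ_contact = zone_occupancy(traj, wall_zone, fps)
    occ_side = zone_occupancy(traj, side_zone, fps)
    pts = traj.loc[valid, ["x_cm", "y_cm"]].to_numpy(dtype=float)
    dist = point_segment_distance(pts, a, b)
    return {
        "contact_time_pct": 100.0 * occ_contact["time_fraction"],
        "side_time_pct": 100.0 * occ_side["time_fraction"],
        "longest_side_bout_pct": 100.0 * occ_contact["longest_bout_s"] / session_s,
        "mean_distance_to_wall_cm": float(dist.mean()),
    }
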