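"""24-h locomotor rhythm assembly.

Locomotion is recorded for one minute every hour over a full day in a
top-view arena; each hourly segment is reduced to the six kinematic
endpoints (average speed, average angular velocity, meandering, and the
freezing / swimming / rapid time ratios) and assigned to the day or night
phase of the light schedule. Phase summaries are plain means over the member
hours; segments that straddle a light transition are assigned by their start
hour (segments are one minute, transitions hourly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics as kin

CIRCADIAN_ENDPOINTS = [
    "average_speed_cm_s", "angular_velocity_deg_s", "meandering_deg_cm",
    "freezing_ratio", "swimming_ratio", "rapid_ratio",
]


@dataclass(frozen=True)
class LightSchedule:
    """Lights-on/off hours on the 24-h clock; the housing cycle is 14 h
    light / 10 h dark."""

    lights_on_hour: int = 8
    lights_off_hour: int = 22

    def is_day(self, hour: int) -> bool:
        h = hour % 24
        on, off = self.lights_on_hour % 24, self.lights_off_hour % 24
        if on <= off:
            return on <= h < off
        return h >= on or h < off

    def phase(self, hour: int) -> str:
        return "day" if self.is_day(hour) else "night"


def segment_endpoints(traj: pd.DataFrame,
                      thresholds: kin.MovementThresholds,
                      fps: float) -> dict:
    """Six kinematic endpoints for one 1-min segment."""
    series = kin.kinematic_series(traj, thresholds, fps=fps)
    out = kin.locomotor_endpoints(series)
    out.update(kin.angular_endpoints(series))
    return {k: out.get(k, np.nan) for k in CIRCADIAN_ENDPOINTS}


def circadian_profile(hourly_trajs: dict, schedule: LightSchedule,
                      thresholds: kin.MovementThresholds = kin.MovementThresholds(),
                      fps: float = 30.0):
    """Hour x endpoint matrix and day/night phase summary.

    ``hourly_trajs`` maps wall-clock hour (0-23) to a single-fish trajectory
    table. Missing hours are flagged and phase means are taken over the
    available member hours.
    """
    rows = []
    for hour in range(24):
        row = {"hour": hour, "phase": schedule.phase(hour),
               "missing": hour not in hourly_trajs}
        if hour in hourly_trajs:
            row.update(segment_endpoints(hourly_trajs[hour], thresholds, fps))
        else:
            row.update({k: np.nan for k in CIRCADIAN_ENDPOINTS})
        rows.append(row)
    hourly = pd.DataFrame(rows)
    summary = (hourly.groupby("phase")[CIRCADIAN_ENDPOINTS]
               .mean().reset_index())
    summary["n_hours"] = hourly.groupby("phase")["missing"].apply(
        lambda m: int((~m).sum())).values
    return hourly, summary
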