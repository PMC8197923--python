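"""Trajectory I/O, calibration and gap handling.

The pipeline consumes idTracker-style trajectory tables (one row per video
frame, per-fish column triplets ``X_i Y_i ProbId_i``, ``NaN`` for frames where
identity was lost) or a tidy native CSV. All downstream endpoint code works on
the long-format :class:`TrajectoryTable` produced here, in centimetres, with
the origin at the arena's bottom-left water corner and y increasing toward the
water surface.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._geometry import (
    clip_to_convex_polygon,
    points_in_convex_polygon,
    polygon_is_simple,
)

TRAJ_COLUMNS = ["frame", "time_s", "fish_id", "x_cm", "y_cm", "valid", "interpolated"]


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory file does not match the declared layout."""


class ConfigError(ValueError):
    """Raised for inconsistent arena / assay configuration."""


@dataclass(frozen=True)
class ArenaSpec:
    """Arena cross-section geometry and video calibration.

    Parameters
    ----------
    polygon_cm : sequence of (x, y)
        Vertices of the 2-D water cross-section in cm, bottom-left origin,
        y up. Must be simple (non-self-intersecting).
    water_level_cm : float
        Height of the water surface above the bottom.
    px_per_cm : float
        Pixel-to-centimetre calibration of the video.
    y_axis : {"video-down", "physical-up"}
        Whether raw pixel y grows downward (typical video) or upward.
    fps : float
        Camera frame rate; the tracker emits one row per frame.
    """

    polygon_cm: tuple = ()
    water_level_cm: float = 15.2
    px_per_cm: float = 1.0
    y_axis: str = "video-down"
    fps: float = 30.0

    def __post_init__(self):
        if self.px_per_cm <= 0:
            raise ConfigError("px_per_cm must be > 0")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.y_axis not in ("video-down", "physical-up"):
            raise ConfigError(f"unknown y_axis {self.y_axis!r}")
        poly = np.asarray(self.polygon_cm, dtype=float)
        if poly.size and not polygon_is_simple(poly):
            raise ConfigError("arena polygon is self-intersecting")

    @property
    def polygon(self) -> np.ndarray:
        return np.asarray(self.polygon_cm, dtype=float)

    @classmethod
    def from_file(cls, path) -> "ArenaSpec":
        """Load from YAML or JSON with the field names of this class."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        data["polygon_cm"] = tuple(tuple(v) for v in data["polygon_cm"])
        return cls(**data)


def behavior_tank_arena(px_per_cm: float = 1.0, fps: float = 30.0,
                        y_axis: str = "physical-up") -> ArenaSpec:
    """The trapezoid assay tank: 22 cm bottom, 28 cm top, 15.2 cm high."""
    return ArenaSpec(
        polygon_cm=((3.0, 0.0), (25.0, 0.0), (28.0, 15.2), (0.0, 15.2)),
        water_level_cm=15.2, px_per_cm=px_per_cm, y_axis=y_axis, fps=fps,
    )


def circadian_arena(px_per_cm: float = 1.0, fps: float = 30.0,
                    y_axis: str = "physical-up") -> ArenaSpec:
    """Top-view 30 x 30 cm square arena used for 24-h locomotor recording."""
    return ArenaSpec(
        polygon_cm=((0.0, 0.0), (30.0, 0.0), (30.0, 30.0), (0.0, 30.0)),
        water_level_cm=7.5, px_per_cm=px_per_cm, y_axis=y_axis, fps=fps,
    )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TRAJ_COLUMNS, [int, float, int, float, float, bool, bool])})


def read_idtracker(path, n_fish: int, fps: float = 30.0) -> pd.DataFrame:
    """Parse an idTracker ``trajectories.txt`` table into long format.

    The file holds one whitespace-separated row per frame with a triplet
    ``X_i Y_i ProbId_i`` per fish; a missing detection is written as ``NaN``.
    Output columns: frame, time_s, fish_id, x_cm (pixels at this stage),
    y_cm, valid, interpolated. ``valid`` is False wherever X or Y is missing.
    """
    raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                      skip_blank_lines=True, na_values=["NaN", "nan", "NA"],
                      float_precision="round_trip")
    if raw.shape[1] and isinstance(raw.iloc[0, 0], str):
        raw = raw.iloc[1:].reset_index(drop=True).astype(float)
    if raw.shape[1] % 3 != 0:
        raise TrajectoryFormatError(
            f"column count {raw.shape[1]} is not a multiple of 3 (X, Y, ProbId per fish)")
    if raw.shape[1] // 3 != n_fish:
        raise TrajectoryFormatError(
            f"file holds {raw.shape[1] // 3} fish, expected {n_fish}")
    frames = np.arange(len(raw))
    parts = []
    for i in range(n_fish):
        x = raw.iloc[:, 3 * i].to_numpy(dtype=float)
        y = raw.iloc[:, 3 * i + 1].to_numpy(dtype=float)
        valid = np.isfinite(x) & np.isfinite(y)
        parts.append(pd.DataFrame({
            "frame": frames, "time_s": frames / fps, "fish_id": i + 1,
            "x_cm": x, "y_cm": y, "valid": valid,
            "interpolated": np.zeros(len(raw), dtype=bool),
        }))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["fish_id", "frame"], ignore_index=True)


def read_native(path) -> pd.DataFrame:
    """Read the package's tidy CSV dialect (columns as in TRAJ_COLUMNS)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "interpolated" not in df.columns:
        df["interpolated"] = False
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise TrajectoryFormatError(f"native CSV missing columns {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    df["interpolated"] = df["interpolated"].astype(bool)
    return df[TRAJ_COLUMNS].sort_values(["fish_id", "frame"], ignore_index=True)


def write_native(table: pd.DataFrame, path) -> None:
    table[TRAJ_COLUMNS].to_csv(path, index=False)


def write_idtracker(table: pd.DataFrame, path) -> None:
    """Write the idTracker triplet dialect (ProbId filled with 1.0)."""
    fish_ids = sorted(table["fish_id"].unique())
    frames = np.sort(table["frame"].unique())
    cols = []
    for fid in fish_ids:
        sub = table[table["fish_id"] == fid].set_index("frame").reindex(frames)
        x = sub["x_cm"].to_numpy(dtype=float).copy()
        y = sub["y_cm"].to_numpy(dtype=float).copy()
        bad = ~sub["valid"].fillna(False).to_numpy(dtype=bool)
        x[bad] = np.nan
        y[bad] = np.nan
        prob = np.where(bad, np.nan, 1.0)
        cols.extend([x, y, prob])
    mat = np.column_stack(cols)
    buf = io.StringIO()
    np.savetxt(buf, mat, fmt="%.17g")
    Path(path).write_text(buf.getvalue())


def calibrate(table: pd.DataFrame, arena: ArenaSpec) -> pd.DataFrame:
    """Convert a pixel-space table to arena centimetres.

    Divides by ``px_per_cm``; if the video y axis points down, flips y so that
    y_cm increases toward the water surface. Valid points that land outside
    the arena polygon (lens distortion, reflections) are clipped to the
    boundary; the count of clipped points is stored in
    ``table.attrs["n_clipped"]``.
    """
    if arena.px_per_cm <= 0:
        raise ConfigError("px_per_cm must be > 0")
    out = table.copy()
    out["x_cm"] = out["x_cm"] / arena.px_per_cm
    y = out["y_cm"] / arena.px_per_cm
    if arena.y_axis == "video-down":
        y = arena.water_level_cm - y
    out["y_cm"] = y
    n_clipped = 0
    if arena.polygon.size:
        pts = out.loc[out["valid"], ["x_cm", "y_cm"]].to_numpy(dtype=float)
        if len(pts):
            inside = points_in_convex_polygon(pts, arena.polygon, tol=1e-9)
            if not inside.all():
                clipped = clip_to_convex_polygon(pts[~inside], arena.polygon)
                pts[~inside] = clipped
                out.loc[out["valid"], ["x_cm", "y_cm"]] = pts
                n_clipped = int((~inside).sum())
    out.attrs["n_clipped"] = n_clipped
    return out


def fill_gaps(table: pd.DataFrame, max_gap_frames: int | None = None,
              fps: float = 30.0) -> pd.DataFrame:
    """Linearly interpolate short identity-loss gaps per fish.

    Runs of invalid frames no longer than ``max_gap_frames`` (default: one
    second, i.e. round(fps)) that are flanked by valid frames on both sides
    are filled on the straight segment between the flanking positions and
    marked ``interpolated``. Longer runs, and runs touching the session edge,
    stay invalid and are excluded from every endpoint denominator downstream.
    """
    if max_gap_frames is None:
        max_gap_frames = int(round(fps))
    out = table.sort_values(["fish_id", "frame"], ignore_index=True).copy()
    for fid, idx in out.groupby("fish_id").groups.items():
        idx = np.asarray(idx)
        valid = out.loc[idx, "valid"].to_numpy(dtype=bool)
        x = out.loc[idx, "x_cm"].to_numpy(dtype=float)
        y = out.loc[idx, "y_cm"].to_numpy(dtype=float)
        interp = out.loc[idx, "interpolated"].to_numpy(dtype=bool)
        n = len(idx)
        i = 0
        while i < n:
            if valid[i]:
                i += 1
                continue
            j = i
            while j < n and not valid[j]:
                j += 1
            run = j - i
            if i > 0 and j < n and run <= max_gap_frames:
                x0, y0, x1, y1 = x[i - 1], y[i - 1], x[j], y[j]
                for k in range(run):
                    t = (k + 1) / (run + 1)
                    x[i + k] = x0 + t * (x1 - x0)
                    y[i + k] = y0 + t * (y1 - y0)
                valid[i:j] = True
                interp[i:j] = True
            i = j
        out.loc[idx, "x_cm"] = x
        out.loc[idx, "y_cm"] = y
        out.loc[idx, "valid"] = valid
        out.loc[idx, "interpolated"] = interp
    return out


def smooth(table: pd.DataFrame, window: int) -> pd.DataFrame:
    """Optional centred moving-average smoother (off by default).

    Raw tracker jitter inflates path length; a small window (3-5 frames)
    damps it. Applied only across runs of valid frames; invalid frames break
    the window. Reported endpoints should record the window used.
    """
    if window <= 1:
        return table
    out = table.sort_values(["fish_id", "frame"], ignore_index=True).copy()
    for fid, idx in out.groupby("fish_id").groups.items():
        idx = np.asarray(idx)
        valid = out.loc[idx, "valid"].to_numpy(dtype=bool)
        for col in ("x_cm", "y_cm"):
            v = out.loc[idx, col].to_numpy(dtype=float)
            s = pd.Series(np.where(valid, v, np.nan))
            sm = s.rolling(window, center=True, min_periods=1).mean()
            v2 = np.where(valid, sm.to_numpy(), v)
            out.loc[idx, col] = v2
    return out


def single_fish(table: pd.DataFrame, fish_id: int = 1) -> pd.DataFrame:
    """Extract one fish's rows, frame-sorted."""
    sub = table[table["fish_id"] == fish_id]
    return sub.sort_values("frame", ignore_index=True)


def from_arrays(x: np.ndarray, y: np.ndarray, fps: float,
                valid: np.ndarray | None = None, fish_id: int = 1,
                frame_offset: int = 0) -> pd.DataFrame:
    """Build a single-fish TrajectoryTable from coordinate arrays (cm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    frames = np.arange(n) + frame_offset
    return pd.DataFrame({
        "frame": frames, "time_s": frames / fps,
        "fish_id": fish_id, "x_cm": x, "y_cm": y,
        "valid": np.asarray(valid, dtype=bool),
        "interpolated": np.zeros(n, dtype=bool),
    })
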