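"""Shoal-cohesion endpoints for simultaneously tracked fish.

Groups of three fish are the study design; the code accepts any n >= 2.
Endpoints are computed per frame only where *all* fish are valid, so the four
summaries share one denominator, and averaged over the session:

* average inter-fish distance — mean over all pairs;
* average shoal area — polygon area of the fish positions (triangle for
  three fish via the shoelace formula, convex hull for more);
* average nearest-neighbor distance — per fish, distance to its closest
  shoal-mate, averaged over fish;
* average farthest-neighbor distance — same with the most distant mate.

All four are symmetric in fish identity, so tracker identity swaps do not
affect them and no identity repair is attempted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from ._geometry import polygon_area


def _position_cube(multi_traj: pd.DataFrame):
    """(frames, n_fish, 2) position array plus all-valid frame mask."""
    fish_ids = sorted(multi_traj["fish_id"].unique())
    frames = np.sort(multi_traj["frame"].unique())
    pos = np.full((len(frames), len(fish_ids), 2), np.nan)
    ok = np.zeros((len(frames), len(fish_ids)), dtype=bool)
    frame_idx = {f: i for i, f in enumerate(frames)}
    for j, fid in enumerate(fish_ids):
        sub = multi_traj[multi_traj["fish_id"] == fid]
        rows = [frame_idx[f] for f in sub["frame"]]
        pos[rows, j, 0] = sub["x_cm"].to_numpy(dtype=float)
        pos[rows, j, 1] = sub["y_cm"].to_numpy(dtype=float)
        ok[rows, j] = sub["valid"].to_numpy(dtype=bool)
    return pos, ok.all(axis=1)


def _hull_area(points: np.ndarray) -> float:
    if len(points) == 3:
        return polygon_area(points)
    try:
        return float(ConvexHull(points).volume)   # "volume" is area in 2-D
    except QhullError:                            # collinear configuration
        return 0.0


def shoal_endpoints(multi_traj: pd.DataFrame) -> dict:
    """Session-average cohesion endpoints over all-valid frames.

    Returns NaNs with ``n_frames_used = 0`` when no frame has every fish
    valid (flagged empty result).
    """
    pos, all_ok = _position_cube(multi_traj)
    out = {"avg_interfish_cm": np.nan, "avg_area_cm2": np.nan,
           "avg_nearest_cm": np.nan, "avg_farthest_cm": np.nan,
           "n_frames_used": int(all_ok.sum())}
    if not all_ok.any():
        return out
    p = pos[all_ok]                                # (m, n_fish, 2)
    m, n_fish, _ = p.shape
    if n_fish < 2:
        raise ValueError("need at least 2 fish for shoaling endpoints")
    diff = p[:, :, None, :] - p[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)              # (m, n, n)
    iu = np.triu_indices(n_fish, k=1)
    out["avg_interfish_cm"] = float(d[:, iu[0], iu[1]].mean())
    d_self = d.copy()
    ar = np.arange(n_fish)
    d_self[:, ar, ar] = np.inf
    out["avg_nearest_cm"] = float(d_self.min(axis=2).mean())
    out["avg_farthest_cm"] = float(d.max(axis=2).mean())
    if n_fish == 2:
        out["avg_area_cm2"] = 0.0
    else:
        areas = np.array([_hull_area(p[i]) for i in range(m)])
        out["avg_area_cm2"] = float(areas.mean())
    return out
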