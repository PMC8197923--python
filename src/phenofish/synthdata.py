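"""Synthetic study generator.

Every pipeline stage is exercised against data with known ground truth.
Species differences are parameterized as :class:`SpeciesArchetype` and
trajectories are produced by a stochastic walker:

* a two-state freeze/move Markov chain (rates per second, discretized at the
  frame rate) gates locomotion; frozen frames have zero displacement, so the
  long-run freezing time ratio equals the chain's stationary probability
  freeze_rate / (freeze_rate + unfreeze_rate);
* while moving, the per-frame step length is a zero-clipped normal around
  mean_speed / fps, with occasional rapid bursts at burst_speed;
* heading is persistent with wrapped-normal turning noise (concentration
  kappa_turn) plus drift terms: a slow two-mode vertical preference whose
  stationary top-seeking probability is top_pref (so long-run top-half
  occupancy tracks top_pref, transit times cancelling to first order),
  attraction to a stimulus wall (mirror / predator / conspecific separator),
  attraction to the shoal centroid, and optional wall attraction;
* the arena boundary reflects.

Sequences are evolved along a known tree under Jukes-Cantor so the gene-tree
stage has a recoverable truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import trajio
from ._geometry import (
    _edge_normals,
    clip_to_convex_polygon,
    point_segment_distance,
    points_in_convex_polygon,
)
from .phylo import read_newick
from .trajio import ArenaSpec, behavior_tank_arena, circadian_arena, from_arrays

# walker drift weights (relative to the unit persistence vector)
W_TRANSIT = 3.0        # vertical pull while in the wrong half for the mode
W_SETTLE = 0.3         # gentle centering within the preferred half
MODE_SWITCH_RATE = 0.1  # total per-second scale of top/bottom mode switching
WALL_MARGIN_CM = 0.5   # inward repulsion kicks in this close to the boundary
W_WALL_REPEL = 0.8


@dataclass(frozen=True)
class SpeciesArchetype:
    """Behavioral parameter set for one species/group.

    Rates are per second; speeds in cm/s; attractions are drift weights on
    the heading update (0 disables a term); kappa_turn is the wrapped-normal
    turning concentration (higher = straighter paths).
    """

    name: str = "generic"
    freeze_rate: float = 0.05          # move -> freeze
    unfreeze_rate: float = 0.45        # freeze -> move
    mean_speed_cm_s: float = 4.0
    speed_sd_cm_s: float = 1.0
    burst_prob: float = 0.02           # per moving frame
    burst_speed_cm_s: float = 14.0
    top_pref: float = 0.5              # stationary top-seeking probability
    wall_attraction: float = 0.0
    stim_attraction: float = 0.0
    shoal_attraction: float = 0.0
    day_multiplier: float = 1.0
    night_multiplier: float = 1.0
    turn_concentration: float = 4.0

    def __post_init__(self):
        if min(self.freeze_rate, self.unfreeze_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.top_pref <= 1.0:
            raise ValueError("top_pref must lie in [0, 1]")
        if self.mean_speed_cm_s <= 0 or self.speed_sd_cm_s < 0:
            raise ValueError("speeds must be positive")


#: named archetypes emulating the qualitative species contrasts of the study:
#: zebrafish most active; O. woworae the most active and most social medaka;
#: O. sinensis slow, surface-oriented and mirror-aggressive; O. dancena
#: active with weak predator avoidance; O. latipes calm and less social.
ARCHETYPES = {
    "D_rerio": SpeciesArchetype(
        name="D_rerio", freeze_rate=0.02, unfreeze_rate=0.6,
        mean_speed_cm_s=7.0, speed_sd_cm_s=1.8, burst_prob=0.05,
        burst_speed_cm_s=16.0, top_pref=0.25, stim_attraction=0.5,
        shoal_attraction=0.8, day_multiplier=1.2, night_multiplier=0.5,
        turn_concentration=5.0),
    "O_dancena": SpeciesArchetype(
        name="O_dancena", freeze_rate=0.05, unfreeze_rate=0.5,
        mean_speed_cm_s=5.0, speed_sd_cm_s=1.4, burst_prob=0.04,
        burst_speed_cm_s=13.0, top_pref=0.55, stim_attraction=0.9,
        shoal_attraction=1.0, day_multiplier=1.15, night_multiplier=0.6,
        turn_concentration=4.0),
    "O_latipes": SpeciesArchetype(
        name="O_latipes", freeze_rate=0.08, unfreeze_rate=0.4,
        mean_speed_cm_s=3.5, speed_sd_cm_s=1.0, burst_prob=0.015,
        burst_speed_cm_s=12.0, top_pref=0.5, stim_attraction=0.3,
        shoal_attraction=1.0, day_multiplier=1.1, night_multiplier=0.7,
        turn_concentration=3.5),
    "O_woworae": SpeciesArchetype(
        name="O_woworae", freeze_rate=0.03, unfreeze_rate=0.7,
        mean_speed_cm_s=6.0, speed_sd_cm_s=1.6, burst_prob=0.05,
        burst_speed_cm_s=14.0, top_pref=0.45, stim_attraction=1.1,
        shoal_attraction=0.5, day_multiplier=1.2, night_multiplier=0.55,
        turn_concentration=4.5),
    "O_sinensis": SpeciesArchetype(
        name="O_sinensis", freeze_rate=0.12, unfreeze_rate=0.3,
        mean_speed_cm_s=3.0, speed_sd_cm_s=0.9, burst_prob=0.01,
        burst_speed_cm_s=11.0, top_pref=0.7, stim_attraction=1.2,
        shoal_attraction=0.5, day_multiplier=1.05, night_multiplier=0.8,
        turn_concentration=3.0),
}

ASSAYS = ("novel_tank", "mirror", "predator", "social", "shoaling", "circadian")


@dataclass
class SimulationConfig:
    """Study-level simulation settings; the seed fixes every draw."""

    seed: int = 0
    fps: float = 30.0
    n_per_group: dict = field(default_factory=lambda: {
        "D_rerio": 30, "O_dancena": 30, "O_latipes": 30,
        "O_woworae": 30, "O_sinensis": 22})
    archetypes: dict = field(default_factory=lambda: dict(ARCHETYPES))
    assays: tuple = ASSAYS
    novel_bin_s: float = 60.0
    novel_n_bins: int = 7
    assay_duration_s: float = 300.0
    circadian_segment_s: float = 60.0
    n_shoals_per_group: int = 10
    seq_length: int = 1000
    #: mirrors the published nd2 relationships: zebrafish as the distant
    #: outgroup; within medaka a latipes species group (latipes + sinensis)
    #: and the separate javanicus (dancena) / celebensis (woworae) groups
    tree_newick: str = ("(((O_latipes:0.02,O_sinensis:0.02):0.08,"
                        "(O_woworae:0.09,O_dancena:0.11):0.02):0.3,"
                        "D_rerio:0.35);")

    def to_json(self) -> str:
        d = asdict(self)
        d["archetypes"] = {k: asdict(v) for k, v in self.archetypes.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["archetypes"] = {k: SpeciesArchetype(**v)
                           for k, v in d["archetypes"].items()}
        d["assays"] = tuple(d["assays"])
        return cls(**d)


#: two well-separated behavioral archetypes for planted-truth recovery
#: studies: "bold" (fast, surface-oriented, stimulus-seeking, loose shoal)
#: vs "timid" (slow, freeze-prone, bottom-hugging, tight shoal)
BOLD = SpeciesArchetype(
    name="bold", freeze_rate=0.02, unfreeze_rate=0.7, mean_speed_cm_s=6.5,
    speed_sd_cm_s=1.5, burst_prob=0.05, burst_speed_cm_s=15.0, top_pref=0.75,
    stim_attraction=1.0, shoal_attraction=0.3, day_multiplier=1.2,
    night_multiplier=0.5, turn_concentration=5.0)
TIMID = SpeciesArchetype(
    name="timid", freeze_rate=0.25, unfreeze_rate=0.35, mean_speed_cm_s=2.5,
    speed_sd_cm_s=0.8, burst_prob=0.005, burst_speed_cm_s=11.0, top_pref=0.2,
    stim_attraction=0.1, shoal_attraction=1.2, day_multiplier=1.05,
    night_multiplier=0.8, turn_concentration=2.5)

#: planted 5-group design: G1-G3 bold, G4-G5 timid
PLANTED_LABELS = {"G1": "bold", "G2": "bold", "G3": "bold",
                  "G4": "timid", "G5": "timid"}
#: gene tree matching the planted phenotype grouping ...
PLANTED_MATCHED_TREE = ("(((G1:0.01,G2:0.01):0.005,G3:0.012):0.15,"
                        "(G4:0.01,G5:0.01):0.15);")
#: ... and one conflicting with it (G1 grouped with the timid pair)
PLANTED_CONFLICT_TREE = ("(((G4:0.01,G1:0.01):0.005,G5:0.012):0.15,"
                         "(G2:0.01,G3:0.01):0.15);")


def planted_study_config(seed: int = 0, n_per_group: int = 30,
                         matched: bool = True, fps: float = 10.0,
                         session_s: float = 30.0,
                         assays: tuple = ("novel_tank", "mirror", "shoaling"),
                         ) -> SimulationConfig:
    """Study with two planted behavioral archetypes over five groups.

    Session lengths are short (the archetype separation, not duration,
    drives recovery); the sequence tree either matches the planted grouping
    or conflicts with it.
    """
    archs = {g: dataclasses.replace(BOLD if a == "bold" else TIMID, name=g)
             for g, a in PLANTED_LABELS.items()}
    return SimulationConfig(
        seed=seed, fps=fps,
        n_per_group={g: n_per_group for g in archs},
        archetypes=archs, assays=assays,
        novel_bin_s=session_s, novel_n_bins=1,
        assay_duration_s=session_s,
        n_shoals_per_group=max(3, n_per_group // 3),
        tree_newick=PLANTED_MATCHED_TREE if matched else PLANTED_CONFLICT_TREE)


# ------------------------------------------------------------------ dynamics

def _simulate_paths(arch: SpeciesArchetype, arena: ArenaSpec, n_frames: int,
                    fps: float, rng: np.random.Generator, n_paths: int = 1,
                    vertical_pref: bool = False, stim_segment=None,
                    shoal_groups: int | None = None,
                    speed_multiplier: float = 1.0,
                    start_frozen: bool | None = None):
    """Vectorized walker core.

    Returns (positions (n_frames, n_paths, 2), frozen (n_frames-1, n_paths)).
    ``shoal_groups``: if set, paths are consecutive blocks of
    n_paths/shoal_groups fish attracted to their block centroid.
    """
    poly = np.asarray(arena.polygon, dtype=float)
    normals, offsets = _edge_normals(poly)
    lo, hi = poly.min(axis=0), poly.max(axis=0)
    y_mid = arena.water_level_cm * 0.5

    pos = np.empty((n_frames, n_paths, 2))
    p = lo + rng.random((n_paths, 2)) * (hi - lo)
    p = clip_to_convex_polygon(p, poly)
    pos[0] = p
    heading = rng.random(n_paths) * 2.0 * np.pi

    p_mf = min(1.0, arch.freeze_rate / fps)
    p_fm = min(1.0, arch.unfreeze_rate / fps)
    pi_freeze = (arch.freeze_rate / (arch.freeze_rate + arch.unfreeze_rate)
                 if arch.freeze_rate + arch.unfreeze_rate > 0 else 0.0)
    if start_frozen is None:
        frozen_now = rng.random(n_paths) < pi_freeze
    else:
        frozen_now = np.full(n_paths, bool(start_frozen))

    # vertical preference mode chain (True = top-seeking)
    p_tb = min(1.0, MODE_SWITCH_RATE * (1.0 - arch.top_pref) / fps)
    p_bt = min(1.0, MODE_SWITCH_RATE * arch.top_pref / fps)
    mode_top = rng.random(n_paths) < arch.top_pref

    turn_sd = 1.0 / np.sqrt(max(arch.turn_concentration, 1e-6))
    mu_step = arch.mean_speed_cm_s * speed_multiplier / fps
    sd_step = arch.speed_sd_cm_s * speed_multiplier / fps
    burst_step = arch.burst_speed_cm_s * speed_multiplier / fps

    if stim_segment is not None:
        seg_a = np.asarray(stim_segment[0], dtype=float)
        seg_b = np.asarray(stim_segment[1], dtype=float)

    frozen = np.empty((n_frames - 1, n_paths), dtype=bool)

    for t in range(n_frames - 1):
        # state transitions for the step t -> t+1
        u = rng.random(n_paths)
        frozen_now = np.where(frozen_now, u >= p_fm, u < p_mf)
        frozen[t] = frozen_now

        # mode chain always advances (keeps draw counts state-independent)
        um = rng.random(n_paths)
        mode_top = np.where(mode_top, um >= p_tb, um < p_bt)

        drift = np.stack([np.cos(heading), np.sin(heading)], axis=1)
        if vertical_pref:
            target_high = mode_top
            y = p[:, 1]
            wrong = np.where(target_high, y < y_mid, y >= y_mid)
            vert = np.where(target_high, 1.0, -1.0)
            w = np.where(wrong, W_TRANSIT, W_SETTLE)
            # settle drift aims at the middle of the preferred half
            y_goal = np.where(target_high, 0.75, 0.25) * arena.water_level_cm
            settle_sign = np.sign(y_goal - y)
            vy = np.where(wrong, vert, settle_sign) * w
            drift[:, 1] += vy
        if stim_segment is not None and arch.stim_attraction > 0:
            ab = seg_b - seg_a
            tt = np.clip((p - seg_a) @ ab / float(ab @ ab), 0.0, 1.0)
            proj = seg_a + tt[:, None] * ab[None, :]
            v = proj - p
            norm = np.linalg.norm(v, axis=1, keepdims=True)
            v = np.divide(v, norm, out=np.zeros_like(v), where=norm > 1e-9)
            drift += arch.stim_attraction * v
        if arch.wall_attraction > 0:
            slack = p @ normals.T - offsets[None, :]
            nearest = np.argmin(slack, axis=1)
            drift -= arch.wall_attraction * normals[nearest]
        if shoal_groups:
            blk = p.reshape(shoal_groups, -1, 2)
            nfish = blk.shape[1]
            cent = (blk.sum(axis=1, keepdims=True) - blk) / max(nfish - 1, 1)
            v = (cent - blk).reshape(n_paths, 2)
            norm = np.linalg.norm(v, axis=1, keepdims=True)
            v = np.divide(v, norm, out=np.zeros_like(v), where=norm > 1e-9)
            drift += arch.shoal_attraction * v
        # inward repulsion near the boundary
        slack = p @ normals.T - offsets[None, :]
        close = slack < WALL_MARGIN_CM
        if close.any():
            push = (close.astype(float) @ normals) * W_WALL_REPEL
            drift += push

        ang = np.arctan2(drift[:, 1], drift[:, 0])
        noise = rng.normal(0.0, turn_sd, n_paths)
        new_heading = ang + noise
        heading = np.where(frozen_now, heading, new_heading)

        step = np.maximum(0.0, rng.normal(mu_step, sd_step, n_paths))
        burst = rng.random(n_paths) < arch.burst_prob
        step = np.where(burst,
                        np.maximum(0.0, rng.normal(burst_step, sd_step, n_paths)),
                        step)
        step = np.where(frozen_now, 0.0, step)

        prop = p + step[:, None] * np.stack([np.cos(heading),
                                             np.sin(heading)], axis=1)
        # reflect across violated edges, then clip any residue
        sl = prop @ normals.T - offsets[None, :]
        out = sl < 0
        if out.any():
            for e in range(len(normals)):
                viol = out[:, e]
                if viol.any():
                    prop[viol] -= 2.0 * sl[viol, e][:, None] * normals[e][None, :]
            inside = points_in_convex_polygon(prop, poly)
            if not inside.all():
                prop[~inside] = clip_to_convex_polygon(prop[~inside], poly)
        p = prop
        pos[t + 1] = p
    return pos, frozen


# ----------------------------------------------------------------- wrappers

def simulate_trajectory(archetype: SpeciesArchetype, arena: ArenaSpec,
                        duration_s: float, seed: int, fps: float | None = None,
                        assay: str = "novel_tank", stim_segment=None,
                        speed_multiplier: float = 1.0,
                        start_frozen: bool | None = None) -> pd.DataFrame:
    """One single-fish session as a calibrated TrajectoryTable.

    Vertical preference is active for side-view behavior-tank assays; a
    stimulus segment (mirror or separator wall) adds contact attraction.
    The same (archetype, arena, seed) always yields the identical table.
    """
    fps = fps or arena.fps
    n_frames = int(round(duration_s * fps)) + 1
    rng = np.random.default_rng(seed)
    vertical = assay in ("novel_tank", "mirror", "predator", "social")
    if stim_segment is None and assay in ("mirror", "predator", "social"):
        stim_segment = default_stim_segment(arena)
    pos, _ = _simulate_paths(archetype, arena, n_frames, fps, rng,
                             vertical_pref=vertical, stim_segment=stim_segment,
                             speed_multiplier=speed_multiplier,
                             start_frozen=start_frozen)
    return from_arrays(pos[:, 0, 0], pos[:, 0, 1], fps)


def default_stim_segment(arena: ArenaSpec):
    """The stimulus wall: the left sloped side of the tank cross-section."""
    poly = np.asarray(arena.polygon, dtype=float)
    # left edge: the two leftmost vertices, ordered bottom to top
    left = poly[np.argsort(poly[:, 0])[:2]]
    left = left[np.argsort(left[:, 1])]
    return (tuple(left[0]), tuple(left[1]))


def simulate_shoal(archetype: SpeciesArchetype, arena: ArenaSpec,
                   duration_s: float, seed: int, n_fish: int = 3,
                   fps: float | None = None) -> pd.DataFrame:
    """One shoaling session: n_fish walkers attracted to their centroid."""
    if n_fish < 2:
        raise ValueError("a shoal needs at least 2 fish")
    fps = fps or arena.fps
    n_frames = int(round(duration_s * fps)) + 1
    rng = np.random.default_rng(seed)
    pos, _ = _simulate_paths(archetype, arena, n_frames, fps, rng,
                             n_paths=n_fish, shoal_groups=1)
    parts = [from_arrays(pos[:, i, 0], pos[:, i, 1], fps, fish_id=i + 1)
             for i in range(n_fish)]
    return pd.concat(parts, ignore_index=True)


def simulate_group_sessions(archetype: SpeciesArchetype, arena: ArenaSpec,
                            duration_s: float, n_sessions: int, seed: int,
                            fps: float | None = None, assay: str = "novel_tank",
                            speed_multiplier: float = 1.0) -> list:
    """n independent sessions in one vectorized run (one walker each)."""
    fps = fps or arena.fps
    n_frames = int(round(duration_s * fps)) + 1
    rng = np.random.default_rng(seed)
    vertical = assay in ("novel_tank", "mirror", "predator", "social")
    stim = (default_stim_segment(arena)
            if assay in ("mirror", "predator", "social") else None)
    pos, _ = _simulate_paths(archetype, arena, n_frames, fps, rng,
                             n_paths=n_sessions, vertical_pref=vertical,
                             stim_segment=stim,
                             speed_multiplier=speed_multiplier)
    return [from_arrays(pos[:, i, 0], pos[:, i, 1], fps)
            for i in range(n_sessions)]


# ----------------------------------------------------------------- sequences

_BASES = np.array(list("ACGT"))


def evolve_sequences(tree, seq_length: int, seed: int | None = None) -> dict:
    """Evolve sequences from a uniform-random root along a tree under
    Jukes-Cantor: per-site substitution probability p(t) = (3/4)(1 - e^(-4t/3))
    on a branch of length t; a substituted site takes one of the three other
    bases uniformly. Returns leaf name -> sequence.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    out = {}

    def descend(node, seq):
        for child in node.children:
            t = child.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            s = seq.copy()
            hit = rng.random(seq_length) < p_sub
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                s[hit] = (s[hit] + shift) % 4
            if child.is_tip():
                out[child.name] = "".join(_BASES[s])
            else:
                descend(child, s)

    descend(tree, root_seq)
    return out


# -------------------------------------------------------------------- study

def generate_study(config: SimulationConfig, outdir=None) -> dict:
    """Simulate the full study: every group x assay, plus nd2-like sequences.

    Returns a dict with trajectories, sequences, the truth record and a
    manifest; when ``outdir`` is given also writes native CSV trajectories,
    a FASTA, manifest.csv and truth.json.
    """
    rng_master = np.random.default_rng(config.seed)
    arena = behavior_tank_arena(fps=config.fps)
    carena = circadian_arena(fps=config.fps)
    trajectories = {}
    manifest_rows = []

    for g_idx, (group, arch) in enumerate(sorted(config.archetypes.items())):
        n = config.n_per_group.get(group, 30)
        base = config.seed * 1_000 + g_idx * 101

        if "novel_tank" in config.assays:
            per_bin = []
            for b in range(config.novel_n_bins):
                sessions = simulate_group_sessions(
                    arch, arena, config.novel_bin_s, n,
                    seed=base + 7 * b + 1, assay="novel_tank")
                per_bin.append(sessions)
            for s in range(n):
                parts = []
                for b in range(config.novel_n_bins):
                    tb = per_bin[b][s].copy()
                    off = int(round(300.0 * b * config.fps))
                    tb["frame"] += off
                    tb["time_s"] = tb["frame"] / config.fps
                    parts.append(tb)
                key = (group, "novel_tank", s)
                trajectories[key] = pd.concat(parts, ignore_index=True)
                manifest_rows.append({"group": group, "assay": "novel_tank",
                                      "session": s})
        for assay in ("mirror", "predator", "social"):
            if assay not in config.assays:
                continue
            sessions = simulate_group_sessions(
                arch, arena, config.assay_duration_s, n,
                seed=base + {"mirror": 211, "predator": 223,
                             "social": 227}[assay], assay=assay)
            for s, tb in enumerate(sessions):
                trajectories[(group, assay, s)] = tb
                manifest_rows.append({"group": group, "assay": assay,
                                      "session": s})
        if "shoaling" in config.assays:
            for s in range(config.n_shoals_per_group):
                tb = simulate_shoal(arch, arena, config.assay_duration_s,
                                    seed=base + 331 + s)
                trajectories[(group, "shoaling", s)] = tb
                manifest_rows.append({"group": group, "assay": "shoaling",
                                      "session": s})
        if "circadian" in config.assays:
            light = range(8, 22)
            for s in range(min(n, 18)):
                hours = {}
                for hour in range(24):
                    mult = (arch.day_multiplier if hour in light
                            else arch.night_multiplier)
                    hours[hour] = simulate_trajectory(
                        arch, carena, config.circadian_segment_s,
                        seed=base + 401 + 29 * s + hour, fps=config.fps,
                        assay="circadian", speed_multiplier=mult)
                trajectories[(group, "circadian", s)] = hours
                manifest_rows.append({"group": group, "assay": "circadian",
                                      "session": s})

    sequences = evolve_sequences(config.tree_newick, config.seq_length,
                                 seed=int(rng_master.integers(0, 2**31 - 1)))
    truth = {"config": json.loads(config.to_json()),
             "tree_newick": config.tree_newick}
    manifest = pd.DataFrame(manifest_rows)
    study = {"trajectories": trajectories, "sequences": sequences,
             "truth": truth, "manifest": manifest,
             "arena": arena, "circadian_arena": carena}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .trajio import write_native
        for key, tb in trajectories.items():
            group, assay, s = key
            if assay == "circadian":
                for hour, ht in tb.items():
                    write_native(ht, outdir /
                                 f"{group}__{assay}__{s:03d}__h{hour:02d}.csv")
            else:
                write_native(tb, outdir / f"{group}__{assay}__{s:03d}.csv")
        from .phylo import write_fasta
        write_fasta(sequences, outdir / "nd2_synthetic.fasta")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return study


def load_study(outdir) -> dict:
    """Reload a study directory written by :func:`generate_study`."""
    from .phylo import read_fasta
    from .trajio import read_native

    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    config = SimulationConfig.from_json(json.dumps(truth["config"]))
    manifest = pd.read_csv(outdir / "manifest.csv")
    trajectories = {}
    for _, row in manifest.iterrows():
        group, assay, s = row["group"], row["assay"], int(row["session"])
        if assay == "circadian":
            hours = {}
            for f in sorted(outdir.glob(f"{group}__{assay}__{s:03d}__h*.csv")):
                hour = int(f.stem.rsplit("h", 1)[1])
                hours[hour] = read_native(f)
            trajectories[(group, assay, s)] = hours
        else:
            trajectories[(group, assay, s)] = read_native(
                outdir / f"{group}__{assay}__{s:03d}.csv")
    return {"trajectories": trajectories,
            "sequences": read_fasta(outdir / "nd2_synthetic.fasta"),
            "truth": truth, "manifest": manifest,
            "arena": behavior_tank_arena(fps=config.fps),
            "circadian_arena": circadian_arena(fps=config.fps)}
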