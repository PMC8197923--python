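import numpy as np
import pytest

from oracles import brute_zone_occupancy
from phenofish import zones
from phenofish.trajio import ConfigError, behavior_tank_arena, from_arrays
from phenofish.synthdata import (
    SpeciesArchetype,
    default_stim_segment,
    simulate_trajectory,
)
from phenofish.zones import (
    SessionSchedule,
    ZoneSpec,
    novel_tank_endpoints,
    side_preference_endpoints,
    top_zone,
    wall_strip_zone,
    zone_occupancy,
)

SQ = ZoneSpec("box", ((0, 0), (10, 0), (10, 10), (0, 10)))


class TestZoneOccupancy:
    def test_always_inside(self):
        t = from_arrays(np.full(50, 5.0), np.full(50, 5.0), fps=10)
        occ = zone_occupancy(t, SQ, fps=10)
        assert occ["time_fraction"] == 1.0
        assert occ["entries"] == 1          # initial placement counts
        assert occ["latency_s"] == 0.0
        assert not occ["latency_censored"]
        assert occ["longest_bout_s"] == pytest.approx(5.0)

    def test_never_inside_latency_censored(self):
        t = from_arrays(np.full(50, 20.0), np.full(50, 5.0), fps=10)
        occ = zone_occupancy(t, SQ, fps=10)
        assert occ["time_fraction"] == 0.0
        assert occ["entries"] == 0
        assert occ["latency_censored"]
        assert occ["latency_s"] == pytest.approx(5.0)

    def test_square_wave_crossings(self):
        """k in/out alternations with >= hysteresis frames per side."""
        xs, k = [], 6
        for rep in range(k):
            xs.extend([5.0] * 5)   # inside
            xs.extend([15.0] * 5)  # outside
        t = from_arrays(np.array(xs), np.full(len(xs), 5.0), fps=10)
        occ = zone_occupancy(t, SQ, fps=10)
        assert occ["entries"] == k

    def test_single_frame_blips_debounced(self):
        xs = [15.0] * 10 + [5.0] + [15.0] * 10   # 1-frame dip inside
        t = from_arrays(np.array(xs), np.full(len(xs), 5.0), fps=10)
        assert zone_occupancy(t, SQ, fps=10)["entries"] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        x = np.clip(np.cumsum(rng.normal(0, 2.0, n)) + 8, -5, 25)
        y = np.clip(np.cumsum(rng.normal(0, 2.0, n)) + 5, -5, 25)
        valid = rng.random(n) > 0.08
        t = from_arrays(x, y, fps=10, valid=valid)
        occ = zone_occupancy(t, SQ, fps=10)
        inside = zones.in_zone_mask(t, SQ)
        oracle = brute_zone_occupancy(x, y, valid, t["time_s"].to_numpy(),
                                      inside, fps=10)
        assert occ["time_fraction"] == pytest.approx(oracle["time_fraction"],
                                                     abs=1e-12)
        assert occ["entries"] == oracle["entries"]
        assert occ["latency_s"] == pytest.approx(oracle["latency_s"], abs=1e-12)
        assert occ["distance_in_zone_cm"] == pytest.approx(
            oracle["distance_in_zone_cm"], abs=1e-9)
        assert occ["longest_bout_s"] == pytest.approx(
            oracle["longest_bout_s"], abs=1e-12)

    def test_inside_count_exact(self, rng):
        n = 500
        x = rng.uniform(-2, 14, n)
        y = rng.uniform(-2, 14, n)
        t = from_arrays(x, y, fps=10)
        occ = zone_occupancy(t, SQ, fps=10)
        brute = sum((0 <= xi <= 10) and (0 <= yi <= 10)
                    for xi, yi in zip(x, y))
        assert occ["time_fraction"] * n == pytest.approx(brute, abs=1e-9)


class TestNovelTank:
    def test_fish_at_centroid_zero_distance(self, arena):
        from phenofish._geometry import polygon_centroid
        c = polygon_centroid(arena.polygon)
        t = from_arrays(np.full(601, c[0]), np.full(601, c[1]), fps=10)
        sched = SessionSchedule("novel_tank", ((0.0, 60.0),))
        out = novel_tank_endpoints(t, arena, schedule=sched)
        assert out["mean_distance_to_center_cm"].iloc[0] == pytest.approx(0.0)

    def test_surface_fish_full_top_fraction(self, arena):
        t = from_arrays(np.full(601, 14.0), np.full(601, 15.0), fps=10)
        sched = SessionSchedule("novel_tank", ((0.0, 60.0),))
        out = novel_tank_endpoints(t, arena, schedule=sched)
        assert out["time_in_top_fraction"].iloc[0] == pytest.approx(1.0)

    def test_top_bias_recovery(self, arena):
        """Generator occupancy parameter is recovered by the endpoint."""
        arch = SpeciesArchetype(freeze_rate=0.0, unfreeze_rate=1.0,
                                mean_speed_cm_s=5, speed_sd_cm_s=1,
                                burst_prob=0.0, top_pref=0.8)
        tz = top_zone(arena)
        fr = []
        for s in range(40):
            tr = simulate_trajectory(arch, arena, 120, seed=7000 + s, fps=10,
                                     assay="novel_tank")
            fr.append(zone_occupancy(tr, tz, 10)["time_fraction"])
        fr = np.array(fr)
        se = fr.std(ddof=1) / np.sqrt(len(fr))
        assert abs(fr.mean() - 0.8) < 3 * se

    def test_missing_bins_flagged(self, arena):
        t = from_arrays(np.full(601, 14.0), np.full(601, 7.0), fps=10)
        out = novel_tank_endpoints(t, arena)   # full 7-bin schedule
        assert not out["bin_missing"].iloc[0]
        assert out["bin_missing"].iloc[1:].all()


class TestSidePreference:
    def _zones(self, arena):
        seg = default_stim_segment(arena)
        strip = wall_strip_zone("contact", seg, 1.0, inward=(1, 0))
        half = ZoneSpec("side", ((0, 0), (14, 0), (14, 15.2), (-1, 15.2)))
        return strip, half

    def test_fish_on_mirror_wall(self, arena):
        strip, half = self._zones(arena)
        # on the wall segment midline
        seg = np.asarray(strip.wall_segment)
        mid = seg.mean(axis=0)
        t = from_arrays(np.full(100, mid[0] + 0.01), np.full(100, mid[1]),
                        fps=10)
        out = side_preference_endpoints(t, strip, half, fps=10)
        assert out["contact_time_pct"] == pytest.approx(100.0)
        assert out["mean_distance_to_wall_cm"] == pytest.approx(0.0, abs=0.05)

    def test_fish_on_far_wall(self, arena):
        strip, half = self._zones(arena)
        t = from_arrays(np.full(100, 25.0), np.full(100, 0.0), fps=10)
        out = side_preference_endpoints(t, strip, half, fps=10)
        assert out["contact_time_pct"] == 0.0
        assert out["mean_distance_to_wall_cm"] == pytest.approx(22.0, abs=0.3)

    def test_degenerate_wall_rejected(self, arena):
        strip = ZoneSpec("bad", ((0, 0), (1, 0), (1, 1), (0, 1)),
                         kind="wall-strip", wall_segment=((1, 1), (1, 1)))
        half = ZoneSpec("side", ((0, 0), (14, 0), (14, 15), (0, 15)))
        t = from_arrays([1.0], [1.0], fps=10)
        with pytest.raises(ConfigError):
            side_preference_endpoints(t, strip, half, fps=10)

    def test_attracted_walk_beats_neutral(self, arena):
        """Separator-attracted walkers show more contact time and smaller
        wall distance than neutral walkers in every seeded replicate."""
        strip, half = self._zones(arena)
        attracted = SpeciesArchetype(freeze_rate=0.0, unfreeze_rate=1.0,
                                     mean_speed_cm_s=5, stim_attraction=1.5)
        neutral = SpeciesArchetype(freeze_rate=0.0, unfreeze_rate=1.0,
                                   mean_speed_cm_s=5, stim_attraction=0.0)
        wins_contact = wins_dist = reps = 0
        for s in range(30):
            ta = simulate_trajectory(attracted, arena, 60, seed=8000 + s,
                                     fps=10, assay="mirror")
            tn = simulate_trajectory(neutral, arena, 60, seed=8000 + s,
                                     fps=10, assay="mirror")
            ea = side_preference_endpoints(ta, strip, half, fps=10)
            en = side_preference_endpoints(tn, strip, half, fps=10)
            reps += 1
            wins_contact += ea["contact_time_pct"] > en["contact_time_pct"]
            wins_dist += (ea["mean_distance_to_wall_cm"]
                          < en["mean_distance_to_wall_cm"])
        assert wins_contact == reps
        assert wins_dist == reps

    def test_contact_never_exceeds_side(self, arena):
        strip, half = self._zones(arena)
        arch = SpeciesArchetype(freeze_rate=0.05, unfreeze_rate=0.5,
                                mean_speed_cm_s=5, stim_attraction=0.6)
        for s in range(10):
            t = simulate_trajectory(arch, arena, 30, seed=9000 + s, fps=10,
                                    assay="mirror")
            out = side_preference_endpoints(t, strip, half, fps=10)
            assert out["contact_time_pct"] <= out["side_time_pct"] + 1e-9
            assert 0 <= out["contact_time_pct"] <= 100
            assert 0 <= out["longest_side_bout_pct"] <= 100
            assert out["mean_distance_to_wall_cm"] >= 0


def test_schedule_rejects_overlap():
    with pytest.raises(ConfigError):
        SessionSchedule("novel_tank", ((0, 60), (30, 90)))


def test_top_zone_is_upper_half(arena):
    tz = top_zone(arena, fraction=0.5)
    ys = tz.polygon[:, 1]
    assert ys.min() == pytest.approx(7.6)
    assert ys.max() == pytest.approx(15.2)
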