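"""Synthetic-data generator: determinism, noise-free limits, ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnkit.config import ConfigurationError, SimConfig
from tnkit.io import tracks_to_frame
from tnkit.lr_screen import LRPair, screen_pairs
from tnkit.simulate import (DesignError, render_frames, simulate_tracks,
                            synth_expression, synth_flow)
from tnkit.flow import fold_change_table
from tnkit.tracking import analyze_cohort, phase_velocity


class TestSimConfig:
    def test_rejects_nonpositive_sizes(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, arena_size=-5)
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, base_speed_t=0)

    def test_rejects_contact_radius_at_arena_scale(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, arena_size=10.0, contact_radius=10.0)

    def test_rejects_bad_factors(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, deceleration_factors=0.0)
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, deceleration_factors=1.5)
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, n_t=3, deceleration_factors=[0.1, 0.2])

    def test_rejects_too_few_frames(self):
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, n_frames=2)


class TestSimulateTracks:
    def test_noise_free_contact_speed_is_exact(self):
        cfg = SimConfig(seed=4, n_t=3, n_nk=3, noise_sd_frac=0.0,
                        base_speed_t=1.0, deceleration_factors=0.2,
                        n_frames=100)
        truth = simulate_tracks(cfg)
        for ci in truth.contact_intervals:
            tr = next(t for t in truth.tracks if t.track_id == ci.focal_id)
            v = phase_velocity(tr, (ci.start_frame, ci.end_frame), "path")
            assert v == pytest.approx(0.2, rel=1e-12)
            v1 = phase_velocity(tr, (0, ci.start_frame - 1), "path")
            assert v1 == pytest.approx(1.0, rel=1e-12)

    def test_same_seed_reproduces_bit_for_bit(self):
        cfg = SimConfig(seed=7, n_t=4, n_nk=4, n_frames=30)
        df1 = tracks_to_frame(simulate_tracks(cfg).tracks)
        df2 = tracks_to_frame(simulate_tracks(cfg).tracks)
        pd.testing.assert_frame_equal(df1, df2)

    def test_different_seeds_differ(self):
        cfg1 = SimConfig(seed=7, n_t=2, n_nk=2, n_frames=10)
        cfg2 = SimConfig(seed=8, n_t=2, n_nk=2, n_frames=10)
        df1 = tracks_to_frame(simulate_tracks(cfg1).tracks)
        df2 = tracks_to_frame(simulate_tracks(cfg2).tracks)
        assert not df1.equals(df2)

    def test_contact_intervals_respect_contact_radius(self):
        cfg = SimConfig(seed=2, n_t=5, n_nk=5, n_frames=60)
        truth = simulate_tracks(cfg)
        tracks = {t.track_id: t for t in truth.tracks}
        for ci in truth.contact_intervals:
            a, b = tracks[ci.focal_id], tracks[ci.partner_id]
            for f in range(ci.start_frame, ci.end_frame + 1):
                pa, pb = a.point_at(f), b.point_at(f)
                assert math.hypot(pa.x - pb.x, pa.y - pb.y) \
                    <= cfg.contact_radius

    def test_tracks_stay_inside_arena(self):
        cfg = SimConfig(seed=6, n_t=5, n_nk=5, n_frames=80, arena_size=50.0,
                        contact_radius=5.0, cell_radius_um=2.0)
        for tr in simulate_tracks(cfg).tracks:
            for p in tr.points:
                assert 0 <= p.x <= cfg.arena_size
                assert 0 <= p.y <= cfg.arena_size

    def test_pipeline_recovers_per_cell_factors(self):
        """End to end: configured deceleration factors are recovered from
        the detected ratios with mean absolute error <= 0.05."""
        cfg = SimConfig(seed=1, deceleration_factors=[0.1] * 15 + [0.5] * 5,
                        noise_sd_frac=0.1)
        truth = simulate_tracks(cfg)
        df = analyze_cohort(truth.tracks, contact_distance=cfg.contact_radius)
        rated = df[df["ratio"].notna()].set_index("track_id")["ratio"]
        assert len(rated) == 20
        err = (rated - pd.Series(truth.factors).loc[rated.index]).abs()
        assert err.mean() <= 0.05

    def test_noise_free_recovery_is_exact(self):
        cfg = SimConfig(seed=9, n_t=6, n_nk=6, noise_sd_frac=0.0,
                        deceleration_factors=[0.1, 0.2, 0.3, 0.4, 0.5, 1.0])
        truth = simulate_tracks(cfg)
        df = analyze_cohort(truth.tracks, contact_distance=cfg.contact_radius)
        rated = df[df["ratio"].notna()].set_index("track_id")["ratio"]
        for tid, ratio in rated.items():
            assert ratio == pytest.approx(truth.factors[tid], rel=1e-9)


def brute_force_disk_area(cy: float, cx: float, radius_px: float,
                          shape: tuple[int, int]) -> int:
    """Lattice points strictly inside the circle: the rendered mask rule."""
    return sum(1 for y in range(shape[0]) for x in range(shape[1])
               if (y - cy) ** 2 + (x - cx) ** 2 < radius_px ** 2)


class TestRenderFrames:
    def test_static_cell_mask_area_matches_disk_enumeration(self):
        cfg = SimConfig(seed=3, n_t=1, n_nk=0, n_frames=3, arena_size=50.0,
                        noise_sd_frac=0.0, base_speed_t=1e-9,
                        pixel_size=1.0, cell_radius_um=4.0)
        truth = simulate_tracks(cfg)
        rendered = render_frames(truth, cfg)
        p = truth.tracks[0].point_at(0)
        expected = brute_force_disk_area(p.y / cfg.pixel_size,
                                         p.x / cfg.pixel_size, 4.0, (50, 50))
        area = int(np.count_nonzero(rendered.labels[0]["T"]))
        assert area == expected

    def test_transfer_event_paints_exact_pixel_count(self):
        cfg = SimConfig(seed=5, n_t=1, n_nk=1, n_frames=40, arena_size=80.0,
                        transfer_pixels=50, noise_sd_frac=0.0)
        truth = simulate_tracks(cfg)
        rendered = render_frames(truth, cfg)
        ev = truth.transfer_events[0]
        f = ev.start_frame
        donor_ch = rendered.channel_roles["T"]
        nk_mask = rendered.labels[f]["NK"] > 0
        t_mask = rendered.labels[f]["T"] > 0
        painted = (rendered.stack[f, donor_ch] > 0) & nk_mask & ~t_mask
        assert int(np.count_nonzero(painted)) == 50

    def test_zero_cells_gives_zero_stack(self):
        cfg = SimConfig(seed=1, n_t=0, n_nk=0, n_frames=3, arena_size=20.0,
                        contact_radius=2.0, cell_radius_um=1.0)
        rendered = render_frames(simulate_tracks(cfg), cfg)
        assert rendered.stack.sum() == 0

    def test_cell_count_conserved_per_frame(self):
        cfg = SimConfig(seed=8, n_t=3, n_nk=2, n_frames=8, arena_size=200.0)
        rendered = render_frames(simulate_tracks(cfg), cfg)
        for f in range(cfg.n_frames):
            # disks are far smaller than the arena; overlaps are possible
            # but every live track must contribute a label
            assert rendered.labels[f]["T"].max() <= 3
            assert rendered.labels[f]["NK"].max() <= 2
            assert len(np.unique(rendered.labels[f]["T"])) >= 2

    def test_oversized_cell_rejected(self):
        cfg = SimConfig(seed=1, n_t=1, n_nk=0, n_frames=3, arena_size=10.0,
                        contact_radius=1.0, cell_radius_um=6.0)
        with pytest.raises(ConfigurationError):
            render_frames(simulate_tracks(cfg), cfg)


def random_pairs(rng, n):
    pairs = []
    for i in range(n):
        n_l = int(rng.integers(1, 3))
        n_r = int(rng.integers(1, 3))
        lig = tuple(f"L{i}S{j}" for j in range(n_l))
        rec = tuple(f"R{i}S{j}" for j in range(n_r))
        pairs.append(LRPair(lig, rec))
    return pairs


class TestSynthExpression:
    def test_all_pass10_design(self):
        rng = np.random.default_rng(0)
        pairs = random_pairs(rng, 6)
        expr = synth_expression(pairs, ["pass10"] * 6, seed=1)
        res = screen_pairs(pairs, expr, 10.0)
        assert set(p.key() for p in res.passing) == {p.key() for p in pairs}

    def test_pass2_only_pair_straddles_thresholds(self):
        pairs = [LRPair(("LIGA",), ("RECA",))]
        expr = synth_expression(pairs, ["pass2_only"], seed=2)
        assert screen_pairs(pairs, expr, 2.0).n_passing == 1
        assert screen_pairs(pairs, expr, 10.0).n_passing == 0

    def test_design_faithfulness_over_random_designs(self):
        """screen(synth_expression(design)) == design, 120 random designs."""
        rng = np.random.default_rng(42)
        options = np.array(["pass10", "pass2_only", "fail"])
        for trial in range(120):
            n = int(rng.integers(1, 12))
            pairs = random_pairs(rng, n)
            design = list(options[rng.integers(0, 3, size=n)])
            expr = synth_expression(pairs, design, seed=int(rng.integers(2**31)))
            at10 = {p.key() for p in screen_pairs(pairs, expr, 10.0).passing}
            at2 = {p.key() for p in screen_pairs(pairs, expr, 2.0).passing}
            for pair, a in zip(pairs, design):
                k = pair.key()
                assert (k in at10) == (a == "pass10")
                assert (k in at2) == (a in ("pass10", "pass2_only"))

    def test_contradictory_design_names_genes(self):
        # both genes of the failing pair are pinned >= 10 by the first pair
        fwd = LRPair(("GENEX",), ("RECA",))
        rev = LRPair(("RECA",), ("GENEX",))
        with pytest.raises(DesignError, match="GENEX"):
            synth_expression([fwd, rev], ["pass10", "fail"], seed=1)


class TestSynthFlow:
    def test_noise_free_recovery_is_exact(self):
        df = synth_flow({"STAT1": 2.0, "AKT": 0.5}, noise_sd=0.0, seed=3)
        fc = fold_change_table(df).set_index("marker")["fold_change"]
        assert fc["STAT1"] == pytest.approx(2.0)
        assert fc["AKT"] == pytest.approx(0.5)

    def test_identity_fold_changes(self):
        df = synth_flow({"LCK": 1.0, "P38": 1.0}, noise_sd=0.0, seed=3)
        fc = fold_change_table(df)["fold_change"]
        assert np.allclose(fc, 1.0)

    def test_mean_recovery_under_small_noise(self):
        truth = {f"M{i:04d}": 1.5 for i in range(1000)}
        df = synth_flow(truth, noise_sd=0.01, seed=7)
        fc = fold_change_table(df)["fold_change"]
        assert fc.mean() == pytest.approx(1.5, rel=0.01)

    def test_percentages_stay_in_range(self):
        df = synth_flow({"STAT3": 3.0}, noise_sd=0.2, seed=5)
        assert ((df["pX"] > 0) & (df["pX"] <= 100)).all()
        assert ((df["X"] > 0) & (df["X"] <= 100)).all()

    def test_invalid_fold_change_rejected(self):
        with pytest.raises(ValueError):
            synth_flow({"STAT1": -1.0}, noise_sd=0.0, seed=1)
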