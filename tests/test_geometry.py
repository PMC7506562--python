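"""Player-ball-goal angle geometry, attack normalization and pitch zones."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teamsync import geometry
from teamsync.geometry import (
    ZoneGrid,
    assign_zone,
    assign_zones,
    compute_pbga,
    default_zone_grid,
    normalize_attack_direction,
    pbga_angle,
)
from teamsync.tracking_io import MatchMetadata

from conftest import build_manual_dataset

GOAL = np.array([52.5, 0.0])
BALL = np.array([0.0, 0.0])


class TestPbgaAngle:
    @pytest.mark.parametrize(
        "player,expected",
        [
            ((26.25, 0.0), 0.0),          # collinear, between ball and goal
            ((-10.0, 0.0), np.pi),        # anti-parallel
            ((0.0, 7.0), np.pi / 2),      # perpendicular
            ((0.0, -7.0), np.pi / 2),     # perpendicular, other side
            ((100.0, 0.0), 0.0),          # beyond the goal, still aligned
        ],
    )
    def test_analytic_cases(self, player, expected):
        assert pbga_angle(np.array(player), BALL, GOAL) == pytest.approx(
            expected, abs=1e-12
        )

    def test_player_on_ball_is_flagged_undefined(self):
        assert np.isnan(pbga_angle(BALL, BALL, GOAL))

    def test_ball_on_goal_is_flagged_undefined(self):
        assert np.isnan(pbga_angle(np.array([1.0, 1.0]), GOAL, GOAL))

    def test_range_is_0_pi(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-60, 60, size=(500, 3, 2))
        theta = pbga_angle(pts[:, 0], pts[:, 1], pts[:, 2])
        ok = ~np.isnan(theta)
        assert ((theta[ok] >= 0) & (theta[ok] <= np.pi)).all()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_under_similarity_transforms(self, angle, scale, tx, ty, seed):
        """θ is preserved by rotation + translation + positive scaling."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, size=(3, 2))
        theta0 = pbga_angle(pts[0], pts[1], pts[2])
        if np.isnan(theta0):
            return
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        moved = scale * pts @ R.T + np.array([tx, ty])
        theta1 = pbga_angle(moved[0], moved[1], moved[2])
        assert theta1 == pytest.approx(theta0, abs=1e-9)

    def test_atan2_form_equals_arccos_form(self):
        """Oracle equivalence with arccos of the normalized dot product."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(-50, 50, size=(2000, 3, 2))
        theta = pbga_angle(pts[:, 0], pts[:, 1], pts[:, 2])
        bp = pts[:, 0] - pts[:, 1]
        bg = pts[:, 2] - pts[:, 1]
        cosang = np.einsum("ij,ij->i", bp, bg) / (
            np.linalg.norm(bp, axis=1) * np.linalg.norm(bg, axis=1)
        )
        expected = np.arccos(np.clip(cosang, -1, 1))
        assert np.allclose(theta, expected, atol=1e-7)


class TestComputePbga:
    def test_uses_goal_attacked_by_possession_team(self):
        # home possession in half 1 -> home attacks +x -> goal (52.5, 0)
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 0.0), possession="home",
                  players={("home", 0): (26.25, 0.0), ("away", 0): (-10.0, 0.0)})]
        )
        th_home = compute_pbga(ds, "home").theta
        th_away = compute_pbga(ds, "away").theta
        assert th_home.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert th_away.iloc[0, 0] == pytest.approx(np.pi, abs=1e-12)
        # away possession: attacked goal flips to (-52.5, 0)
        ds2 = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 0.0), possession="away",
                  players={("home", 0): (26.25, 0.0)})]
        )
        assert compute_pbga(ds2, "home").theta.iloc[0, 0] == pytest.approx(np.pi)

    def test_degenerate_player_flagged_not_zero(self):
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(3.0, 4.0),
                  players={("home", 0): (3.0, 4.0)})]
        )
        theta = compute_pbga(ds, "home").theta
        assert np.isnan(theta.iloc[0, 0])
        assert not np.isnan(theta.iloc[0, 1:]).any()


class TestNormalizeAttackDirection:
    def test_second_half_points_are_reflected(self):
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(10.0, 5.0)),
             dict(half=2, frame=0, ball=(10.0, 5.0))]
        )
        norm = normalize_attack_direction(ds)
        ball = norm.ball_positions()
        assert tuple(ball.loc[(1, 0)]) == (10.0, 5.0)
        assert tuple(ball.loc[(2, 0)]) == (-10.0, -5.0)

    def test_first_half_unchanged(self, small_ds):
        norm = normalize_attack_direction(small_ds)
        h1 = small_ds.frames[small_ds.frames.half == 1]
        n1 = norm.frames[norm.frames.half == 1]
        assert np.allclose(h1[["x_m", "y_m"]], n1[["x_m", "y_m"]])

    def test_double_application_is_identity(self, small_ds):
        once = normalize_attack_direction(small_ds)
        twice = normalize_attack_direction(once)
        assert once.equals(twice)

    def test_attack_directions_constant_after(self, small_ds):
        norm = normalize_attack_direction(small_ds)
        for team in ("home", "away"):
            assert (
                norm.metadata.attack_direction[(team, 1)]
                == norm.metadata.attack_direction[(team, 2)]
            )


class TestZones:
    def test_default_grid_tiles_the_pitch(self):
        grid = default_zone_grid()
        areas = grid.cell_areas()
        assert areas.shape == (4, 5)
        assert areas.sum() == pytest.approx(105 * 68)
        assert len(grid.labels) == 20

    def test_center_point_resolves_half_open_to_MO_C(self):
        assert assign_zone((0.0, 0.0), default_zone_grid()) == "MO-C"

    def test_defensive_left_corner(self):
        assert assign_zone((-52.5, -34.0), default_zone_grid()) == "D-L"

    def test_every_point_gets_exactly_one_code(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform([-52.5, -34], [52.5, 34], size=(2000, 2))
        codes, clamped = assign_zones(pts, default_zone_grid())
        assert not clamped.any()
        valid = set(default_zone_grid().labels)
        assert set(codes) <= valid

    def test_zone_occupancy_proportional_to_area(self):
        """Uniform points land in each equal-area cell ~uniformly."""
        rng = np.random.default_rng(3)
        n = 40_000
        pts = rng.uniform([-52.5, -34], [52.5, 34], size=(n, 2))
        codes, _ = assign_zones(pts, default_zone_grid())
        _, counts = np.unique(codes, return_counts=True)
        assert len(counts) == 20
        # 5 sigma binomial band around n/20
        sd = np.sqrt(n * 0.05 * 0.95)
        assert (np.abs(counts - n / 20) < 5 * sd).all()

    def test_out_of_bounds_clamped_and_flagged(self):
        codes, clamped = assign_zones(np.array([[999.0, 0.0]]), default_zone_grid())
        assert clamped[0]
        assert codes[0] == "O-C"

    def test_attack_sign_mirrors_labels(self):
        grid = default_zone_grid()
        assert assign_zone((-52.5, -34.0), grid, attack_sign=-1) == "O-R"
        assert assign_zone((-52.5, -34.0), grid, attack_sign=-1,
                           lateral_frame="absolute") == "O-L"

    def test_custom_edges_validated(self):
        with pytest.raises(ValueError):
            ZoneGrid(longitudinal_edges=(0, 1, 2), lateral_edges=(0, 1, 2, 3, 4, 5))
        with pytest.raises(ValueError, match="ascending"):
            ZoneGrid(
                longitudinal_edges=(0, 2, 1, 3, 4),
                lateral_edges=(0, 1, 2, 3, 4, 5),
            )
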