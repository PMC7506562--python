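"""Angular histograms, team configuration codes and subgroup hulls."""

import numpy as np
import pandas as pd
import pytest

from teamsync.binning import (
    TCC_EDGES,
    pbga_relative_frequency,
    subgroup_hulls,
    team_configuration_code,
)
from teamsync.geometry import PhaseSeries, compute_pbga
from teamsync.tracking_io import filter_frames

from conftest import build_manual_dataset
from test_synchrony import make_phase


def phase_for(ds, team="home"):
    return compute_pbga(ds, team)


def constant_angle_dataset(theta, n_frames=100, possession="home"):
    """All home players at angle theta from the ball-goal (+x) axis."""
    frames = []
    for i in range(n_frames):
        players = {
            ("home", k): (
                10.0 * np.cos(theta),
                10.0 * np.sin(theta) + 0.01 * k,  # tiny spread, same bin
            )
            for k in range(11)
        }
        frames.append(
            dict(half=1, frame=i, ball=(0.0, 0.0), possession=possession,
                 players=players)
        )
    return build_manual_dataset(frames)


class TestAngleHistogram:
    def test_single_bin_occupancy(self):
        ds = constant_angle_dataset(0.05)
        hist = pbga_relative_frequency(phase_for(ds), ds, role="with_ball")
        assert hist.counts.shape == (11, 18)
        assert (hist.counts[:, 0] == 100).all()
        assert (hist.counts[:, 1:] == 0).all()
        assert np.allclose(hist.proportions[:, 0], 1.0)

    def test_counts_conserve_qualifying_frames(self, small_match):
        ds, _ = small_match
        phase = phase_for(ds, "away")
        for role in ("with_ball", "without_ball"):
            hist = pbga_relative_frequency(phase, ds, role=role)
            sub = filter_frames(ds, status="alive", role_for_team=role, team="away")
            assert (hist.counts.sum(axis=1) == hist.total_frames).all()
            assert hist.total_frames.max() <= sub.n_frames

    def test_zero_qualifying_frames_gives_empty_histogram(self):
        ds = constant_angle_dataset(0.05, n_frames=5, possession="away")
        hist = pbga_relative_frequency(phase_for(ds), ds, role="with_ball")
        assert hist.counts.sum() == 0
        assert (hist.total_frames == 0).all()
        assert np.allclose(hist.proportions, 0.0)

    def test_uniform_phases_spread_within_binomial_bounds(self):
        rng = np.random.default_rng(10)
        n = 18_000
        theta = rng.uniform(0, np.pi, size=(n, 1))
        counts, _ = np.histogram(theta, bins=np.linspace(0, np.pi, 19))
        p = 1 / 18
        sigma = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) < 4 * sigma).all()

    def test_tidy_export_columns(self):
        ds = constant_angle_dataset(0.05, n_frames=3)
        hist = pbga_relative_frequency(phase_for(ds), ds, role="with_ball")
        tidy = hist.to_frame()
        assert list(tidy.columns) == [
            "player_id", "role", "bin_lo_rad", "bin_hi_rad", "count", "proportion",
        ]
        assert len(tidy) == 11 * 18

    def test_invalid_role_rejected(self):
        ds = constant_angle_dataset(0.05, n_frames=2)
        with pytest.raises(ValueError, match="role"):
            pbga_relative_frequency(phase_for(ds), ds, role="sometimes")


class TestTeamConfigurationCode:
    def test_all_front_players(self):
        ds = constant_angle_dataset(0.2)
        tcc = team_configuration_code(phase_for(ds), ds)
        assert (tcc["fs_c"] == 11).all()
        assert (tcc[["ls_c", "bs_c"]] == 0).all().all()
        assert (tcc["role_label"] == "support").all()

    def test_constructed_4_4_3_code(self):
        """Phases {0.1×4, 1.2×4, 3.0×3} → sectors 4-4-3."""
        players = {}
        angles = [0.1] * 4 + [1.2] * 4 + [3.0] * 3
        # away possession: the attacked goal is at -x, so angle a from the
        # ball-goal axis means position (-10 cos a, 10 sin a)
        for k, a in enumerate(angles):
            players[("home", k)] = (-10 * np.cos(a), 10 * np.sin(a))
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 0.0), possession="away",
                  players=players)]
        )
        tcc = team_configuration_code(phase_for(ds), ds)
        assert tcc.iloc[0][["fs_c", "ls_c", "bs_c"]].tolist() == [4, 4, 3]
        assert tcc.iloc[0]["role_label"] == "cover"

    def test_components_sum_to_team_size(self, small_match):
        ds, _ = small_match
        tcc = team_configuration_code(phase_for(ds, "home"), ds)
        assert (tcc[["fs_c", "ls_c", "bs_c"]].sum(axis=1) == 11).all()

    def test_sector_boundaries_half_open(self):
        phase = make_phase([[np.pi / 3, 2 * np.pi / 3, np.pi]])
        ds = constant_angle_dataset(0.1, n_frames=1)
        # direct sector assignment on the constructed phases
        from teamsync import binning

        theta = phase.theta.to_numpy()
        edges = np.asarray(TCC_EDGES)
        idx = np.searchsorted(edges, theta, side="right") - 1
        idx = np.where(theta == edges[-1], 2, idx)
        assert idx.ravel().tolist() == [1, 2, 2]

    def test_18_bin_aggregation_matches_3_bin(self, small_match):
        """Summing 18-bin counts in blocks of 6 equals the TCC sectors."""
        ds, _ = small_match
        phase = phase_for(ds, "away")
        tcc = team_configuration_code(phase, ds)
        theta = phase.theta.loc[tcc.index].to_numpy()
        edges18 = np.linspace(0, np.pi, 19)
        for t in range(0, len(tcc), 37):
            row = theta[t][~np.isnan(theta[t])]
            h18, _ = np.histogram(row, bins=edges18)
            agg = [h18[:6].sum(), h18[6:12].sum(), h18[12:].sum()]
            assert agg == tcc.iloc[t][["fs_c", "ls_c", "bs_c"]].tolist()


class TestSubgroupHulls:
    def test_triangle_hull_for_three_noncollinear(self):
        players = {("home", k): p for k, p in enumerate(
            [(10.0, 1.0), (12.0, 6.0), (7.0, 4.0)]  # all in the front sector
        )}
        # remaining players far behind the ball (theta > 2pi/3)
        for k in range(3, 11):
            players[("home", k)] = (-20.0 - k, 0.5 * k)
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 0.0), players=players)]
        )
        hulls = subgroup_hulls(ds, phase_for(ds), 1, 0)
        tri = [h for h in hulls.values() if len(h.members) == 3]
        assert tri and not tri[0].degenerate
        assert len(tri[0].vertices) == 3

    def test_single_member_is_degenerate_point(self):
        players = {("home", 0): (10.0, 0.0)}
        for k in range(1, 11):
            players[("home", k)] = (-15.0 - k, 1.0 * k)
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 0.0), players=players)]
        )
        hulls = subgroup_hulls(ds, phase_for(ds), 1, 0)
        solo = [h for h in hulls.values() if len(h.members) == 1]
        assert solo and solo[0].degenerate
        assert solo[0].vertices.shape == (1, 2)

    def test_interior_point_excluded_from_hull(self):
        """5 front players, one strictly inside the others' quadrilateral."""
        quad = [(5.0, 1.0), (15.0, 1.0), (15.0, 9.0), (5.0, 9.0)]
        inner = (10.0, 5.0)
        players = {("home", k): p for k, p in enumerate(quad + [inner])}
        for k in range(5, 11):
            players[("home", k)] = (-20.0 - k, 1.0 * k)
        ds = build_manual_dataset(
            [dict(half=1, frame=0, ball=(0.0, 10.0),
                  players=players)]
        )
        hulls = subgroup_hulls(ds, phase_for(ds), 1, 0)
        big = hulls["FS/C"]
        assert len(big.members) == 5
        assert len(big.vertices) == 4
        # brute-force: every member (incl. the interior one) inside the hull
        for p in quad + [inner]:
            assert big.contains(p, tol=1e-9)

    def test_every_member_inside_its_hull(self, small_match):
        ds, _ = small_match
        phase = phase_for(ds, "home")
        players, pos = ds.player_positions("home")
        fidx = ds.frame_index().index
        for key in [fidx[0], fidx[40], fidx[200]]:
            hulls = subgroup_hulls(ds, phase, *key)
            loc = fidx.get_loc(key)
            for h in hulls.values():
                for pid in h.members:
                    p = pos[loc, players.index(pid)]
                    assert h.contains(p, tol=1e-6)

    def test_missing_frame_rejected(self, small_match):
        ds, _ = small_match
        with pytest.raises(KeyError):
            subgroup_hulls(ds, phase_for(ds), 9, 99999)
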