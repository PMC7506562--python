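"""Player-ball-goal angles, attack-direction normalization and pitch zones.

The player-ball-goal angle (PBGA) is the angle at the ball between the
ball→player and ball→goal vectors,

    θ_k(t) = atan2(‖(P_k − B) × (G − B)‖, (P_k − B) · (G − B)) ∈ [0, π],

where the cross product is the planar (z-component magnitude) cross
product. θ = 0 means the player sits on the ball–goal line on the goal
side; θ = π means directly behind the ball. The goal G is the goal-mouth
centre of the goal being *attacked* in that frame — the same goal for both
teams, determined by which team has possession.

Degenerate geometry (player coincident with the ball, or ball coincident
with the goal centre, within ``DEGENERATE_EPS`` metres) yields NaN, never a
silent 0: atan2(0, 0) would masquerade as perfect alignment and bias
synchrony upward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .tracking_io import MatchDataset, MatchMetadata, TEAMS

__all__ = [
    "DEGENERATE_EPS",
    "LONG_LABELS",
    "LAT_LABELS",
    "PhaseSeries",
    "ZoneGrid",
    "pbga_angle",
    "compute_pbga",
    "normalize_attack_direction",
    "default_zone_grid",
    "assign_zone",
    "assign_zones",
]

#: Vectors shorter than this (metres) are treated as degenerate.
DEGENERATE_EPS = 1e-6

#: Longitudinal zone labels from the defended end toward the attacked goal.
LONG_LABELS = ("D", "MD", "MO", "O")
#: Lateral zone labels; L..R ascend with y in the +x attacking frame.
LAT_LABELS = ("L", "CL", "C", "CR", "R")


@dataclass
class PhaseSeries:
    """Per-frame PBGA values for one team.

    ``theta`` is indexed by (half, frame) with one column per player_id;
    NaN entries mark degenerate geometry flagged by :func:`compute_pbga`.
    """

    team: str
    theta: pd.DataFrame

    @property
    def players(self) -> list:
        return list(self.theta.columns)

    @property
    def n_players(self) -> int:
        return self.theta.shape[1]


def pbga_angle(player: np.ndarray, ball: np.ndarray, goal: np.ndarray) -> np.ndarray:
    """Vectorized PBGA with the vertex on the ball.

    All arguments broadcast against each other with a trailing axis of
    length 2 (x, y). Returns angles in [0, π]; NaN where either the
    ball→player or ball→goal vector is shorter than :data:`DEGENERATE_EPS`.
    """
    player = np.asarray(player, dtype=float)
    ball = np.asarray(ball, dtype=float)
    goal = np.asarray(goal, dtype=float)
    bp = player - ball
    bg = goal - ball
    cross = np.abs(bp[..., 0] * bg[..., 1] - bp[..., 1] * bg[..., 0])
    dot = bp[..., 0] * bg[..., 0] + bp[..., 1] * bg[..., 1]
    theta = np.arctan2(cross, dot)
    degenerate = (np.linalg.norm(bp, axis=-1) < DEGENERATE_EPS) | (
        np.linalg.norm(bg, axis=-1) < DEGENERATE_EPS
    )
    return np.where(degenerate, np.nan, theta)


def _attacked_goal_per_frame(ds: MatchDataset) -> np.ndarray:
    """Goal-mouth centre of the attacked goal, one (x, y) row per frame.

    The attacked goal is the one the team in possession is attacking (the
    goal defended by the team without the ball); both teams' angles use it.
    """
    idx = ds.frame_index().reset_index()
    meta = ds.metadata
    sign = np.array(
        [
            meta.attack_direction[(poss, int(half))]
            for poss, half in zip(idx["possession"], idx["half"])
        ],
        dtype=float,
    )
    goals = np.zeros((len(idx), 2))
    goals[:, 0] = sign * meta.pitch_length / 2.0
    return goals


def compute_pbga(ds: MatchDataset, team: str) -> PhaseSeries:
    """Compute the PBGA series θ_k(t) for every player of ``team``.

    Degenerate entries (player on the ball, or ball on the goal centre) are
    NaN; downstream synchrony drops them per frame rather than treating
    them as zero angles.
    """
    if team not in TEAMS:
        raise ValueError(f"unknown team {team!r}")
    players, pos = ds.player_positions(team)
    ball = ds.ball_positions()
    goals = _attacked_goal_per_frame(ds)
    theta = pbga_angle(pos, ball.to_numpy()[:, None, :], goals[:, None, :])
    frame = pd.DataFrame(theta, index=ball.index, columns=players)
    return PhaseSeries(team=team, theta=frame)


def normalize_attack_direction(ds: MatchDataset) -> MatchDataset:
    """Make each team attack one fixed direction for the whole match.

    If the metadata says attack directions flip between halves, second-half
    positions (ball and players) are reflected through the pitch centre
    (both axes negated) and the metadata is rewritten so both halves share
    the first-half directions. Applying the operation to an
    already-normalized dataset is the identity.
    """
    meta = ds.metadata
    for team in TEAMS:
        for half in (1, 2):
            if (team, half) not in meta.attack_direction:
                raise ValueError(f"attack direction missing for ({team}, {half})")
    if not meta.directions_flip_between_halves():
        return ds
    df = ds.frames.copy()
    mask = df["half"] == 2
    df.loc[mask, ["x_m", "y_m"]] = -df.loc[mask, ["x_m", "y_m"]].to_numpy()
    new_attack = {
        (t, h): meta.attack_direction[(t, 1)] for t in TEAMS for h in (1, 2)
    }
    new_meta = replace(meta, attack_direction=new_attack)
    return MatchDataset(metadata=new_meta, frames=df)


# ---------------------------------------------------------------------------
# pitch zones


@dataclass(frozen=True)
class ZoneGrid:
    """A 4 longitudinal × 5 lateral partition of the pitch (20 cells).

    Edges are ascending pitch coordinates in metres spanning the full
    extents. Cells are half-open [lo, hi) with the final cell closed, so
    every in-bounds point maps to exactly one cell.
    """

    longitudinal_edges: tuple[float, ...]
    lateral_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.longitudinal_edges) != 5:
            raise ValueError("need 5 longitudinal edges (4 zones)")
        if len(self.lateral_edges) != 6:
            raise ValueError("need 6 lateral edges (5 zones)")
        for edges in (self.longitudinal_edges, self.lateral_edges):
            if not np.all(np.diff(edges) > 0):
                raise ValueError("zone edges must be strictly ascending")

    @property
    def labels(self) -> list[str]:
        return [f"{lo}-{la}" for lo in LONG_LABELS for la in LAT_LABELS]

    def cell_areas(self) -> np.ndarray:
        dl = np.diff(self.longitudinal_edges)
        dw = np.diff(self.lateral_edges)
        return np.outer(dl, dw)


def default_zone_grid(meta: MatchMetadata | None = None) -> ZoneGrid:
    """Equal partition: longitudinal quarters × lateral fifths of the pitch."""
    meta = meta or MatchMetadata()
    hl, hw = meta.pitch_length / 2.0, meta.pitch_width / 2.0
    return ZoneGrid(
        longitudinal_edges=tuple(np.linspace(-hl, hl, 5)),
        lateral_edges=tuple(np.linspace(-hw, hw, 6)),
    )


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open binning with final bin closed; out-of-bounds clamped."""
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    clamped = (values < edges[0]) | (values > edges[-1])
    idx = np.clip(idx, 0, len(edges) - 2)
    return idx, clamped


def assign_zones(
    points: np.ndarray,
    grid: ZoneGrid,
    attack_sign: int | np.ndarray = +1,
    lateral_frame: Literal["attacking", "absolute"] = "attacking",
) -> tuple[np.ndarray, np.ndarray]:
    """Map points to zone codes like ``"MO-CL"``.

    ``attack_sign`` (+1/-1, scalar or per-point) orients the longitudinal
    labels so "O" (offensive) is the quarter nearest the goal being
    attacked. With ``lateral_frame="attacking"`` the L..R labels are also
    mirrored with the attack sign; ``"absolute"`` keeps L at negative y
    regardless of direction. Out-of-bounds points are clamped to the
    nearest cell and flagged in the returned boolean mask.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sign = np.broadcast_to(np.asarray(attack_sign), pts.shape[0])
    li, lc = _bin_indices(pts[:, 0], np.asarray(grid.longitudinal_edges))
    wi, wc = _bin_indices(pts[:, 1], np.asarray(grid.lateral_edges))
    n_long, n_lat = len(LONG_LABELS), len(LAT_LABELS)
    long_idx = np.where(sign > 0, li, n_long - 1 - li)
    if lateral_frame == "attacking":
        lat_idx = np.where(sign > 0, wi, n_lat - 1 - wi)
    elif lateral_frame == "absolute":
        lat_idx = wi
    else:
        raise ValueError(f"unknown lateral_frame {lateral_frame!r}")
    long_arr = np.asarray(LONG_LABELS)[long_idx]
    lat_arr = np.asarray(LAT_LABELS)[lat_idx]
    codes = np.char.add(np.char.add(long_arr, "-"), lat_arr)
    return codes, lc | wc


def assign_zone(
    point,
    grid: ZoneGrid,
    attack_sign: int = +1,
    lateral_frame: Literal["attacking", "absolute"] = "attacking",
) -> str:
    """Zone code for a single point (clamped to the pitch if outside)."""
    codes, _ = assign_zones(
        np.asarray(point, dtype=float)[None, :], grid, attack_sign, lateral_frame
    )
    return str(codes[0])
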