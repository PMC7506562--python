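"""Reading, validating, writing and filtering planar tracking data.

The on-disk format is a long-format CSV (one row per tracked object per
frame) plus a small YAML metadata file. Per frame the data carry the ball
position, eleven player positions per team, a ball-status flag
(``alive``/``dead``, i.e. whether play is running) and a possession flag
(which team has the ball). Analysis-stage filtering (alive frames,
possession role, half) happens here; raw files keep every frame.

Coordinate convention: pitch-centred origin, longitudinal axis ``x``
(positive toward the end where the away team defends in the first half by
default), lateral axis ``y``. Units are metres throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TEAMS",
    "TRACKING_COLUMNS",
    "MatchMetadata",
    "MatchDataset",
    "SchemaError",
    "IntegrityError",
    "RosterError",
    "read_metadata",
    "write_metadata",
    "read_tracking",
    "write_tracking",
    "filter_frames",
]

TEAMS = ("home", "away")

#: Column order of the tracking CSV dialect.
TRACKING_COLUMNS = (
    "half",
    "frame",
    "object_type",
    "team",
    "player_id",
    "x_m",
    "y_m",
    "ball_status",
    "possession",
)


class SchemaError(ValueError):
    """A required column is missing or a column holds an illegal value."""


class IntegrityError(ValueError):
    """Duplicate or out-of-order rows within a frame sequence."""


class RosterError(ValueError):
    """A frame does not carry exactly 11 players per team."""


@dataclass(frozen=True)
class MatchMetadata:
    """Pitch geometry, frame rate and per-half attack directions.

    ``attack_direction`` maps ``(team, half)`` to the sign (+1/-1) of the
    longitudinal direction that team attacks in that half. Goal centres are
    the physical goal-mouth midpoints on the two goal lines; under the
    centred convention they sit at ``(±pitch_length/2, 0)``.
    """

    pitch_length: float = 105.0
    pitch_width: float = 68.0
    frame_rate: float = 25.0
    home_goal_center: tuple[float, float] = (-52.5, 0.0)
    away_goal_center: tuple[float, float] = (52.5, 0.0)
    attack_direction: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: {
            ("home", 1): +1,
            ("away", 1): -1,
            ("home", 2): -1,
            ("away", 2): +1,
        }
    )

    def __post_init__(self) -> None:
        if self.pitch_length <= 0 or self.pitch_width <= 0:
            raise ValueError("pitch dimensions must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.home_goal_center[0] * self.away_goal_center[0] >= 0:
            raise ValueError("goal centers must lie on opposite pitch ends")
        for half in (1, 2):
            dirs = {
                t: self.attack_direction.get((t, half)) for t in TEAMS
            }
            if None in dirs.values():
                raise ValueError(f"attack_direction missing for half {half}")
            if dirs["home"] * dirs["away"] != -1:
                raise ValueError(
                    f"teams must attack opposite directions in half {half}"
                )

    def attacked_goal(self, team: str, half: int) -> tuple[float, float]:
        """Goal-mouth centre of the goal *attacked* by ``team`` in ``half``."""
        sign = self.attack_direction[(team, half)]
        return (sign * self.pitch_length / 2.0, 0.0)

    def directions_flip_between_halves(self) -> bool:
        return any(
            self.attack_direction[(t, 1)] != self.attack_direction[(t, 2)]
            for t in TEAMS
        )


@dataclass
class MatchDataset:
    """A validated tracking dataset: metadata plus long-format frames.

    ``frames`` holds one row per tracked object per frame with the columns
    of :data:`TRACKING_COLUMNS`. Rows are sorted by (half, frame) with the
    ball row first within each frame.
    """

    metadata: MatchMetadata
    frames: pd.DataFrame

    def __post_init__(self) -> None:
        self.frames = _canonical_order(self.frames)

    # ---- convenience accessors -------------------------------------------

    def frame_index(self) -> pd.DataFrame:
        """One row per (half, frame) with ball_status and possession."""
        ball = self.frames[self.frames["object_type"] == "ball"]
        out = ball[["half", "frame", "ball_status", "possession"]].copy()
        return out.set_index(["half", "frame"])

    def ball_positions(self) -> pd.DataFrame:
        ball = self.frames[self.frames["object_type"] == "ball"]
        return ball.set_index(["half", "frame"])[["x_m", "y_m"]]

    def player_positions(self, team: str) -> tuple[list, np.ndarray]:
        """Return (player_ids, positions[n_frames, n_players, 2]) for a team.

        Frame order matches :meth:`frame_index`.
        """
        rows = self.frames[
            (self.frames["object_type"] == "player")
            & (self.frames["team"] == team)
        ]
        x = rows.pivot(index=["half", "frame"], columns="player_id", values="x_m")
        y = rows.pivot(index=["half", "frame"], columns="player_id", values="y_m")
        players = list(x.columns)
        pos = np.stack([x.to_numpy(), y.to_numpy()], axis=-1)
        return players, pos

    @property
    def n_frames(self) -> int:
        return int((self.frames["object_type"] == "ball").sum())

    def equals(self, other: "MatchDataset") -> bool:
        return self.metadata == other.metadata and self.frames.reset_index(
            drop=True
        ).equals(other.frames.reset_index(drop=True))


def _canonical_order(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    order = df["object_type"].map({"ball": 0, "player": 1})
    team_order = df["team"].map({"none": 0, "home": 1, "away": 2})
    df = (
        df.assign(_o=order, _t=team_order)
        .sort_values(["half", "frame", "_o", "_t", "player_id"], kind="stable")
        .drop(columns=["_o", "_t"])
        .reset_index(drop=True)
    )
    return df


# ---------------------------------------------------------------------------
# validation


def validate(ds: MatchDataset) -> None:
    """Check dataset invariants; raise a specific error on first violation.

    Checks: required columns, legal flag values, one ball row per frame,
    exactly 11 players per team per frame (no dismissals assumed),
    no duplicate (half, frame, team, player_id) rows, frame counters
    strictly increasing within each half, and flags constant within a frame.
    """
    df = ds.frames
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    bad_status = set(df["ball_status"].unique()) - {"alive", "dead"}
    if bad_status:
        raise SchemaError(f"illegal ball_status value(s): {sorted(bad_status)}")
    bad_poss = set(df["possession"].unique()) - set(TEAMS)
    if bad_poss:
        raise SchemaError(f"illegal possession value(s): {sorted(bad_poss)}")
    bad_half = set(df["half"].unique()) - {1, 2}
    if bad_half:
        raise SchemaError(f"illegal half value(s): {sorted(bad_half)}")
    if not np.isfinite(df[["x_m", "y_m"]].to_numpy()).all():
        raise SchemaError("non-finite position values")

    players = df[df["object_type"] == "player"]
    dup = players.duplicated(["half", "frame", "team", "player_id"])
    if dup.any():
        row = players[dup].iloc[0]
        raise IntegrityError(
            "duplicate (time_index, team, player_id) row at half "
            f"{row['half']} frame {row['frame']}: {row['team']}/{row['player_id']}"
        )

    balls = df[df["object_type"] == "ball"]
    ball_dup = balls.duplicated(["half", "frame"])
    if ball_dup.any():
        row = balls[ball_dup].iloc[0]
        raise IntegrityError(
            f"duplicate ball row at half {row['half']} frame {row['frame']}"
        )

    counts = players.groupby(["half", "frame", "team"], observed=True).size()
    bad = counts[counts != 11]
    if len(bad):
        (half, frame, team) = bad.index[0]
        raise RosterError(
            f"frame with {bad.iloc[0]} {team} players (expected 11) at "
            f"half {half} time_index {frame}"
        )
    # every frame must have both teams and a ball row
    frame_keys = df[["half", "frame"]].drop_duplicates()
    n_ball = len(balls[["half", "frame"]].drop_duplicates())
    if n_ball != len(frame_keys):
        missing_ball = (
            frame_keys.merge(
                balls[["half", "frame"]].drop_duplicates(),
                how="left",
                indicator=True,
            )
            .query("_merge == 'left_only'")
            .iloc[0]
        )
        raise RosterError(
            f"frame without ball row at half {missing_ball['half']} "
            f"time_index {missing_ball['frame']}"
        )
    per_frame_teams = players.groupby(["half", "frame"], observed=True)["team"].nunique()
    if (per_frame_teams != 2).any():
        key = per_frame_teams[per_frame_teams != 2].index[0]
        raise RosterError(f"frame missing a team at half {key[0]} time_index {key[1]}")

    for half, grp in balls.groupby("half"):
        f = grp["frame"].to_numpy()
        if len(f) > 1 and not (np.diff(np.sort(f)) > 0).all():
            raise IntegrityError(f"time_index not strictly increasing in half {half}")

    flag_n = df.groupby(["half", "frame"], observed=True)[
        ["ball_status", "possession"]
    ].nunique()
    if (flag_n > 1).any().any():
        key = flag_n[(flag_n > 1).any(axis=1)].index[0]
        raise IntegrityError(
            f"inconsistent flags within frame at half {key[0]} time_index {key[1]}"
        )


# ---------------------------------------------------------------------------
# metadata I/O (YAML)


def write_metadata(meta: MatchMetadata, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "pitch_length": meta.pitch_length,
        "pitch_width": meta.pitch_width,
        "frame_rate": meta.frame_rate,
        "home_goal_center": list(meta.home_goal_center),
        "away_goal_center": list(meta.away_goal_center),
        "attack_direction": {
            team: {half: meta.attack_direction[(team, half)] for half in (1, 2)}
            for team in TEAMS
        },
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_metadata(path: str | Path) -> MatchMetadata:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        attack = {
            (team, int(half)): int(sign)
            for team, halves in raw["attack_direction"].items()
            for half, sign in halves.items()
        }
        return MatchMetadata(
            pitch_length=float(raw["pitch_length"]),
            pitch_width=float(raw["pitch_width"]),
            frame_rate=float(raw["frame_rate"]),
            home_goal_center=tuple(raw["home_goal_center"]),
            away_goal_center=tuple(raw["away_goal_center"]),
            attack_direction=attack,
        )
    except KeyError as exc:  # pragma: no cover - trivial mapping
        raise SchemaError(f"metadata missing key: {exc}") from exc


# ---------------------------------------------------------------------------
# tracking I/O


def read_tracking(path: str | Path, metadata_path: str | Path) -> MatchDataset:
    """Read and validate a tracking CSV plus its metadata file."""
    meta = read_metadata(metadata_path)
    df = pd.read_csv(path, dtype={"player_id": "string"}, float_precision="round_trip")
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[list(TRACKING_COLUMNS)]
    df["player_id"] = df["player_id"].fillna("").astype(str)
    df["team"] = df["team"].fillna("none").astype(str)
    ds = MatchDataset(metadata=meta, frames=df)
    if len(df):
        validate(ds)
    return ds


def write_tracking(
    ds: MatchDataset,
    path: str | Path,
    metadata_path: str | Path | None = None,
    quantize: bool = True,
) -> Path:
    """Write a dataset to the tracking CSV dialect.

    Positions are quantized to 0.01 m by default, mirroring the spatial
    resolution of optical tracking feeds; pass ``quantize=False`` to keep
    full float precision.
    """
    path = Path(path)
    df = ds.frames.copy()
    if quantize and len(df):
        df["x_m"] = df["x_m"].round(2)
        df["y_m"] = df["y_m"].round(2)
    df.to_csv(path, index=False)
    if metadata_path is not None:
        write_metadata(ds.metadata, metadata_path)
    return path


# ---------------------------------------------------------------------------
# filtering


def filter_frames(
    ds: MatchDataset,
    status: Literal["alive", "dead", "any"] = "any",
    role_for_team: Literal["with_ball", "without_ball", "any"] = "any",
    team: str | None = None,
    half: int | Literal["any"] = "any",
) -> MatchDataset:
    """Select the subsequence of frames matching all selectors.

    ``role_for_team="with_ball"`` keeps frames where possession equals
    ``team``; ``"without_ball"`` keeps the complement. The result is a valid
    (possibly empty) dataset; selectors compose and the operation is
    idempotent.
    """
    if role_for_team != "any" and team not in TEAMS:
        raise ValueError("role_for_team requires team='home' or 'away'")
    idx = ds.frame_index().reset_index()
    keep = pd.Series(True, index=idx.index)
    if status != "any":
        keep &= idx["ball_status"] == status
    if role_for_team == "with_ball":
        keep &= idx["possession"] == team
    elif role_for_team == "without_ball":
        keep &= idx["possession"] != team
    if half != "any":
        keep &= idx["half"] == int(half)
    kept = idx.loc[keep, ["half", "frame"]]
    merged = ds.frames.merge(kept, on=["half", "frame"], how="inner")
    return MatchDataset(metadata=ds.metadata, frames=merged)
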