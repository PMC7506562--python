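"""Angular binning of PBGA series: linkage profiles, team configurations, hulls.

Two bin grids over the PBGA domain [0, π]:

* 18 bins of π/18 (10°) each — per-player relative-frequency profiles that
  show how much of the match each player spends at each angle to the
  ball-goal axis, split by possession role (interpersonal linkages);
* 3 bins of π/3 (60°) each — per-frame team configuration codes (TCC)
  counting players in the front / lateral / back sectors (degeneracy):
  Front Support/Cover [0, π/3), Lateral Support/Cover [π/3, 2π/3), Back
  Support/Cover [2π/3, π]. "Support" when the team has the ball, "cover"
  when it does not.

All intervals are half-open [lo, hi) with the final interval closed at π;
the nominal closed-interval sector definitions overlap at boundaries, and
a deterministic disjoint partition is required (the measure-zero boundary
choice is statistically inconsequential).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .geometry import PhaseSeries
from .tracking_io import MatchDataset, filter_frames

__all__ = [
    "TCC_EDGES",
    "AngleHistogram",
    "SubgroupHull",
    "pbga_relative_frequency",
    "team_configuration_code",
    "subgroup_hulls",
]

#: Sector edges of the 3-bin team-configuration grid.
TCC_EDGES = (0.0, np.pi / 3, 2 * np.pi / 3, np.pi)

#: Subgroup labels in printed TCC order (e.g. "6-4-1" = 6 front, 4 lateral, 1 back).
TCC_BINS = ("FS/C", "LS/C", "BS/C")


@dataclass
class AngleHistogram:
    """Per-player PBGA occupancy histogram for one role.

    ``counts`` is players × bins (raw frame counts — the "relative
    frequency" axis of polar profile plots); ``proportions`` divides each
    player's row by that player's contributing frames. Undefined
    (degenerate-geometry) phases do not contribute.
    """

    team: str
    role: str
    players: list
    bin_edges: np.ndarray
    counts: np.ndarray
    total_frames: np.ndarray

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_frames[:, None] > 0,
                self.counts / np.maximum(self.total_frames[:, None], 1),
                0.0,
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready table: player_id, role, bin_lo_rad, bin_hi_rad, count, proportion."""
        rows = []
        prop = self.proportions
        for i, pid in enumerate(self.players):
            for b in range(self.counts.shape[1]):
                rows.append(
                    {
                        "player_id": pid,
                        "role": self.role,
                        "bin_lo_rad": self.bin_edges[b],
                        "bin_hi_rad": self.bin_edges[b + 1],
                        "count": int(self.counts[i, b]),
                        "proportion": prop[i, b],
                    }
                )
        return pd.DataFrame(rows)


def _bin_counts(theta: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram rows of ``theta`` (players axis last) on half-open bins.

    np.histogram implements exactly the [lo, hi) / last-closed rule.
    """
    n_players = theta.shape[1]
    counts = np.empty((n_players, len(edges) - 1), dtype=int)
    for k in range(n_players):
        col = theta[:, k]
        counts[k], _ = np.histogram(col[~np.isnan(col)], bins=edges)
    return counts


def pbga_relative_frequency(
    pbga: PhaseSeries,
    ds: MatchDataset,
    role: str,
    n_bins: int = 18,
) -> AngleHistogram:
    """Per-player PBGA histogram over alive frames in the stated role.

    Counts sum to each player's number of qualifying frames with a defined
    angle; zero qualifying frames give an all-zero histogram.
    """
    if role not in ("with_ball", "without_ball"):
        raise ValueError(f"role must be with_ball or without_ball, got {role!r}")
    sub = filter_frames(ds, status="alive", role_for_team=role, team=pbga.team)
    keys = sub.frame_index().index
    theta = pbga.theta.loc[pbga.theta.index.isin(keys)]
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    arr = theta.to_numpy(dtype=float)
    counts = _bin_counts(arr, edges)
    totals = (~np.isnan(arr)).sum(axis=0)
    return AngleHistogram(
        team=pbga.team,
        role=role,
        players=list(theta.columns),
        bin_edges=edges,
        counts=counts,
        total_frames=totals,
    )


def team_configuration_code(pbga: PhaseSeries, ds: MatchDataset) -> pd.DataFrame:
    """Per-frame team configuration codes over alive frames.

    Returns a frame indexed by (half, frame) with columns ``fs_c``,
    ``ls_c``, ``bs_c`` (player counts per sector, summing to the number of
    defined phases — 11 in normal play) and ``role_label`` (support when
    the team has possession, cover otherwise).
    """
    alive = filter_frames(ds, status="alive")
    keys = alive.frame_index()
    theta = pbga.theta.loc[pbga.theta.index.isin(keys.index)]
    arr = theta.to_numpy(dtype=float)
    edges = np.asarray(TCC_EDGES)
    # vectorized per-frame sector counts with the half-open/last-closed rule
    idx = np.searchsorted(edges, arr, side="right") - 1
    idx = np.where(arr == edges[-1], len(edges) - 2, idx)
    defined = ~np.isnan(arr)
    counts = np.stack(
        [((idx == b) & defined).sum(axis=1) for b in range(3)], axis=1
    )
    poss = keys.loc[theta.index, "possession"].to_numpy()
    out = pd.DataFrame(
        {
            "team": pbga.team,
            "role_label": np.where(poss == pbga.team, "support", "cover"),
            "fs_c": counts[:, 0],
            "ls_c": counts[:, 1],
            "bs_c": counts[:, 2],
        },
        index=theta.index,
    )
    return out


@dataclass
class SubgroupHull:
    """Planar convex hull of one TCC subgroup's player positions.

    ``vertices`` are hull vertices in counter-clockwise order (a subset of
    member positions); subgroups of fewer than three members, or collinear
    ones, are flagged degenerate and keep their raw points as vertices.
    """

    label: str
    members: list
    vertices: np.ndarray
    degenerate: bool

    def contains(self, point, tol: float = 1e-9) -> bool:
        """Point inside or on the hull (half-plane test; degenerate: on the set)."""
        p = np.asarray(point, dtype=float)
        v = self.vertices
        if self.degenerate:
            if len(v) == 1:
                return bool(np.linalg.norm(p - v[0]) <= tol)
            a, b = v[0], v[-1]
            ab = b - a
            t = np.dot(p - a, ab) / max(np.dot(ab, ab), tol)
            proj = a + np.clip(t, 0, 1) * ab
            return bool(np.linalg.norm(p - proj) <= tol)
        n = len(v)
        for i in range(n):
            a, b = v[i], v[(i + 1) % n]
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            if cross < -tol:
                return False
        return True


def subgroup_hulls(
    ds: MatchDataset, pbga: PhaseSeries, half: int, frame: int
) -> dict[str, SubgroupHull]:
    """Convex hull of each non-empty TCC subgroup in one frame.

    Subgroup membership uses the same sector assignment as
    :func:`team_configuration_code`.
    """
    key = (half, frame)
    if key not in pbga.theta.index:
        raise KeyError(f"frame {key} not in phase series")
    theta = pbga.theta.loc[key]
    players, pos = ds.player_positions(pbga.team)
    fidx = ds.frame_index().index
    loc = fidx.get_loc(key)
    positions = pd.DataFrame(pos[loc], index=players, columns=["x", "y"])
    edges = np.asarray(TCC_EDGES)
    out: dict[str, SubgroupHull] = {}
    for b, label in enumerate(TCC_BINS):
        lo, hi = edges[b], edges[b + 1]
        if b == 2:
            member_mask = (theta >= lo) & (theta <= hi)
        else:
            member_mask = (theta >= lo) & (theta < hi)
        members = list(theta.index[member_mask.fillna(False)])
        if not members:
            continue
        pts = positions.loc[members].to_numpy()
        if len(pts) < 3:
            out[label] = SubgroupHull(label, members, pts.copy(), degenerate=True)
            continue
        try:
            hull = ConvexHull(pts)
            out[label] = SubgroupHull(
                label, members, pts[hull.vertices], degenerate=False
            )
        except QhullError:  # collinear members
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            out[label] = SubgroupHull(label, members, pts[order], degenerate=True)
    return out


def hulls_to_geojson(hulls: dict[str, SubgroupHull]) -> dict:
    """GeoJSON-style FeatureCollection of subgroup hull polygons."""
    features = []
    for label, h in hulls.items():
        ring = [list(map(float, v)) for v in h.vertices]
        if not h.degenerate and ring:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "subgroup": label,
                    "members": [str(m) for m in h.members],
                    "degenerate": h.degenerate,
                },
                "geometry": {
                    "type": "Polygon" if not h.degenerate else "MultiPoint",
                    "coordinates": [ring] if not h.degenerate else ring,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
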