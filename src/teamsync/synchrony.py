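"""Cluster-phase synchrony from PBGA series.

A team of n players is treated as a population of phase oscillators with
phases θ_k(t) ∈ [0, π]. The Kuramoto order parameter

    r'(t) e^{iψ(t)} = (1/n) Σ_k e^{iθ_k(t)}

gives per-frame cluster amplitude r' ∈ [0, 1] (1 = perfect synchrony,
0 = full cancellation) and cluster mean phase ψ. The player-team relative
phase Φ_k(t) = θ_k(t) − ψ(t) measures each player's deviation from the
team, the basis of reciprocal-compensation analysis.

The complex mean is computed directly from the PBGA phases; no Hilbert
transform is involved anywhere — the phases are geometric, not extracted
from displacement oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .geometry import PhaseSeries, ZoneGrid, assign_zones, default_zone_grid, \
    normalize_attack_direction
from .tracking_io import MatchDataset

__all__ = [
    "SynchronySeries",
    "kuramoto",
    "relative_phase",
    "summarize_synchrony",
    "moving_average",
]


class AlignmentError(ValueError):
    """Frame indices of two series do not match."""


@dataclass
class SynchronySeries:
    """Per-frame order parameter for one team.

    ``data`` is indexed by (half, frame) with columns ``r_prime`` (cluster
    amplitude), ``psi`` (cluster phase, radians) and ``n_defined`` (number
    of non-degenerate phases entering the mean). Frames where every phase
    is undefined carry NaN r'/ψ and n_defined = 0.
    """

    team: str
    data: pd.DataFrame

    @property
    def r_prime(self) -> pd.Series:
        return self.data["r_prime"]

    @property
    def psi(self) -> pd.Series:
        return self.data["psi"]


def kuramoto(
    pbga: PhaseSeries,
    psi_convention: Literal["circular", "arithmetic"] = "circular",
) -> SynchronySeries:
    """Kuramoto order parameter of a PBGA series.

    Undefined (NaN) phases are dropped from the frame's complex mean with
    n reduced accordingly, so one degenerate sample cannot poison the
    series. ``psi_convention="circular"`` (default, the standard
    cluster-phase definition) takes ψ as the argument of the complex mean;
    ``"arithmetic"`` replaces it with the plain mean of the defined θ_k.
    """
    theta = pbga.theta.to_numpy(dtype=float)
    if theta.shape[1] == 0:
        raise ValueError("empty team: no players in the phase series")
    defined = ~np.isnan(theta)
    n_def = defined.sum(axis=1)
    z = np.where(defined, np.exp(1j * np.where(defined, theta, 0.0)), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = z.sum(axis=1) / np.where(n_def > 0, n_def, np.nan)
    r = np.abs(mean)
    if psi_convention == "circular":
        psi = np.angle(mean)
    elif psi_convention == "arithmetic":
        psi = np.nanmean(np.where(defined, theta, np.nan), axis=1)
    else:
        raise ValueError(f"unknown psi_convention {psi_convention!r}")
    out = pd.DataFrame(
        {"r_prime": r, "psi": psi, "n_defined": n_def.astype(int)},
        index=pbga.theta.index,
    )
    return SynchronySeries(team=pbga.team, data=out)


def relative_phase(pbga: PhaseSeries, sync: SynchronySeries) -> pd.DataFrame:
    """Player-team relative phase Φ_k(t) = θ_k(t) − ψ(t).

    With θ ∈ [0, π] and ψ ∈ [0, π] the result lies in [−π, π] already and
    is reported without further wrapping. Indexed like the phase series,
    one column per player.
    """
    if not pbga.theta.index.equals(sync.data.index):
        raise AlignmentError("phase series and synchrony series are misaligned")
    return pbga.theta.sub(sync.data["psi"], axis=0)


def moving_average(sync: SynchronySeries, window: int) -> SynchronySeries:
    """Centered moving average of r' for visualization (off by default)."""
    data = sync.data.copy()
    data["r_prime"] = data["r_prime"].rolling(window, center=True, min_periods=1).mean()
    return SynchronySeries(team=sync.team, data=data)


_GROUP_LEVELS = {
    "team": ["away", "home"],
    "half": [1, 2],
    "role": ["with_ball", "without_ball"],
}


def summarize_synchrony(
    sync: SynchronySeries,
    ds: MatchDataset,
    group_by: Iterable[str] = ("team", "half", "role"),
    grid: ZoneGrid | None = None,
) -> pd.DataFrame:
    """Mean/SD of r' per group over alive frames only.

    ``group_by`` is any subset of {team, half, role, lateral_zone,
    longitudinal_zone}; role is with_ball when possession equals the
    analyzed team. Zone grouping indexes the ball position (after
    attack-direction normalization) on ``grid``, oriented so "O" is
    nearest the goal attacked by the team in possession. Groups with no
    frames appear with n_frames 0 and NaN mean.
    """
    group_by = list(group_by)
    allowed = {"team", "half", "role", "lateral_zone", "longitudinal_zone"}
    unknown = set(group_by) - allowed
    if unknown:
        raise ValueError(f"unknown group keys: {sorted(unknown)}")

    idx = ds.frame_index()
    table = sync.data.join(idx)
    table = table[table["ball_status"] == "alive"].copy()
    table["team"] = pd.Categorical([sync.team] * len(table), _GROUP_LEVELS["team"])
    table["half"] = pd.Categorical(
        table.index.get_level_values("half"), _GROUP_LEVELS["half"]
    )
    table["role"] = pd.Categorical(
        np.where(table["possession"] == sync.team, "with_ball", "without_ball"),
        _GROUP_LEVELS["role"],
    )
    if "lateral_zone" in group_by or "longitudinal_zone" in group_by:
        norm = normalize_attack_direction(ds)
        grid = grid or default_zone_grid(norm.metadata)
        ball = norm.ball_positions()
        fi = norm.frame_index()
        sign = np.array(
            [
                norm.metadata.attack_direction[(p, int(h))]
                for p, h in zip(fi["possession"], fi.index.get_level_values("half"))
            ]
        )
        codes, _ = assign_zones(ball.to_numpy(), grid, attack_sign=sign)
        zones = pd.DataFrame(
            {
                "longitudinal_zone": [c.split("-")[0] for c in codes],
                "lateral_zone": [c.split("-")[1] for c in codes],
            },
            index=ball.index,
        )
        table = table.join(zones)
        from .geometry import LAT_LABELS, LONG_LABELS

        table["longitudinal_zone"] = pd.Categorical(
            table["longitudinal_zone"], list(LONG_LABELS)
        )
        table["lateral_zone"] = pd.Categorical(table["lateral_zone"], list(LAT_LABELS))

    grouped = table.reset_index(drop=True).groupby(group_by, observed=False)["r_prime"]
    out = grouped.agg(mean="mean", sd="std", n_frames="count").reset_index()
    return out
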