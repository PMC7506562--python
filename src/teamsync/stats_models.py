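"""Linear mixed-effects analysis of per-frame synchrony.

The response is the per-frame cluster amplitude r'. Fixed effects are any
subset of {team, role, lateral_zone, longitudinal_zone} plus pairwise
interactions; half enters as a random intercept. Models are fit by maximum
likelihood so that nested models can be compared with likelihood-ratio
chi-square tests against explicit null models (the same model with one
term removed).

Reference levels are fixed at away team, with_ball role, D longitudinal
zone and L lateral zone, so that positive coefficients read as "home
increases synchrony relative to away" and "losing the ball increases
synchrony", the conventional phrasing for these effects.

Frames are treated as independent observations; serial autocorrelation of
r' is not modelled (a documented limitation — standard errors are
anti-conservative for strongly autocorrelated series).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .geometry import LAT_LABELS, LONG_LABELS, ZoneGrid, assign_zones, \
    default_zone_grid, normalize_attack_direction
from .synchrony import SynchronySeries
from .tracking_io import MatchDataset

__all__ = ["LmmSpec", "LmmResult", "build_model_table", "fit_lmm", "zone_effect_table"]

logger = logging.getLogger(__name__)

_REFERENCE = {
    "team": "away",
    "role": "with_ball",
    "longitudinal_zone": "D",
    "lateral_zone": "L",
}
_LEVELS = {
    "team": ["away", "home"],
    "role": ["with_ball", "without_ball"],
    "longitudinal_zone": list(LONG_LABELS),
    "lateral_zone": list(LAT_LABELS),
}


class DesignError(ValueError):
    """Singular or degenerate fixed-effect design."""


@dataclass
class LmmSpec:
    """Specification of one mixed model.

    ``fixed`` lists main effects; ``interactions`` lists pairs (each a
    2-tuple of fixed-effect names). ``random`` names the grouping column of
    the random intercept. Estimation is maximum likelihood throughout.
    """

    fixed: Sequence[str] = ("team", "role")
    interactions: Sequence[tuple[str, str]] = ()
    random: str = "half"

    def all_pairs(self) -> "LmmSpec":
        return LmmSpec(
            fixed=tuple(self.fixed),
            interactions=tuple(itertools.combinations(self.fixed, 2)),
            random=self.random,
        )

    def terms(self) -> list[str]:
        return list(self.fixed) + [f"{a}:{b}" for a, b in self.interactions]


@dataclass
class LmmResult:
    """ML coefficients and per-term likelihood-ratio tests.

    ``coefficients``: term, estimate, se per design column.
    ``lrt``: one row per dropped term with chisq = 2(llf_full − llf_null),
    df = parameter-count difference, and the chi-square p-value.
    """

    coefficients: pd.DataFrame
    lrt: pd.DataFrame
    loglik: float
    n_obs: int
    model_spec: LmmSpec = field(repr=False, default=None)

    def report(self) -> str:
        lines = [f"Linear mixed model (ML), n = {self.n_obs}, logLik = {self.loglik:.2f}", ""]
        lines.append(self.coefficients.to_string(index=False))
        if len(self.lrt):
            lines.append("")
            lines.append("Likelihood-ratio tests vs null models without each term:")
            lines.append(self.lrt.to_string(index=False))
        return "\n".join(lines)


def build_model_table(
    syncs: Iterable[SynchronySeries] | Mapping[str, SynchronySeries],
    ds: MatchDataset,
    grid: ZoneGrid | None = None,
) -> pd.DataFrame:
    """Assemble the regression table: one row per (alive frame, team).

    Columns: r_prime, team, role, half, lateral_zone, longitudinal_zone.
    Zones index the ball position after attack-direction normalization,
    oriented in the attacked-goal frame of the team in possession. Frames
    with undefined r' are dropped with a logged count.
    """
    if isinstance(syncs, Mapping):
        syncs = list(syncs.values())
    else:
        syncs = list(syncs)
    norm = normalize_attack_direction(ds)
    grid = grid or default_zone_grid(norm.metadata)
    fi = norm.frame_index()
    alive = fi["ball_status"] == "alive"
    ball = norm.ball_positions()
    sign = np.array(
        [
            norm.metadata.attack_direction[(p, int(h))]
            for p, h in zip(fi["possession"], fi.index.get_level_values("half"))
        ]
    )
    codes, _ = assign_zones(ball.to_numpy(), grid, attack_sign=sign)
    zone = pd.DataFrame(
        {
            "longitudinal_zone": [c.split("-")[0] for c in codes],
            "lateral_zone": [c.split("-")[1] for c in codes],
        },
        index=fi.index,
    )
    pieces = []
    for sync in syncs:
        t = sync.data.join(fi).join(zone)
        t = t[t["ball_status"] == "alive"].copy()
        t["team"] = sync.team
        t["role"] = np.where(t["possession"] == sync.team, "with_ball", "without_ball")
        t["half"] = t.index.get_level_values("half")
        pieces.append(
            t.reset_index(drop=True)[
                ["r_prime", "team", "role", "half", "lateral_zone", "longitudinal_zone"]
            ]
        )
    table = pd.concat(pieces, ignore_index=True)
    n_bad = int(table["r_prime"].isna().sum())
    if n_bad:
        logger.info("dropping %d rows with undefined r_prime", n_bad)
        table = table.dropna(subset=["r_prime"]).reset_index(drop=True)
    for col, levels in _LEVELS.items():
        table[col] = pd.Categorical(table[col], categories=levels)
    return table


def _design_matrix(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Treatment-coded design with the fixed reference levels."""
    cols = {"Intercept": np.ones(len(table))}
    for term in terms:
        parts = term.split(":")
        dummies = []
        for p in parts:
            if p not in table.columns:
                raise DesignError(f"fixed effect {p!r} not a column of the table")
            present = set(table[p].astype(str))
            if len(present) < 2:
                raise DesignError(f"fixed effect {p!r} has <2 levels present")
            levels = [l for l in _LEVELS.get(p, sorted(table[p].unique())) if l != _REFERENCE.get(p)]
            levels = [l for l in levels if str(l) in present]
            d = {f"{p}[{l}]": (table[p].astype(str) == str(l)).astype(float) for l in levels}
            dummies.append(d)
        if len(parts) == 1:
            cols.update(dummies[0])
        else:
            for (na, va) in dummies[0].items():
                for (nb, vb) in dummies[1].items():
                    cols[f"{na}:{nb}"] = va * vb
    X = pd.DataFrame(cols, index=table.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise DesignError(f"singular design; collinear terms: {bad}")
    return X


def _fit_ml(table: pd.DataFrame, X: pd.DataFrame, random: str):
    """ML fit of a random-intercept model; constant response short-circuits."""
    y = table["r_prime"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return None, 0.0
    model = sm.MixedLM(y, X.to_numpy(), groups=table[random].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = model.fit(reml=False, maxiter=200)
    return fit, float(fit.llf)


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """Fit the mixed model by ML and test each term by likelihood ratio.

    For every term (main effect or interaction) in the spec, the null
    model is the same model with that term's design columns removed; the
    statistic is 2(llf_full − llf_null) on df = number of removed columns.
    A constant response yields zero coefficients and zero statistics.
    """
    terms = spec.terms()
    X_full = _design_matrix(table, terms)
    fit_full, llf_full = _fit_ml(table, X_full, spec.random)

    if fit_full is None:  # constant response: no variance to explain
        coef = pd.DataFrame(
            {"term": X_full.columns, "estimate": 0.0, "se": 0.0}
        )
        coef.loc[coef["term"] == "Intercept", "estimate"] = float(
            table["r_prime"].iloc[0]
        ) if len(table) else 0.0
        lrt = pd.DataFrame(
            {"term": terms, "chisq": 0.0, "df": 0, "p_value": 1.0}
        )
        return LmmResult(coef, lrt, 0.0, len(table), spec)

    k = X_full.shape[1]
    coef = pd.DataFrame(
        {
            "term": X_full.columns,
            "estimate": fit_full.params[:k],
            "se": fit_full.bse[:k],
        }
    )
    rows = []
    for term in terms:
        keep = [t for t in terms if t != term]
        X_null = _design_matrix(table, keep) if keep else _design_matrix(table, [])
        _, llf_null = _fit_ml(table, X_null, spec.random)
        stat = max(0.0, 2.0 * (llf_full - llf_null))
        df = X_full.shape[1] - X_null.shape[1]
        p = float(scipy.stats.chi2.sf(stat, df)) if df > 0 else np.nan
        rows.append({"term": term, "chisq": stat, "df": df, "p_value": p})
    lrt = pd.DataFrame(rows)
    return LmmResult(coef, lrt, llf_full, len(table), spec)


def zone_effect_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean r' per 20-cell zone (longitudinal rows × lateral columns)."""
    pivot = table.pivot_table(
        index="longitudinal_zone",
        columns="lateral_zone",
        values="r_prime",
        aggfunc="mean",
        observed=False,
    )
    return pivot.reindex(index=list(LONG_LABELS), columns=list(LAT_LABELS))
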