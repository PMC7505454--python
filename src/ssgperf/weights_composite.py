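"""Success-correlation indicator weights and composite performance scores.

The weight of each performance indicator is its team-wise Spearman rank
correlation with a game-level success proxy — shots on target for offensive
indicators, shots on target conceded for defensive ones — aggregated across
age-category teams by a DerSimonian-Laird random-effects meta-analysis on
the Fisher-z scale.  The composite offensive/defensive score of a player is
the weight-weighted sum of the player's within-team z-scored indicator
scores; the player's own shots-on-target rate enters the offensive composite
with a fixed weight of 1, and the defensive weighted sum is multiplied by -1
so that a higher score always means better performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ssgperf.data_model import AERIAL_LABELS, CODING_SCHEME, OUTCOME_SUCCESS

Z975 = float(stats.norm.ppf(0.975))

#: Composite-formula weights as published for the reference academy study
#: (aggregated indicator-vs-proxy correlations); usable instead of freshly
#: derived weights via ``weights_source="reference"``.
REFERENCE_WEIGHTS = {
    "pass_forward": 0.21,
    "offensive_duel": 0.17,
    "chance_created": 0.50,
    "shot_on_target": 1.0,
    "defensive_duel": -0.14,
    "applying_pressure": -0.11,
    "pass_interception": -0.06,
}

OFFENSIVE_COMPOSITE = ("pass_forward", "offensive_duel", "chance_created", "shot_on_target")
DEFENSIVE_COMPOSITE = ("defensive_duel", "pass_interception", "applying_pressure")


@dataclass
class MetaCorrelation:
    """Random-effects aggregate of per-group Spearman correlations."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    k: int
    n_total: int
    group_r: dict = field(default_factory=dict)
    group_n: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "tau2": self.tau2,
            "k": self.k,
            "n_total": self.n_total,
            "group_r": self.group_r,
            "group_n": self.group_n,
            "skipped": self.skipped,
        }


def _fisher_z(r: float, eps: float = 1e-6) -> float:
    # |r| = 1 can occur in small groups; clamp to keep the transform finite
    return float(np.arctanh(np.clip(r, -1 + eps, 1 - eps)))


def meta_spearman(groups: dict, min_n: int = 4, tau2_estimator: str = "DL") -> MetaCorrelation:
    """Aggregate per-group Spearman correlations by random-effects meta-analysis.

    Parameters
    ----------
    groups
        Mapping group label -> ``(x, y)`` paired samples.  Pairs with a
        missing value in either variable are dropped; groups with fewer than
        ``min_n`` complete pairs or zero variance in either variable are
        skipped with a warning.
    tau2_estimator
        ``"DL"`` (DerSimonian-Laird, default, non-iterative) or ``"REML"``
        (iterated Paule-Mandel-style REML solve).

    Notes
    -----
    Each group's coefficient (mid-rank ties) is Fisher-z transformed with
    variance 1/(n-3); the between-group variance tau^2 is estimated on that
    scale; inverse-variance weights 1/(1/(n-3)+tau^2) give the pooled z,
    back-transformed with a normal-theory 95% CI and two-sided p-value.
    """
    zs, vs, labels, rs, ns = [], [], [], {}, {}
    skipped = []
    for label, (x, y) in groups.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        n = len(x)
        if n < min_n:
            skipped.append((label, f"n={n} < {min_n}"))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"group {label!r} skipped: zero variance", stacklevel=2)
            skipped.append((label, "zero variance"))
            continue
        r = float(stats.spearmanr(x, y).statistic)
        zs.append(_fisher_z(r))
        vs.append(1.0 / (n - 3))
        labels.append(label)
        rs[label] = r
        ns[label] = n
    if not zs:
        raise ValueError("no usable groups for meta-analysis")

    z = np.array(zs)
    v = np.array(vs)
    k = len(z)
    w = 1.0 / v
    z_fe = float((w * z).sum() / w.sum())
    if k == 1:
        tau2 = 0.0
    elif tau2_estimator == "DL":
        q = float((w * (z - z_fe) ** 2).sum())
        c = float(w.sum() - (w**2).sum() / w.sum())
        tau2 = max(0.0, (q - (k - 1)) / c)
    elif tau2_estimator == "REML":
        tau2 = _reml_tau2(z, v)
    else:
        raise ValueError(f"unknown tau2_estimator {tau2_estimator!r}")

    ws = 1.0 / (v + tau2)
    z_bar = float((ws * z).sum() / ws.sum())
    se = float(1.0 / np.sqrt(ws.sum()))
    p = float(2 * stats.norm.sf(abs(z_bar / se)))
    return MetaCorrelation(
        r=float(np.tanh(z_bar)),
        ci_low=float(np.tanh(z_bar - Z975 * se)),
        ci_high=float(np.tanh(z_bar + Z975 * se)),
        p=p,
        tau2=float(tau2),
        k=k,
        n_total=int(sum(ns.values())),
        group_r=rs,
        group_n=ns,
        skipped=skipped,
    )


def _reml_tau2(z: np.ndarray, v: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> float:
    """Fixed-point REML estimate of the between-group variance tau^2."""
    tau2 = max(0.0, float(np.var(z, ddof=1) - np.mean(v)))
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float((w * z).sum() / w.sum())
        # standard REML fixed point; 1/sum(w) corrects for estimating mu
        new = max(
            0.0,
            float((w**2 * ((z - mu) ** 2 - v)).sum() / (w**2).sum())
            + 1.0 / float(w.sum()),
        )
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def team_game_indicator_totals(
    events: pd.DataFrame,
    games: pd.DataFrame,
    binary_performance: str = "count",
) -> pd.DataFrame:
    """Per (game, side) indicator performance paired with the success proxy.

    For count-type indicators the side's performance in a game is its event
    count; for binary indicators it is the count of successful events by
    default (``binary_performance="proportion"`` uses the success fraction
    instead).  Each row carries the side's own ``shots_on_target`` and the
    opposing side's as ``shots_on_target_conceded``.  Only sides with at
    least one coded event are scored (in the 11-vs-11 format the opponent is
    typically uncoded and contributes only its shot count); games lacking a
    second side in the games table are rejected.
    """
    if binary_performance not in ("count", "proportion"):
        raise ValueError("binary_performance must be 'count' or 'proportion'")

    sides = games[["game_id", "format", "team", "side_team_id", "shots_on_target"]].copy()
    n_sides = sides.groupby("game_id")["side_team_id"].nunique()
    bad = n_sides[n_sides != 2].index.tolist()
    if bad:
        raise ValueError(f"game(s) without exactly two sides: {bad[:10]}")

    conceded = sides.merge(
        sides[["game_id", "side_team_id", "shots_on_target"]],
        on="game_id",
        suffixes=("", "_opp"),
    )
    conceded = conceded[conceded["side_team_id"] != conceded["side_team_id_opp"]]
    conceded = conceded.rename(columns={"shots_on_target_opp": "shots_on_target_conceded"})
    conceded = conceded.drop(columns=["side_team_id_opp"])

    ev = events.copy()
    is_binary = ev["indicator"].map(lambda n: CODING_SCHEME[n].outcome_type) == "binary"
    ev["success"] = (ev["outcome"] == OUTCOME_SUCCESS).astype(int)
    # performance value per event: 1 for count indicators, success flag for binary
    ev["value"] = np.where(is_binary, ev["success"], 1)

    grouped = ev.groupby(["game_id", "side_team_id", "indicator"], observed=True).agg(
        value=("value", "sum"), attempts=("value", "size")
    )
    if binary_performance == "proportion":
        binary_names = [n for n, i in CODING_SCHEME.items() if i.outcome_type == "binary"]
        idx = grouped.index.get_level_values("indicator").isin(binary_names)
        grouped.loc[idx, "value"] = (
            grouped.loc[idx, "value"] / grouped.loc[idx, "attempts"]
        )
    wide = grouped["value"].unstack("indicator", fill_value=0).reset_index()

    coded_sides = conceded.merge(
        ev[["game_id", "side_team_id"]].drop_duplicates(),
        on=["game_id", "side_team_id"],
        how="inner",
    )
    out = coded_sides.merge(wide, on=["game_id", "side_team_id"], how="left")
    ind_cols = [c for c in out.columns if c in CODING_SCHEME]
    out[ind_cols] = out[ind_cols].fillna(0)
    return out


def derive_weights(
    totals: pd.DataFrame,
    min_n: int = 4,
    tau2_estimator: str = "DL",
    exclude: tuple[str, ...] = AERIAL_LABELS,
) -> tuple[dict, dict]:
    """Indicator weights from team-wise indicator-vs-proxy correlations.

    Offensive indicators are correlated with the side's own shots on target,
    defensive indicators with shots on target conceded, within each
    team-by-format group (units = game-sides; grouping by format as well as
    team keeps the large per-game event totals of 11-vs-11 halves from
    inducing a spurious positive scale correlation), then aggregated by
    :func:`meta_spearman`.  Shots on target itself carries the fixed
    weight 1 (it *is* the proxy).

    Returns
    -------
    (weights, provenance)
        ``weights`` maps indicator -> aggregated coefficient; ``provenance``
        maps indicator -> :class:`MetaCorrelation` details.
    """
    ind_cols = [
        c for c in totals.columns if c in CODING_SCHEME and c not in exclude
    ]
    weights: dict[str, float] = {}
    provenance: dict[str, dict] = {}
    for ind in ind_cols:
        if ind == "shot_on_target":
            weights[ind] = 1.0
            provenance[ind] = {"fixed": True}
            continue
        proxy = (
            "shots_on_target"
            if CODING_SCHEME[ind].side == "offense"
            else "shots_on_target_conceded"
        )
        groups = {
            f"{team}/{fmt}": (grp[ind].to_numpy(float), grp[proxy].to_numpy(float))
            for (team, fmt), grp in totals.groupby(["team", "format"])
        }
        try:
            meta = meta_spearman(groups, min_n=min_n, tau2_estimator=tau2_estimator)
        except ValueError as err:
            warnings.warn(f"indicator {ind!r} omitted from weights: {err}", stacklevel=2)
            continue
        weights[ind] = meta.r
        provenance[ind] = meta.as_dict()
    return weights, provenance


def _zscore_within_team(scores: pd.DataFrame, teams: pd.Series) -> pd.DataFrame:
    """Within-team z-scores (sample SD); SD=0 maps to z=0 with a warning."""
    out = scores.copy().astype(float)
    for team, idx in scores.groupby(teams).groups.items():
        grp = scores.loc[idx]
        if len(grp) < 2:
            raise ValueError(f"team {team!r} has a single player: z-score undefined")
        mean = grp.mean()
        sd = grp.std(ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"team {team!r}: zero SD for {list(sd.index[zero])}; z set to 0",
                stacklevel=3,
            )
        sd = sd.replace(0, np.inf)  # (x - mean)/inf -> 0
        out.loc[idx] = (grp - mean) / sd
    return out


def composite_scores(
    scores: pd.DataFrame,
    weights: dict | None = None,
    teams: pd.Series | None = None,
) -> pd.DataFrame:
    """Composite offensive and defensive scores per player.

    Parameters
    ----------
    scores
        Wide table indexed by ``player_id`` with one column per indicator
        score (posterior logits for binary indicators, per-bout rates for
        count indicators); NaN marks a player lacking that indicator.
    weights
        Indicator -> weight mapping (defaults to :data:`REFERENCE_WEIGHTS`).
        ``shot_on_target`` is forced to weight 1.
    teams
        Team label per player (aligned with ``scores.index``).

    Returns
    -------
    DataFrame indexed by player_id with columns ``offensive`` and
    ``defensive``; a player missing any indicator of a composite gets NaN
    for that composite (they are dropped from analyses using it), mirroring
    the handling of players without duel events.
    """
    if weights is None:
        weights = dict(REFERENCE_WEIGHTS)
    else:
        weights = dict(weights)
    weights["shot_on_target"] = 1.0
    if teams is None:
        raise ValueError("teams must be supplied for within-team z-scoring")
    teams = teams.reindex(scores.index)

    cols = [c for c in scores.columns if c in set(OFFENSIVE_COMPOSITE + DEFENSIVE_COMPOSITE)]
    z = _zscore_within_team(scores[cols], teams)

    out = pd.DataFrame(index=scores.index)
    for name, members, sign in (
        ("offensive", OFFENSIVE_COMPOSITE, 1.0),
        ("defensive", DEFENSIVE_COMPOSITE, -1.0),
    ):
        missing_cols = [m for m in members if m not in z.columns]
        if missing_cols:
            raise ValueError(f"missing indicator column(s) for {name} composite: {missing_cols}")
        contrib = sum(weights[m] * z[m] for m in members)
        out[name] = sign * contrib
    return out
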