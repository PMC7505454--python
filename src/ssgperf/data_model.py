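"""Event-data schema, coding scheme, I/O, player exclusion and inter-rater QC.

The unit of observation is one coded on-ball event: a player of a known
age-category team performs an action of one of eleven indicator types in a
game of one of two formats (``SSG`` = 7-vs-7 small-sided game, ``M11`` =
11-vs-11 match half).  Indicators are either *binary* (each event carries a
successful/unsuccessful outcome) or *count* type (the occurrence itself is
the datum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FORMATS = ("SSG", "M11")

OUTCOME_SUCCESS = "success"
OUTCOME_FAILURE = "failure"
OUTCOME_NA = "not_applicable"


class SchemaError(ValueError):
    """Raised when an input file violates the documented schema."""


@dataclass(frozen=True)
class Indicator:
    """One performance-indicator type of the coding scheme.

    Parameters
    ----------
    name
        Canonical label, e.g. ``"pass_forward"``.
    side
        ``"offense"`` or ``"defense"``.
    outcome_type
        ``"binary"`` (successful/unsuccessful) or ``"count"`` (counted when
        it occurs; the event has no outcome).
    merged
        True for labels produced only by :func:`merge_indicators`
        (``offensive_duel``, ``defensive_duel``); these never appear in
        input files.
    """

    name: str
    side: str
    outcome_type: str
    merged: bool = False


#: The coding scheme: every raw label maps to exactly one side and one
#: outcome type.  ``offensive_duel``/``defensive_duel`` exist only as merge
#: products.
CODING_SCHEME: dict[str, Indicator] = {
    ind.name: ind
    for ind in [
        Indicator("pass_forward", "offense", "binary"),
        Indicator("dribble", "offense", "binary"),
        Indicator("take_on", "offense", "binary"),
        Indicator("chance_created", "offense", "count"),
        Indicator("shot_on_target", "offense", "count"),
        Indicator("offensive_aerial_duel", "offense", "binary"),
        Indicator("tackle", "defense", "binary"),
        Indicator("staying_in_front", "defense", "binary"),
        Indicator("applying_pressure", "defense", "count"),
        Indicator("pass_interception", "defense", "count"),
        Indicator("defensive_aerial_duel", "defense", "binary"),
        Indicator("offensive_duel", "offense", "binary", merged=True),
        Indicator("defensive_duel", "defense", "binary", merged=True),
    ]
}

RAW_LABELS = tuple(n for n, i in CODING_SCHEME.items() if not i.merged)

#: raw label -> merged label, for the player-quantification view
MERGE_MAP = {
    "dribble": "offensive_duel",
    "take_on": "offensive_duel",
    "tackle": "defensive_duel",
    "staying_in_front": "defensive_duel",
}

#: aerial duels are validated on input but dropped from individual player
#: quantification (too sparse at the individual level in the SSG format)
AERIAL_LABELS = ("offensive_aerial_duel", "defensive_aerial_duel")

#: count-type indicators scored as rate statistics
COUNT_INDICATORS = tuple(
    n for n, i in CODING_SCHEME.items() if i.outcome_type == "count"
)

#: binary indicators scored through the random-intercept success model
#: (merged view, aerials excluded)
MODEL_INDICATORS = ("pass_forward", "offensive_duel", "defensive_duel")

EVENT_COLUMNS = [
    "game_id",
    "format",
    "team",
    "side_team_id",
    "player_id",
    "indicator",
    "outcome",
]
ROSTER_COLUMNS = [
    "player_id",
    "team",
    "minutes_ssg",
    "minutes_m11",
    "n_ssg_played",
    "sprint_10m",
    "sprint_30m",
    "isrt_tracks",
    "agility_left",
    "agility_right",
]
GAME_COLUMNS = ["game_id", "format", "team", "side_team_id", "shots_on_target"]

TEST_COLUMNS = ["sprint_10m", "sprint_30m", "isrt_tracks", "agility_mean"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _bad_rows(df: pd.DataFrame, mask: pd.Series, what: str) -> None:
    """Raise a SchemaError quoting the offending 1-based data-row numbers."""
    if mask.any():
        rows = (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # +2: header line
        raise SchemaError(f"{what} (file line(s) {rows[:20]}{'...' if len(rows) > 20 else ''})")


def validate_events(events: pd.DataFrame, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate an event table against the coding scheme.

    Enforces: known raw indicator labels, ``outcome`` present exactly for
    binary indicators, a consistent (format, team) per game, and — when a
    roster is supplied — referential integrity of ``player_id``.
    Returns a normalised copy (count-indicator outcomes set to
    ``"not_applicable"``).
    """
    _require_columns(events, EVENT_COLUMNS, "events")
    ev = events.loc[:, EVENT_COLUMNS].copy()
    ev["outcome"] = ev["outcome"].fillna("").astype(str).str.strip()

    _bad_rows(ev, ~ev["format"].isin(FORMATS), "unknown game format")
    known = ev["indicator"].isin(RAW_LABELS)
    _bad_rows(ev, ~known, "unknown or merged indicator label in input")

    otype = ev["indicator"].map(lambda n: CODING_SCHEME[n].outcome_type)
    is_binary = otype == "binary"
    _bad_rows(
        ev,
        is_binary & ~ev["outcome"].isin([OUTCOME_SUCCESS, OUTCOME_FAILURE]),
        "binary indicator requires outcome success|failure",
    )
    _bad_rows(
        ev,
        ~is_binary & ~ev["outcome"].isin(["", OUTCOME_NA]),
        "outcome given for a count indicator",
    )
    ev.loc[~is_binary, "outcome"] = OUTCOME_NA

    per_game = ev.groupby("game_id")[["format", "team"]].nunique()
    bad_games = per_game[(per_game > 1).any(axis=1)].index.tolist()
    if bad_games:
        raise SchemaError(f"game(s) with inconsistent format/team: {bad_games[:10]}")

    if roster is not None:
        _bad_rows(ev, ~ev["player_id"].isin(roster["player_id"]), "unknown player_id")
    return ev


def load_roster(path) -> pd.DataFrame:
    """Read and validate ``roster.csv``; adds ``agility_mean`` (mean of the
    left and right trial, NaN when either is missing)."""
    roster = pd.read_csv(path, dtype={"player_id": str, "team": str})
    _require_columns(roster, ROSTER_COLUMNS, "roster")
    if roster["player_id"].duplicated().any():
        dup = roster.loc[roster["player_id"].duplicated(), "player_id"].tolist()
        raise SchemaError(f"duplicate player_id in roster: {dup}")
    _bad_rows(roster, roster["minutes_ssg"] < 0, "negative minutes_ssg")
    _bad_rows(roster, roster["minutes_m11"] < 0, "negative minutes_m11")
    _bad_rows(roster, roster["n_ssg_played"] < 0, "negative n_ssg_played")
    roster = roster.copy()
    roster["agility_mean"] = roster[["agility_left", "agility_right"]].mean(
        axis=1, skipna=False
    )
    return roster


def load_events(events_path, roster_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``events.csv`` and ``roster.csv`` and cross-validate them."""
    roster = load_roster(roster_path)
    events = pd.read_csv(
        events_path,
        dtype={c: str for c in EVENT_COLUMNS},
        keep_default_na=False,
    )
    return validate_events(events, roster), roster


def load_games(path) -> pd.DataFrame:
    """Read ``games.csv`` (per game-side shots on target, including goals)."""
    games = pd.read_csv(
        path, dtype={"game_id": str, "format": str, "team": str, "side_team_id": str}
    )
    _require_columns(games, GAME_COLUMNS, "games")
    _bad_rows(games, games["shots_on_target"] < 0, "negative shots_on_target")
    return games


def write_events(events: pd.DataFrame, path) -> None:
    """Write a validated event table; ``load_events`` round-trips losslessly."""
    events.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def merge_indicators(events: pd.DataFrame) -> pd.DataFrame:
    """Return the player-quantification view of an event table.

    Dribbles and take-ons are relabelled ``offensive_duel``; tackles and
    staying-in-front events ``defensive_duel``.  Outcomes are preserved and
    the total event count is unchanged.  The representativeness analyses use
    the raw (unmerged) table instead, where all eleven labels stay distinct.
    """
    merged = events.copy()
    merged["indicator"] = merged["indicator"].replace(MERGE_MAP)
    return merged


def exclude_players(
    roster: pd.DataFrame, sd_multiplier: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's player-exclusion policy.

    A player is dropped when they played no 11-vs-11 minutes, or when their
    number of small-sided games is *more than* ``sd_multiplier`` sample
    standard deviations below their team's mean (strict inequality, so a
    player exactly at the boundary is retained).  The SD criterion is
    evaluated per team; for a team of fewer than two players the SD is
    undefined and that criterion is skipped with a warning.

    Returns
    -------
    (retained, exclusion_log)
        ``retained`` is the filtered roster; ``exclusion_log`` has columns
        ``player_id``, ``team``, ``reason``.
    """
    log_rows: list[dict] = []
    drop: set[str] = set()

    no_m11 = roster["minutes_m11"] <= 0
    for _, row in roster[no_m11].iterrows():
        drop.add(row["player_id"])
        log_rows.append(
            {"player_id": row["player_id"], "team": row["team"], "reason": "no_m11_minutes"}
        )

    for team, grp in roster.groupby("team"):
        if len(grp) < 2:
            warnings.warn(
                f"team {team!r} has fewer than 2 players; SSG-count exclusion skipped",
                stacklevel=2,
            )
            continue
        mean = grp["n_ssg_played"].mean()
        sd = grp["n_ssg_played"].std(ddof=1)  # sample SD, n-1 denominator
        threshold = mean - sd_multiplier * sd
        few = grp["n_ssg_played"] < threshold
        for _, row in grp[few].iterrows():
            if row["player_id"] not in drop:
                log_rows.append(
                    {
                        "player_id": row["player_id"],
                        "team": row["team"],
                        "reason": f"n_ssg_played {row['n_ssg_played']} < {threshold:.2f}",
                    }
                )
            drop.add(row["player_id"])

    retained = roster[~roster["player_id"].isin(drop)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["player_id", "team", "reason"])
    return retained, log


def cohens_kappa(codes_a: Iterable, codes_b: Iterable) -> float:
    """Cohen's kappa for two aligned sequences of category labels.

    kappa = (p_o - p_e) / (1 - p_e), with the expected agreement p_e from the
    product of the raters' marginal category frequencies.  Used as the
    inter-rater reliability check for the manual event coding.

    Raises
    ------
    ValueError
        If the sequences differ in length, are empty, or p_e = 1 (both
        raters constant and identical), where kappa is undefined.
    """
    a = np.asarray(list(codes_a))
    b = np.asarray(list(codes_b))
    if a.shape != b.shape:
        raise ValueError("rater sequences must be aligned (equal length)")
    if a.size == 0:
        raise ValueError("empty rater sequences")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        raise ValueError("kappa undefined: both raters constant and equal (p_e = 1)")
    return (p_o - p_e) / (1.0 - p_e)
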