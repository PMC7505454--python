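"""Synthetic study generator with known ground truth.

Emulates the design of the reference academy study: four age-category teams
(U15/U17/U19/U23) of 15-17 players; each team plays a dozen-to-twenty
six-minute 7-vs-7 small-sided games (side compositions re-drawn every game)
and six 11-vs-11 half-games of 45 minutes; eleven event-type indicators with
format-specific base rates calibrated to the reference study's observed
totals (including the suppression of aerial duels in the small format).

The statistical structure matches the assumptions of the analysis pipeline:

* count-type events are Poisson given a player's exposure, a log-normal
  player-ability modifier and a per-game-side team-strength factor;
* binary-indicator attempts are Poisson and successes Bernoulli with
  ``logit = beta0 + team effect + sigma_u * ability``;
* each player's small-sided and 11-vs-11 latent abilities are joined by a
  Gaussian copula with correlation ``rho`` — the single knob controlling the
  true cross-format consistency (predictive validity);
* a side's shots on target accumulate from its generated shot events and are
  additionally boosted by the side's offensive strength and suppressed by
  the opponent's defensive strength, which induces the positive
  (offense vs shots) and negative (defense vs shots conceded) team-level
  correlations that the weight-derivation stage estimates;
* physiological test scores load on a player's latent ability with a
  configurable correlation and are missing completely at random at the
  reference study's observed rates.

All multiplicative modifiers are mean-centred on the log scale so that the
configured base rates equal the population-average event rates, and every
draw flows from a single :class:`numpy.random.Generator`, making a study a
pure function of its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from ssgperf.data_model import (
    CODING_SCHEME,
    EVENT_COLUMNS,
    GAME_COLUMNS,
    OUTCOME_FAILURE,
    OUTCOME_NA,
    OUTCOME_SUCCESS,
    RAW_LABELS,
)
from ssgperf.datasets import REFERENCE_EVENT_TOTALS

_DEFAULT_TEAMS = {"U15": 17, "U17": 15, "U19": 16, "U23": 15}
# per-team SSG counts chosen so that the mean number of SSGs per player
# (14 of the squad appear per game) matches the reference study's 16/11/18/15
_DEFAULT_N_SSG = {"U15": 19, "U17": 12, "U19": 20, "U23": 16}
_DEFAULT_BETA0 = {
    "pass_forward": 0.85,
    "dribble": 0.10,
    "take_on": 0.00,
    "tackle": 0.10,
    "staying_in_front": 0.30,
    "offensive_aerial_duel": 0.00,
    "defensive_aerial_duel": 0.00,
}
_DEFAULT_TEAM_EFFECTS = {"U15": 0.0, "U17": 0.1, "U19": 0.2, "U23": 0.3}


def default_base_rates(
    teams: dict[str, int] | None = None,
    n_ssg_per_team: dict[str, int] | None = None,
    n_m11_halves: int = 6,
    ssg_players_per_side: int = 7,
    m11_players: int = 11,
    ssg_duration: float = 6.0,
    half_duration: float = 45.0,
) -> dict[str, dict[str, float]]:
    """Per-player per-bout base event rates calibrated to the reference totals.

    The reference study's per-format indicator totals are divided by the
    total player exposure (in six-minute bouts) implied by the default
    design, yielding rates whose expected totals echo the observed frequency
    structure — including the SSG aerial suppression.
    """
    teams = teams or _DEFAULT_TEAMS
    n_ssg = n_ssg_per_team or _DEFAULT_N_SSG
    ssg_bouts = sum(n_ssg.values()) * 2 * ssg_players_per_side * (ssg_duration / 6.0)
    m11_bouts = len(teams) * n_m11_halves * m11_players * (half_duration / 6.0)
    return {
        "SSG": {ind: tot_ssg / ssg_bouts for ind, (_, tot_ssg) in REFERENCE_EVENT_TOTALS.items()},
        "M11": {ind: tot_m11 / m11_bouts for ind, (tot_m11, _) in REFERENCE_EVENT_TOTALS.items()},
    }


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic study; defaults emulate the reference design."""

    seed: int = 0
    teams: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_TEAMS))
    n_ssg_per_team: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_SSG))
    ssg_duration: float = 6.0
    ssg_players_per_side: int = 7
    n_m11_halves: int = 6
    half_duration: float = 45.0
    m11_players: int = 11
    #: per-format per-indicator mean events per player per six-minute bout
    base_rates: dict[str, dict[str, float]] | None = None
    #: fixed logit intercept per binary indicator
    success_beta0: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BETA0))
    #: team logit offsets for binary-indicator success
    team_effects: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TEAM_EFFECTS))
    #: SD of the player random intercept on the logit scale
    sigma_u: float = 0.5
    #: cross-format latent-ability correlation (the true validity knob)
    rho: float = 0.7
    #: log-scale loading of player ability on count-indicator rates
    ability_rate_loading: float = 0.4
    #: SD of per-game-side offensive/defensive strength on the log scale
    team_strength_sd: float = 0.3
    #: log-scale suppression of shots by the opponent's defensive strength
    defense_suppression: float = 0.3
    #: |correlation| of test scores with the latent athletic factor
    test_validity: float = 0.2
    test_missing_rate_sprint: float = 6 / 63
    test_missing_rate_isrt: float = 1 / 63

    def __post_init__(self) -> None:
        if self.base_rates is None:
            self.base_rates = default_base_rates(
                self.teams,
                self.n_ssg_per_team,
                self.n_m11_halves,
                self.ssg_players_per_side,
                self.m11_players,
                self.ssg_duration,
                self.half_duration,
            )
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        for fmt, rates in self.base_rates.items():
            for ind, lam in rates.items():
                if lam < 0:
                    raise ValueError(f"negative base rate for {ind}/{fmt}")
        if self.sigma_u < 0 or self.team_strength_sd < 0:
            raise ValueError("scale parameters must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Latent quantities underlying a generated study."""

    abilities: pd.DataFrame  # player_id, team, a_off_ssg, a_off_m11, a_def_ssg, a_def_m11
    side_strengths: pd.DataFrame  # game_id, side_team_id, offense, defense
    config: GeneratorConfig

    def latent_validity(self, side: str = "offense") -> dict:
        """True cross-format consistency: per-team Spearman correlation of the
        latent abilities, with the achieved pooled value.

        This is the generator's target validity for the corresponding rate
        indicators; the observed aggregated coefficient approaches it as
        Poisson noise shrinks (exposure grows).
        """
        a, b = (
            ("a_off_ssg", "a_off_m11") if side == "offense" else ("a_def_ssg", "a_def_m11")
        )
        from ssgperf.weights_composite import meta_spearman

        groups = {
            team: (grp[a].to_numpy(), grp[b].to_numpy())
            for team, grp in self.abilities.groupby("team")
        }
        meta = meta_spearman(groups, min_n=4)
        return {"aggregated_r": meta.r, "per_team": meta.group_r}

    def to_json(self, path) -> None:
        def pack(df: pd.DataFrame) -> dict:
            return {"columns": list(df.columns), "data": df.to_numpy().tolist()}

        payload = {
            "abilities": pack(self.abilities),
            "side_strengths": pack(self.side_strengths),
            "config": self.config.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())

        def unpack(d: dict) -> pd.DataFrame:
            return pd.DataFrame(d["data"], columns=d["columns"])

        return cls(
            abilities=unpack(payload["abilities"]),
            side_strengths=unpack(payload["side_strengths"]),
            config=GeneratorConfig.from_dict(payload["config"]),
        )


@dataclass
class StudyData:
    """A complete generated study in the pipeline's input schemas."""

    events: pd.DataFrame
    roster: pd.DataFrame
    games: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(outdir / "events.csv", index=False)
        self.roster.to_csv(outdir / "roster.csv", index=False, float_format="%.6g")
        self.games.to_csv(outdir / "games.csv", index=False)
        self.truth.to_json(outdir / "ground_truth.json")


def _bivariate_std_normal(rng: np.random.Generator, n: int, rho: float):
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rho * x + math.sqrt(max(0.0, 1 - rho**2)) * e
    return x, y


def generate_study(config: GeneratorConfig) -> StudyData:
    """Generate one complete synthetic study.

    Returns events, roster and games tables in the documented CSV schemas
    plus the :class:`GroundTruth`.  Regeneration from the same configuration
    (including the seed) is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    gamma = config.ability_rate_loading
    omega = config.team_strength_sd
    dsup = config.defense_suppression

    # --- players and latent abilities -----------------------------------
    players, teams_col = [], []
    for team in config.teams:  # insertion order: deterministic
        for j in range(config.teams[team]):
            players.append(f"{team}_P{j + 1:02d}")
            teams_col.append(team)
    n_players = len(players)
    a_off_ssg, a_off_m11 = _bivariate_std_normal(rng, n_players, config.rho)
    a_def_ssg, a_def_m11 = _bivariate_std_normal(rng, n_players, config.rho)
    abilities = pd.DataFrame(
        {
            "player_id": players,
            "team": teams_col,
            "a_off_ssg": a_off_ssg,
            "a_off_m11": a_off_m11,
            "a_def_ssg": a_def_ssg,
            "a_def_m11": a_def_m11,
        }
    )
    pidx = {p: i for i, p in enumerate(players)}
    team_of = dict(zip(players, teams_col))

    # --- schedule: appearances and per-side strengths -------------------
    app_rows = []  # (game_id, format, team, side_team_id, player_id, bouts)
    side_rows = []  # (game_id, format, team, side_team_id, offense, defense, coded)
    team_players = {t: [p for p in players if team_of[p] == t] for t in config.teams}

    for team in config.teams:
        squad = np.array(team_players[team])
        for g in range(config.n_ssg_per_team[team]):
            game_id = f"{team}_SSG{g + 1:02d}"
            picked = rng.permutation(squad)[: 2 * config.ssg_players_per_side]
            half = len(picked) // 2
            for tag, members in (("A", picked[:half]), ("B", picked[half:])):
                side_id = f"{game_id}{tag}"
                off, de = rng.normal(0, omega, 2)
                side_rows.append((game_id, "SSG", team, side_id, off, de, True))
                for p in members:
                    app_rows.append(
                        (game_id, "SSG", team, side_id, p, config.ssg_duration / 6.0)
                    )
        for h in range(config.n_m11_halves):
            game_id = f"{team}_M11H{h + 1}"
            picked = rng.permutation(squad)[: config.m11_players]
            home_id, away_id = f"{game_id}_home", f"{game_id}_away"
            off_h, def_h = rng.normal(0, omega, 2)
            off_a, def_a = rng.normal(0, omega, 2)
            side_rows.append((game_id, "M11", team, home_id, off_h, def_h, True))
            side_rows.append((game_id, "M11", team, away_id, off_a, def_a, False))
            for p in picked:
                app_rows.append(
                    (game_id, "M11", team, home_id, p, config.half_duration / 6.0)
                )

    sides = pd.DataFrame(
        side_rows,
        columns=["game_id", "format", "team", "side_team_id", "offense", "defense", "coded"],
    )
    # opponent defensive strength per side
    opp = sides.merge(
        sides[["game_id", "side_team_id", "defense"]],
        on="game_id",
        suffixes=("", "_opp"),
    )
    opp = opp[opp["side_team_id"] != opp["side_team_id_opp"]]
    sides = sides.merge(
        opp[["game_id", "side_team_id", "defense_opp"]], on=["game_id", "side_team_id"]
    )

    apps = pd.DataFrame(
        app_rows, columns=["game_id", "format", "team", "side_team_id", "player_id", "bouts"]
    )
    apps = apps.merge(
        sides[["game_id", "side_team_id", "offense", "defense", "defense_opp"]],
        on=["game_id", "side_team_id"],
    )
    ip = apps["player_id"].map(pidx).to_numpy()
    fmt_arr = apps["format"].to_numpy()
    is_ssg = fmt_arr == "SSG"
    a_off = np.where(is_ssg, a_off_ssg[ip], a_off_m11[ip])
    a_def = np.where(is_ssg, a_def_ssg[ip], a_def_m11[ip])
    team_eff = apps["team"].map(config.team_effects).fillna(0.0).to_numpy()
    bouts = apps["bouts"].to_numpy()
    off_strength = apps["offense"].to_numpy()
    def_strength = apps["defense"].to_numpy()
    def_opp = apps["defense_opp"].to_numpy()

    # --- events ---------------------------------------------------------
    ev_game, ev_fmt, ev_team, ev_side, ev_player, ev_ind, ev_out = (
        [], [], [], [], [], [], [],
    )

    def emit(mask_counts, indicator, outcomes):
        reps = mask_counts
        ev_game.append(np.repeat(apps["game_id"].to_numpy(), reps))
        ev_fmt.append(np.repeat(fmt_arr, reps))
        ev_team.append(np.repeat(apps["team"].to_numpy(), reps))
        ev_side.append(np.repeat(apps["side_team_id"].to_numpy(), reps))
        ev_player.append(np.repeat(apps["player_id"].to_numpy(), reps))
        total = int(reps.sum())
        ev_ind.append(np.full(total, indicator))
        ev_out.append(outcomes)

    for indicator in RAW_LABELS:
        info = CODING_SCHEME[indicator]
        lam_f = np.where(
            is_ssg,
            config.base_rates["SSG"].get(indicator, 0.0),
            config.base_rates["M11"].get(indicator, 0.0),
        )
        ability = a_off if info.side == "offense" else a_def
        strength = off_strength if info.side == "offense" else def_strength
        log_mod = strength - omega**2 / 2.0
        if indicator == "shot_on_target":
            log_mod = log_mod - dsup * def_opp - (dsup * omega) ** 2 / 2.0
        if info.outcome_type == "count":
            log_mod = log_mod + gamma * ability - gamma**2 / 2.0
            counts = rng.poisson(lam_f * bouts * np.exp(log_mod))
            emit(counts, indicator, np.full(int(counts.sum()), OUTCOME_NA))
        else:
            attempts = rng.poisson(lam_f * bouts * np.exp(log_mod))
            p_succ = expit(
                config.success_beta0.get(indicator, 0.0)
                + team_eff
                + config.sigma_u * ability
            )
            succ = rng.binomial(attempts, p_succ)
            fail = attempts - succ
            # per appearance: successes first, then failures
            reps = np.empty(2 * len(succ), dtype=np.int64)
            reps[0::2], reps[1::2] = succ, fail
            outcomes = np.repeat(
                np.tile(np.array([OUTCOME_SUCCESS, OUTCOME_FAILURE], dtype=object), len(succ)),
                reps,
            )
            emit(attempts, indicator, outcomes)

    events = pd.DataFrame(
        {
            "game_id": np.concatenate(ev_game),
            "format": np.concatenate(ev_fmt),
            "team": np.concatenate(ev_team),
            "side_team_id": np.concatenate(ev_side),
            "player_id": np.concatenate(ev_player),
            "indicator": np.concatenate(ev_ind),
            "outcome": np.concatenate(ev_out),
        },
        columns=EVENT_COLUMNS,
    )

    # --- games table: shots per side ------------------------------------
    shot_counts = (
        events[events["indicator"] == "shot_on_target"]
        .groupby("side_team_id")
        .size()
    )
    games = sides[["game_id", "format", "team", "side_team_id"]].copy()
    games["shots_on_target"] = (
        games["side_team_id"].map(shot_counts).fillna(0).astype(int)
    )
    # uncoded (external 11-vs-11 opponent) sides: team-level Poisson shots
    uncoded = ~sides["coded"].to_numpy()
    if uncoded.any():
        lam_shot = config.base_rates["M11"].get("shot_on_target", 0.0)
        side_exposure = config.m11_players * config.half_duration / 6.0
        log_mod = (
            sides.loc[uncoded, "offense"].to_numpy()
            - omega**2 / 2.0
            - dsup * sides.loc[uncoded, "defense_opp"].to_numpy()
            - (dsup * omega) ** 2 / 2.0
        )
        games.loc[uncoded, "shots_on_target"] = rng.poisson(
            lam_shot * side_exposure * np.exp(log_mod)
        )
    games = games[GAME_COLUMNS]

    # --- roster ----------------------------------------------------------
    minutes = apps.assign(mins=apps["bouts"] * 6.0).pivot_table(
        index="player_id", columns="format", values="mins", aggfunc="sum", fill_value=0.0
    )
    n_ssg_played = (
        apps[is_ssg].groupby("player_id").size().reindex(players).fillna(0).astype(int)
    )
    roster = pd.DataFrame({"player_id": players, "team": teams_col})
    roster["minutes_ssg"] = (
        roster["player_id"].map(minutes.get("SSG", pd.Series(dtype=float))).fillna(0.0)
    )
    roster["minutes_m11"] = (
        roster["player_id"].map(minutes.get("M11", pd.Series(dtype=float))).fillna(0.0)
    )
    roster["n_ssg_played"] = roster["player_id"].map(n_ssg_played).to_numpy()

    # --- physiological/motor tests ---------------------------------------
    c = config.test_validity
    resid = math.sqrt(max(0.0, 1 - c**2))
    athletic = (a_off_m11 + a_def_m11) / math.sqrt(2.0)
    specs = [  # name, mean, sd, sign (-1: lower time = better ability)
        ("sprint_10m", 1.80, 0.08, -1.0),
        ("sprint_30m", 4.20, 0.15, -1.0),
        ("isrt_tracks", 75.0, 12.0, +1.0),
        ("agility_left", 7.20, 0.30, -1.0),
        ("agility_right", 7.20, 0.30, -1.0),
    ]
    for name, mean, sd, sign in specs:
        noise = rng.standard_normal(n_players)
        vals = mean + sd * (sign * c * athletic + resid * noise)
        if name == "isrt_tracks":
            vals = np.round(vals).clip(min=1)
        roster[name] = np.round(vals, 3)
    miss_sprint = rng.random(n_players) < config.test_missing_rate_sprint
    miss_isrt = rng.random(n_players) < config.test_missing_rate_isrt
    for name in ("sprint_10m", "sprint_30m", "agility_left", "agility_right"):
        roster.loc[miss_sprint, name] = np.nan
    roster.loc[miss_isrt, "isrt_tracks"] = np.nan

    truth = GroundTruth(
        abilities=abilities,
        side_strengths=sides[["game_id", "side_team_id", "offense", "defense"]].copy(),
        config=config,
    )
    return StudyData(events=events, roster=roster, games=games, truth=truth)


def replicate(config: GeneratorConfig, n_reps: int, callback):
    """Run ``callback(study)`` over ``n_reps`` independently seeded studies.

    Child seeds are derived deterministically from ``config.seed`` via a
    :class:`numpy.random.SeedSequence` spawn, so the whole experiment is a
    pure function of the master seed.  A callback failure on one replicate
    is recorded and the remaining replicates continue.

    Returns
    -------
    (results, errors)
        ``results``: list of callback outputs (None for failed replicates);
        ``errors``: list of ``(replicate_index, exception)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_reps)
    results, errors = [], []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        cfg = dataclasses.replace(config, seed=child_seed)
        study = generate_study(cfg)
        try:
            results.append(callback(study))
        except Exception as err:  # noqa: BLE001 - replicate isolation
            results.append(None)
            errors.append((i, err))
    return results, errors
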