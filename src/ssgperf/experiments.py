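"""Canned simulation experiments validating the pipeline's estimators.

Each experiment generates synthetic studies with known ground truth and
measures how well a pipeline stage recovers it:

* :func:`null_validity_coverage` — with zero cross-format consistency
  (rho = 0), the aggregated-validity confidence intervals should contain 0
  for ~95% of replicate-indicator combinations;
* :func:`consistency_recovery` — under high consistency and low Poisson
  noise, the mean aggregated rate-indicator coefficient should approach the
  generator's latent target validity;
* :func:`sigma_u_recovery` — the random-intercept logistic fit should
  recover the generating player-ability SD and the true ability ranking.

All experiments are deterministic functions of their seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ssgperf.data_model import exclude_players
from ssgperf.rates import events_per_bout
from ssgperf.success_model import fit_success_model
from ssgperf.synthetic import GeneratorConfig, default_base_rates, generate_study, replicate
from ssgperf.validity import predictive_validity
from ssgperf.weights_composite import meta_spearman


def _rate_validity_table(study) -> pd.DataFrame:
    """Aggregated SSG-vs-M11 validity of the four count-indicator rates."""
    roster, _ = exclude_players(study.roster)
    ev = study.events[study.events["player_id"].isin(roster["player_id"])]
    ssg = events_per_bout(ev, roster, "SSG").pivot(
        index="player_id", columns="indicator", values="rate"
    )
    m11 = events_per_bout(ev, roster, "M11").pivot(
        index="player_id", columns="indicator", values="rate"
    )
    teams = roster.set_index("player_id")["team"]
    return predictive_validity(ssg, m11, teams)


def null_validity_coverage(seed: int, n_reps: int = 200) -> dict:
    """CI coverage of zero under a zero-consistency generator (rho = 0).

    Returns the percentage of replicate-by-indicator aggregated-validity
    CIs that contain 0, plus the mean aggregated coefficient.
    """
    cfg = GeneratorConfig(seed=seed, rho=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, errors = replicate(cfg, n_reps, _rate_validity_table)
    tables = pd.concat([r for r in results if r is not None])
    covered = (tables["ci_low"] <= 0) & (0 <= tables["ci_high"])
    return {
        "coverage_pct": 100.0 * float(covered.mean()),
        "mean_r": float(tables["r"].mean()),
        "n_cis": int(len(tables)),
        "n_failed_replicates": len(errors),
    }


def consistency_recovery(seed: int, n_reps: int = 40, rho: float = 0.9) -> dict:
    """Mean aggregated rate-indicator validity vs the latent target.

    Uses a low-noise configuration (event rates boosted 25-fold, strong
    ability loading, weak game-to-game team-strength variation) so that the
    observed per-bout rates are nearly deterministic functions of the latent
    abilities; the observed aggregated coefficient should then approach the
    generator's own cross-format latent-ability correlation.
    """
    rates = default_base_rates()
    boosted = {f: {k: 25.0 * v for k, v in d.items()} for f, d in rates.items()}
    cfg = GeneratorConfig(
        seed=seed,
        rho=rho,
        ability_rate_loading=1.0,
        team_strength_sd=0.05,
        base_rates=boosted,
    )

    def cb(study):
        table = _rate_validity_table(study).set_index("measure")["r"]
        roster, _ = exclude_players(study.roster)
        tr = study.truth.abilities[
            study.truth.abilities["player_id"].isin(roster["player_id"])
        ]
        targets = {}
        for side, (a, b) in {
            "offense": ("a_off_ssg", "a_off_m11"),
            "defense": ("a_def_ssg", "a_def_m11"),
        }.items():
            groups = {
                t: (g[a].to_numpy(), g[b].to_numpy()) for t, g in tr.groupby("team")
            }
            targets[side] = meta_spearman(groups).r
        return table, targets

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, errors = replicate(cfg, n_reps, cb)
    results = [r for r in results if r is not None]
    observed = pd.DataFrame([r[0] for r in results]).mean()
    target_off = float(np.mean([r[1]["offense"] for r in results]))
    target_def = float(np.mean([r[1]["defense"] for r in results]))
    side_of = {
        "chance_created": "offense",
        "shot_on_target": "offense",
        "pass_interception": "defense",
        "applying_pressure": "defense",
    }
    targets = {ind: (target_off if s == "offense" else target_def) for ind, s in side_of.items()}
    return {
        "observed_mean_r": observed.to_dict(),
        "target_r": targets,
        "max_abs_gap": float(
            max(abs(observed[ind] - targets[ind]) for ind in side_of)
        ),
        "n_failed_replicates": len(errors),
    }


def sigma_u_recovery_config(seed: int) -> GeneratorConfig:
    """Recovery design: 60 players in 4 teams, unit ability SD, ~80 forward
    passes per player in the small-sided format."""
    teams = {"U15": 15, "U17": 15, "U19": 15, "U23": 15}
    n_ssg = {t: 25 for t in teams}
    rates = default_base_rates(teams, n_ssg)
    rates["SSG"]["pass_forward"] = 4.5  # >= 50 trials per player
    return GeneratorConfig(
        seed=seed,
        teams=teams,
        n_ssg_per_team=n_ssg,
        team_effects={"U15": 0.0, "U17": 0.3, "U19": -0.3, "U23": 0.5},
        success_beta0={"pass_forward": 0.0},
        sigma_u=1.0,
        team_strength_sd=0.15,
        base_rates=rates,
    )


def sigma_u_recovery(seed: int) -> dict:
    """Fit the success model to one recovery-design study; report the
    estimated ability SD and the rank agreement of the player modes with the
    true latent abilities."""
    study = generate_study(sigma_u_recovery_config(seed))
    ev = study.events
    pf = ev[(ev["indicator"] == "pass_forward") & (ev["format"] == "SSG")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_success_model(pf)
    truth = study.truth.abilities.set_index("player_id")["a_off_ssg"]
    rank_corr = float(
        spearmanr(fit.player_modes, truth[fit.player_modes.index]).statistic
    )
    trials = pf.groupby("player_id").size()
    return {
        "sigma_u_true": study.truth.config.sigma_u,
        "sigma_u_est": fit.sigma_u,
        "rank_corr": rank_corr,
        "min_trials": int(trials.min()),
        "mean_trials": float(trials.mean()),
        "converged": fit.converged,
    }
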