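"""End-to-end orchestration: events in, report tables out.

Stage order: player exclusion -> indicator merging -> rate statistics ->
success models -> weight derivation -> composite scores ->
representativeness -> validity.  Every run writes a manifest (config hash,
library versions) sufficient to reproduce its outputs; all stages are
deterministic given the inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import ssgperf
from ssgperf.data_model import (
    COUNT_INDICATORS,
    MODEL_INDICATORS,
    exclude_players,
    merge_indicators,
)
from ssgperf.rates import events_per_bout
from ssgperf.representativeness import (
    gof_chi_square,
    distribution_rank_correlation,
    mean_events_per_bout_by_format,
)
from ssgperf.success_model import SeparationError, fit_success_model, player_posterior_scores
from ssgperf.validity import predictive_validity, test_validity
from ssgperf.weights_composite import (
    REFERENCE_WEIGHTS,
    composite_scores,
    derive_weights,
    team_game_indicator_totals,
)
from ssgperf.data_model import TEST_COLUMNS


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    weights_source: str = "derived"  # or "reference" (published composite weights)
    tau2_estimator: str = "DL"
    min_n: int = 4
    binary_performance: str = "count"  # team-game binary performance: count|proportion
    exclusion_sd: float = 2.0
    ssg_minutes: float = 6.0
    m11_minutes: float = 45.0

    def manifest(self) -> dict:
        cfg = {
            "weights_source": self.weights_source,
            "tau2_estimator": self.tau2_estimator,
            "min_n": self.min_n,
            "binary_performance": self.binary_performance,
            "exclusion_sd": self.exclusion_sd,
            "ssg_minutes": self.ssg_minutes,
            "m11_minutes": self.m11_minutes,
        }
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "versions": {
                "ssgperf": ssgperf.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }


@dataclass
class PipelineResult:
    """All artefacts of one pipeline run."""

    roster: pd.DataFrame
    exclusions: pd.DataFrame
    weights: dict
    weight_provenance: dict
    fits: dict  # (indicator, fmt) -> SuccessModelFit
    scores: dict  # fmt -> wide per-player score table (incl. composites)
    repr_gof: object
    repr_gof_no_aerials: object
    repr_corr: object
    repr_corr_no_aerials: object
    fig_data: pd.DataFrame
    validity_predictive: pd.DataFrame
    validity_tests: pd.DataFrame
    manifest: dict


def player_score_table(
    events_merged: pd.DataFrame,
    roster: pd.DataFrame,
    fmt: str,
    fits: dict,
) -> pd.DataFrame:
    """Wide per-player score table for one format.

    Count indicators contribute events-per-bout rates; model indicators the
    posterior logit scores, with NaN for players without a single trial on
    that indicator (such players are dropped from analyses that need it).
    """
    rates = events_per_bout(events_merged, roster, fmt)
    wide = rates.pivot(index="player_id", columns="indicator", values="rate")
    for ind in MODEL_INDICATORS:
        fit = fits.get((ind, fmt))
        if fit is None:
            wide[ind] = np.nan
            continue
        sc = player_posterior_scores(fit, roster).set_index("player_id")
        col = sc["score"].where(sc["n_trials"] > 0)  # no-trial players: missing
        wide[ind] = col.reindex(wide.index)
    return wide


def run_pipeline(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    games: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis pipeline on validated input tables."""
    config = config or RunConfig()

    retained, exclusions = exclude_players(roster, sd_multiplier=config.exclusion_sd)
    ev = events[events["player_id"].isin(retained["player_id"])].reset_index(drop=True)
    merged = merge_indicators(ev)

    # success models: one per binary indicator per format
    fits = {}
    for ind in MODEL_INDICATORS:
        for fmt in ("SSG", "M11"):
            sub = merged[(merged["indicator"] == ind) & (merged["format"] == fmt)]
            if sub.empty:
                warnings.warn(f"no events for {ind}/{fmt}; model skipped", stacklevel=2)
                continue
            try:
                fits[(ind, fmt)] = fit_success_model(sub)
            except (SeparationError, ValueError) as err:
                warnings.warn(f"model {ind}/{fmt} not fitted: {err}", stacklevel=2)

    # indicator weights from team-game totals across both formats
    totals = team_game_indicator_totals(
        merged, games, binary_performance=config.binary_performance
    )
    derived, provenance = derive_weights(
        totals, min_n=config.min_n, tau2_estimator=config.tau2_estimator
    )
    weights = dict(REFERENCE_WEIGHTS) if config.weights_source == "reference" else derived

    # per-format score tables and composites
    teams = retained.set_index("player_id")["team"]
    scores = {}
    for fmt in ("SSG", "M11"):
        wide = player_score_table(merged, retained, fmt, fits)
        comps = composite_scores(wide, weights, teams)
        scores[fmt] = wide.join(comps)

    # representativeness on the raw (unmerged) view
    counts = (
        ev.groupby(["format", "indicator"], observed=True).size().unstack("format").fillna(0)
    )
    order = counts.get("M11", pd.Series(dtype=float)).sort_values(ascending=False).index
    observed_ssg = counts["SSG"].reindex(order).fillna(0)
    observed_m11 = counts["M11"].reindex(order).fillna(0)
    keep = observed_m11 > 0
    observed_ssg, observed_m11 = observed_ssg[keep], observed_m11[keep]
    gof = gof_chi_square(observed_ssg, observed_m11)
    corr = distribution_rank_correlation(observed_m11, observed_ssg)
    no_aer = [i for i in observed_ssg.index if "aerial" not in i]
    gof2 = gof_chi_square(observed_ssg[no_aer], observed_m11[no_aer])
    corr2 = distribution_rank_correlation(observed_m11[no_aer], observed_ssg[no_aer])

    durations = pd.Series(
        {
            gid: config.ssg_minutes if fmt == "SSG" else config.m11_minutes
            for gid, fmt in ev[["game_id", "format"]].drop_duplicates().to_numpy()
        }
    )
    fig_data = mean_events_per_bout_by_format(ev, durations)

    validity_pred = predictive_validity(
        scores["SSG"], scores["M11"], teams, min_n=config.min_n,
        tau2_estimator=config.tau2_estimator,
    )
    if "agility_mean" not in retained.columns:
        retained = retained.copy()
        retained["agility_mean"] = retained[["agility_left", "agility_right"]].mean(
            axis=1, skipna=False
        )
    tests = retained.set_index("player_id")[TEST_COLUMNS]
    validity_tests = test_validity(
        tests, scores["M11"][["offensive", "defensive"]], teams,
        min_n=config.min_n, tau2_estimator=config.tau2_estimator,
    )

    return PipelineResult(
        roster=retained,
        exclusions=exclusions,
        weights=weights,
        weight_provenance=provenance,
        fits=fits,
        scores=scores,
        repr_gof=gof,
        repr_gof_no_aerials=gof2,
        repr_corr=corr,
        repr_corr_no_aerials=corr2,
        fig_data=fig_data,
        validity_predictive=validity_pred,
        validity_tests=validity_tests,
        manifest=config.manifest(),
    )


def write_report(result: PipelineResult, outdir) -> None:
    """Write the report bundle (CSV/JSON) for one pipeline run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    gof, corr = result.repr_gof, result.repr_corr
    table = gof.table.copy()
    table.index.name = "indicator"
    table.to_csv(out / "repr_report.csv", float_format="%.6g")
    repr_summary = {
        "chi2": gof.chi2,
        "df": gof.df,
        "n": gof.n,
        "p_value": gof.p_value,
        "p_display": gof.p_display(),
        "spearman_r": corr.r,
        "spearman_ci": [corr.ci_low, corr.ci_high],
        "no_aerials": {
            "chi2": result.repr_gof_no_aerials.chi2,
            "df": result.repr_gof_no_aerials.df,
            "n": result.repr_gof_no_aerials.n,
            "spearman_r": result.repr_corr_no_aerials.r,
            "spearman_ci": [
                result.repr_corr_no_aerials.ci_low,
                result.repr_corr_no_aerials.ci_high,
            ],
        },
    }
    (out / "repr_summary.json").write_text(json.dumps(repr_summary, indent=1))
    result.fig_data.to_csv(out / "fig1_data.csv", index=False, float_format="%.6g")

    (out / "weights.json").write_text(
        json.dumps(
            {"weights": result.weights, "provenance": result.weight_provenance},
            indent=1,
            default=str,
        )
    )
    (out / "model_fits.json").write_text(
        json.dumps(
            {f"{ind}_{fmt}": fit.summary() for (ind, fmt), fit in result.fits.items()},
            indent=1,
        )
    )

    comp = []
    for fmt, tab in result.scores.items():
        c = tab[["offensive", "defensive"]].copy()
        c.insert(0, "format", fmt)
        comp.append(c.reset_index())
    pd.concat(comp).to_csv(out / "composite_scores.csv", index=False, float_format="%.6g")

    result.validity_predictive.to_csv(
        out / "validity_predictive.csv", index=False, float_format="%.6g"
    )
    result.validity_tests.to_csv(
        out / "validity_tests.csv", index=False, float_format="%.6g"
    )
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
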