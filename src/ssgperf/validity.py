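"""Predictive-validity analyses: team-wise rank correlations, meta-aggregated.

Predictor-criterion relationships (small-sided-game player scores vs
11-vs-11 scores per indicator; physiological/motor test results vs composite
11-vs-11 performance) are quantified by Spearman rank correlations computed
*within* each age-category team — so that between-team differences in
performance level and observation counts cannot inflate the coefficients —
and aggregated across teams with the same random-effects machinery used for
the indicator weights.  Magnitudes follow Cohen's thresholds for
correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ssgperf.weights_composite import meta_spearman

#: left-closed Cohen magnitude bins for |r|
_MAGNITUDE_BINS = (
    (0.5, "large"),
    (0.3, "moderate"),
    (0.1, "small"),
    (0.0, "trivial"),
)


def magnitude_label(r: float) -> str:
    """Cohen magnitude label for a correlation coefficient.

    |r| < 0.1 trivial; [0.1, 0.3) small; [0.3, 0.5) moderate; >= 0.5 large
    (thresholds left-closed).
    """
    if not -1 <= r <= 1:
        raise ValueError(f"correlation out of range: {r}")
    a = abs(r)
    for lo, label in _MAGNITUDE_BINS:
        if a >= lo:
            return label
    return "trivial"


def _meta_rows(
    pairs: dict[str, tuple[pd.Series, pd.Series]],
    teams: pd.Series,
    min_n: int = 4,
    tau2_estimator: str = "DL",
) -> pd.DataFrame:
    """One meta-aggregated correlation row per named predictor-criterion pair.

    ``pairs`` maps a row label to a (predictor, criterion) pair of Series
    indexed by player_id; ``teams`` assigns each player to a group.  Pairwise
    deletion: players missing either value drop out of that row only.
    """
    rows = []
    for name, (x, y) in pairs.items():
        idx = x.index.union(y.index)
        x = x.reindex(idx).astype(float)
        y = y.reindex(idx).astype(float)
        grp_labels = teams.reindex(idx)
        groups = {}
        for team in sorted(grp_labels.dropna().unique()):
            mask = (grp_labels == team).to_numpy()
            groups[team] = (x.to_numpy()[mask], y.to_numpy()[mask])
        try:
            meta = meta_spearman(groups, min_n=min_n, tau2_estimator=tau2_estimator)
        except ValueError:
            rows.append(
                {
                    "measure": name,
                    "r": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": 0,
                    "k_teams": 0,
                    "tau2": np.nan,
                    "magnitude": "",
                }
            )
            continue
        rows.append(
            {
                "measure": name,
                "r": meta.r,
                "ci_low": meta.ci_low,
                "ci_high": meta.ci_high,
                "p": meta.p,
                "n": meta.n_total,
                "k_teams": meta.k,
                "tau2": meta.tau2,
                "magnitude": magnitude_label(meta.r),
            }
        )
    return pd.DataFrame(rows)


def predictive_validity(
    ssg_scores: pd.DataFrame,
    m11_scores: pd.DataFrame,
    teams: pd.Series,
    min_n: int = 4,
    tau2_estimator: str = "DL",
) -> pd.DataFrame:
    """Validity of small-sided-game scores for 11-vs-11 scores, per measure.

    Parameters
    ----------
    ssg_scores, m11_scores
        Wide per-player score tables (index player_id, one column per
        measure: indicator scores and/or ``offensive``/``defensive``
        composites).  Shared columns define the rows of the output.
    teams
        Team label per player_id.

    Returns
    -------
    Table with one row per measure: aggregated ``r``, 95% CI, two-sided
    ``p`` from the aggregate z statistic, pooled ``n`` (complete pairs),
    number of contributing teams, tau2 and the Cohen magnitude label.
    """
    shared = [c for c in ssg_scores.columns if c in m11_scores.columns]
    if not shared:
        raise ValueError("no shared measure columns between formats")
    pairs = {c: (ssg_scores[c], m11_scores[c]) for c in shared}
    return _meta_rows(pairs, teams, min_n=min_n, tau2_estimator=tau2_estimator)


def test_validity(
    test_scores: pd.DataFrame,
    composites: pd.DataFrame,
    teams: pd.Series,
    min_n: int = 4,
    tau2_estimator: str = "DL",
) -> pd.DataFrame:
    """Validity of physiological/motor tests for composite game performance.

    One row per (test, composite) combination, e.g. ``sprint_10m~offensive``.
    Players with partially missing test data contribute to the rows for
    which they have values (pairwise deletion).  Note that on the sprint and
    agility tests a *lower* time is better, so a negative correlation with a
    composite means faster players perform better.
    """
    pairs = {
        f"{test}~{comp}": (test_scores[test], composites[comp])
        for test in test_scores.columns
        for comp in composites.columns
    }
    return _meta_rows(pairs, teams, min_n=min_n, tau2_estimator=tau2_estimator)
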