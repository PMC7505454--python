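"""Representativeness of the small-sided format for the full format.

How similar is the *frequency structure* of coded events in 7-vs-7
small-sided games to that of 11-vs-11 matches?  Three complementary views:

* mean events per six-minute bout per indicator per format (pace),
* a chi-square goodness-of-fit test of the SSG event-type distribution
  against the 11-vs-11 distribution taken as the theoretical one, with
  multinomial-adjusted standardized residuals per indicator, and
* a Spearman rank correlation between the two observed-count vectors with a
  Fisher-z confidence interval (an interpretable effect size next to the
  chi-square statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ChiSquareGof:
    """Goodness-of-fit of observed SSG counts against the M11 distribution."""

    table: pd.DataFrame  # per indicator: observed_m11, proportion, observed_ssg,
    #                      expected_ssg, std_residual
    chi2: float
    df: int
    p_value: float
    n: int  # total observed SSG events

    def p_display(self, floor: float = 0.01) -> str:
        return f"< {floor:g}" if self.p_value < floor else f"{self.p_value:.2f}"


@dataclass
class SpearmanCI:
    r: float
    ci_low: float
    ci_high: float
    k: int


def mean_events_per_bout_by_format(
    events: pd.DataFrame, game_durations: pd.Series
) -> pd.DataFrame:
    """Mean events per six-minute bout, per indicator and game format.

    For each game the per-bout frequency of an indicator is
    ``6 * count / duration`` (duration in minutes; 6 for a small-sided game,
    ~45 for an 11-vs-11 half); the statistic is the mean over the games of a
    format.  Games with zero events on an indicator contribute zeros.
    """
    durations = pd.Series(game_durations, dtype=float)
    if (durations <= 0).any():
        bad = durations[durations <= 0].index.tolist()
        raise ValueError(f"non-positive game duration(s): {bad}")
    missing = set(events["game_id"]) - set(durations.index)
    if missing:
        raise ValueError(f"game(s) without a duration: {sorted(missing)[:10]}")

    counts = (
        events.groupby(["format", "indicator", "game_id"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    fmt_games = events[["format", "game_id"]].drop_duplicates()
    grid = fmt_games.merge(
        counts["indicator"].drop_duplicates(), how="cross"
    ).merge(counts, on=["format", "game_id", "indicator"], how="left")
    grid["count"] = grid["count"].fillna(0)
    grid["per_bout"] = 6.0 * grid["count"] / grid["game_id"].map(durations)
    out = (
        grid.groupby(["format", "indicator"], observed=True)["per_bout"]
        .mean()
        .rename("mean_events_per_bout")
        .reset_index()
    )
    return out


def gof_chi_square(observed_ssg: pd.Series, reference_m11: pd.Series) -> ChiSquareGof:
    """Chi-square goodness of fit of SSG event counts to the M11 distribution.

    The 11-vs-11 counts define category proportions p_i; expected SSG counts
    are E_i = N * p_i with N the SSG total.  The statistic is
    ``chi2 = sum (O_i - E_i)^2 / E_i`` on k-1 degrees of freedom with an
    upper-tail p-value.  Residuals use the multinomial-adjusted form

        s_i = (O_i - E_i) / sqrt(E_i * (1 - p_i)),

    whose variance is 1 under the fitted multinomial (the plain Pearson
    ``(O-E)/sqrt(E)`` understates large-category deviations).

    Categories absent from the reference (p_i = 0) must be removed by the
    caller first; re-running on a reduced indicator set renormalises the
    proportions and drops df accordingly.
    """
    observed = pd.Series(observed_ssg, dtype=float)
    reference = pd.Series(reference_m11, dtype=float)
    if set(observed.index) != set(reference.index):
        raise ValueError("observed and reference must cover the same indicator set")
    reference = reference.reindex(observed.index)
    if (reference <= 0).any():
        zero = reference.index[reference <= 0].tolist()
        raise ValueError(
            f"reference count(s) <= 0 for {zero}; remove these categories explicitly"
        )

    n = float(observed.sum())
    p = reference / reference.sum()
    expected = n * p
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    residual = (observed - expected) / np.sqrt(expected * (1 - p))
    table = pd.DataFrame(
        {
            "observed_m11": reference.astype(int),
            "proportion_m11": p,
            "observed_ssg": observed.astype(int),
            "proportion_ssg": observed / n,
            "expected_ssg": expected,
            "std_residual": residual,
        }
    )
    return ChiSquareGof(
        table=table,
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        n=int(round(n)),
    )


def distribution_rank_correlation(counts_a: pd.Series, counts_b: pd.Series) -> SpearmanCI:
    """Spearman correlation between two count vectors with a Fisher-z 95% CI.

    Mid-rank ties; the confidence interval uses the Fisher transform of the
    *unrounded* coefficient with standard error 1/sqrt(k-3).
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if len(a) != len(b):
        raise ValueError("count vectors must be paired")
    k = len(a)
    if k < 4:
        raise ValueError("need at least 4 paired categories")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    r = float(stats.spearmanr(a, b).statistic)
    se = 1.0 / np.sqrt(k - 3)
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return SpearmanCI(
        r=r,
        ci_low=float(np.tanh(z - Z975 * se)),
        ci_high=float(np.tanh(z + Z975 * se)),
        k=k,
    )


def representativeness_report(
    observed_ssg: pd.Series, reference_m11: pd.Series
) -> tuple[ChiSquareGof, SpearmanCI]:
    """Convenience bundle: goodness-of-fit plus distribution correlation."""
    gof = gof_chi_square(observed_ssg, reference_m11)
    corr = distribution_rank_correlation(
        reference_m11.reindex(observed_ssg.index), observed_ssg
    )
    return gof, corr
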