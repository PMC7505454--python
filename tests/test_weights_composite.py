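import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssgperf.data_model import merge_indicators
from ssgperf.synthetic import GeneratorConfig, generate_study
from ssgperf.weights_composite import (
    REFERENCE_WEIGHTS,
    composite_scores,
    derive_weights,
    meta_spearman,
    team_game_indicator_totals,
)
from tests.conftest import make_events


def rank_pairs(r, n, seed=0):
    """Seeded bivariate-normal pairs; the achieved (not target) Spearman
    coefficient is whatever the sample gives."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n)
    return x, y


#: disjoint index-pair swaps realising exact Spearman coefficients: swapping
#: positions i and i+k in an identity permutation adds 2k^2 to sum(d^2), and
#: r = 1 - 6*sum(d^2) / (n(n^2-1))
_EXACT_SWAPS = {
    (0.2, 20): [(0, 19), (1, 12), (2, 9), (3, 4)],
    (0.6, 20): [(0, 16), (1, 4), (2, 3)],
    (0.1, 15): [(0, 14), (1, 8), (2, 4), (5, 6), (9, 10), (11, 12)],
    (0.3, 25): [(0, 24), (1, 18), (2, 8), (3, 6)],
    (0.5, 40): [(0, 39), (1, 33), (2, 12), (3, 7), (4, 6)],
}


def monotone_pairs_with_r(r_target, n):
    """Tie-free paired ranks whose sample Spearman coefficient is *exactly*
    ``r_target`` (for the tabulated (r, n) combinations)."""
    from scipy.stats import spearmanr

    x = np.arange(n, dtype=float)
    y = x.copy()
    for i, j in _EXACT_SWAPS[(r_target, n)]:
        y[i], y[j] = y[j], y[i]
    assert spearmanr(x, y).statistic == pytest.approx(r_target, abs=1e-12)
    return x, y


class TestMetaSpearman:
    def test_single_group_reduces_to_its_coefficient(self):
        x = np.arange(20.0)
        rng = np.random.default_rng(1)
        y = x + rng.normal(0, 5, 20)
        from scipy.stats import spearmanr

        r = spearmanr(x, y).statistic
        meta = meta_spearman({"only": (x, y)})
        assert meta.r == pytest.approx(r)
        assert meta.tau2 == 0.0
        # CI from atanh(r) +/- 1.96/sqrt(17)
        z = np.arctanh(r)
        assert meta.ci_low == pytest.approx(np.tanh(z - 1.959964 / np.sqrt(17)), abs=1e-6)

    def test_identical_coefficients_give_zero_tau2(self):
        # three groups of different sizes, all with Spearman r exactly 0.2/0.6
        x1, y1 = monotone_pairs_with_r(0.2, 20)
        groups = {"a": (x1, y1), "b": (x1, y1), "c": (x1, y1)}
        meta = meta_spearman(groups)
        assert meta.tau2 == pytest.approx(0.0, abs=1e-12)
        assert meta.r == pytest.approx(0.2, abs=1e-9)

    def test_two_group_dersimonian_laird_hand_oracle(self):
        # groups with Spearman r = 0.2 (n=20) and 0.6 (n=20): frozen values
        # from a direct transcription of the Fisher-z / DL formulas
        x1, y1 = monotone_pairs_with_r(0.2, 20)
        x2, y2 = monotone_pairs_with_r(0.6, 20)
        meta = meta_spearman({"g1": (x1, y1), "g2": (x2, y2)})
        assert meta.r == pytest.approx(0.420204, abs=1e-4)
        assert meta.ci_low == pytest.approx(-0.032646, abs=1e-4)
        assert meta.ci_high == pytest.approx(0.729911, abs=1e-4)
        assert meta.tau2 == pytest.approx(0.061430, abs=1e-4)
        assert meta.p == pytest.approx(0.067733, abs=1e-4)

    def test_three_group_dersimonian_laird_hand_oracle(self):
        groups = {
            "a": monotone_pairs_with_r(0.1, 15),
            "b": monotone_pairs_with_r(0.3, 25),
            "c": monotone_pairs_with_r(0.5, 40),
        }
        meta = meta_spearman(groups)
        assert meta.r == pytest.approx(0.376550, abs=1e-4)
        assert meta.ci_low == pytest.approx(0.155975, abs=1e-4)
        assert meta.ci_high == pytest.approx(0.561354, abs=1e-4)
        assert meta.tau2 == pytest.approx(0.001923, abs=1e-4)

    def test_zero_variance_group_skipped_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero variance"):
            meta = meta_spearman({"ok": (x, x), "flat": (x, np.zeros(10))})
        assert meta.k == 1

    def test_all_groups_unusable_is_an_error(self):
        with pytest.raises(ValueError, match="no usable groups"):
            meta_spearman({"tiny": (np.arange(2.0), np.arange(2.0))})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        groups, tgroups = {}, {}
        for g in range(3):
            x = rng.standard_normal(12)
            y = 0.5 * x + rng.standard_normal(12)
            groups[g] = (x, y)
            tgroups[g] = (np.exp(x), np.arctan(y))  # strictly monotone maps
        a = meta_spearman(groups)
        b = meta_spearman(tgroups)
        assert a.r == pytest.approx(b.r)
        assert a.tau2 == pytest.approx(b.tau2)

    def test_aggregate_within_group_range_and_fe_reduction(self):
        groups = {
            "a": rank_pairs(0.2, 23, seed=5),
            "b": rank_pairs(0.5, 33, seed=6),
        }
        meta = meta_spearman(groups)
        rs = list(meta.group_r.values())
        assert min(rs) <= meta.r <= max(rs)
        if meta.tau2 == 0:
            z = np.arctanh(rs)
            w = np.array([len(groups["a"][0]) - 3, len(groups["b"][0]) - 3])
            assert meta.r == pytest.approx(np.tanh((w * z).sum() / w.sum()))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_meta_matches_metafor(tmp_path):
    """Cross-check the DL aggregation against the metafor package."""
    groups = {
        "a": rank_pairs(0.15, 18, seed=7),
        "b": rank_pairs(0.45, 27, seed=8),
        "c": rank_pairs(-0.1, 22, seed=9),
    }
    meta = meta_spearman(groups)
    rs = ",".join(str(meta.group_r[g]) for g in sorted(meta.group_r))
    ns = ",".join(str(meta.group_n[g]) for g in sorted(meta.group_n))
    script = tmp_path / "meta.R"
    script.write_text(
        f"""
        suppressMessages(library(metafor))
        r <- c({rs}); n <- c({ns})
        m <- rma(yi=atanh(r), vi=1/(n-3), method="DL")
        cat(tanh(m$beta), tanh(m$ci.lb), tanh(m$ci.ub), m$tau2, m$pval, sep="\\n")
        """
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
    r, lo, hi, tau2, p = map(float, out.stdout.split())
    assert meta.r == pytest.approx(r, abs=1e-6)
    assert meta.ci_low == pytest.approx(lo, abs=1e-6)
    assert meta.ci_high == pytest.approx(hi, abs=1e-6)
    assert meta.tau2 == pytest.approx(tau2, abs=1e-6)
    assert meta.p == pytest.approx(p, abs=1e-6)


class TestTeamGameTotals:
    def test_two_side_bookkeeping(self):
        rows = [("g1", "SSG", "U15", "A", "P1", "pass_forward", "success")] * 10
        rows += [("g1", "SSG", "U15", "B", "P2", "pass_forward", "success")] * 4
        ev = make_events(rows)
        games = pd.DataFrame(
            {
                "game_id": ["g1", "g1"],
                "format": ["SSG", "SSG"],
                "team": ["U15", "U15"],
                "side_team_id": ["A", "B"],
                "shots_on_target": [2, 0],
            }
        )
        totals = team_game_indicator_totals(ev, games).set_index("side_team_id")
        assert totals.loc["A", "shots_on_target"] == 2
        assert totals.loc["A", "shots_on_target_conceded"] == 0
        assert totals.loc["B", "shots_on_target_conceded"] == 2
        assert totals.loc["A", "pass_forward"] == 10

    def test_game_without_two_sides_rejected(self):
        ev = make_events([("g1", "SSG", "U15", "A", "P1", "pass_forward", "success")])
        games = pd.DataFrame(
            {
                "game_id": ["g1"],
                "format": ["SSG"],
                "team": ["U15"],
                "side_team_id": ["A"],
                "shots_on_target": [1],
            }
        )
        with pytest.raises(ValueError, match="two sides"):
            team_game_indicator_totals(ev, games)

    def test_common_latent_factor_yields_positive_offensive_weights(self):
        study = generate_study(GeneratorConfig(seed=21, team_strength_sd=0.8))
        totals = team_game_indicator_totals(merge_indicators(study.events), study.games)
        weights, _ = derive_weights(totals)
        assert weights["pass_forward"] > 0.2
        assert weights["chance_created"] > 0.1
        assert weights["shot_on_target"] == 1.0


class TestCompositeScores:
    def _teams(self, players, team="U15"):
        return pd.Series(team, index=players)

    def test_reference_formula_all_z_one(self):
        # an indicator vector that z-scores to exactly +1/-1 in a 2-player team
        idx = ["P1", "P2"]
        cols = [
            "pass_forward",
            "offensive_duel",
            "chance_created",
            "shot_on_target",
            "defensive_duel",
            "pass_interception",
            "applying_pressure",
        ]
        base = pd.DataFrame(
            {c: [1.0, 1.0 - np.sqrt(2)] for c in cols}, index=idx
        )  # z(P1) = +1/sqrt(2)... not +1
        # two players: z-scores are +-1/sqrt(2); scale so P1's z is exactly 1
        scores = composite_scores(base, REFERENCE_WEIGHTS, self._teams(idx))
        z1 = 1 / np.sqrt(2)
        assert scores.loc["P1", "offensive"] == pytest.approx(1.88 * z1)
        assert scores.loc["P1", "defensive"] == pytest.approx(0.31 * z1)

    def test_weight_sums_match_published_formula(self):
        # with every offensive z = 1 the composite is 0.21+0.17+0.50+1 = 1.88;
        # with every defensive z = 1 it is -(-0.14-0.06-0.11) = 0.31
        off = REFERENCE_WEIGHTS["pass_forward"] + REFERENCE_WEIGHTS["offensive_duel"] + \
            REFERENCE_WEIGHTS["chance_created"] + REFERENCE_WEIGHTS["shot_on_target"]
        de = -(REFERENCE_WEIGHTS["defensive_duel"] + REFERENCE_WEIGHTS["pass_interception"]
               + REFERENCE_WEIGHTS["applying_pressure"])
        assert off == pytest.approx(1.88)
        assert de == pytest.approx(0.31)

    def test_all_average_player_scores_zero(self):
        rng = np.random.default_rng(2)
        idx = [f"P{i}" for i in range(9)]
        cols = list(REFERENCE_WEIGHTS)
        base = pd.DataFrame(rng.normal(size=(9, len(cols))), index=idx, columns=cols)
        # append a player sitting exactly at the team mean of every indicator
        base.loc["MEAN"] = base.mean()
        scores = composite_scores(base, REFERENCE_WEIGHTS, self._teams(base.index))
        assert scores.loc["MEAN", "offensive"] == pytest.approx(0.0, abs=1e-10)
        assert scores.loc["MEAN", "defensive"] == pytest.approx(0.0, abs=1e-10)

    def test_within_team_composite_mean_is_zero(self):
        rng = np.random.default_rng(3)
        idx = [f"P{i}" for i in range(12)]
        cols = list(REFERENCE_WEIGHTS)
        base = pd.DataFrame(rng.normal(size=(12, len(cols))), index=idx, columns=cols)
        teams = pd.Series(["U15"] * 6 + ["U17"] * 6, index=idx)
        scores = composite_scores(base, REFERENCE_WEIGHTS, teams)
        for team in ("U15", "U17"):
            sub = scores[teams == team]
            assert sub["offensive"].mean() == pytest.approx(0.0, abs=1e-10)
            assert sub["defensive"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_missing_indicator_drops_player_from_that_composite_only(self):
        idx = ["P1", "P2", "P3"]
        cols = list(REFERENCE_WEIGHTS)
        base = pd.DataFrame(1.0, index=idx, columns=cols)
        base.loc["P2"] = [1.0, 2.0, 0.5, 1.5, 2.0, 0.3, 0.7]
        base.loc["P3"] = [0.2, 0.4, 1.5, 0.5, 1.0, 1.3, 0.1]
        base.loc["P1", "offensive_duel"] = np.nan
        scores = composite_scores(base, REFERENCE_WEIGHTS, self._teams(idx))
        assert np.isnan(scores.loc["P1", "offensive"])
        assert np.isfinite(scores.loc["P1", "defensive"])

    def test_single_player_team_is_an_error(self):
        base = pd.DataFrame(1.0, index=["P1"], columns=list(REFERENCE_WEIGHTS))
        with pytest.raises(ValueError, match="single player"):
            composite_scores(base, REFERENCE_WEIGHTS, self._teams(["P1"]))

    def test_higher_defensive_skill_raises_defensive_score(self):
        # more duels won / interceptions => z up => weighted sum more negative
        # => final (sign-flipped) score higher
        rng = np.random.default_rng(12)
        idx = ["GOOD", "AVG", "BAD"]
        cols = list(REFERENCE_WEIGHTS)
        base = pd.DataFrame(rng.normal(size=(3, len(cols))), index=idx, columns=cols)
        defensive = ["defensive_duel", "pass_interception", "applying_pressure"]
        base.loc["GOOD", defensive] = 2.0
        base.loc["AVG", defensive] = 0.0
        base.loc["BAD", defensive] = -2.0
        scores = composite_scores(base, REFERENCE_WEIGHTS, self._teams(idx))
        assert scores.loc["GOOD", "defensive"] > scores.loc["AVG", "defensive"]
        assert scores.loc["AVG", "defensive"] > scores.loc["BAD", "defensive"]


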