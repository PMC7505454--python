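"""Random-intercept logistic player scores for success/failure indicators.

For indicators with a successful/unsuccessful outcome (forward passes,
offensive duels, defensive duels) a naive success fraction is unreliable when
trial counts differ across players.  Instead, each player's trials are
modelled with a random-intercept multilevel logistic regression,

    logit P(success_ij) = beta0 + beta_team(i) + u_i,   u_i ~ N(0, sigma_u^2),

with the age-category team as a categorical covariate (reference team =
lexicographically first) and one random intercept per player.  The marginal
likelihood integrates the random effect per player; because all covariates
are constant within a player the per-player data reduce to a
(successes, failures) pair and each integral is one-dimensional.  It is
evaluated by adaptive Gauss-Hermite quadrature (nodes centred on the
player's posterior mode, scaled by the Laplace curvature) and maximised by
L-BFGS-B, which makes the fit deterministic for a fixed configuration.

A player's performance score is the empirical-Bayes linear predictor
``beta0 + beta_team + u_hat_i`` on the logit scale; the shrinkage of the
random-effect prior keeps scores finite even for players whose trials were
all successes or all failures.  All downstream use is rank-based, so any
strictly monotone transform of the score is equivalent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from ssgperf.data_model import OUTCOME_FAILURE, OUTCOME_SUCCESS


class SeparationError(RuntimeError):
    """All outcomes identical overall: the intercept is not identified."""


@dataclass
class SuccessModelFit:
    """Fitted random-intercept logistic model for one indicator in one format."""

    indicator: str
    fmt: str
    teams: list[str]
    reference_team: str
    beta0: float
    team_effects: dict[str, float]  # reference team maps to 0.0
    sigma_u: float
    player_modes: pd.Series  # empirical-Bayes mode u_i per player with >=1 trial
    player_teams: pd.Series
    n_trials: pd.Series
    converged: bool
    loglik: float
    method: str = "adaptive_gauss_hermite"
    n_quad: int = 21
    ridge: bool = False
    message: str = ""
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """JSON-serialisable coefficient summary (one model of the S-table
        style layout: fixed effects, random-intercept SD, convergence)."""
        return {
            "indicator": self.indicator,
            "format": self.fmt,
            "reference_team": self.reference_team,
            "fixed_intercept": self.beta0,
            "team_effects": dict(self.team_effects),
            "random_intercept_sd": self.sigma_u,
            "n_players": int(len(self.player_modes)),
            "n_trials_total": int(self.n_trials.sum()),
            "log_likelihood": self.loglik,
            "converged": bool(self.converged),
            "method": self.method,
            "n_quad": self.n_quad,
            "ridge_penalty": bool(self.ridge),
        }


def _posterior_modes(s, f, eta0, sigma, max_iter=50):
    """Vectorised Newton search for the mode of each player's random-effect
    posterior and the Laplace standard deviation at the mode."""
    u = np.zeros_like(eta0)
    inv_v = 1.0 / sigma**2
    n = s + f
    for _ in range(max_iter):
        p = expit(eta0 + u)
        grad = s - n * p - u * inv_v
        hess = -(n * p * (1 - p)) - inv_v
        step = grad / hess
        # damp large steps; the objective is strictly concave so this converges
        step = np.clip(step, -4.0, 4.0)
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta0 + u)
    hess = -((s + f) * p * (1 - p)) - inv_v
    h = 1.0 / np.sqrt(-hess)
    return u, h


def _marginal_loglik(s, f, eta0, sigma, nodes, logw):
    """Per-player marginal log-likelihood by adaptive Gauss-Hermite."""
    if sigma < 1e-6:
        # degenerate random effect: plain logistic likelihood
        p = expit(eta0)
        eps = 1e-12
        return s * np.log(p + eps) + f * np.log(1 - p + eps)
    m, h = _posterior_modes(s, f, eta0, sigma)
    u = m[:, None] + math.sqrt(2.0) * h[:, None] * nodes[None, :]
    eta = eta0[:, None] + u
    # binomial log-likelihood + normal prior log-density at each node
    ll = (
        s[:, None] * eta
        - (s + f)[:, None] * np.logaddexp(0.0, eta)
        - 0.5 * (u / sigma) ** 2
    )
    log_integrand = logw[None, :] + nodes[None, :] ** 2 + ll
    log_int = logsumexp(log_integrand, axis=1) + 0.5 * math.log(2.0) + np.log(h)
    return log_int - 0.5 * math.log(2.0 * math.pi) - math.log(sigma)


def _sufficient_stats(events: pd.DataFrame) -> pd.DataFrame:
    ok = events["outcome"].isin([OUTCOME_SUCCESS, OUTCOME_FAILURE])
    if not ok.all():
        raise ValueError("success model requires binary outcomes only")
    tab = (
        events.assign(y=(events["outcome"] == OUTCOME_SUCCESS).astype(int))
        .groupby(["player_id", "team"], observed=True)["y"]
        .agg(successes="sum", trials="count")
        .reset_index()
    )
    tab["failures"] = tab["trials"] - tab["successes"]
    return tab


def fit_success_model(
    events: pd.DataFrame,
    n_quad: int = 21,
    ridge_sd: float = 2.5,
) -> SuccessModelFit:
    """Fit the random-intercept logistic model to one indicator's events.

    Parameters
    ----------
    events
        Validated events for exactly one binary indicator in one format
        (merged view for duel indicators).
    n_quad
        Number of adaptive Gauss-Hermite nodes per player integral.
    ridge_sd
        Prior SD of the weakly-informative ridge penalty on fixed effects,
        activated automatically when some team's outcomes are all identical
        (quasi-separation); flagged in the fit diagnostics.

    Raises
    ------
    SeparationError
        If all outcomes in the data are identical (fit refused).
    ValueError
        If fewer than two players have trials, or the events span several
        indicators/formats.
    """
    for col in ("indicator", "format"):
        vals = events[col].unique()
        if len(vals) != 1:
            raise ValueError(f"events must cover exactly one {col}, got {list(vals)}")
    indicator = events["indicator"].iloc[0]
    fmt = events["format"].iloc[0]

    tab = _sufficient_stats(events)
    if len(tab) < 2:
        raise ValueError("need at least 2 players with trials")
    if tab["successes"].sum() == 0 or tab["failures"].sum() == 0:
        raise SeparationError(
            f"{indicator}/{fmt}: all outcomes identical; intercept not identified"
        )

    teams = sorted(events["team"].unique())
    reference = teams[0]
    s = tab["successes"].to_numpy(float)
    f = tab["failures"].to_numpy(float)
    team_idx = tab["team"].map({t: k for k, t in enumerate(teams)}).to_numpy()

    per_team = tab.groupby("team").agg(sj=("successes", "sum"), fj=("failures", "sum"))
    use_ridge = bool(((per_team["sj"] == 0) | (per_team["fj"] == 0)).any())
    if use_ridge:
        warnings.warn(
            f"{indicator}/{fmt}: a team has all-identical outcomes; "
            f"applying ridge penalty (prior SD {ridge_sd}) on fixed effects",
            stacklevel=2,
        )

    nodes, weights = hermgauss(n_quad)
    logw = np.log(weights)
    n_teams = len(teams)

    def unpack(theta):
        beta0 = theta[0]
        beta_team = np.concatenate([[0.0], theta[1 : n_teams]])
        sigma = math.exp(theta[-1])
        return beta0, beta_team, sigma

    def nll(theta):
        beta0, beta_team, sigma = unpack(theta)
        eta0 = beta0 + beta_team[team_idx]
        ll = _marginal_loglik(s, f, eta0, sigma, nodes, logw).sum()
        if use_ridge:
            ll -= 0.5 * (theta[: n_teams] ** 2).sum() / ridge_sd**2
        return -ll

    frac = np.clip(s.sum() / (s.sum() + f.sum()), 0.02, 0.98)
    theta0 = np.zeros(n_teams + 1)
    theta0[0] = math.log(frac / (1 - frac))
    theta0[-1] = math.log(0.5)

    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * n_teams + [(math.log(1e-4), math.log(10.0))],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        warnings.warn(
            f"{indicator}/{fmt}: optimizer did not report convergence: {res.message}",
            stacklevel=2,
        )

    beta0, beta_team, sigma = unpack(res.x)
    eta0 = beta0 + beta_team[team_idx]
    modes, _ = _posterior_modes(s, f, eta0, max(sigma, 1e-6))

    return SuccessModelFit(
        indicator=indicator,
        fmt=fmt,
        teams=teams,
        reference_team=reference,
        beta0=float(beta0),
        team_effects={t: float(beta_team[k]) for k, t in enumerate(teams)},
        sigma_u=float(sigma),
        player_modes=pd.Series(modes, index=tab["player_id"].to_numpy(), name="u"),
        player_teams=pd.Series(
            tab["team"].to_numpy(), index=tab["player_id"].to_numpy(), name="team"
        ),
        n_trials=pd.Series(
            tab["trials"].to_numpy(), index=tab["player_id"].to_numpy(), name="n_trials"
        ),
        converged=bool(res.success),
        loglik=float(-res.fun),
        n_quad=n_quad,
        ridge=use_ridge,
        message=str(res.message),
    )


def player_posterior_scores(
    fit: SuccessModelFit, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Empirical-Bayes performance scores, one row per player.

    score = beta0 + beta_team + u_i on the logit scale.  When a roster is
    supplied, retained players without any trial on this indicator receive
    the fully shrunk score ``beta0 + beta_team`` (u_i = 0, n_trials = 0).
    """
    rows = {
        "player_id": list(fit.player_modes.index),
        "team": list(fit.player_teams.values),
        "u": list(fit.player_modes.values),
        "n_trials": list(fit.n_trials.values),
    }
    df = pd.DataFrame(rows)
    if roster is not None:
        missing = roster[~roster["player_id"].isin(df["player_id"])]
        if len(missing):
            extra = pd.DataFrame(
                {
                    "player_id": missing["player_id"].to_numpy(),
                    "team": missing["team"].to_numpy(),
                    "u": 0.0,
                    "n_trials": 0,
                }
            )
            df = pd.concat([df, extra], ignore_index=True)
    unknown = set(df["team"]) - set(fit.team_effects)
    if unknown:
        raise ValueError(f"team(s) not in fit: {sorted(unknown)}")
    df["score"] = fit.beta0 + df["team"].map(fit.team_effects) + df["u"]
    df["indicator"] = fit.indicator
    df["format"] = fit.fmt
    return df[["player_id", "team", "indicator", "format", "score", "n_trials"]]
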