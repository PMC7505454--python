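# Methods

This note documents the statistical procedures implemented in `ssgperf`,
the assumptions behind the synthetic-study generator, and the numerical and
design choices made where several defensible options existed.

## Data model

The unit of observation is one coded on-ball event. Eleven raw indicator
types are recognised; each maps to exactly one side (offense/defense) and
one outcome type:

| indicator | side | outcome |
|---|---|---|
| pass_forward | offense | binary |
| dribble, take_on | offense | binary (merged → offensive_duel) |
| chance_created, shot_on_target | offense | count |
| offensive_aerial_duel | offense | binary |
| tackle, staying_in_front | defense | binary (merged → defensive_duel) |
| applying_pressure, pass_interception | defense | count |
| defensive_aerial_duel | defense | binary |

Input files carry raw labels only; merging is a pipeline step, so the
player-quantification view (merged duels) and the representativeness view
(all eleven labels distinct) derive from the same file. Aerial duels are
validated on input but excluded from individual player quantification and
from weight derivation: they are too sparse at the individual level in the
small-sided format for a stable per-player estimate.

**Player exclusion.** Players with zero 11-vs-11 minutes are dropped, as are
players whose small-sided-game count is *more than* two sample standard
deviations (n−1 denominator) below their team's mean — strict inequality, so
a player exactly at the boundary is retained. Both criteria are evaluated
once, on the roster as given; the policy is deliberately not iterated to a
fixed point (removing low outliers shifts the team mean upward, and an
iterated rule could cascade). The SD criterion is per team; for a team of
one it is skipped with a warning.

**Inter-rater QC.** `cohens_kappa` implements the standard
κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products, as the
reliability check for double-coded games. κ is undefined (and signalled)
when both raters are constant and identical.

## Rate statistics

Count-type indicators are scored as events per six-minute bout,
`6·count/minutes`, against the player's *total* minutes in the format. A
per-player (rather than per-game) exposure is used because all downstream
analyses are per-player; rates are computed separately per format and only
ever compared on the per-bout scale. Zero-exposure players are an error at
this stage — they must have been excluded upstream.

## Random-intercept success model

For binary-outcome indicators, per-player success fractions are unreliable
when trial counts vary widely, so the package fits, per indicator and
format,

    logit P(success_ij) = β₀ + β_team(i) + u_i,  u_i ~ N(0, σ_u²),

with team as a fixed categorical covariate (reference team =
lexicographically first) and one random intercept per player. Because all
covariates are constant within a player, the data reduce to per-player
(successes, failures) pairs and the marginal likelihood factorises into
one-dimensional integrals. These are evaluated by *adaptive* Gauss–Hermite
quadrature — 21 nodes centred on each player's posterior mode with the
Laplace curvature as scale — and maximised by L-BFGS-B over
(β₀, β_team, log σ_u). The fit is deterministic given the data and the
recorded configuration (method and node count are stored in the fit
object). Agreement with `lme4::glmer` (nAGQ = 10) is verified in the test
suite to ~1e-3 on all coefficients and to ~1e-5 on the per-player modes.

A player's score is the empirical-Bayes linear predictor
β₀ + β_team + û_i on the logit scale. All downstream use is rank-based
(Spearman), so any strictly monotone transform of the score is equivalent;
the logit scale is kept for numerical symmetry. A player with zero trials
receives the fully shrunk score β₀ + β_team, but is treated as *missing*
for composites and per-indicator validity (mirroring the exclusion of
players without duel events from those analyses).

Degenerate inputs: if all outcomes are identical the fit is refused
(intercept not identified). If one team's outcomes are all identical
(quasi-separation), a weakly informative ridge penalty (prior SD 2.5) on
the fixed effects keeps the estimates finite; the fallback is flagged in
the diagnostics.

## Meta-analytic correlation aggregation

All validity-type quantities are Spearman correlations (mid-rank ties)
computed *within* groups and aggregated by a random-effects meta-analysis:
Fisher transform z = atanh(r) with variance 1/(n−3), DerSimonian–Laird
between-group variance τ², inverse-variance weights 1/(1/(n−3)+τ²), and a
normal-theory 95% CI and two-sided p on the pooled z, back-transformed. DL
is the default because it is non-iterative and deterministic; an iterative
REML estimator is available behind `tau2_estimator="REML"`. With one group
the aggregate reduces to that group's coefficient. Groups with fewer than
`min_n = 4` complete pairs or zero variance are skipped with a warning;
|r| = 1 coefficients are clamped at 1 − 1e−6 before the transform to keep z
finite (the back-transformed aggregate still rounds to ±1).

## Indicator weights and composites

A game-side's performance on a count indicator is its event count in that
game; on a binary indicator it is the count of *successful* events (a
success-proportion alternative sits behind
`binary_performance="proportion"`; the count is the default because the
game-level accounting throughout is count-based). Offensive rows are paired
with the side's own shots on target, defensive rows with the opposing
side's (= shots conceded). Correlations are computed per team *and* format
— pooling the two formats would let the tenfold scale difference between a
45-minute half and a 6-minute game masquerade as a positive association —
then aggregated as above. Shots on target itself carries a fixed weight
of 1 (it is the proxy).

Composites are weighted sums of within-team z-scores (sample SD; an
all-constant indicator within a team gives z = 0 with a warning; a
single-player team is an error). The defensive weighted sum is multiplied
by −1 so that higher is better on both composites. The player's own
shots-on-target *z-score* enters the offensive composite at weight 1:
z-scoring is applied to every term because the published formula denotes
standardized scores throughout. A player missing any indicator of a
composite gets a missing composite rather than an imputed one. Weights are
freshly derived by default; `weights_source="reference"` substitutes the
published reference weights (0.21, 0.17, 0.50, 1; −0.14, −0.11, −0.06).

## Representativeness

The 11-vs-11 counts define multinomial proportions p_i; expected SSG counts
are E_i = N·p_i (computed from exact count ratios, not rounded
proportions), χ² = Σ(O−E)²/E on k−1 df with an upper-tail p-value.
Residuals use the multinomial-adjusted form (O−E)/√(E(1−p)), whose variance
is 1 under the fitted model; the plain Pearson form (O−E)/√E understates
deviations in large categories, and the test suite asserts the adjusted
convention. Removing a category (the aerial-duel sensitivity analysis) is
an explicit re-run on the reduced indicator set. The accompanying effect
size is the Spearman correlation between the two observed-count vectors,
with a Fisher-z CI (SE 1/√(k−3)) computed on the unrounded coefficient.
p-values below 0.01 are displayed as "< 0.01".

## Synthetic-study generator

The generator emulates the reference academy design: four age-category
teams of 17/15/16/15 players; 19/12/20/16 six-minute 7-vs-7 games per team
(14 of the squad appear per game, sides re-drawn every game, so the mean
number of SSGs per player matches the reference 16/11/18/15); six 45-minute
11-vs-11 halves per team with 11 random players each, against an uncoded
external opponent.

Structure, per player i, game-side s, indicator j:

* latent abilities: offensive and defensive, one pair per format, joined
  across formats by a Gaussian copula with correlation ρ (default 0.7) —
  the single knob for true predictive validity;
* count events: Poisson with mean λ_j^fmt · bouts · exp(γ·a_i + S_s),
  with ability loading γ = 0.4 and per-game-side strengths
  S ~ N(0, 0.3²); shot rates are additionally suppressed by the opposing
  side's defensive strength (loading 0.3), which induces the positive
  offense-vs-shots and negative defense-vs-conceded team-level
  correlations that weight derivation estimates;
* binary events: attempts Poisson as above, successes Bernoulli with
  logit β₀_j + team effect + σ_u·a_i (σ_u default 0.5, team effects
  0/0.1/0.2/0.3);
* all multiplicative modifiers are mean-centred on the log scale so the
  configured λ equal population-mean rates (tested: realised totals within
  3–3.5 Monte-Carlo SEs);
* base rates default to the reference study's per-format indicator totals
  divided by the design's total player exposure in bouts, so the synthetic
  frequency structure (including SSG aerial suppression) echoes the
  observed one;
* test scores load on the average of the offensive and defensive latent
  ability with correlation 0.2 (sprints and agility negatively — faster is
  better; ISRT positively), with MCAR missingness at the reference rates
  (≈9.5% sprint/agility, ≈1.6% ISRT);
* each side's shots on target accumulate from its generated shot events;
  the uncoded 11-vs-11 opponent contributes a team-level Poisson shot
  count.

Everything flows from one `numpy.random.Generator`, so a study is a pure
function of its configuration and regeneration is byte-identical.
`replicate` derives child seeds from the master seed via a
`SeedSequence.spawn`, isolating callback failures per replicate.

What the generator does **not** emulate: positions and spatial structure,
within-game fatigue or momentum, dependence between indicators beyond the
shared latent abilities and side strengths, realistic substitution
patterns, and non-random test-score missingness. Passing tests therefore
show that the estimators recover the generating structure at the study's
design size — not that real match data satisfy that structure.

## Simulation experiments (`ssgperf.experiments`)

* **Null coverage**: 200 zero-consistency (ρ = 0) replicates at the default
  design; ~95% of aggregated rate-indicator validity CIs should contain 0.
  Observed ≈ 95–97% — slightly conservative, consistent with DL's known
  small-k behaviour with four groups.
* **Consistency recovery**: ρ = 0.9 with 25-fold event rates, loading 1.0
  and side-strength SD 0.05 (the low-noise condition), 40 replicates; the
  mean aggregated coefficient per rate indicator should sit within 0.1 of
  the generator's latent target validity (the meta-aggregated Spearman
  correlation of the true latent abilities across formats). The residual
  gap is Poisson rank-attenuation, which shrinks as exposure grows.
* **Ability-SD recovery**: 60 players (4 teams × 15), σ_u = 1, team effects
  0/0.3/−0.3/0.5, forward-pass rate raised so every player has ≥ 50 trials;
  one fit should recover σ_u within ±0.35 and rank players consistently
  with the truth (Spearman ≥ 0.7). Team-effect point estimates are *not*
  asserted: with 15 players per team the sampled team-mean ability
  confounds the fixed effect (SE ≈ σ_u/√15), which is a property of the
  design, not the estimator.

Replicate counts (200/40/1) were chosen to keep the full experiment suite
around a minute on one CPU while leaving Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

* The success model supports a single (player) random-intercept level — no
  crossed game-level effects or random slopes.
* Weight derivation is univariate (indicator vs proxy); collinear
  indicators are not adjusted for each other.
* The normal-theory CI on the DL aggregate ignores uncertainty in τ²;
  with four teams the intervals are mildly conservative under homogeneity.
* The Fisher-z variance 1/(n−3) is an approximation for Spearman
  coefficients (the exact variance is ≈6% larger), shared with standard
  practice.
* Position-stratified and longitudinal validity are out of scope.
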