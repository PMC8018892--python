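# Methods

## Scope and approach

`riskchoice` implements a complete desk pipeline for the axiomatic
analysis of risky binary choice: gamble algebra, stochastic tests of the
expected-utility axioms (dominance, transitivity, continuity),
indifference-point (IP) and indifference-curve (IC) estimation, discrete
choice value-model fitting and comparison, and a single-trial choice
regression. Since no behavioral data ship with the package, a
first-class synthetic-agent module generates trial tables with the
statistical structure the analyses assume, and the validation studies
(`riskchoice.benchmarks`, `scripts/acceptance.py`) characterize the
pipeline's sensitivity, specificity and recovery on that synthetic data.
Passing these studies shows the machinery is correct and well calibrated
under its own generating assumptions; it does not by itself certify
behavior on real animals, whose choices include history effects,
satiation and attentional lapses beyond the generator's model.

## Gambles

A gamble is a finite distribution over reward magnitudes (ml), kept in
canonical form: outcomes sorted ascending, magnitudes within 1e-9 ml
merged by summing probability, probabilities validated to sum to 1
within 1e-9 and renormalized (text round-trip safety), zero-probability
outcomes dropped. Merging matters: the three-outcome mixtures used in
Marschak–Machina-triangle tests arise from two-outcome components that
share a middle outcome, and must merge to live on the simplex. The
triangle maps a gamble on three fixed magnitudes (0, 0.25, 0.5 ml by
default) to (p1, p3), the probabilities of the lowest and highest
outcome.

First-order stochastic dominance is decided on the pooled support: g1
dominates g2 iff CDF_g1 ≤ CDF_g2 everywhere with strict inequality
somewhere.

## Stochastic axiom tests

Deterministic axioms are read stochastically: "A preferred to B" means
the A-choice proportion differs from 0.5 by an exact two-sided binomial
test (p < 0.05), with direction taken from the point estimate.
Clopper–Pearson intervals are used throughout because per-condition trial
counts are small (tens).

* **FSD**: per-pair preference for the dominant option plus a pooled
  verdict (pooled binomial 95% CI above 0.5).
* **Transitivity**: weak stochastic transitivity (WST) requires all three
  triplet proportions significantly above 0.5; strong (SST) additionally
  requires the A-over-C proportion to be at least the maximum of the
  other two, compared on point estimates without an extra test, since the
  definition is stated on proportions.
* **Continuity**: B against mixtures AC(p_A) on a grid (0–1 in 0.1 steps
  by default). Per-level binomial tests are Benjamini–Hochberg corrected
  within the test — the FDR family is the set of levels of one test, so
  compliance semantics do not depend on how many other tests were run.
  Compliance = (a) at least one significantly dispreferred and one
  significantly preferred *interior* level (Archimedean criterion) and
  (b) significant positive Spearman correlation between p_A and the
  binary choice at trial level (monotonicity). The endpoint levels
  p_A = 0 and p_A = 1 are pure C-vs-B and A-vs-B choices: they restate
  the A ≻ B ≻ C premise rather than probe the axiom, so they are
  excluded from the Archimedean count (a magnitude-first lexicographic
  agent, which genuinely violates continuity, would otherwise pass on
  its endpoint behavior alone). An optional explicit precheck of
  A ≻ B and B ≻ C raises an error when the ranking premise fails,
  because the test is undefined without it; the precheck pools sessions
  by default.

The trial-level Spearman choice maximizes power and is defined for any
level design; group-level alternatives differ only in tie handling.

## Indifference points and curves

The IP is estimated by weighted nonlinear least squares of the softmax
P(p_A) = 1/(1+exp(−(p_A−α)/τ)) to per-level choice proportions, weights
proportional to per-level trial counts. α starts at the interpolated
empirical 0.5 crossing (always computable from the data), τ at 0.1 with
bounds (1e-4, 10]. By construction the fitted curve equals 0.5 at α
exactly. When the proportions never cross 0.5, the fit is returned but
flagged `extrapolated`. The 95% CI on α comes from a seeded bootstrap
that resamples trials within each level (binomial resampling, exactly
equivalent to resampling that level's trials with replacement); 200
resamples by default, configurable.

ICs are fitted to (magnitude, probability) IP sets by least squares in
the probability domain, with three forms: linear a·x+b, power a·(x−c)^b
and hyperbolic a+b/(x−c). The power offset is constrained to
0 ≤ c < min(x) so the base stays positive; the hyperbolic pole is kept
below the data range. Leave-one-out coverage refits without each point
and checks containment in a bootstrap 95% band at the left-out
magnitude.

IP variability: sessions are split at the trial-index midpoint (odd
counts put the middle trial in the first half), each half gets its own
softmax fit, and the per-session second-minus-first differences are
tested with a one-sample t test. Across-session series are smoothed with
a centered 5-session moving average (windows shrink at the edges).

## Value models and MLE

All utilities are normalized to [0, 1] on [0, m0] with m0 = 0.5 ml, the
maximum magnitude of the default design. Families and free parameters:

| kind            | value of a gamble                         | params          |
|-----------------|-------------------------------------------|-----------------|
| `EV`            | Σ (m_i/m0) p_i                            | τ               |
| `EU_power`      | Σ (m_i/m0)^a p_i                          | a, τ            |
| `EU_sshape`     | Σ exp(−b(−ln(m_i/m0))^a) p_i              | a, b, τ         |
| `PW`            | U(m\|a) · exp(−b_w(−ln p)^{a_w})          | a, a_w, b_w, τ  |
| `additive`      | ω_m U(m\|a) + ω_p p                       | a, ω_m, ω_p, τ  |
| `mean_variance` | EV + β · Risk (raw ml scale)              | β, τ            |

`PW` and `additive` are defined (as in prospect theory) only for gambles
with at most one non-zero outcome and raise an explicit error otherwise —
no silent extension to richer gambles. Both use the power utility for
U(m); the underlying theory leaves the utility family open and the power
form keeps these models nested above `EU_power` under identity
weighting. The additive model's (ω_m, ω_p, τ) triple is identified only
up to a common scale by choice probabilities; parameters are bounded and
all counted in the information criteria. β in the mean–variance model is
sign-free (risk seeking > 0, averse < 0). The S-shaped utility's log
domain ends at m0; above it the value saturates at 1 with a warning (the
default designs never exceed m0).

Choice probabilities follow the logistic rule on value differences.
Likelihoods clip probabilities at 1e-12 to stay finite under
near-deterministic fits. MLE minimizes the negative log-likelihood with
Nelder–Mead (derivative-free, robust to the multimodal S-shaped/PW
surfaces) from 5 seeded starts: a canonical initialization (all shape
parameters 1, τ = 0.1) plus log-scale Gaussian jitter. Positive
parameters are optimized on the log scale; τ is rejected outside
[1e-5, 50]. Each model family carries its own τ in comparisons.
Optional Wald CIs come from a central-difference Hessian at the optimum,
delta-method-transformed back from the log scale. BIC/AIC use n = number
of trials in the fitted set.

The model-predicted indifference map follows a pure grid procedure: for
each reference gamble B, probes step up from B's magnitude in 0.001 ml
increments, and for each probe the probability grid {0.001, …, 1.000} is
searched for the value closest to V_B, ties to the smaller p. For power
utility this agrees with the closed form p(m) = (m_B/m)^a within one
grid step (verified for a ∈ {0.5, 1, 2} over the whole design grid).

Model comparison reports four lower-is-better metrics per fit on a
common trial set: RMSE between modeled and measured IPs (probability
units), BIC, AIC, and `var_pref` — the variance across (test, level)
conditions of the difference between predicted and observed AC-choice
proportions.

Cross-IP correlation takes a sessions × IPs table, computes all pairwise
Pearson correlations on pairwise-complete sessions (pairs with fewer
than 3 shared sessions are skipped), groups pairs by shared indifference
curve, and tests each group's mean ρ against zero with a one-sample
t test.

## Choice regression

Logit(P_right) = β0 + β1 m_L + β2 p_L + β3 m_R + β4 p_R +
β5·preCh·preRew, fitted per session by MLE. preCh is the previous
trial's side (−1/+1, 0 on the first trial of a session) and preRew the
delivered reward in ml. Each option enters as (m, p) = (largest outcome
magnitude, its probability); degenerate options get p = 1 and the
all-zero option (0, 1). Zero-variance regressors are excluded and
reported as NaN; separation or non-convergence triggers a flagged
ridge-penalized refit. Standardization multiplies each slope by
SD(x)/SD(y) (the intercept has no standardized form and is tested raw —
it is the side bias). Population tests are one-sample t tests of the
per-session coefficients with BH-FDR across the six coefficients. A
session-random-effect variant is deliberately out of scope; per-session
fits plus population tests carry the across-session analysis.

## Synthetic agents

An agent is a value model plus noise, or a heuristic:

* **value**: P(A) = logistic((V_A−V_B)/τ + side-bias logit toward the
  right side).
* **lexicographic** (magnitude-first): pick the option with the larger
  maximum magnitude, ties broken by that outcome's probability; a lapse
  rate (default 0.02) mixes in random choice so proportions stay
  estimable. This agent satisfies transitivity but violates continuity —
  the canonical negative control.
* **indifferent**: P = 0.5 everywhere (null control for type-I rates).

Sessions balance left/right placement of each option exactly for even
repeat counts and shuffle trial order. Rewards are realized by sampling
the chosen gamble. Nonstationarity has two components: an
across-session Gaussian random walk on one named model parameter
(emulating slow risk-attitude drift), and a within-session linear IP
drift — trial t's perceived mixture probability is shifted by
δ(t) = decline·(2·frac(t)−1), so the half-session means of the measured
IP differ by exactly `decline`. Reproducibility comes from one root
seed with per-session substreams.

Two design presets mirror the task variants the analyses must handle:
"AB" (reference may be risky, low outcome 0 ml) and "CD"-style gambles
with a fixed small 0.05 ml low outcome, which have two non-zero
outcomes and are therefore scoreable only under EV/EU/mean–variance
kinds. Trial counts per condition default to 10–30; the underlying
experiments do not fix this number, and these values give the binomial
tests reasonable power at desk scale.

## Validation studies and problem sizes

`scripts/acceptance.py` (seeded, one CPU, a few minutes) recomputes:

1. Continuity sensitivity: EU-power agent (a = 0.8, τ = 0.05), triplet
   0.5/0.25/0 ml, 11 levels × 30 trials, 100 replicates; compliant and
   |α̂ − α_true| ≤ 0.05 with α_true = 0.5^0.8 from the closed form.
2. Specificity: lexicographic agent non-compliant (100 replicates);
   indifferent agent compliant in ≤ 5% (1,000 replicates).
3. Exactness: binomial test vs pmf enumeration for all (k, n ≤ 25);
   BH-FDR vs the brute-force step-up rule on 1,000 random p-vectors.
4. Indifference map vs closed form within one 0.001 grid step.
5. MLE recovery: ~5,000 trials/replicate from EU-power (a = 0.6,
   τ = 0.1), 20 replicates, all six families fitted; exponent within
   ±0.1, BIC picks the generating family; power fit to EV data has a
   CI covering a = 1.
6. Transitivity: value-ordered agent satisfies WST+SST at n = 100/pair;
   a 0.7-pairwise stochastic cycle violates WST.
7. Drift recovery: −0.10 within-session decline recovered to ±0.03 and
   significant over 50 sessions; drift-free control non-significant.
8. Cross-IP correlation: shared random-walk exponent across 60 sessions
   gives significantly positive mean ρ within and across ICs;
   independent-noise control non-significant.

The two "non-significant control" checks (7, 8) are 5%-level tests and
so carry the usual type-I risk under reseeding; all other quantities are
far from their thresholds.

## Known limitations

* The generator draws trials independently given the drifted state; real
  choice data show sequential dependencies the regression's single
  history term only partly captures.
* The regression's (m, p) encoding of multi-outcome options is a
  convention (largest outcome and its probability); no canonical
  encoding exists for three-outcome gambles in a scalar-per-attribute
  model.
* PW/additive values are undefined for gambles with two distinct
  non-zero outcomes; designs using a fixed small low outcome are scored
  only under EV/EU/mean–variance families.
* Only the logistic psychometric family is implemented (no
  probit/Weibull), and losses/reference-point adaptation are out of
  scope.
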