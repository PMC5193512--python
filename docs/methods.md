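# Methods

This note documents the models, numerical choices, and known limits of the
package. It covers the two prediction engines, the synthetic-data
generator, the ordinal mixed-model estimator, the model-selection layer,
and the power simulator.

## Causal Bayes net engine (`cbn`)

Three binary variables. The common-effect structure factorizes
`Pr(p,q,r) = Pr(p)·Pr(r)·Pr(q|p,r)` with `Pr(q|p,r)` given by either

- noisy-OR: `1 − (1−w_a)·(1−w_p)^ind(p)·(1−w_r)^ind(r)`, or
- noisy-AND: `1 − (1−w_a)·(1−w_pr)^(ind(p)·ind(r))`,

where `w_p`, `w_r` are causal powers (probability a cause alone produces
the effect), `w_pr` the conjunctive power, and `w_a` the aggregate weight
of background causes — all probabilities in [0, 1]. The common-cause
structure factorizes `Pr(q)·Pr(p|q)·Pr(r|q)`; the rule linking each effect
to the single cause is taken to be the one-parent special case of the
noisy-OR with a per-effect background weight `w_a`, which is the natural
reduction of the multi-cause rule (the structure itself fixes everything
the qualitative predictions need — screening-off holds for any
conditional-probability table of this factorization).

All inference is exact enumeration over the 8-cell joint. Conditioning on
a zero-probability event raises rather than returning a convention value.
A change magnitude below `1e-12` in absolute value is reported as sign 0;
this separates the exact independence identities (which hold to double
precision) from genuine discounting/augmentation, whose magnitudes on any
interior parameter grid are orders of magnitude larger. Sweeps over `w_a`
default to 101 evenly spaced points on [0, 1].

The theory-level prediction panel emits **signs only**. The quantitative
curves depend on base rates and powers that the paradigm never fixes, so
the panel uses a canonical interior parameterisation (base rates .2,
powers .9, `w_a` = .5 — the values used for the published sweep figures)
purely to extract signs, and leaves magnitudes undefined. For the second
study's diagnostic rule pairs (mutually exclusive alternatives, e.g.
glasses vs contact lenses), any network implementation — e.g. a
three-level corrected-vision node — predicts discounting whether or not
the consequent is known; the panel encodes those two cells as −1 directly
rather than through the three-binary-variable engine, which has no
mutually-exclusive-effects structure.

## Mental-models engine (`mentalmodels`)

A model set is an ordered list of distinct truth-value possibilities with
weights, equiprobable by default. Event probabilities are weighted
possibility proportions; conditioning excises violating possibilities and
renormalizes (with equiprobable weights the survivors are again
equiprobable). All arithmetic uses `fractions.Fraction`, so the worked
values — 1/10, 1/15, −1/6, 2/3 — are exact equalities in the tests, not
tolerance checks.

Three-variable interpretations are generated by filtering the eight truth
assignments with the interpretation's truth condition: the disjunctive
recoding *if (p or r) then q*, the conjunctive-consequent recoding
*if q then (p and r)*, its disjunctive-consequent dual *if q then (p or r)*,
and the four readings of the conjunctive-antecedent conditional
*if (p and r) then q* — material (7 possibilities), material + sole causes
(6; the effect cannot occur with no cause present), enables/reverse
conditional (5), biconditional (4). The enables reading's truth condition
coincides set-wise with the conjunctive-consequent recoding; both are kept
as separate named interpretations because they answer different design
cells.

Design choices where the calculus is silent:

- **Initial (truncated) models** carry an explicit implicit-model flag; the
  ellipsis is a marker, not a possibility. Because the calculus gives no
  way to count the implicit model, their change predictions are emitted as
  sign 0 with undefined magnitude ("no effects").
- **Shallow encodings** range over (p, r) only. The exclusive-or set gives
  a well-defined naive difference (0 − 1/2 = −1/2, discounting). The
  conjunctive set has a single possibility, making the literal difference
  degenerate (Pr(r) = Pr(r|p) = 1); its prediction is emitted as sign +1
  from the hypothesis's verbal content (learning p demands r), with no
  magnitude. Whether a principled positive magnitude exists is unresolved.
- **Condition order** for consequent-present cells is implemented as a
  single joint conditioning on {p, q} vs {q}; order is mathematically
  irrelevant for conjunctive events.
- Custom (non-equiprobable) weights are supported but nothing in the
  shipped analyses uses them; equiprobability is the naive-probability
  default.

## Synthetic data (`simulate`)

The generator is the exact generative dual of the fitted model: latent
`y* = effect_scale·sign(theory, condition) + u_participant + v_item + ε`
with `u ~ N(0, σ_P²)`, `v ~ N(0, σ_I²)`, `ε ~ N(0, 1)` (probit scale fixed
to 1 — the identification convention), cut at `θ1 < θ2` into −1/0/+1.
Making the generator the dual of the estimator is what renders parameter
recovery a well-posed check.

Study conditions baked into the defaults:

- scenario counts per causal direction: 10 causal + 7 diagnostic (first
  study), 6 + 6 (second study), each pool split as evenly as possible
  between the consequent-present and consequent-absent cells, with the odd
  item going to the present cell;
- items are **nested within cells** (participants see different materials
  in the C and NC tasks) and every participant rates every scenario once,
  giving 40×17 = 680 and 28×12 = 336 trials at the studies' sample sizes —
  the trial counts implied by the published information criteria;
- thresholds default to (−0.43, +0.43), which puts the three rating
  categories near uniform use under the null;
- `effect_scale` defaults to 1 latent SD per unit sign — effects of
  roughly the size the paradigm reports (standardized effects of 2–4);
  `σ_P = 0.5`, `σ_I = 0.3` give participant and item heterogeneity that is
  visible but smaller than the residual.

The generator emulates the design's statistical skeleton, not its surface:
no scenario content, no response-format or memory-load effects, no
violations of the generating model (e.g. non-normal random effects,
participant × condition interactions beyond the optional slope). Passing
recovery tests therefore shows the estimator is correct under its own
assumptions, not that real data satisfy them.

An explicit `cell_means` override bypasses the theory-sign layer for
calibration studies (e.g. a pure causal-direction effect). A
column-mapping and rating-recoding adapter on the CSV reader accommodates
externally deposited files whose schema differs from the canonical header.

## Ordinal mixed-model estimation (`clmm`)

Cumulative-link model with probit link: `Pr(y ≤ k | x, b) = Φ(θ_k − x'β − z'b)`.
Fixed effects use sum-to-zero coding (CE = +1/EC = −1, C = +1/NC = −1, and
their product), so latent cell means are signed sums of coefficients and
zero is "no change"; the published analyses do not state their coding, and
this choice matches marginal-means reporting. Thresholds are parameterized
as `(θ1, log(θ2 − θ1))` to enforce ordering.

Marginal maximum likelihood:

- **Crossed or slope structures** use a joint Laplace approximation: the
  stacked random-effect vector is profiled by a damped Newton iteration
  (analytic gradient and Hessian of the penalized log-likelihood, warm
  started across outer evaluations), and the marginal log-likelihood is
  the penalized maximum corrected by the log-determinant of the curvature.
  Crossed factors preclude simple nested quadrature, which is why the
  joint approximation is used.
- **A single random-intercept factor** uses adaptive Gauss–Hermite
  quadrature (15 nodes by default, minimum 7), with per-group modes and
  scales found by a vectorized Newton pass.
- **No random effects** reduces to ordered probit; the intercept-only ML
  thresholds are exactly `Φ⁻¹` of the empirical cumulative category
  proportions, which is also where every optimization starts (coefficients
  0, variances 0.5).

The outer optimizer is L-BFGS-B with finite-difference gradients, variance
parameters on the log scale bounded to [−6, 4] (σ between ~0.0025 and
~55), and a Nelder–Mead polish when there are no random effects or the
gradient-based stage reports a line-search failure; everything is
deterministic given data and specification. Non-convergence sets a flag
and raises a warning with the optimizer's diagnostic, never silently.
Category probabilities are computed with survival-function forms in the
tails and cutpoint arguments clamped at |z| = 37 (the double-precision
saturation point) so far-out linear predictors cannot overflow the
derivative ratios.

Random slopes default to a correlated intercept–slope covariance
(log-Cholesky parameterization), which reproduces the published
parameter counts (e.g. 8 for intercept + direction slope + item
intercepts); a `correlated=False` switch gives the diagonal variant, since
the published formulas do not disambiguate the covariance structure.

Simple effects: latent cell means and their standard errors come from the
fixed-effect block of the inverse numerical Hessian at the optimum;
pairwise contrasts are asymptotic z-ratios; per-cell tests against zero
use `t = mean/SE` with `df = n_participants − 1` (the df the published
t-statistics carry). The standardized effect is computed as
`d = 2|t|/√df`, the relation the published t/d pairs satisfy to their
printed precision (the textbook one-sample conversion `t/√n` does not
reproduce them).

The likelihood-ratio test requires nested specifications; the ladder
runner passes `allow_nonnested` because the published sequence itself
compares one non-nested pair (dropping the direction effect while keeping
its random slope), reporting the absolute deviance difference on the
absolute parameter difference as those tables do.

## Model selection (`selection`)

`BF = exp(BIC_prev − BIC_curr)` by default — the form the published tables
print (their BF columns of 0.01 and 0.02 follow it exactly, and are not
consistent with the conventional ½ factor); `schwarz=True` gives the
standard `exp(ΔBIC/2)` approximation. Display rounding is two decimals
below 100 and scientific notation above. Theory adjudication maps the
null, consequent-only, and direction + consequent fixed-effect structures
to the initial-models, fully-fleshed, and causal-model accounts, and
reports the BIC minimizer over fits with crossed random intercepts.

## Power simulation (`power`)

Each round: draw a calibration dataset of the prior-evidence size from
`N(gen_mean, gen_sd)`; use its sample mean and SD as the plug-in generator
for a simulated experiment of the candidate size; form the posterior of
`(μ, σ²)` under a normal likelihood with the noninformative
normal–inverse-χ² limit (`σ² ~ (n−1)s²/χ²_{n−1}`, `μ|σ² ~ N(x̄, σ²/n)`);
propagate to draws of `d = μ/σ` (2000 per round); compute the shortest
interval holding 95% of the sorted draws (sliding-window HDI); count the
round a success if the HDI lies entirely outside ±0.75 SD. Power is the
success fraction with a Jeffreys beta-binomial credible interval.

Rounds are keyed by (seed, round index) and the experiment reuses the
leading draws of a per-round standard-normal pool, so runs differing only
in candidate size or ROPE width are paired (common random numbers) — this
is what makes the monotonicity properties testable at modest simulation
counts. Defaults mirror the first study's planning inputs: mean −0.63,
`gen_sd = 0.63/2.32` (the SD implied by the printed mean and effect-size
mode, since the SD itself is not printed), calibration base 68, ROPE 0.75,
95% HDI. The exact generative procedure behind the published power values
is under-specified (what the calibration sample feeds is not stated), so
those values are qualitative reference points, not targets; the package's
contract is the procedure above plus its monotonicity and calibration
properties.

## Orchestration (`workflow`, `cli`)

A run config names a mode (predict / simulate / fit / ladder / power /
full), a seed, and sizes. The seed is fanned out to per-stage child seeds
via SHA-256, so stages are individually reproducible; identical configs
produce byte-identical numeric outputs, and every written table carries a
header naming the config hash. Reports are written both human-readable
(CSV tables) and machine-readable (JSON summary). The console script is a
thin argument parser over this module.

## Problem sizes in the shipped checks

The standing suite uses: 25 replicates at the first study's size (40
participants × 17 scenarios) for parameter recovery; 50 replicates at the
second study's size for selection consistency; 100 small replicates for
likelihood-ratio calibration; 200 simulation rounds per power estimate;
and a 6-participant dataset for the dense-quadrature oracle comparison.
These sizes keep every Monte-Carlo check comfortably away from its
decision boundary (e.g. recovery bias lands near 0.01–0.08 against a 0.15
bound; selection consistency at 50/50 against a 45/50 bound).

## Known limitations

- Networks are exactly three binary variables; no parameter learning, no
  interventions, no mutually-exclusive-effects (multinomial) nodes.
- The probit link is the only link; estimation is frequentist marginal ML
  (no MCMC), and the Laplace approximation's usual small-cluster variance
  bias applies to the crossed-random-effects fits.
- The mental-models engine covers the listed interpretations only; it does
  not model the construction process (working-memory dynamics) or
  pragmatic modulation beyond them.
- The power simulator's prior is the noninformative conjugate limit; a
  user wanting the heavier-tailed priors of common Bayesian-estimation
  packages must treat the current posterior as an approximation.
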