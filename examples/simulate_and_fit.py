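"""Generate a synthetic study and fit the cumulative-probit mixed model.

Simulates 40 participants under the causal-model sign pattern (discounting
in CEC, augmentation in ECNC), fits CR ~ CD + C with crossed participant
and item intercepts, and reports latent-scale cell means with simple
effects -- the same summaries the published analysis reports.
"""

from discaug import (
    ClmSpec,
    RandomTerm,
    SimConfig,
    Theory,
    emmeans_simple_effects,
    fit_clm,
    simulate_experiment,
)

records = simulate_experiment(
    SimConfig(n_participants=40, theory=Theory.CM, effect_scale=1.0, seed=42)
)
print(f"simulated {len(records)} trials "
      f"(40 participants x 17 scenarios, ratings -1/0/+1)")

spec = ClmSpec(
    fixed=("CD", "C"),
    random=(RandomTerm(factor="participant"), RandomTerm(factor="item")),
)
fit = fit_clm(records, spec)
print(f"\nfitted {fit.spec.formula}")
print(f"  loglik = {fit.loglik:.2f}, AIC = {fit.aic:.1f}, BIC = {fit.bic:.1f}")
print(f"  thresholds = ({fit.thresholds[0]:.3f}, {fit.thresholds[1]:.3f})")
for name, value in fit.coefficients.items():
    print(f"  beta_{name} = {value:.3f}")
for name, value in fit.variance_components.items():
    print(f"  {name} = {value:.3f}")

emm = emmeans_simple_effects(fit)
print("\nlatent-scale cell means (0 = no change):")
print(emm.cell_means.round(3).to_string(index=False))
print("\none-sample tests vs zero (d = standardized effect):")
print(emm.vs_zero.round(3).to_string(index=False))

print(
    "\nThe CEC mean sits below zero (discounting) and ECNC above"
    "\n(augmentation), recovering the generating pattern; the d column is"
    "\ncomparable to the published effect sizes."
)
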