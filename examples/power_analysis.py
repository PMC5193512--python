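"""Prospective Bayesian power with a 0.75-SD ROPE on the effect size.

Reproduces the planning logic of the first study: prior evidence (a
68-participant calibration base with mean change rating -0.63 and
standardized effect -2.32) feeds simulated replications at candidate
sample sizes; power is the probability that the 95% HDI of d = mu/sigma
falls entirely outside the +/-0.75 region of practical equivalence.
"""

from discaug import PowerConfig, power_curve

config = PowerConfig(
    gen_mean=-0.63,
    gen_sd=0.63 / 2.32,  # SD implied by the prior mean and effect size
    rope_halfwidth=0.75,
    calibration_n=68,
    n_sims=200,
    seed=7,
)

print("candidate N   power   95% CI on power")
for result in power_curve(config, [10, 20, 40]):
    lo, hi = result.credible_interval
    print(f"{result.candidate_n:>11d}   {result.power:.3f}   [{lo:.3f}, {hi:.3f}]")

print(
    "\nWith an effect this large (|d| = 2.32), even modest samples almost"
    "\nalways exclude the ROPE; power rises monotonically with N because"
    "\nevery size reuses the same underlying draws (common random numbers)."
)
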