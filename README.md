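# discaug

Tools for studying **discounting** and **augmentation** in causal conditional
reasoning: theory prediction engines, a synthetic ordinal-data generator,
cumulative-link mixed-model fitting with Bayes-factor model comparison, and
prospective Bayesian power analysis. It is aimed at cognitive scientists who
run (or reanalyse) the two-conditional change-rating paradigm and want the
whole pipeline — from formal predictions to fitted ladders — reproducible in
one place.

## The problem

Pairs of conditionals such as *if the fuse blows, the lights go out* / *if
there is a power cut, the lights go out* describe two causes of one effect.
Learning that the lights are out and that there was a power cut makes the
blown fuse *less* likely (discounting, or explaining away). Conversely, two
effects of one cause — fever and spots from chickenpox — support each other
while the cause is unknown (augmentation). Whether people's judgments follow
these patterns discriminates between three accounts:

- **Causal model theory (CM).** The rule pair is represented as a
  three-variable causal Bayes net. With independent causes integrated by a
  noisy-OR, `Pr(q=1|p,r) = 1 − (1−W_a) · Π_i (1−W_i)^ind(i)`, discounting
  follows: `Pr(r|p,q) < Pr(r|q)` whenever `W_a < 1`. With conjunctive causes
  integrated by a noisy-AND, `Pr(q=1|p,r) = 1 − (1−W_a)(1−W_pr)^(ind(p)·ind(r))`,
  the inequality flips (augmentation) for `0 < W_a < 1`. Common-cause
  structures give screening-off: `Pr(p|r,q) = Pr(p|q)` exactly.
- **Mental models (FM/IM).** The rule pair is recoded as one conditional
  with a compound clause and represented as a list of equiprobable
  possibilities; probabilities are possibility proportions and conditioning
  excises possibilities. Fully fleshed-out models (FM) predict, e.g., a
  `1/2 − 2/5 = 1/10` augmentation where CM predicts no change; truncated
  initial models (IM) predict no effects at all.
- **Shallow encoding.** Reasoners keep only a partial model of the recoded
  antecedents (an exclusive-or or a conjunction) and ignore the consequent,
  predicting the same change whether or not the consequent is known.

The measured variable is an ordinal change rating (−1 / 0 / +1) per
participant × scenario × design cell, analysed with cumulative-link mixed
models (probit link, crossed participant and item random effects), a ladder
of nested model comparisons scored by `G²` and the BIC Bayes factor
`BF = e^(BIC₁ − BIC₂)`, and latent-scale simple effects.

## Worked example

```python
from discaug import (SimConfig, Theory, simulate_experiment,
                     EXPT1_LADDER, run_ladder, ladder_frame,
                     theory_adjudication)

records = simulate_experiment(
    SimConfig(n_participants=40, theory=Theory.CM, effect_scale=1.0, seed=11))
print(ladder_frame(run_ladder(records, EXPT1_LADDER)))
print(theory_adjudication(records).favored)
```

prints

```
                           Model  Pars    AIC    BIC     LR  df         BF
                  CR ~ 1 + (1|P)     3 1456.6 1470.2    NaN NaN       None
             CR ~ CD + C + (1|P)     5 1235.8 1258.5 224.80 2.0  9.2x10^91
     CR ~ CD + C + (1|P) + (1|I)     6 1237.6 1264.7   0.23 1.0  1.8x10^-3
CR ~ CD + C + (1 + CD|P) + (1|I)     8 1240.1 1276.3   1.52 2.0  9.9x10^-6
     CR ~ C + (1 + CD|P) + (1|I)     7 1277.2 1308.9  39.12 1.0 6.9x10^-15
Theory.CM
```

Each row is one cumulative-probit mixed model (`CD` = causal direction,
`C` = consequent, `(1|P)`/`(1|I)` = participant/item intercepts), compared
to its predecessor by the likelihood ratio (`LR`, on `df` degrees of
freedom) and the BIC Bayes factor. On data generated under the causal-model
sign pattern, the `CD + C` fixed-effect structure wins and the
consequent-only (mental-models) structure is decisively rejected — the same
adjudication logic as the published tables, here recovering the generating
theory.

The `examples/` directory holds one short script per capability: theory
sign panels, network sweeps over the background-cause weight, exact
mental-model fractions, simulate-and-fit, the model ladder, and the
ROPE/HDI power analysis.

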