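"""Discounting and augmentation as the background-cause weight varies.

Builds the three-variable common-effect network at base rates .2 and causal
powers .9, and traces Pr(r|q) vs Pr(r|p,q) across w_a for both integration
rules.  Discounting means the curve with p known lies below the curve
without; augmentation means it lies above.
"""

from discaug import CausalStructure, CbnParams, IntegrationRule, sweep_wa
from discaug.cbn import FIG5_AND_PARAMS, FIG5_OR_PARAMS

grid = [0.0, 0.25, 0.5, 0.75, 1.0]

or_params = CbnParams(structure=CausalStructure.COMMON_EFFECT, **FIG5_OR_PARAMS)
print("noisy-OR (independent causes):")
print(sweep_wa(or_params, grid).round(4).to_string(index=False))

and_params = CbnParams(
    structure=CausalStructure.COMMON_EFFECT,
    rule=IntegrationRule.NOISY_AND,
    **FIG5_AND_PARAMS,
)
print("\nnoisy-AND (conjunctive causes):")
print(sweep_wa(and_params, grid).round(4).to_string(index=False))

print(
    "\nWith noisy-OR, Pr(r|p,q) < Pr(r|q) everywhere except w_a = 1:"
    "\nlearning one cause explains the effect away. With noisy-AND the"
    "\norder flips (augmentation), vanishing at w_a = 0 and w_a = 1."
)
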