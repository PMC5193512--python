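"""The naive-probability calculus on mental-model possibility sets.

Under equiprobability, the probability of an event is the proportion of
represented possibilities in which it holds; conditioning excises the
violating possibilities.  The change prediction for a cell is the
difference between that proportion after and before learning p.
"""

from discaug import (
    Condition,
    Interpretation,
    change_prediction_mm,
    conditionalize,
    enumerate_models,
    naive_prob,
)

disj = enumerate_models(Interpretation.FULLY_FLESHED_OR)
print(f'"if p or r then q" fleshes out to {len(disj)} possibilities')
print("  Pr(r)        =", naive_prob(disj, r=True))
print("  Pr(r | p)    =", naive_prob(conditionalize(disj, p=True), r=True))
pred = change_prediction_mm(Interpretation.FULLY_FLESHED_OR, Condition.CENC)
print("  change (CENC) =", pred.magnitude, "-> augmentation predicted")

conj = enumerate_models(Interpretation.FULLY_FLESHED_AND)
print(f'\n"if q then p and r" fleshes out to {len(conj)} possibilities')
print("  Pr(r)        =", naive_prob(conj, r=True))
print("  Pr(r | p)    =", naive_prob(conditionalize(conj, p=True), r=True))
pred = change_prediction_mm(Interpretation.FULLY_FLESHED_AND, Condition.ECNC)
print("  change (ECNC) =", pred.magnitude, "-> augmentation predicted")

print("\nPragmatic readings of the conjunctive-antecedent conditional:")
for interp in (
    Interpretation.MATERIAL,
    Interpretation.MATERIAL_SOLE_CAUSES,
    Interpretation.ENABLES,
    Interpretation.BICONDITIONAL,
):
    models = enumerate_models(interp)
    cec = change_prediction_mm(interp, Condition.CEC).magnitude
    cenc = change_prediction_mm(interp, Condition.CENC).magnitude
    print(f"  {interp.value:22s} {len(models)} possibilities, "
          f"change CEC = {cec}, CENC = {cenc}")

print(
    "\nAll fractions are exact rationals: the engine works in Fraction"
    "\narithmetic, so 1/2 - 2/5 really is 1/10, not 0.09999..."
)
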