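"""Sign predictions of the four competing theories for both study designs.

Each theory predicts, per design cell (causal/diagnostic rule pair x
consequent known/unknown), whether learning the other antecedent should
raise (+1), lower (-1), or leave unchanged (0) the target's likelihood.
"""

from discaug import prediction_frame

for experiment in (1, 2):
    frame = prediction_frame(experiment)
    panel = frame.pivot(index="theory", columns="condition", values="sign")
    panel = panel[["CEC", "CENC", "ECC", "ECNC"]]
    print(f"\nExperiment {experiment} sign panel (rows: theory, cols: condition):")
    print(panel.to_string())

print(
    "\n-1 = discounting, +1 = augmentation, 0 = no change. The causal-model"
    "\n(CM) and shallow-encoding rows differ in the consequent-unknown cells,"
    "\nwhich is what makes the second design a critical test between them."
)
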