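"""Relative qPCR expression by the 2^-ddCt method.

A target gene's Ct is normalized to a reference gene within each sample,
then to a calibrator sample (here: one parent); 2^-ddCt is the fold
change of the target in the test sample relative to the calibrator.
"""

from triohet import ddct_relative_expression

# hybrid root sample vs the female-parent calibrator
fold = ddct_relative_expression(
    ct_target_sample=22.1,   # target gene in the hybrid
    ct_ref_sample=18.0,      # actin in the hybrid
    ct_target_calibrator=24.6,  # target gene in the parent
    ct_ref_calibrator=18.2,     # actin in the parent
)
print(f"relative expression (hybrid vs parent): {fold:.2f}-fold")
print("Values above 1 indicate higher expression in the hybrid than in "
      "the calibrator parent after reference-gene normalization.")
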