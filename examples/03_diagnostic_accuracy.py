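"""Predictive values of EEG patterns with exact confidence intervals.

Computes the two headline accuracy rows — favorable EEG at 12 h predicting
good outcome, unfavorable EEG at 24 h predicting poor outcome — from a
synthetic cohort, and shows the exact (Clopper-Pearson) interval at the
published specificity boundary of 178/178.
"""

from eegprog import (
    clopper_pearson,
    default_calibration,
    generate_cohort,
    predictive_table,
)

cohort = generate_cohort(default_calibration(), seed=0)
table = predictive_table(cohort)
print(table.to_string(index=False))

lo, hi = clopper_pearson(178, 178, 0.95)
print(f"\nexact 95% CI for 178/178 correct negatives: "
      f"{100 * lo:.1f}-{100 * hi:.0f}% -> a specificity of 100% is still only "
      "certain down to ~98% with this sample size.")
print("sensitivity near 29% for the unfavorable pattern means the rule "
      "identifies about a third of poor-outcome patients without false positives.")
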