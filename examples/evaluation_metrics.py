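"""Evaluation statistics from explicit count tables.

Validation ratio = TV / (TV + NV), where TV are urinalysis-confirmed alerts
and NV are unconfirmed ones (not necessarily false).  Sensitivity,
specificity and accuracy come from a prediction-vs-reference confusion
table, with never-validated reference days dropped.
"""

from dwellsense.evaluation import (
    ConfusionCounts,
    ValidationCounts,
    confusion_metrics,
    round_report,
    validation_metrics,
)

supervised = validation_metrics(ValidationCounts(tv=6, nv=147))
unsupervised = validation_metrics(ValidationCounts(tv=6, nv=35))
print(f"supervised baseline: {6 + 147} alerts, validation ratio "
      f"{round_report(supervised.validation_ratio)}")
print(f"unsupervised model:  {6 + 35} alerts, validation ratio "
      f"{round_report(unsupervised.validation_ratio)}")

sleep = confusion_metrics(ConfusionCounts(tp=25, fp=19, fn=9, tn=140))
print(f"sleep analysis vs self-reports: sensitivity {sleep.sensitivity:.3f}, "
      f"specificity {round_report(sleep.specificity)}, accuracy {round_report(sleep.accuracy)}")
# The unsupervised detector confirms the same number of true cases with four
# times fewer unconfirmed alerts - the point of fusing activity patterns with
# physiology instead of thresholding each signal alone.
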