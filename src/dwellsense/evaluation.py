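"""Evaluation statistics: validation ratio, prevalence, and confusion metrics.

Alert-level outcomes in a home-monitoring trial are either truly validated
(TV: confirmed by urinalysis) or not validated (NV: unconfirmed, which is not
the same as false).  The validation ratio is TV / (TV + NV) and prevalence is
condition-positives over the monitored population.  Where a reference label
exists per day (e.g. sleep self-reports), standard sensitivity, specificity
and accuracy are computed from the confusion counts; reference days that were
never validated are dropped from the confusion table rather than coerced to
negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np


@dataclass
class ValidationCounts:
    tv: int
    nv: int

    def __post_init__(self) -> None:
        if self.tv < 0 or self.nv < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ValidationMetrics:
    validation_ratio: float  # nan when undefined
    prevalence: float
    undefined: tuple[str, ...] = ()


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    undefined: tuple[str, ...] = ()


def validation_metrics(
    counts: ValidationCounts,
    positives: int | None = None,
    total_population: int | None = None,
) -> ValidationMetrics:
    """Validation ratio TV/(TV+NV) and prevalence positives/population."""
    undefined = []
    if counts.tv + counts.nv > 0:
        ratio = counts.tv / (counts.tv + counts.nv)
    else:
        ratio = float("nan")
        undefined.append("validation_ratio")
    if positives is not None and total_population:
        prevalence = positives / total_population
    else:
        prevalence = float("nan")
        undefined.append("prevalence")
    return ValidationMetrics(
        validation_ratio=ratio, prevalence=prevalence, undefined=tuple(undefined)
    )


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/all."""
    undefined = []
    if counts.tp + counts.fn > 0:
        sen = counts.tp / (counts.tp + counts.fn)
    else:
        sen = float("nan")
        undefined.append("sensitivity")
    if counts.tn + counts.fp > 0:
        spe = counts.tn / (counts.tn + counts.fp)
    else:
        spe = float("nan")
        undefined.append("specificity")
    total = counts.tp + counts.fp + counts.fn + counts.tn
    if total > 0:
        acc = (counts.tp + counts.tn) / total
    else:
        acc = float("nan")
        undefined.append("accuracy")
    return ConfusionMetrics(
        sensitivity=sen, specificity=spe, accuracy=acc, undefined=tuple(undefined)
    )


def assemble_confusion(predicted, reference) -> ConfusionCounts:
    """Confusion counts from paired labels; not-validated reference days dropped.

    ``predicted`` and ``reference`` are aligned sequences with entries
    "disturbed"/"normal" (reference may also contain "not_validated").
    """
    tp = fp = fn = tn = 0
    for p, r in zip(predicted, reference, strict=True):
        if r == "not_validated":
            continue
        pos_p, pos_r = p == "disturbed", r == "disturbed"
        if pos_p and pos_r:
            tp += 1
        elif pos_p and not pos_r:
            fp += 1
        elif not pos_p and pos_r:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def round_report(value: float, decimals: int = 2) -> float:
    """Half-up rounding used for reported tables (so 0.145 prints as 0.15)."""
    if not np.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
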