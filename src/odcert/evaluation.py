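"""Evaluation statistics for overdose classifiers.

The operating metrics of surveillance interest are positive predictive
value (PPV, precision), sensitivity (recall), specificity, and the
F-score — the harmonic mean of PPV and sensitivity, which is the tuning
and headline metric because only ~3% of deaths are overdoses and accuracy
would reward the majority class.

Classifier comparisons use the pooled two-proportion z-test with a
one-tailed ("greater") alternative:

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)),   p = (x1+x2)/(n1+n2)

with p-value 1 - Phi(z).  No continuity correction is applied.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy.stats import norm

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "ProportionTestResult",
    "confusion",
    "format_report_table",
    "metrics",
    "successes_from_rate",
    "trials_from_rate",
    "two_proportion_z_test",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with "overdose" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative count {name}={getattr(self, name)}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Gold-standard positives (row/column total TP+FN)."""
        return self.tp + self.fn

    @property
    def n_predicted_positive(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class EvaluationReport:
    """PPV/sensitivity/specificity/F for one classifier.

    A metric whose denominator is zero is reported as ``None``
    (undefined), never silently as 0.
    """

    cm: ConfusionMatrix
    ppv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    f_score: Optional[float]

    def to_dict(self) -> dict:
        return {
            "tp": self.cm.tp,
            "fp": self.cm.fp,
            "fn": self.cm.fn,
            "tn": self.cm.tn,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
        }


@dataclass(frozen=True)
class ProportionTestResult:
    """One-tailed pooled two-proportion z-test result.

    ``degenerate`` marks the case where the pooled proportion is 0 or 1,
    which forces both sample proportions to be equal; the test then
    carries no evidence either way and is reported as z=0, p=0.5.
    """

    z: float
    p: float
    degenerate: bool = False


def confusion(y_true: Sequence[bool], y_pred: Sequence[bool]) -> ConfusionMatrix:
    """Count agreements and errors; positive = overdose."""
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true labels vs {len(y_pred)} predictions"
        )
    if len(y_true) == 0:
        raise ValidationError("cannot build a confusion matrix from zero records")
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif t and not p:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


def metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """PPV, sensitivity, specificity, and F-score from counts."""
    ppv = cm.tp / cm.n_predicted_positive if cm.n_predicted_positive else None
    sens = cm.tp / cm.n_positive if cm.n_positive else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else None
    if ppv is None or sens is None:
        f = None
    elif ppv + sens == 0:
        f = 0.0
    else:
        f = 2 * ppv * sens / (ppv + sens)
    for name, value in (("PPV", ppv), ("sensitivity", sens), ("specificity", spec)):
        if value is None:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=2)
    return EvaluationReport(cm, ppv, sens, spec, f)


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Pooled two-proportion z-test, alternative: proportion 1 > proportion 2."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValidationError("each group needs at least one trial")
        if not (0 <= x <= n):
            raise ValidationError(f"successes {x} outside 0..{n}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(z=0.0, p=0.5, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return ProportionTestResult(z=z, p=float(norm.sf(z)))


def successes_from_rate(rate: float, n: int) -> int:
    """Reconstruct a success count from a printed proportion (approximate).

    Rounds ``rate * n`` to the nearest integer; intended for recovering
    counts from published 4-decimal metrics when raw counts are not
    reported.
    """
    return round(rate * n)


def trials_from_rate(successes: int, rate: float) -> int:
    """Reconstruct a trial count from successes and a printed proportion."""
    if rate <= 0:
        raise ValidationError("rate must be positive to reconstruct trials")
    return round(successes / rate)


def _fmt(value: Optional[float]) -> str:
    return "   --  " if value is None else f"{value:.4f}"


def format_report_table(reports: Mapping[str, EvaluationReport]) -> str:
    """Human-readable table with the conventional column order."""
    width = max([len(k) for k in reports] + [8])
    lines = [f"{'Method':<{width}}  PPV     Sensitivity  F-score"]
    for name, rep in reports.items():
        lines.append(
            f"{name:<{width}}  {_fmt(rep.ppv)}  {_fmt(rep.sensitivity)}       {_fmt(rep.f_score)}"
        )
    return "\n".join(lines)


def reports_to_json(reports: Mapping[str, EvaluationReport], **extra) -> str:
    payload: dict = {name: rep.to_dict() for name, rep in reports.items()}
    payload.update(extra)
    return json.dumps(payload, indent=1, sort_keys=True)
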