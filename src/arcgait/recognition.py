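"""Walking-style recognition from the roll factor.

The roll-factor axis partitions into three walking states:

* ``rho <= 1`` (equivalently step length below foot length) — *small
  broken step* walking, typical of weakened lower-limb strength;
* ``1 < rho < 2`` — efficient *inverted pendulum* (normal) walking;
* ``rho >= 2`` — *inefficient* walking (very slow, little ankle motion).

Classification is the threshold rule on the per-step roll factor; the
report mirrors the published evaluation: per-style accuracy (share of a
style's steps recognized as that style) and per-style error rate (share
of the *other* styles' steps mistaken for it).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArcGaitError
from .events import StepRecord

__all__ = [
    "WalkStyle",
    "ClassificationReport",
    "classify_step",
    "classify_records",
    "evaluate_recognition",
    "summarize_accuracy",
    "PUBLISHED_ACCURACY",
]


class WalkStyle(str, enum.Enum):
    SMALL_BROKEN_STEP = "small_broken_step"
    INEFFICIENT = "inefficient"
    INVERTED_PENDULUM = "inverted_pendulum"


_STYLES = [s.value for s in WalkStyle]

#: Published per-subject recognition accuracies (%) of the threshold rule,
#: seven healthy adults, 100 steps per style (validation study of this
#: model).  Used by summarize_accuracy as a worked example.
PUBLISHED_ACCURACY = {
    "small_broken_step": [100, 100, 99, 99, 100, 99, 100],
    "inefficient": [98, 100, 98, 100, 97, 98, 96],
    "inverted_pendulum": [100, 100, 100, 96, 100, 100, 100],
}


def classify_step(rho: float, singular: bool = False) -> WalkStyle:
    """Threshold rule on the roll factor (total over finite rho).

    Band edges are assigned to the abnormal side: ``rho = 1`` is a small
    broken step, ``rho = 2`` inefficient ("between 1 and 2" read as the
    open interval).  A singular step (``Sl == f``) is a vanishingly short
    step, hence small-broken-step.
    """
    if singular or (isinstance(rho, float) and math.isnan(rho)):
        return WalkStyle.SMALL_BROKEN_STEP
    rho = float(rho)
    if not math.isfinite(rho):
        raise ArcGaitError("roll factor must be finite or flagged singular")
    if rho <= 1.0:
        return WalkStyle.SMALL_BROKEN_STEP
    if rho < 2.0:
        return WalkStyle.INVERTED_PENDULUM
    return WalkStyle.INEFFICIENT


def classify_records(records: list[StepRecord]) -> list[WalkStyle]:
    """Per-step classification of a step sequence."""
    return [classify_step(r.rho, singular=r.singular) for r in records]


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts (true style x predicted style), per-style accuracy
    and error rate (%), and per-style step counts."""

    confusion: pd.DataFrame
    accuracy: dict
    error_rate: dict
    n: dict
    error_rate_denominator: str = "other_true"

    def to_dict(self) -> dict:
        return {
            "confusion": {t: self.confusion.loc[t].to_dict() for t in self.confusion.index},
            "accuracy": dict(self.accuracy),
            "error_rate": dict(self.error_rate),
            "n": dict(self.n),
            "error_rate_denominator": self.error_rate_denominator,
        }


def _style_value(x) -> str:
    s = x.value if isinstance(x, WalkStyle) else str(x)
    if s not in _STYLES:
        raise ArcGaitError(f"unknown walking style {x!r}")
    return s


def evaluate_recognition(
    true_labels, predicted_labels, error_rate_denominator: str = "other_true"
) -> ClassificationReport:
    """Confusion counts and the published accuracy/error-rate measures.

    accuracy(style)  = 100 * correct predictions among steps truly of
    that style / steps truly of that style.

    error_rate(style): with the default ``other_true`` denominator, 100 *
    steps of *other* true styles predicted as this style / steps of other
    true styles (a false-positive rate); with ``predicted``, the same
    numerator over all predictions of this style (a false-discovery
    proportion).
    """
    true_s = [_style_value(x) for x in true_labels]
    pred_s = [_style_value(x) for x in predicted_labels]
    if len(true_s) != len(pred_s):
        raise ArcGaitError("label sequences differ in length")
    if error_rate_denominator not in ("other_true", "predicted"):
        raise ArcGaitError(f"unknown denominator {error_rate_denominator!r}")
    conf = pd.DataFrame(0, index=_STYLES, columns=_STYLES, dtype=int)
    for t, p in zip(true_s, pred_s):
        conf.loc[t, p] += 1
    total = len(true_s)
    accuracy, error_rate, n = {}, {}, {}
    for s in _STYLES:
        n_true = int(conf.loc[s].sum())
        n[s] = n_true
        accuracy[s] = 100.0 * conf.loc[s, s] / n_true if n_true else float("nan")
        false_pos = int(conf[s].sum() - conf.loc[s, s])
        if error_rate_denominator == "other_true":
            denom = total - n_true
        else:
            denom = int(conf[s].sum())
        error_rate[s] = 100.0 * false_pos / denom if denom else 0.0
    return ClassificationReport(
        confusion=conf,
        accuracy=accuracy,
        error_rate=error_rate,
        n=n,
        error_rate_denominator=error_rate_denominator,
    )


def summarize_accuracy(per_subject) -> dict:
    """Mean per-style accuracy (%) across subjects, to two decimals.

    ``per_subject`` maps style name -> per-subject accuracy sequence (or
    is a DataFrame with one column per style, one row per subject).
    """
    if isinstance(per_subject, pd.DataFrame):
        per_subject = {c: per_subject[c].tolist() for c in per_subject.columns}
    if not per_subject:
        raise ArcGaitError("empty accuracy table")
    out = {}
    for style, vals in per_subject.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ArcGaitError(f"no subject rows for style {style!r}")
        out[_style_value(style)] = round(float(vals.mean()), 2)
    return out
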