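"""Expert interval rules: per-feature numeric intervals combined into a class
decision.

An expert defines, for each interpretable feature, the numeric interval its
value must fall into for the positive class; a rule combines those per-feature
conditions by conjunction (default) or majority vote.  Bounds may be open or
closed on each side, so clinical conventions like "QRS >= 120 ms" (closed
lower bound) and "LVEF < 45%" (open upper bound) are expressed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["Interval", "IntervalRule"]


@dataclass(frozen=True)
class Interval:
    """A one-dimensional interval with per-side closedness."""

    low: float = -np.inf
    high: float = np.inf
    closed_low: bool = True
    closed_high: bool = True

    def contains(self, x: float) -> bool:
        lo_ok = x >= self.low if self.closed_low else x > self.low
        hi_ok = x <= self.high if self.closed_high else x < self.high
        return bool(lo_ok and hi_ok)


@dataclass
class IntervalRule:
    """Map a feature row to ``positive_class`` / ``negative_class``.

    ``conditions`` maps feature name -> Interval the value must satisfy.
    ``combine`` is ``"and"`` (all conditions must hold) or ``"majority"``
    (strictly more than half).
    """

    conditions: Mapping[str, Interval] = field(default_factory=dict)
    positive_class: str = "positive"
    negative_class: str = "negative"
    combine: str = "and"

    def __post_init__(self) -> None:
        if self.combine not in ("and", "majority"):
            raise ValueError(f"combine must be 'and' or 'majority', got {self.combine!r}")

    def decide(self, features: Mapping[str, float]) -> str:
        missing = [f for f in self.conditions if f not in features]
        if missing:
            raise KeyError(f"rule requires missing feature(s): {missing}")
        hits = [iv.contains(float(features[f]))
                for f, iv in self.conditions.items()]
        if self.combine == "and":
            ok = all(hits)
        else:
            ok = sum(hits) * 2 > len(hits)
        return self.positive_class if ok else self.negative_class
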