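"""Phrase-boundary detection from information-content profiles.

Perceived grouping boundaries tend to fall before contextually
unpredictable events: the last note of a phrase is highly predictable
(falling IC), while the first note of the next phrase is not (a marked
rise).  A boundary is therefore placed at event n when its IC exceeds
the mean of the previous ``window`` events by at least ``k`` standard
deviations of that window and also exceeds the previous event's IC.  The
boundary marks the first event of the new group; its strength is the
z-score of the IC rise against the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .predictor import PredictionRecord, Profile

_STDEV_FLOOR = 1e-6


@dataclass
class BoundarySet:
    """Detected group-initial event positions with per-position strengths."""

    indices: tuple[int, ...] = ()
    strengths: dict[int, float] = field(default_factory=dict)

    def __contains__(self, index: int) -> bool:
        return index in self.strengths

    def __len__(self) -> int:
        return len(self.indices)


def _as_ics(profile) -> list[float]:
    if isinstance(profile, Profile):
        return profile.ics("joint")
    if profile and isinstance(profile[0], PredictionRecord):
        return [r.h for r in profile]
    return list(profile)


def detect_boundaries(profile: Profile | Sequence, window: int = 10,
                      k: float = 2.0) -> BoundarySet:
    """Mark events whose IC rises markedly above the recent trend.

    ``profile`` may be a :class:`~melexp.predictor.Profile`, a sequence of
    prediction records, or a raw IC sequence in bits.  Event ``n`` (for
    ``n >= 2``, so that a preceding context exists) is a boundary iff

        IC(n) > mean(IC[n−w .. n−1]) + k · stdev(IC[n−w .. n−1])
        and IC(n) > IC(n−1),

    using the sample standard deviation floored at 1e−6.  Raising ``k``
    can only remove boundaries.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if k <= 0:
        raise ValueError("threshold k must be positive")
    ics = _as_ics(profile)
    if len(ics) < window + 1:
        raise ValueError(f"profile of length {len(ics)} is shorter than "
                         f"window + 1 = {window + 1}")
    indices: list[int] = []
    strengths: dict[int, float] = {}
    for n in range(2, len(ics)):
        lo = max(0, n - window)
        if n - lo < 2:
            continue
        w = ics[lo:n]
        mean = math.fsum(w) / len(w)
        var = math.fsum((x - mean) ** 2 for x in w) / (len(w) - 1)
        sd = max(math.sqrt(var), _STDEV_FLOOR)
        if ics[n] > mean + k * sd and ics[n] > ics[n - 1]:
            indices.append(n)
            strengths[n] = (ics[n] - mean) / sd
    return BoundarySet(indices=tuple(indices), strengths=strengths)


def evaluate_boundaries(predicted: BoundarySet | Sequence[int],
                        annotated: Sequence[int],
                        tolerance: int = 1) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted against annotated boundaries.

    A prediction within ``tolerance`` events of an annotation counts as a
    hit; each annotation can be matched at most once (greedy matching in
    position order).  Empty prediction or annotation sets use the
    undefined-as-zero convention for the affected rates.
    """
    pred = sorted(predicted.indices if isinstance(predicted, BoundarySet)
                  else predicted)
    gold = sorted(annotated)
    unmatched = list(gold)
    hits = 0
    for p in pred:
        best = None
        for g in unmatched:
            if abs(g - p) <= tolerance and (best is None
                                            or abs(g - p) < abs(best - p)):
                best = g
        if best is not None:
            unmatched.remove(best)
            hits += 1
    precision = hits / len(pred) if pred else 0.0
    recall = hits / len(gold) if gold else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1
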