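"""Conventional paired-limb comparison metrics and questionnaire scoring.

Circumference and ultrasound thickness comparisons are expressed as a
percentage of the unaffected side (affected / unaffected x 100), which
removes inter-individual size differences. Two-point-discrimination and
joint-mobility comparisons use the plain signed difference
(affected - unaffected). Quality-of-life questionnaire items are rated
1-4, grouped into categories, and each category score is the mean of
the answered items rescaled to 0-100; unanswered items are excluded.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

__all__ = [
    "percent_change",
    "side_difference",
    "questionnaire_score",
]


def percent_change(affected: float, unaffected: float) -> float:
    """affected / unaffected x 100; requires a positive unaffected value."""
    if not unaffected > 0:
        raise ValueError("percent change needs a positive unaffected-side value")
    return affected / unaffected * 100.0


def side_difference(affected: float, unaffected: float) -> float:
    """Signed difference affected - unaffected (same units)."""
    return affected - unaffected


def questionnaire_score(item_scores: Iterable[float | None]) -> float:
    """Category score 0-100 from 1-4 item ratings; missing items excluded.

    The unique order-preserving affine map of the 1-4 item range onto
    0-100 is (mean - 1) / 3 x 100. All items missing raises ValueError.
    """
    answered = [s for s in item_scores if s is not None and not (
        isinstance(s, float) and math.isnan(s))]
    if not answered:
        raise ValueError("questionnaire category has no answered items")
    for s in answered:
        if not 1.0 <= s <= 4.0:
            raise ValueError(f"item score {s} outside the 1-4 rating scale")
    mean = sum(answered) / len(answered)
    return (mean - 1.0) / 3.0 * 100.0
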