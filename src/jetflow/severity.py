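"""Categorical MR severity from regurgitant volume.

Guideline thresholds: none (< 10 mL), mild (10-30 mL), moderate
(30-60 mL), severe (>= 60 mL). The printed grade boundaries overlap at
10, 30 and 60 mL; they are resolved here as half-open intervals closed on
the left, consistent with the "< 10" and ">= 60" endpoints.
"""

from __future__ import annotations

import math

__all__ = ["SEVERITY_GRADES", "classify_mr_severity"]

SEVERITY_GRADES = ("none", "mild", "moderate", "severe")

_THRESHOLDS = ((60.0, "severe"), (30.0, "moderate"), (10.0, "mild"))


def classify_mr_severity(mr_volume: float) -> str:
    """Map an MR volume in mL to a severity grade.

    Negative volumes (possible from the indirect method's subtraction)
    are treated as 0 mL, i.e. graded "none". The mapping is monotone
    non-decreasing and total on finite inputs.
    """
    if not math.isfinite(mr_volume):
        raise ValueError(f"MR volume must be finite, got {mr_volume}")
    volume = max(float(mr_volume), 0.0)
    for threshold, grade in _THRESHOLDS:
        if volume >= threshold:
            return grade
    return "none"
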