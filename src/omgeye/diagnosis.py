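"""Rule-based ocular myasthenia gravis (OMG) screening from eye masks.

The decision rule is deliberately simple and mirrors clinical practice for
the lateral-gaze test: if the residual gaze-side scleral area exceeds 3% of
the whole eye area, the eye cannot rotate fully and the eye is flagged as
OMG; otherwise it is normal.  The 3% threshold absorbs residual
segmentation inaccuracy.  Equality with the threshold is conservatively
read as normal.  A subject is flagged when either eye is flagged; clock
grade and eyelid distance are carried along as supporting evidence but do
not enter the decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .geometry import IndicatorSet, compute_indicators
from .mask import LabelMask

__all__ = [
    "DEFAULT_THRESHOLD",
    "EyeDiagnosis",
    "SubjectReport",
    "diagnose_eye",
    "diagnose_subject",
    "full_pipeline",
]

DEFAULT_THRESHOLD = 0.03

NORMAL = "normal"
OMG = "OMG"


@dataclass(frozen=True)
class EyeDiagnosis:
    """Per-eye decision: OMG iff the scleral proportion strictly exceeds the threshold."""

    eye: str
    indicators: IndicatorSet
    decision: str
    threshold: float

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
        expected = OMG if self.indicators.sclera_proportion > self.threshold else NORMAL
        if self.decision != expected:
            raise ValueError("decision inconsistent with proportion and threshold")

    def as_dict(self) -> dict:
        return {
            "eye": self.eye,
            "indicators": self.indicators.as_dict(),
            "decision": self.decision,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class SubjectReport:
    """Two-eye report; the overall decision is the OR of the per-eye decisions."""

    left: EyeDiagnosis | None
    right: EyeDiagnosis | None
    overall: str
    narrative: str

    def as_dict(self) -> dict:
        return {
            "left": self.left.as_dict() if self.left else None,
            "right": self.right.as_dict() if self.right else None,
            "overall": self.overall,
            "narrative": self.narrative,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)


def diagnose_eye(
    indicators: IndicatorSet, threshold: float = DEFAULT_THRESHOLD, eye: str = "left"
) -> EyeDiagnosis:
    """Threshold the gaze-side scleral proportion for one eye.

    A proportion strictly greater than ``threshold`` (default 3%) is read as
    impaired eye movement and flagged OMG; at or below it, normal.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    decision = OMG if indicators.sclera_proportion > threshold else NORMAL
    return EyeDiagnosis(eye=eye, indicators=indicators, decision=decision, threshold=threshold)


def _eye_summary(diag: EyeDiagnosis) -> str:
    ind = diag.indicators
    return (
        f"{diag.eye} eye: scleral proportion {ind.sclera_proportion:.4f} "
        f"(threshold {diag.threshold:.2f}) -> {diag.decision}; "
        f"clock point {ind.clock_point} (grade {ind.clock_grade}); "
        f"eyelid distance {ind.eyelid_distance_px} px"
    )


def diagnose_subject(
    left: EyeDiagnosis | None, right: EyeDiagnosis | None
) -> SubjectReport:
    """Combine per-eye decisions into a subject-level report (OR rule).

    If only one eye is available the report flags single-eye mode and the
    overall decision follows the present eye.
    """
    if left is None and right is None:
        raise ValueError("at least one eye diagnosis is required")
    lines = []
    decisions = []
    for diag in (left, right):
        if diag is not None:
            lines.append(_eye_summary(diag))
            decisions.append(diag.decision)
    if left is None or right is None:
        lines.append("single-eye mode: only one eye was assessed")
    overall = OMG if OMG in decisions else NORMAL
    lines.append(f"overall: {overall}")
    return SubjectReport(left=left, right=right, overall=overall, narrative="\n".join(lines))


def full_pipeline(
    left_mask: LabelMask,
    right_mask: LabelMask,
    gaze: str = "front",
    threshold: float = DEFAULT_THRESHOLD,
) -> SubjectReport:
    """Masks in, report out: indicators for both eyes, per-eye rule, OR combine."""
    left = diagnose_eye(compute_indicators(left_mask, gaze), threshold, eye="left")
    right = diagnose_eye(compute_indicators(right_mask, gaze), threshold, eye="right")
    return diagnose_subject(left, right)
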