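"""Cine-sweep decision support: frame adequacy gating, the capture loop, and
the 3-way per-hip management decision.

Every frame of a sweep is first screened for landmark adequacy — both
landmark classes present with enough area, line and circle fits within
residual bounds, head radius plausible — mirroring an acquisition loop that
only accepts frames containing all clinically necessary landmarks.  If fewer
than ``min_adequate_frames`` frames pass, the sweep is INCONCLUSIVE (repeat
scan).  Otherwise the alpha angle and femoral head coverage are aggregated
(median by default, robust to residual outlier frames) over the adequate
frames and compared against Graf-method thresholds: HEALTHY iff
``alpha >= 60 degrees`` and ``coverage >= 0.50`` (boundary equality counts
as healthy), FOLLOW_UP otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .geometry import (
    GeometryConfig,
    HipGeometry,
    DEGENERATE_ANGLE,
    measure,
)
from .phantom import LabelMask

HEALTHY = "HEALTHY"
FOLLOW_UP = "FOLLOW_UP"
INCONCLUSIVE = "INCONCLUSIVE"

#: App-style display strings for each canonical label.
DISPLAY_STRINGS = {
    HEALTHY: "Healthy",
    FOLLOW_UP: "FU Recommended",
    INCONCLUSIVE: "Inconclusive, Repeat Scan",
}

# Frame-inadequacy reason codes.
REASON_MISSING_CLASS_1 = "MISSING_CLASS_1"
REASON_MISSING_CLASS_2 = "MISSING_CLASS_2"
REASON_SMALL_CLASS_1 = "SMALL_CLASS_AREA_1"
REASON_SMALL_CLASS_2 = "SMALL_CLASS_AREA_2"
REASON_HIGH_LINE_RESIDUAL = "HIGH_LINE_RESIDUAL"
REASON_HIGH_CIRCLE_RESIDUAL = "HIGH_CIRCLE_RESIDUAL"
REASON_SMALL_HEAD = "SMALL_HEAD"
REASON_NO_GEOMETRY = "GEOMETRY_INCOMPLETE"


@dataclass(frozen=True)
class AdequacyThresholds:
    """Minimum requirements for a frame to enter the measurement pool."""

    required_classes: tuple[int, ...] = (1, 2)
    min_class_area_px: int = 50
    max_line_residual_px: float = 1.5
    max_circle_residual_px: float = 2.0
    min_head_radius_px: float = 8.0

    def __post_init__(self) -> None:
        if self.min_class_area_px <= 0 or self.max_line_residual_px <= 0 \
                or self.max_circle_residual_px <= 0 or self.min_head_radius_px <= 0:
            raise ValidationError("all adequacy thresholds must be positive")

    def geometry_config(self) -> GeometryConfig:
        return GeometryConfig(
            max_line_residual_px=self.max_line_residual_px,
            max_circle_residual_px=self.max_circle_residual_px,
            min_head_radius_px=self.min_head_radius_px,
        )


@dataclass(frozen=True)
class DecisionThresholds:
    """Graf-style decision heuristics; all values are configuration."""

    alpha_healthy_deg: float = 60.0
    fhc_healthy: float = 0.50
    min_adequate_frames: int = 5
    aggregator: str = "median"

    def __post_init__(self) -> None:
        if self.min_adequate_frames < 1:
            raise ValidationError("min_adequate_frames must be >= 1")
        if not (np.isfinite(self.alpha_healthy_deg) and np.isfinite(self.fhc_healthy)):
            raise ValidationError("decision thresholds must be finite")
        if self.aggregator not in ("median", "mean"):
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")

    def aggregate(self, values: Sequence[float]) -> float:
        arr = np.asarray(values, dtype=float)
        return float(np.median(arr) if self.aggregator == "median" else np.mean(arr))


@dataclass
class FrameAssessment:
    frame_id: int
    adequate: bool
    reasons: list[str]
    geometry: HipGeometry | None


@dataclass
class SweepDecision:
    label: str
    alpha_agg_deg: float | None
    fhc_agg: float | None
    n_adequate: int
    n_frames: int
    frame_assessments: list[FrameAssessment]

    @property
    def display(self) -> str:
        return DISPLAY_STRINGS[self.label]

    def to_json(self, **extra) -> str:
        frames = [
            dict(frame_id=a.frame_id, adequate=a.adequate, reasons=a.reasons,
                 alpha_deg=None if a.geometry is None else a.geometry.alpha_deg,
                 fhc=None if a.geometry is None else a.geometry.fhc,
                 quality_flags=sorted(a.geometry.quality_flags) if a.geometry else [])
            for a in self.frame_assessments
        ]
        return json.dumps(dict(
            label=self.label, display=self.display, alpha_agg_deg=self.alpha_agg_deg,
            fhc_agg=self.fhc_agg, n_adequate=self.n_adequate, n_frames=self.n_frames,
            frames=frames, **extra), indent=2)

    def to_text_report(self) -> str:
        """One-page plain-text report mirroring the app notification."""
        lines = [
            "HIP SCREENING REPORT",
            "====================",
            f"Result: {self.display}",
            "",
            f"Frames analyzed:   {self.n_frames}",
            f"Frames adequate:   {self.n_adequate}",
        ]
        if self.alpha_agg_deg is not None:
            lines.append(f"Alpha angle (agg): {self.alpha_agg_deg:.1f} deg")
        if self.fhc_agg is not None:
            lines.append(f"Head coverage:     {100 * self.fhc_agg:.0f}%")
        lines.append("")
        lines.append("Per-frame: " + " ".join(
            f"[{a.frame_id}:{'ok' if a.adequate else 'x'}]"
            for a in self.frame_assessments))
        return "\n".join(lines) + "\n"


def assess_frame(mask: LabelMask,
                 adequacy: AdequacyThresholds = AdequacyThresholds()) -> FrameAssessment:
    """Screen one frame: are all required landmarks present and well fitted?

    Failures are reported as reason codes, never exceptions; every violated
    criterion appears in ``reasons``.
    """
    labels = np.asarray(mask.labels)
    reasons: list[str] = []
    for c in adequacy.required_classes:
        area = int((labels == c).sum())
        if area == 0:
            reasons.append(REASON_MISSING_CLASS_1 if c == 1 else REASON_MISSING_CLASS_2)
        elif area < adequacy.min_class_area_px:
            reasons.append(REASON_SMALL_CLASS_1 if c == 1 else REASON_SMALL_CLASS_2)

    geometry = None
    if not reasons:
        geometry = measure(mask, adequacy.geometry_config())
        from .geometry import (HIGH_CIRCLE_RESIDUAL, HIGH_LINE_RESIDUAL,
                               MISSING_CLASS, SMALL_HEAD)
        if HIGH_LINE_RESIDUAL in geometry.quality_flags:
            reasons.append(REASON_HIGH_LINE_RESIDUAL)
        if HIGH_CIRCLE_RESIDUAL in geometry.quality_flags:
            reasons.append(REASON_HIGH_CIRCLE_RESIDUAL)
        if SMALL_HEAD in geometry.quality_flags:
            reasons.append(REASON_SMALL_HEAD)
        if (MISSING_CLASS in geometry.quality_flags
                or DEGENERATE_ANGLE in geometry.quality_flags
                or geometry.alpha_deg is None or geometry.fhc is None):
            reasons.append(REASON_NO_GEOMETRY)
    return FrameAssessment(frame_id=-1, adequate=not reasons, reasons=reasons,
                           geometry=geometry)


def capture_loop(frames: Sequence[LabelMask],
                 adequacy: AdequacyThresholds = AdequacyThresholds(),
                 min_adequate_frames: int = 5) -> tuple[list[int], bool]:
    """Scan frames in acquisition order, capturing adequate ones.

    Stops as soon as ``min_adequate_frames`` have been captured (the operator
    would be notified the scan is complete); otherwise returns every adequate
    frame id with ``complete=False``.  Frame ids are 0-based positions.
    """
    captured: list[int] = []
    for i, mask in enumerate(frames):
        if assess_frame(mask, adequacy).adequate:
            captured.append(i)
            if len(captured) >= min_adequate_frames:
                return captured, True
    return captured, False


def classify(alpha_agg_deg: float, fhc_agg: float,
             thresholds: DecisionThresholds = DecisionThresholds()) -> str:
    """Graf-heuristic 2-way call on aggregated indices (total on the plane)."""
    if not (np.isfinite(alpha_agg_deg) and np.isfinite(fhc_agg)):
        raise ValidationError("aggregated indices must be finite")
    if alpha_agg_deg >= thresholds.alpha_healthy_deg and fhc_agg >= thresholds.fhc_healthy:
        return HEALTHY
    return FOLLOW_UP


def decide_sweep(masks: Sequence[LabelMask],
                 adequacy: AdequacyThresholds = AdequacyThresholds(),
                 thresholds: DecisionThresholds = DecisionThresholds()) -> SweepDecision:
    """Assess every frame of a sweep and emit the 3-way management decision.

    INCONCLUSIVE iff fewer than ``thresholds.min_adequate_frames`` frames are
    adequate; otherwise the configured aggregate of the adequate frames'
    indices is classified.  The full per-frame audit trail is retained.
    """
    if len(masks) == 0:
        raise ValidationError("sweep contains no frames")
    assessments = []
    for i, mask in enumerate(masks):
        a = assess_frame(mask, adequacy)
        a.frame_id = i
        assessments.append(a)
    adequate = [a for a in assessments if a.adequate]
    if len(adequate) < thresholds.min_adequate_frames:
        return SweepDecision(label=INCONCLUSIVE, alpha_agg_deg=None, fhc_agg=None,
                             n_adequate=len(adequate), n_frames=len(masks),
                             frame_assessments=assessments)
    alpha_agg = thresholds.aggregate([a.geometry.alpha_deg for a in adequate])
    fhc_agg = thresholds.aggregate([a.geometry.fhc for a in adequate])
    label = classify(alpha_agg, fhc_agg, thresholds)
    return SweepDecision(label=label, alpha_agg_deg=alpha_agg, fhc_agg=fhc_agg,
                         n_adequate=len(adequate), n_frames=len(masks),
                         frame_assessments=assessments)
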