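"""Traffic-light decision matrix and critical-event rules.

Four channels enter the matrix for every structure: DSC, HDD95, the
constraint-selected dose (mean or max per the organ's clinical
constraint) and the matching delta dose from the sensitivity probe.
Each channel is coloured green/yellow/red against organ- and
metric-specific thresholds; colours score 0/1/3 points and a total of
three or more points flags the structure for human review.

Boundary handling is safety-first: on the dose and delta channels ties
escalate to the more severe colour (a dose exactly at the constraint is
red).  An undefined channel value (empty mask on either side) is forced
red — a missing auto-contour can never pass silently.

The critical-event rules mirror the two-condition definition used for
reference labelling: a structure is critical when its dose is near or
above the constraint (proximity condition) OR the contour-induced dose
difference exceeds a threshold (impact condition).  The estimator-side
check applies the same conditions with both thresholds widened by an
additive safety margin, trading specificity for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .dosimetry import DoseReport
from .geometry import GeometricReport
from .policies import OrganPolicy

CHANNELS = ("dsc", "hdd", "dose", "delta")
FLAG_THRESHOLD_POINTS = 3


class Color(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


POINTS = {Color.GREEN: 0, Color.YELLOW: 1, Color.RED: 3}


@dataclass(frozen=True)
class MetricBundle:
    """The four decision-channel values for one structure.

    ``None`` marks an undefined channel (e.g. empty auto-contour) and is
    classified as red.
    """

    dsc: float | None
    hdd95_mm: float | None
    d_constraint_gy: float | None
    delta_dose_gy: float | None


@dataclass
class TrafficLightResult:
    colors: dict[str, Color]
    points: dict[str, int]
    total: int
    flagged: bool


@dataclass(frozen=True)
class CriticalEventRule:
    """Two-condition criticality rule with an estimator-side safety margin.

    proximity_margin : fraction of the constraint dose; the proximity
        condition fires when the dose is within this fraction below the
        constraint, or above it.
    delta_threshold_gy : impact condition fires when the dose difference
        exceeds this (Gy).
    safety_margin_gy : additive widening (Gy) applied by the estimator
        side only — the proximity cut is lowered and the delta threshold
        reduced by this amount.
    """

    proximity_margin: float = 0.10
    delta_threshold_gy: float = 2.0
    safety_margin_gy: float = 1.0

    def __post_init__(self) -> None:
        if self.proximity_margin < 0 or self.delta_threshold_gy < 0 or self.safety_margin_gy < 0:
            raise ValueError("critical-event margins must be >= 0")


def classify_channel(value: float | None, channel: str, policy: OrganPolicy) -> Color:
    """Colour one decision channel against the organ's thresholds.

    Undefined values (``None``) are maximally suspicious: red.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown decision channel {channel!r}")
    if value is None:
        return Color.RED
    if channel == "dsc":
        yellow_below, red_below = policy.dsc_thresholds
        if value < red_below:
            return Color.RED
        if value < yellow_below:
            return Color.YELLOW
        return Color.GREEN
    if channel == "hdd":
        yellow_above, red_above = policy.hdd_thresholds_mm
        if value > red_above:
            return Color.RED
        if value > yellow_above:
            return Color.YELLOW
        return Color.GREEN
    if channel == "dose":
        yellow_within, red_within = policy.dose_margin
        constraint = policy.constraint_dose_gy
        if value >= constraint * (1.0 - red_within):
            return Color.RED
        if value >= constraint * (1.0 - yellow_within):
            return Color.YELLOW
        return Color.GREEN
    # delta channel: absolute dose-sensitivity thresholds in Gy, ties escalate
    yellow_above, red_above = policy.sensitivity_thresholds_gy
    if value >= red_above:
        return Color.RED
    if value >= yellow_above:
        return Color.YELLOW
    return Color.GREEN


def score_structure(bundle: MetricBundle, policy: OrganPolicy) -> TrafficLightResult:
    """Score all four channels; total >= 3 points flags the structure."""
    values = {
        "dsc": bundle.dsc,
        "hdd": bundle.hdd95_mm,
        "dose": bundle.d_constraint_gy,
        "delta": bundle.delta_dose_gy,
    }
    colors = {ch: classify_channel(values[ch], ch, policy) for ch in CHANNELS}
    points = {ch: POINTS[colors[ch]] for ch in CHANNELS}
    total = sum(points.values())
    return TrafficLightResult(
        colors=colors, points=points, total=total, flagged=total >= FLAG_THRESHOLD_POINTS
    )


def reference_critical(
    dose_ref_gy: float,
    dose_alt_gy: float,
    rule: CriticalEventRule,
    policy: OrganPolicy,
) -> bool:
    """Ground-truth criticality: either condition (or both) suffices.

    Proximity: the alternative-contour dose is within
    ``proximity_margin`` × constraint of the constraint dose or above it.
    Impact: |dose_alt − dose_ref| exceeds ``delta_threshold_gy``.
    """
    if dose_ref_gy < 0 or dose_alt_gy < 0:
        raise ValueError("doses must be >= 0")
    proximity_cut = policy.constraint_dose_gy * (1.0 - rule.proximity_margin)
    proximity = dose_alt_gy >= proximity_cut
    impact = abs(dose_alt_gy - dose_ref_gy) > rule.delta_threshold_gy
    return proximity or impact


def estimator_critical(
    report: DoseReport,
    rule: CriticalEventRule,
    policy: OrganPolicy,
) -> bool:
    """Estimator-side criticality on predicted metrics, with safety margin.

    Same two conditions as :func:`reference_critical`, evaluated on the
    constraint-selected predicted dose and the matching sensitivity
    delta, with the proximity cut lowered and the delta threshold
    reduced by ``safety_margin_gy``.  With zero margin this reduces to
    the reference rule on identical inputs.
    """
    d_constraint, delta = constraint_selected(report, policy)
    proximity_cut = (
        policy.constraint_dose_gy * (1.0 - rule.proximity_margin) - rule.safety_margin_gy
    )
    proximity = d_constraint >= proximity_cut
    impact = delta > max(rule.delta_threshold_gy - rule.safety_margin_gy, 0.0)
    return proximity or impact


def constraint_selected(report: DoseReport, policy: OrganPolicy) -> tuple[float, float]:
    """(dose, delta) pair matching the organ's constraint metric."""
    if policy.constraint_metric == "mean":
        return report.d_mean_gy, report.delta_mean_gy
    return report.d_max_gy, report.delta_max_gy


# ---------------------------------------------------------------------------
# Per-structure orchestration: geometry + dosimetry + decision


@dataclass
class EvaluationRecord:
    """Everything the assistant knows about one structure, one row of report."""

    case_id: str
    organ_id: str
    geometric: GeometricReport | None
    dose_report: DoseReport | None
    bundle: MetricBundle
    result: TrafficLightResult
    critical_estimate: bool
    flagged: bool
    combination_mode: str
    notes: str = ""

    def to_row(self) -> dict:
        geo = self.geometric
        rep = self.dose_report
        row: dict = {
            "case_id": self.case_id,
            "organ_id": self.organ_id,
            "dsc": None if geo is None else geo.dsc,
            "hdd95_mm": None if geo is None else geo.hdd95_mm,
            "vol_eval_mm3": None if geo is None else geo.vol_eval_mm3,
            "vol_ref_mm3": None if geo is None else geo.vol_ref_mm3,
            "d_mean_gy": None if rep is None else rep.d_mean_gy,
            "d_max_gy": None if rep is None else rep.d_max_gy,
            "delta_mean_gy": None if rep is None else rep.delta_mean_gy,
            "delta_max_gy": None if rep is None else rep.delta_max_gy,
            "span_mean_gy": None if rep is None else rep.span_mean_gy,
            "span_max_gy": None if rep is None else rep.span_max_gy,
            "d_constraint_gy": self.bundle.d_constraint_gy,
            "delta_constraint_gy": self.bundle.delta_dose_gy,
            "erosion_vanished": bool(rep.erosion_vanished) if rep is not None else False,
        }
        for ch in CHANNELS:
            row[f"color_{ch}"] = self.result.colors[ch].value
            row[f"points_{ch}"] = self.result.points[ch]
        row["total_points"] = self.result.total
        row["score_flagged"] = self.result.flagged
        row["critical_estimate"] = self.critical_estimate
        row["flagged"] = self.flagged
        row["combination_mode"] = self.combination_mode
        row["notes"] = self.notes
        return row


def evaluate_structure(
    case_id: str,
    eval_mask,
    ref_mask,
    dose,
    policy: OrganPolicy,
    rule: CriticalEventRule | None = None,
    combination_mode: str = "score_or_critical",
) -> EvaluationRecord:
    """Run both QA layers on one structure and fuse them into a flag.

    ``combination_mode`` selects the final flag: ``score_only`` uses the
    traffic-light total alone; ``score_or_critical`` (default,
    sensitivity-first) also flags any structure the critical-dose
    estimator deems critical.
    """
    from .geometry import geometric_report

    if combination_mode not in ("score_only", "score_or_critical"):
        raise ValueError(f"unknown combination_mode {combination_mode!r}")
    rule = rule or CriticalEventRule()

    notes: list[str] = []
    geo = geometric_report(eval_mask, ref_mask)
    if geo.note:
        notes.append(geo.note)

    if eval_mask.is_empty:
        rep = None
        d_constraint = delta = None
        critical = True  # an absent structure is treated as maximally critical
        notes.append("empty evaluation mask: dose channels undefined, forced red")
    else:
        from .dosimetry import dose_sensitivity

        rep = dose_sensitivity(eval_mask, dose, policy, with_dvh=False)
        if rep.erosion_vanished:
            notes.append("erosion vanished: deltas use dilated variant only")
        d_constraint, delta = constraint_selected(rep, policy)
        critical = estimator_critical(rep, rule, policy)

    bundle = MetricBundle(
        dsc=geo.dsc, hdd95_mm=geo.hdd95_mm, d_constraint_gy=d_constraint, delta_dose_gy=delta
    )
    result = score_structure(bundle, policy)
    flagged = result.flagged if combination_mode == "score_only" else (result.flagged or critical)
    return EvaluationRecord(
        case_id=case_id,
        organ_id=eval_mask.organ_id,
        geometric=geo,
        dose_report=rep,
        bundle=bundle,
        result=result,
        critical_estimate=critical,
        flagged=flagged,
        combination_mode=combination_mode,
        notes="; ".join(notes),
    )
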