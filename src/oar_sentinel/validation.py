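"""Validation harness: confusion matrix, sensitivity, specificity.

Compares the assistant's review flags against reference criticality
labels, structure by structure, aligned on (case_id, organ_id).  Rates
with a zero denominator are reported as ``None`` (undefined), never
coerced to 0 or 1 — a silent coercion would corrupt QA conclusions.

The per-structure table is the unit of reproducibility: every number in
the summary can be recounted from it, and the false-negative listing
(truly critical structures the assistant missed) carries the full
metric/colour detail for review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import DoseGrid, StructureSet
from .decision import CriticalEventRule, evaluate_structure
from .policies import OrganPolicy


class AlignmentError(ValueError):
    """Flag and label tables do not line up structure-for-structure."""


class ConfigurationError(ValueError):
    """An organ present in the data has no policy."""


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def flagged_fraction(self) -> float:
        return (self.tp + self.fp) / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n_total": self.n_total,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "flagged_fraction": self.flagged_fraction,
        }


def confusion_summary(
    flags: Sequence[bool],
    reference: Sequence[bool],
    keys: Sequence[tuple[str, str]] | None = None,
) -> ConfusionSummary:
    """Confusion counts of assistant flags against reference criticality.

    ``keys`` are optional (case_id, organ_id) pairs; duplicates raise
    :class:`AlignmentError`, as does a length mismatch or empty input.
    """
    if len(flags) != len(reference):
        raise AlignmentError(
            f"{len(flags)} flags vs {len(reference)} reference labels"
        )
    if len(flags) == 0:
        raise AlignmentError("no structures to summarize")
    if keys is not None:
        if len(keys) != len(flags):
            raise AlignmentError("keys length does not match flags")
        if len(set(keys)) != len(keys):
            raise AlignmentError("duplicate (case_id, organ_id) keys")
    tp = fp = fn = tn = 0
    for f, r in zip(flags, reference):
        if r:
            tp, fn = (tp + 1, fn) if f else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if f else (fp, tn + 1)
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


def join_flags_with_labels(
    evaluation: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Inner-align an evaluation table with a labels table on (case, organ)."""
    for df, name in ((evaluation, "evaluation"), (labels, "labels")):
        missing = {"case_id", "organ_id"} - set(df.columns)
        if missing:
            raise AlignmentError(f"{name} table lacks columns {sorted(missing)}")
        if df.duplicated(["case_id", "organ_id"]).any():
            raise AlignmentError(f"duplicate (case_id, organ_id) keys in {name} table")
    if "critical" not in labels.columns:
        raise AlignmentError("labels table lacks a 'critical' column")
    merged = evaluation.merge(labels[["case_id", "organ_id", "critical"]],
                              on=["case_id", "organ_id"], how="inner")
    if len(merged) != len(evaluation) or len(merged) != len(labels):
        raise AlignmentError(
            f"tables do not align: {len(evaluation)} evaluations, "
            f"{len(labels)} labels, {len(merged)} matched"
        )
    merged["critical"] = merged["critical"].astype(bool)
    return merged


def summarize_table(table: pd.DataFrame) -> ConfusionSummary:
    """Confusion summary from a joined table with flagged/critical columns."""
    return confusion_summary(
        table["flagged"].astype(bool).tolist(),
        table["critical"].tolist(),
        keys=list(zip(table["case_id"], table["organ_id"])),
    )


def false_negative_table(table: pd.DataFrame) -> pd.DataFrame:
    """Truly critical structures the assistant did not flag."""
    mask = table["critical"].astype(bool) & ~table["flagged"].astype(bool)
    return table[mask].reset_index(drop=True)


def run_validation_study(
    structure_sets: Iterable[tuple[StructureSet, StructureSet]],
    dose_grids: Mapping[str, DoseGrid],
    reference_labels: pd.DataFrame,
    policies: Mapping[str, OrganPolicy],
    rule: CriticalEventRule | None = None,
    combination_mode: str = "score_or_critical",
) -> tuple[ConfusionSummary, pd.DataFrame]:
    """Run the full assistant over paired (evaluation, reference) cases.

    ``structure_sets`` yields (auto_set, reference_set) pairs sharing a
    case_id; ``dose_grids`` maps case_id to the case's dose.  Returns the
    confusion summary and the joined per-structure table from which it
    is recomputable.
    """
    rows = []
    for auto_set, ref_set in structure_sets:
        case_id = auto_set.case_id
        dose = dose_grids[case_id]
        for organ_id, eval_mask in auto_set.masks.items():
            if organ_id not in policies:
                raise ConfigurationError(f"no policy configured for organ {organ_id!r}")
            if organ_id not in ref_set.masks:
                raise AlignmentError(
                    f"case {case_id!r}: organ {organ_id!r} missing from reference set"
                )
            rec = evaluate_structure(
                case_id,
                eval_mask,
                ref_set.masks[organ_id],
                dose,
                policies[organ_id],
                rule=rule,
                combination_mode=combination_mode,
            )
            rows.append(rec.to_row())
    table = pd.DataFrame(rows)
    joined = join_flags_with_labels(table, reference_labels)
    return summarize_table(joined), joined
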