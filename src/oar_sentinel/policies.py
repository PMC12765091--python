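"""Per-organ QA policy: dose constraint, morphology extents, colour thresholds.

A policy bundles everything the assistant needs to judge one organ:

* which dose statistic its clinical constraint refers to (mean or max)
  and the constraint dose in Gy;
* the organ-specific dilation/erosion extents (mm) used to probe dose
  sensitivity — erosion is never more aggressive than dilation, so that
  small structures are not hollowed into unrealistic remnants;
* traffic-light thresholds for the four decision channels (DSC, HDD95,
  constraint dose, delta dose).

The shipped default file covers the 17 brain organs at risk of the
ESTRO-ACROP consensus set.  Its thresholds are documented defaults meant
to be edited per clinic; every report records which threshold set was
used.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


class PolicyValidationError(ValueError):
    """A policy entry violates the threshold-ordering invariants."""


@dataclass(frozen=True)
class OrganPolicy:
    """QA configuration for one organ at risk.

    Attributes
    ----------
    constraint_metric : {"mean", "max"}
        Which dose statistic the clinical constraint applies to.
    constraint_dose_gy : float
        The constraint dose in Gy (> 0).
    dilation_mm, erosion_mm : float
        Isotropic extents for the over-/under-segmentation probes.
    dsc_thresholds : (yellow_below, red_below)
        DSC below ``yellow_below`` is yellow, below ``red_below`` red.
    hdd_thresholds_mm : (yellow_above, red_above)
        HDD95 above ``yellow_above`` mm is yellow, above ``red_above`` red.
    dose_margin : (yellow_within, red_within_or_exceed)
        Fractions of the constraint dose: the dose channel turns yellow
        within ``yellow_within`` of the constraint and red within
        ``red_within_or_exceed`` of it (or above it).
    sensitivity_thresholds_gy : (yellow_above, red_above)
        Delta-dose thresholds in Gy.
    """

    organ_id: str
    constraint_metric: str
    constraint_dose_gy: float
    dilation_mm: float
    erosion_mm: float
    dsc_thresholds: tuple[float, float]
    hdd_thresholds_mm: tuple[float, float]
    dose_margin: tuple[float, float]
    sensitivity_thresholds_gy: tuple[float, float]

    def __post_init__(self) -> None:
        oid = self.organ_id

        def err(msg: str) -> None:
            raise PolicyValidationError(f"policy for {oid!r}: {msg}")

        if self.constraint_metric not in ("mean", "max"):
            err(f"unknown constraint_metric {self.constraint_metric!r}")
        if self.constraint_dose_gy <= 0:
            err("constraint_dose_gy must be > 0")
        if self.dilation_mm < 0 or self.erosion_mm < 0:
            err("morphology extents must be >= 0")
        if self.erosion_mm > self.dilation_mm:
            err(
                f"erosion_mm ({self.erosion_mm}) must not exceed "
                f"dilation_mm ({self.dilation_mm})"
            )
        yb, rb = self.dsc_thresholds
        if not (0.0 <= rb <= yb <= 1.0):
            err(f"dsc_thresholds must satisfy 0 <= red_below <= yellow_below <= 1, got {self.dsc_thresholds}")
        ya, ra = self.hdd_thresholds_mm
        if not (0.0 <= ya <= ra):
            err(f"hdd_thresholds_mm must satisfy 0 <= yellow_above <= red_above, got {self.hdd_thresholds_mm}")
        yw, rw = self.dose_margin
        if yw < 0 or rw < 0 or rw > yw:
            err(f"dose_margin must satisfy 0 <= red_within_or_exceed <= yellow_within, got {self.dose_margin}")
        ys, rs = self.sensitivity_thresholds_gy
        if not (0.0 <= ys <= rs):
            err(f"sensitivity_thresholds_gy must satisfy 0 <= yellow_above <= red_above, got {self.sensitivity_thresholds_gy}")


def _policy_from_entry(organ_id: str, entry: dict) -> OrganPolicy:
    try:
        return OrganPolicy(
            organ_id=organ_id,
            constraint_metric=str(entry["constraint_metric"]),
            constraint_dose_gy=float(entry["constraint_dose_gy"]),
            dilation_mm=float(entry["dilation_mm"]),
            erosion_mm=float(entry["erosion_mm"]),
            dsc_thresholds=tuple(float(v) for v in entry["dsc_thresholds"]),
            hdd_thresholds_mm=tuple(float(v) for v in entry["hdd_thresholds_mm"]),
            dose_margin=tuple(float(v) for v in entry["dose_margin"]),
            sensitivity_thresholds_gy=tuple(float(v) for v in entry["sensitivity_thresholds_gy"]),
        )
    except KeyError as exc:
        raise PolicyValidationError(f"policy for {organ_id!r}: missing field {exc}") from exc


def load_policies(path: str | Path | None = None) -> dict[str, OrganPolicy]:
    """Load organ policies from a YAML config (default: the shipped file).

    Returns a dict keyed by organ_id.  Raises
    :class:`PolicyValidationError` naming organ and field on any
    invariant violation.
    """
    if path is None:
        text = resources.files("oar_sentinel").joinpath("data/default_policies.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "organs" not in doc:
        raise PolicyValidationError("policy config must be a mapping with an 'organs' section")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise PolicyValidationError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    policies: dict[str, OrganPolicy] = {}
    for organ_id, entry in doc["organs"].items():
        policies[organ_id] = _policy_from_entry(str(organ_id), entry)
    return policies


def threshold_set_id(policies: dict[str, OrganPolicy]) -> str:
    """Stable short hash of a policy set, recorded in every report."""
    import hashlib

    payload = repr(sorted((k, repr(v)) for k, v in policies.items())).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
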