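"""Synthetic phantom study generator.

Emulates the structure of a brain-radiotherapy QA study at desk scale so
every pipeline stage is testable without clinical data: per case, ~17
convex-ish organ masks of varying size arranged around one spherical
planning target volume (PTV), an analytic dose field at the 60 Gy
prescription inside the PTV with a steep sigmoid falloff outside, and
programmatically injected contouring errors of the kinds a human editor
introduces (shifts, global expansion/shrinkage, local blobs, axial
truncation).

The dose stand-in is analytic, not learned: the logic under test is the
QA layer, and a monotone-falloff field gives controllable, provable dose
gradients with zero training.  Every generator is a pure function of its
seed and spec; reference criticality labels computed during generation
equal labels recomputed post hoc from the emitted volumes.

"Gross" errors — kind in {shift, expand, shrink} with magnitude at or
above :data:`GROSS_MAGNITUDE_MM` — are large enough, given the
generator's organ size range, that the overlap with the true contour
falls below any shipped DSC red threshold; combined with an organ
sitting inside the dose falloff shell they form the constructed subset
on which the assistant must reach sensitivity 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DoseGrid, StructureMask, StructureSet, VolumeGrid, write_volume
from .decision import CriticalEventRule, reference_critical
from .geometry import morph_mm
from .policies import OrganPolicy, load_policies

DEFAULT_ORGAN_IDS = (
    "brainstem", "optic_chiasm", "optic_nerve_l", "optic_nerve_r",
    "eye_l", "eye_r", "lens_l", "lens_r", "retina_l", "retina_r",
    "cochlea_l", "cochlea_r", "pituitary", "hippocampus_l",
    "hippocampus_r", "lacrimal_gland_l", "lacrimal_gland_r",
)

DEFAULT_GRID = VolumeGrid(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0))

#: kinds whose large magnitudes destroy global overlap (vs. local/partial edits)
GROSS_KINDS = frozenset({"shift", "expand", "shrink"})
#: magnitude (mm) at or above which a gross-kind error is a "gross" error
GROSS_MAGNITUDE_MM = 8.0

ERROR_KINDS = ("shift", "expand", "shrink", "blob_add", "blob_remove", "truncate_axial")


class PhantomSpecError(ValueError):
    """An organ or PTV does not fit the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of one phantom case."""

    grid: VolumeGrid
    organs: tuple  # of (organ_id, shape, center_mm, radii_mm)
    ptv_center_mm: tuple[float, float, float]
    ptv_radius_mm: float
    seed: int = 0

    def __post_init__(self) -> None:
        lo = np.asarray(self.grid.origin) - np.asarray(self.grid.spacing) / 2
        hi = lo + np.asarray(self.grid.shape) * np.asarray(self.grid.spacing)
        for organ_id, shape, center, radii in self.organs:
            if shape not in ("sphere", "ellipsoid"):
                raise PhantomSpecError(f"{organ_id}: unknown shape {shape!r}")
            c = np.asarray(center, dtype=float)
            r = np.asarray(radii, dtype=float) * np.ones(3)
            if np.any(r <= 0):
                raise PhantomSpecError(f"{organ_id}: radii must be > 0")
            if np.any(c - r < lo) or np.any(c + r > hi):
                raise PhantomSpecError(f"{organ_id}: organ extends outside the grid")


@dataclass(frozen=True)
class DoseModel:
    """Sigmoid distance-to-PTV dose falloff model.

    dose(x) = background + (prescription − background) ·
              sigmoid((midpoint − dist(x, PTV)) / steepness),
    clamped to the prescription inside the PTV.  Dose is monotonically
    non-increasing in distance from the PTV surface and never drops
    below the background.
    """

    prescription_gy: float = 60.0
    midpoint_mm: float = 20.0
    steepness_mm: float = 5.0
    background_gy: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.background_gy < self.prescription_gy):
            raise ValueError("require 0 <= background < prescription")
        if self.midpoint_mm < 0 or self.steepness_mm <= 0:
            raise ValueError("midpoint >= 0 and steepness > 0 required")


@dataclass(frozen=True)
class ErrorSpec:
    """One injected contouring error; deterministic under its seed."""

    kind: str
    magnitude_mm: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.magnitude_mm < 0:
            raise ValueError("magnitude_mm must be >= 0")

    @property
    def is_gross(self) -> bool:
        return self.kind in GROSS_KINDS and self.magnitude_mm >= GROSS_MAGNITUDE_MM


def _rasterize_ellipsoid(grid: VolumeGrid, center, radii) -> np.ndarray:
    axes = [
        (grid.origin[k] + np.arange(grid.shape[k]) * grid.spacing[k] - center[k]) / radii[k]
        for k in range(3)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0


def make_phantom(spec: PhantomSpec) -> StructureSet:
    """Rasterize a phantom spec by voxel-centre inclusion."""
    masks = {}
    for organ_id, shape, center, radii in spec.organs:
        r = np.asarray(radii, dtype=float) * np.ones(3)
        occ = _rasterize_ellipsoid(spec.grid, np.asarray(center, float), r)
        masks[organ_id] = StructureMask(organ_id, spec.grid, occ)
    ptv = StructureMask(
        "ptv", spec.grid,
        _rasterize_ellipsoid(spec.grid, np.asarray(spec.ptv_center_mm, float),
                             np.full(3, spec.ptv_radius_mm)),
    )
    return StructureSet(case_id=f"case_{spec.seed:04d}", masks=masks, ptv=ptv)


def make_dose(ptv: StructureMask, model: DoseModel | None = None) -> DoseGrid:
    """Analytic dose field: prescription inside the PTV, sigmoid falloff outside."""
    model = model or DoseModel()
    if ptv.is_empty:
        raise ValueError("PTV mask is empty")
    dist = ndimage.distance_transform_edt(~ptv.occupancy, sampling=ptv.grid.spacing)
    sig = 1.0 / (1.0 + np.exp(-(model.midpoint_mm - dist) / model.steepness_mm))
    dose = model.background_gy + (model.prescription_gy - model.background_gy) * sig
    dose[ptv.occupancy] = model.prescription_gy
    return DoseGrid(grid=ptv.grid, dose=dose)


def _translate(occ: np.ndarray, offset_vox: np.ndarray) -> np.ndarray:
    out = np.zeros_like(occ)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, off in enumerate(offset_vox):
        n = occ.shape[k]
        if abs(off) >= n:
            return out
        if off >= 0:
            src[k], dst[k] = slice(0, n - off), slice(off, n)
        else:
            src[k], dst[k] = slice(-off, n), slice(0, n + off)
    out[tuple(dst)] = occ[tuple(src)]
    return out


def inject_error(m: StructureMask, err: ErrorSpec) -> StructureMask:
    """Apply one contouring error to a mask; may return an empty mask.

    shift: whole-voxel translation along a seeded random direction;
    expand/shrink: mm-calibrated morphology; blob_add/blob_remove:
    union/difference with a seeded sphere centred on a random surface
    voxel; truncate_axial: removes the top slices of the organ's axial
    extent covering ``magnitude_mm``.
    """
    if m.is_empty:
        raise ValueError("cannot inject an error into an empty mask")
    if err.magnitude_mm == 0:
        return m.with_occupancy(m.occupancy.copy())
    rng = np.random.default_rng(err.seed)
    spacing = np.asarray(m.grid.spacing)
    if err.kind == "shift":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = np.round(direction * err.magnitude_mm / spacing).astype(int)
        if not offset.any():  # never degrade a shift to the identity
            offset[int(np.argmax(np.abs(direction)))] = 1 if direction.max() > 0 else -1
        return m.with_occupancy(_translate(m.occupancy, offset))
    if err.kind == "expand":
        return morph_mm(m, err.magnitude_mm, "dilate")
    if err.kind == "shrink":
        return morph_mm(m, err.magnitude_mm, "erode")
    if err.kind in ("blob_add", "blob_remove"):
        from .geometry import _surface_voxels

        surface_idx = np.argwhere(_surface_voxels(m.occupancy))
        center_idx = surface_idx[rng.integers(len(surface_idx))]
        center_mm = np.asarray(m.grid.origin) + center_idx * spacing
        blob = _rasterize_ellipsoid(m.grid, center_mm, np.full(3, err.magnitude_mm))
        if err.kind == "blob_add":
            return m.with_occupancy(m.occupancy | blob)
        return m.with_occupancy(m.occupancy & ~blob)
    # truncate_axial: drop top-of-organ axial slices spanning the magnitude
    occ = m.occupancy.copy()
    z_occ = np.flatnonzero(occ.any(axis=(0, 1)))
    k = max(1, int(round(err.magnitude_mm / spacing[2])))
    cut = z_occ[-k:] if k <= len(z_occ) else z_occ
    occ[:, :, cut] = False
    return m.with_occupancy(occ)


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass
class SimulatedCase:
    spec: PhantomSpec
    truth: StructureSet
    auto: StructureSet
    dose: DoseGrid


@dataclass
class SimulatedStudy:
    """A full synthetic validation study plus its generation ground truth."""

    cases: list[SimulatedCase]
    labels: pd.DataFrame  # case_id, organ_id, critical
    truth_table: pd.DataFrame  # adds error kind/magnitude, gap, shell/gross flags
    dose_model: DoseModel
    rule: CriticalEventRule
    master_seed: int

    @property
    def n_structures(self) -> int:
        return int(len(self.labels))


@dataclass(frozen=True)
class ErrorMix:
    """Probabilities of error severities injected per structure.

    Remaining probability mass is left error-free.  Magnitude ranges in
    mm; gross draws use only the kinds whose large magnitudes destroy
    global overlap.
    """

    p_minor: float = 0.30
    p_moderate: float = 0.20
    p_gross: float = 0.15
    minor_range_mm: tuple[float, float] = (1.0, 4.0)
    moderate_range_mm: tuple[float, float] = (4.0, 8.0)
    gross_range_mm: tuple[float, float] = (GROSS_MAGNITUDE_MM, 12.0)

    def __post_init__(self) -> None:
        if self.p_minor + self.p_moderate + self.p_gross > 1.0 + 1e-12:
            raise ValueError("error probabilities must sum to <= 1")
        if self.gross_range_mm[0] < GROSS_MAGNITUDE_MM:
            raise ValueError("gross magnitudes must be >= the gross bound")


def _draw_error(rng: np.random.Generator, mix: ErrorMix) -> ErrorSpec | None:
    u = rng.random()
    seed = int(rng.integers(2**31 - 1))
    if u < mix.p_gross:
        kind = rng.choice(sorted(GROSS_KINDS))
        lo, hi = mix.gross_range_mm
    elif u < mix.p_gross + mix.p_moderate:
        kind = rng.choice(ERROR_KINDS)
        lo, hi = mix.moderate_range_mm
    elif u < mix.p_gross + mix.p_moderate + mix.p_minor:
        kind = rng.choice(ERROR_KINDS)
        lo, hi = mix.minor_range_mm
    else:
        return None
    return ErrorSpec(kind=str(kind), magnitude_mm=float(rng.uniform(lo, hi)), seed=seed)


def random_phantom_spec(
    case_seed: int,
    organ_ids: tuple[str, ...] = DEFAULT_ORGAN_IDS,
    grid: VolumeGrid = DEFAULT_GRID,
    ptv_radius_mm: float = 15.0,
    gap_range_mm: tuple[float, float] = (4.0, 28.0),
    organ_radius_range_mm: tuple[float, float] = (6.0, 12.0),
) -> tuple[PhantomSpec, dict[str, float]]:
    """Seeded random phantom: organs scattered around a central PTV.

    Returns the spec plus each organ's sampled gap (mm) between its
    surface and the PTV surface, which determines how deep in the dose
    falloff the organ sits.
    """
    rng = np.random.default_rng(case_seed)
    center = np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing) / 2
    ptv_center = center + rng.uniform(-4, 4, size=3)
    organs = []
    gaps: dict[str, float] = {}
    for organ_id in organ_ids:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        gap = float(rng.uniform(*gap_range_mm))
        radius = float(rng.uniform(*organ_radius_range_mm))
        dist = ptv_radius_mm + gap + radius
        c = ptv_center + direction * dist
        if rng.random() < 0.5:
            radii = (radius, radius, radius)
            shape = "sphere"
        else:
            stretch = rng.uniform(0.7, 1.0, size=3)
            radii = tuple(float(radius * s) for s in stretch)
            shape = "ellipsoid"
        organs.append((organ_id, shape, tuple(float(x) for x in c), radii))
        gaps[organ_id] = gap
    spec = PhantomSpec(
        grid=grid,
        organs=tuple(organs),
        ptv_center_mm=tuple(float(x) for x in ptv_center),
        ptv_radius_mm=ptv_radius_mm,
        seed=case_seed,
    )
    return spec, gaps


def simulate_validation_dataset(
    n_cases: int = 30,
    organs_per_case: int = 17,
    error_mix: ErrorMix | None = None,
    master_seed: int = 0,
    n_dropout_cases: int = 3,
    dose_model: DoseModel | None = None,
    rule: CriticalEventRule | None = None,
    policies: dict[str, OrganPolicy] | None = None,
) -> SimulatedStudy:
    """Generate a full paired validation study with ground-truth labels.

    Per structure: a ground-truth mask, an error-injected "auto" mask,
    the case's dose field, and a reference criticality label from
    :func:`oar_sentinel.decision.reference_critical` applied to the
    constraint-selected dose metrics of the true vs. injected masks.
    In the first ``n_dropout_cases`` cases one seeded-random organ is
    absent from both sets, emulating incomplete structure sets (e.g.
    30 × 17 − 3 = 507 structures with the defaults).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 1 <= organs_per_case <= len(DEFAULT_ORGAN_IDS):
        raise ValueError(f"organs_per_case must be in [1, {len(DEFAULT_ORGAN_IDS)}]")
    mix = error_mix or ErrorMix()
    model = dose_model or DoseModel()
    rule = rule or CriticalEventRule()
    policies = policies or load_policies()
    organ_ids = DEFAULT_ORGAN_IDS[:organs_per_case]
    shell_mm = model.midpoint_mm  # organs with gap <= midpoint sit in the falloff shell

    master = np.random.default_rng(master_seed)
    case_seeds = master.integers(2**31 - 1, size=n_cases)
    cases: list[SimulatedCase] = []
    rows: list[dict] = []
    for i, case_seed in enumerate(case_seeds):
        # separate stream from the one random_phantom_spec derives from case_seed
        rng = np.random.default_rng([int(case_seed), 1])
        spec, gaps = random_phantom_spec(int(case_seed), organ_ids=organ_ids)
        truth = make_phantom(spec)
        case_id = f"case_{i:03d}"
        truth.case_id = case_id
        dose = make_dose(truth.ptv, model)

        drop: str | None = None
        if i < n_dropout_cases:
            drop = str(rng.choice(organ_ids))

        auto_masks: dict[str, StructureMask] = {}
        truth_masks: dict[str, StructureMask] = {}
        for organ_id in organ_ids:
            if organ_id == drop:
                continue
            true_mask = truth.masks[organ_id]
            err = _draw_error(rng, mix)
            auto_mask = inject_error(true_mask, err) if err is not None else true_mask.with_occupancy(true_mask.occupancy.copy())
            truth_masks[organ_id] = true_mask
            auto_masks[organ_id] = auto_mask

            policy = policies[organ_id]
            from .dosimetry import dose_metrics

            ref_mean, ref_max = dose_metrics(true_mask, dose)
            dose_ref = ref_mean if policy.constraint_metric == "mean" else ref_max
            if auto_mask.is_empty:
                critical = True  # vanished contour: maximally critical by definition
                dose_alt = None
            else:
                alt_mean, alt_max = dose_metrics(auto_mask, dose)
                dose_alt = alt_mean if policy.constraint_metric == "mean" else alt_max
                critical = reference_critical(dose_ref, dose_alt, rule, policy)
            rows.append({
                "case_id": case_id,
                "organ_id": organ_id,
                "critical": bool(critical),
                "error_kind": "none" if err is None else err.kind,
                "magnitude_mm": 0.0 if err is None else err.magnitude_mm,
                "gap_mm": gaps[organ_id],
                "in_shell": gaps[organ_id] <= shell_mm,
                "gross": bool(err is not None and err.is_gross),
                "dose_ref_gy": dose_ref,
                "dose_alt_gy": dose_alt,
            })

        cases.append(SimulatedCase(
            spec=spec,
            truth=StructureSet(case_id=case_id, masks=truth_masks, ptv=truth.ptv),
            auto=StructureSet(case_id=case_id, masks=auto_masks, ptv=truth.ptv),
            dose=dose,
        ))

    truth_table = pd.DataFrame(rows)
    labels = truth_table[["case_id", "organ_id", "critical"]].copy()
    return SimulatedStudy(
        cases=cases, labels=labels, truth_table=truth_table,
        dose_model=model, rule=rule, master_seed=master_seed,
    )


def write_dataset(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write a study as NIfTI volumes + labels CSV + regeneration manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for case in study.cases:
        cdir = out / case.truth.case_id
        (cdir / "truth").mkdir(parents=True, exist_ok=True)
        (cdir / "auto").mkdir(parents=True, exist_ok=True)
        for organ_id, mask in case.truth.masks.items():
            write_volume(mask, cdir / "truth" / f"{organ_id}.nii.gz")
        for organ_id, mask in case.auto.masks.items():
            write_volume(mask, cdir / "auto" / f"{organ_id}.nii.gz")
        write_volume(case.truth.ptv, cdir / "ptv.nii.gz")
        write_volume(case.dose, cdir / "dose.nii.gz")
    study.labels.to_csv(out / "labels.csv", index=False)
    study.truth_table.to_csv(out / "truth.csv", index=False)
    manifest = {
        "master_seed": study.master_seed,
        "n_cases": len(study.cases),
        "n_structures": study.n_structures,
        "dose_model": {
            "prescription_gy": study.dose_model.prescription_gy,
            "midpoint_mm": study.dose_model.midpoint_mm,
            "steepness_mm": study.dose_model.steepness_mm,
            "background_gy": study.dose_model.background_gy,
        },
        "rule": {
            "proximity_margin": study.rule.proximity_margin,
            "delta_threshold_gy": study.rule.delta_threshold_gy,
            "safety_margin_gy": study.rule.safety_margin_gy,
        },
        "gross_magnitude_mm": GROSS_MAGNITUDE_MM,
        "gross_kinds": sorted(GROSS_KINDS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
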