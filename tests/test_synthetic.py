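"""Phantom rasterization, analytic dose model, error injection, study generation."""

import numpy as np
import pytest

from conftest import dsc_oracle
from oar_sentinel.core import VolumeGrid
from oar_sentinel.decision import reference_critical
from oar_sentinel.dosimetry import dose_metrics
from oar_sentinel.geometry import compute_dsc
from oar_sentinel.policies import load_policies
from oar_sentinel.synthetic import (
    DoseModel,
    ErrorSpec,
    PhantomSpec,
    PhantomSpecError,
    inject_error,
    make_dose,
    make_phantom,
    random_phantom_spec,
    simulate_validation_dataset,
)

MM1 = VolumeGrid((40, 40, 40), (1.0, 1.0, 1.0))


def sphere_spec(radius=10.0, grid=MM1, center=None):
    c = center or tuple((np.array(grid.shape) - 1) / 2 * np.array(grid.spacing))
    return PhantomSpec(
        grid=grid,
        organs=(("organ", "sphere", c, (radius, radius, radius)),),
        ptv_center_mm=c,
        ptv_radius_mm=radius,
        seed=0,
    )


class TestMakePhantom:
    def test_sphere_volume_matches_analytic_within_2pct(self):
        phantom = make_phantom(sphere_spec(radius=10.0))
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert phantom.masks["organ"].volume_mm3 == pytest.approx(analytic, rel=0.02)

    def test_determinism(self):
        a = make_phantom(sphere_spec())
        b = make_phantom(sphere_spec())
        assert np.array_equal(a.masks["organ"].occupancy, b.masks["organ"].occupancy)

    def test_disjoint_bounding_spheres_give_disjoint_masks(self):
        spec = PhantomSpec(
            grid=MM1,
            organs=(
                ("a", "sphere", (10.0, 10.0, 10.0), (4.0, 4.0, 4.0)),
                ("b", "ellipsoid", (28.0, 28.0, 28.0), (4.0, 3.0, 3.5)),
            ),
            ptv_center_mm=(19.5, 19.5, 19.5),
            ptv_radius_mm=3.0,
        )
        phantom = make_phantom(spec)
        assert not (phantom.masks["a"].occupancy & phantom.masks["b"].occupancy).any()

    def test_organ_outside_grid_rejected(self):
        with pytest.raises(PhantomSpecError, match="outside"):
            PhantomSpec(
                grid=MM1,
                organs=(("a", "sphere", (39.0, 20.0, 20.0), (5.0, 5.0, 5.0)),),
                ptv_center_mm=(20.0, 20.0, 20.0),
                ptv_radius_mm=3.0,
            )


class TestDoseModel:
    def test_prescription_inside_ptv_and_bounds(self):
        phantom = make_phantom(sphere_spec(radius=8.0))
        model = DoseModel()
        dose = make_dose(phantom.ptv, model)
        assert np.all(dose.dose[phantom.ptv.occupancy] == model.prescription_gy)
        assert np.all(dose.dose >= model.background_gy - 1e-12)
        assert np.all(dose.dose <= model.prescription_gy + 1e-12)

    def test_sigmoid_midpoint_value_on_axis(self):
        # PTV sphere r=10 mm centred on a 2 mm lattice: along +x the nearest
        # PTV voxel centre to a probe 10 voxels beyond the edge voxel is that
        # edge voxel, at exactly 20 mm = the model midpoint.
        grid = VolumeGrid((40, 40, 40), (2.0, 2.0, 2.0))
        phantom = make_phantom(sphere_spec(radius=10.0, grid=grid, center=(40.0, 40.0, 40.0)))
        model = DoseModel(midpoint_mm=20.0, steepness_mm=5.0)
        dose = make_dose(phantom.ptv, model)
        # PTV occupies |x-40|<=10 on-axis: voxel centres 30..50 -> idx 15..25
        probe = (35, 20, 20)  # x=70 mm, 20 mm beyond edge voxel at x=50
        expect = model.background_gy + (model.prescription_gy - model.background_gy) / 2
        assert dose.dose[probe] == pytest.approx(expect)

    def test_non_increasing_along_rays_from_center(self):
        phantom = make_phantom(sphere_spec(radius=8.0))
        dose = make_dose(phantom.ptv, DoseModel()).dose
        c = 19  # ray start near the centre voxel (19.5, 19.5, 19.5) mm
        for ray in (dose[c, c, c:], dose[c, c:, c], dose[c:, c, c][::1]):
            assert np.all(np.diff(ray) <= 1e-9)


class TestInjectError:
    @pytest.fixture
    def ball(self):
        return make_phantom(sphere_spec(radius=9.0)).masks["organ"]

    def test_zero_magnitude_identity(self, ball):
        out = inject_error(ball, ErrorSpec("expand", 0.0, seed=1))
        assert np.array_equal(out.occupancy, ball.occupancy)

    def test_determinism_under_seed(self, ball):
        a = inject_error(ball, ErrorSpec("blob_add", 4.0, seed=9))
        b = inject_error(ball, ErrorSpec("blob_add", 4.0, seed=9))
        assert np.array_equal(a.occupancy, b.occupancy)
        c = inject_error(ball, ErrorSpec("blob_add", 4.0, seed=10))
        assert not np.array_equal(a.occupancy, c.occupancy)

    def test_opening_is_subset_of_original(self, ball):
        shrunk = inject_error(ball, ErrorSpec("shrink", 3.0, seed=0))
        opened = inject_error(shrunk, ErrorSpec("expand", 3.0, seed=0))
        assert np.all(~opened.occupancy | ball.occupancy)

    def test_shift_preserves_volume_and_dsc_matches_count_oracle(self, ball):
        out = inject_error(ball, ErrorSpec("shift", 2.0, seed=4))
        assert out.voxel_count == ball.voxel_count  # fully in bounds
        assert compute_dsc(ball, out) == pytest.approx(dsc_oracle(ball.occupancy, out.occupancy))
        assert compute_dsc(ball, out) < 1.0

    def test_blob_add_superset_blob_remove_subset(self, ball):
        added = inject_error(ball, ErrorSpec("blob_add", 3.0, seed=2))
        removed = inject_error(ball, ErrorSpec("blob_remove", 3.0, seed=2))
        assert np.all(~ball.occupancy | added.occupancy)
        assert np.all(~removed.occupancy | ball.occupancy)
        assert added.voxel_count > ball.voxel_count > removed.voxel_count

    def test_truncate_axial_removes_top_slices(self, ball):
        out = inject_error(ball, ErrorSpec("truncate_axial", 4.0, seed=0))
        z_before = np.flatnonzero(ball.occupancy.any(axis=(0, 1)))
        z_after = np.flatnonzero(out.occupancy.any(axis=(0, 1)))
        assert z_after.max() < z_before.max()
        assert np.array_equal(
            out.occupancy[:, :, : z_after.max() + 1],
            ball.occupancy[:, :, : z_after.max() + 1],
        )


class TestSimulateValidationDataset:
    def test_structure_count_with_dropout(self):
        study = simulate_validation_dataset(n_cases=4, organs_per_case=5,
                                            master_seed=11, n_dropout_cases=2)
        assert study.n_structures == 4 * 5 - 2
        assert len(study.cases) == 4

    def test_default_scale_mimics_507(self):
        # only count bookkeeping here; the full-scale run lives in acceptance
        study = simulate_validation_dataset(n_cases=3, organs_per_case=17,
                                            master_seed=0, n_dropout_cases=3)
        assert study.n_structures == 3 * 17 - 3

    def test_same_master_seed_reproduces_dataset(self):
        a = simulate_validation_dataset(n_cases=2, organs_per_case=4, master_seed=21)
        b = simulate_validation_dataset(n_cases=2, organs_per_case=4, master_seed=21)
        assert a.labels.equals(b.labels)
        assert a.truth_table.equals(b.truth_table)
        for ca, cb in zip(a.cases, b.cases):
            assert np.array_equal(ca.dose.dose, cb.dose.dose)
            for k in ca.auto.masks:
                assert np.array_equal(ca.auto.masks[k].occupancy, cb.auto.masks[k].occupancy)

    def test_error_free_structures_have_consistent_labels(self):
        study = simulate_validation_dataset(n_cases=2, organs_per_case=6, master_seed=5)
        tt = study.truth_table
        clean = tt[tt["error_kind"] == "none"]
        # without a contour change the impact condition can't fire: any
        # critical label must come from dose proximity alone
        for _, row in clean.iterrows():
            assert row["dose_alt_gy"] == pytest.approx(row["dose_ref_gy"])

    def test_labels_recomputable_from_emitted_volumes(self):
        study = simulate_validation_dataset(n_cases=2, organs_per_case=5, master_seed=13)
        policies = load_policies()
        for case in study.cases:
            sub = study.truth_table[study.truth_table["case_id"] == case.auto.case_id]
            for _, row in sub.iterrows():
                organ = row["organ_id"]
                policy = policies[organ]
                t_mean, t_max = dose_metrics(case.truth.masks[organ], case.dose)
                dose_ref = t_mean if policy.constraint_metric == "mean" else t_max
                auto_mask = case.auto.masks[organ]
                if auto_mask.is_empty:
                    assert row["critical"]
                    continue
                a_mean, a_max = dose_metrics(auto_mask, case.dose)
                dose_alt = a_mean if policy.constraint_metric == "mean" else a_max
                assert row["critical"] == reference_critical(dose_ref, dose_alt, study.rule, policy)
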