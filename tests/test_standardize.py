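"""Unit and property tests for the five standardization transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.base import clone

from mrinorm.errors import (
    DegenerateHistogramError,
    DegenerateVolumeError,
    EmptyMaskError,
    MissingROIError,
    NonPositiveReferenceError,
    ZeroRangeError,
    ZeroVarianceError,
)
from mrinorm.grid import ROISet, VolumeGrid
from mrinorm.standardize import (
    FatStandardizer,
    MinMaxStandardizer,
    NyulStandardizer,
    NyulTemplate,
    ZScoreStandardizer,
    compute_external_mask,
    nyul_apply,
    nyul_learn,
    standardize_fat,
    standardize_minmax,
    standardize_zscore,
)
from mrinorm.synthetic import PhantomSpec, generate_cohort
from mrinorm.vocab import NYUL_PERCENTILES_DEFAULT


def vol(values, pid="P"):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    return VolumeGrid(patient_id=pid, voxels=arr, spacing=(1, 1, 1))


finite_volumes = hnp.arrays(
    dtype=np.float64,
    shape=st.tuples(
        st.integers(2, 6), st.integers(2, 6), st.integers(1, 4)
    ),
    elements=st.floats(-1e6, 1e6, allow_nan=False),
)


class TestMinMax:
    def test_direct_substitution(self):
        out = standardize_minmax(vol([0, 5, 10]))
        np.testing.assert_array_equal(out.voxels.ravel(), [0, 0.5, 1])

    def test_constant_volume_rejected(self):
        with pytest.raises(ZeroRangeError):
            standardize_minmax(vol([3, 3, 3]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(finite_volumes)
    def test_output_extrema_are_zero_and_one(self, arr):
        if arr.max() == arr.min():
            return
        out = MinMaxStandardizer().fit_transform(arr)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_invariant_under_positive_affine_input_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 500, (6, 6, 3))
        a = standardize_minmax(vol(x, "a")).voxels
        b = standardize_minmax(vol(3.5 * x + 120.0, "b")).voxels
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestZScore:
    def test_closed_form_population_sd(self):
        out = standardize_zscore(vol([1, 2, 3]))
        expect = np.array([-1, 0, 1]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.voxels.ravel(), expect, rtol=1e-12)

    def test_masked_statistics_region_mean0_sd1(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, (8, 8, 4))
        mask = np.zeros_like(x, dtype=bool)
        mask[2:6, 2:6, 1:3] = True
        out = standardize_zscore(vol(x), mask)
        region = out.voxels[mask]
        assert abs(region.mean()) < 1e-10
        assert abs(region.std() - 1) < 1e-10
        # unmasked voxels see the same affine map
        mu, sd = x[mask].mean(), x[mask].std()
        np.testing.assert_allclose(out.voxels, (x - mu) / sd, rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            standardize_zscore(vol([1, 2, 3]), np.zeros((3, 1, 1), dtype=bool))

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            standardize_zscore(vol([5, 5, 5]))

    def test_invariant_under_positive_affine_input_transform(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 500, (6, 6, 3))
        a = standardize_zscore(vol(x)).voxels
        b = standardize_zscore(vol(0.25 * x - 40.0)).voxels
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-10)


class TestFat:
    def make(self, fat_value=600.0):
        x = np.full((6, 6, 2), 100.0)
        masks = {
            "Fat_L": np.zeros_like(x, dtype=bool),
            "Fat_R": np.zeros_like(x, dtype=bool),
        }
        masks["Fat_L"][1, 1, 0] = True
        masks["Fat_R"][1, 4, 0] = True
        x[1, 1, 0] = x[1, 4, 0] = fat_value
        x[3, 3, 1] = fat_value        # probe voxel at the reference mean
        x[4, 4, 1] = 2 * fat_value    # probe voxel at twice the mean
        return vol(x), ROISet(grid_ref="P", masks=masks)

    def test_fixed_point_at_reference_mean(self):
        v, rois = self.make()
        out = standardize_fat(v, rois)
        assert out.voxels[3, 3, 1] == 350.0
        assert out.voxels[4, 4, 1] == 700.0

    def test_pooled_mean_weights_voxels_not_rois(self):
        x = np.full((4, 4, 1), 10.0)
        masks = {
            "Fat_L": np.zeros_like(x, dtype=bool),
            "Fat_R": np.zeros_like(x, dtype=bool),
        }
        masks["Fat_L"][0, :3, 0] = True   # 3 voxels at 300
        masks["Fat_R"][1, 0, 0] = True    # 1 voxel at 700
        x[0, :3, 0] = 300.0
        x[1, 0, 0] = 700.0
        est = FatStandardizer().fit(vol(x), rois=ROISet(grid_ref="P", masks=masks))
        assert est.reference_mean_ == pytest.approx(400.0)  # not (300+700)/2

    def test_missing_and_nonpositive_reference(self):
        v, rois = self.make()
        del rois.masks["Fat_R"]
        with pytest.raises(MissingROIError):
            standardize_fat(v, rois)
        v2, rois2 = self.make(fat_value=-5.0)
        with pytest.raises(NonPositiveReferenceError):
            standardize_fat(v2, rois2)

    def test_invariant_under_pure_gain_but_not_offset(self):
        v, rois = self.make()
        base = standardize_fat(v, rois).voxels
        gained = standardize_fat(v.with_voxels(4.0 * v.voxels), rois).voxels
        np.testing.assert_allclose(base, gained, rtol=1e-12)
        shifted = standardize_fat(v.with_voxels(v.voxels + 50.0), rois).voxels
        assert not np.allclose(base, shifted)


class TestExternalMask:
    @staticmethod
    def body_scale_phantom():
        """Ellipsoid phantom on a body-scale grid (mean 300 over background 5)."""
        from mrinorm.synthetic import RoiShape

        spec = PhantomSpec(
            n_patients=2, seed=9,
            grid_shape=(96, 96, 48), body_semiaxes=(40.0, 40.0, 22.0),
        )
        spec.tissue_table["background"] = (5.0, 1.0)
        spec.tissue_table["muscle"] = (300.0, 10.0)
        spec.roi_layout = {
            name: RoiShape(
                s.center_row * 2, s.center_col * 2, s.z_start * 2,
                s.radius, s.tissue,
            )
            for name, s in spec.roi_layout.items()
        }
        return generate_cohort(spec).patients[0]

    def test_recovers_body_ellipsoid(self):
        patient = self.body_scale_phantom()
        mask = compute_external_mask(patient.volume)
        body = patient.external_mask
        assert (mask & body).sum() >= 0.99 * body.sum()
        assert (mask & ~body).sum() <= 0.01 * (~body).sum()

    def test_single_connected_component(self):
        from scipy import ndimage

        patient = generate_cohort(PhantomSpec(n_patients=2, seed=9)).patients[0]
        mask = compute_external_mask(patient.volume)
        _, n = ndimage.label(mask)
        assert n == 1

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateVolumeError):
            compute_external_mask(vol(np.zeros((5, 5, 3))))


class TestNyul:
    def test_default_percentiles(self):
        assert NYUL_PERCENTILES_DEFAULT == (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)

    def test_single_image_template_is_its_mapped_landmarks(self, het_cohort):
        from mrinorm.grid import Cohort

        one = Cohort(label="one", patients=het_cohort.patients[:1])
        template = nyul_learn(one, use_external_mask=True)
        vals = het_cohort.patients[0].volume.voxels[
            het_cohort.patients[0].external_mask
        ]
        lm = np.percentile(vals, NYUL_PERCENTILES_DEFAULT)
        expect = (lm - lm[0]) / (lm[-1] - lm[0]) * 100.0
        np.testing.assert_allclose(template.standard_positions, expect, atol=1e-9)

    def test_affine_cohort_matches_single_image_template(self, het_cohort):
        from mrinorm.grid import Cohort, CohortImage

        base = het_cohort.patients[0]
        patients = [base]
        for i, (a, b) in enumerate([(2.0, 30.0), (0.5, -10.0)], start=2):
            volume = base.volume.with_voxels(a * base.volume.voxels + b)
            volume = VolumeGrid(
                patient_id=f"C{i}", voxels=volume.voxels,
                spacing=volume.spacing, origin=volume.origin,
            )
            rois = ROISet(grid_ref=f"C{i}", masks=dict(base.rois.masks))
            patients.append(
                CohortImage(volume=volume, rois=rois,
                            external_mask=base.external_mask)
            )
        single = nyul_learn(Cohort(label="s", patients=[base]))
        affine = nyul_learn(Cohort(label="a", patients=patients))
        np.testing.assert_allclose(
            affine.standard_positions, single.standard_positions, atol=1e-9
        )

    def test_apply_maps_landmarks_onto_standard_positions(self, het_cohort):
        from mrinorm.grid import Cohort

        one = Cohort(label="one", patients=het_cohort.patients[:1])
        template = nyul_learn(one)
        patient = het_cohort.patients[0]
        out = nyul_apply(patient.volume, template, mask=patient.external_mask)
        vals_in = patient.volume.voxels[patient.external_mask]
        lm = np.percentile(vals_in, template.percentiles)
        mapped = np.interp(lm, lm, np.asarray(template.standard_positions))
        np.testing.assert_allclose(mapped, template.standard_positions, atol=1e-9)
        # transformed masked landmark values equal the template's positions
        vals_out = out.voxels[patient.external_mask]
        np.testing.assert_allclose(
            np.percentile(vals_out, template.percentiles),
            template.standard_positions,
            atol=1e-6,
        )

    def test_gain_invariance_of_standardized_landmarks(self, het_cohort):
        template = nyul_learn(het_cohort)
        patient = het_cohort.patients[0]
        mask = patient.external_mask
        out_a = nyul_apply(patient.volume, template)
        out_b = nyul_apply(
            patient.volume.with_voxels(3.0 * patient.volume.voxels), template
        )
        np.testing.assert_allclose(
            np.percentile(out_a.voxels[mask], template.percentiles),
            np.percentile(out_b.voxels[mask], template.percentiles),
            atol=1e-8,
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(finite_volumes)
    def test_monotone_nondecreasing(self, arr):
        if np.percentile(arr, 99) <= np.percentile(arr, 1):
            return
        est = NyulStandardizer(use_mask=False).fit([arr])
        out = est.transform(arr)
        order = np.argsort(arr.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-9)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            NyulStandardizer(use_mask=False).fit([np.full((4, 4, 2), 7.0)])

    def test_template_json_round_trip(self, tmp_path, het_cohort):
        template = nyul_learn(het_cohort)
        path = tmp_path / "template.json"
        template.to_json(path)
        back = NyulTemplate.from_json(path)
        assert back == template


class TestEstimatorAPI:
    @pytest.mark.parametrize(
        "est",
        [MinMaxStandardizer(), ZScoreStandardizer(), FatStandardizer(scale=200),
         NyulStandardizer(scale_bounds=(0, 50))],
        ids=["minmax", "zscore", "fat", "nyul"],
    )
    def test_get_params_and_clone(self, est):
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_set_params(self):
        est = FatStandardizer().set_params(scale=123.0)
        assert est.scale == 123.0
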