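import math

import numpy as np
import pytest

from petharm.image import (
    FractionalMask,
    SubjectContext,
    VolumetricImage,
    fwhm_to_sigma,
    gaussian_postfilter,
    make_sphere_mask,
    suv_normalize,
    suv_peak,
)

from oracles import brute_force_suv_peak


@pytest.mark.parametrize(
    "fwhm, expected",
    [
        (2.35482, 1.0),  # definition of FWHM, to the precision of the input
        (0.0, 0.0),
        (7.0, 2.9726408610989847),  # 7 / (2 sqrt(2 ln 2))
    ],
)
def test_fwhm_to_sigma(fwhm, expected):
    assert fwhm_to_sigma(fwhm) == pytest.approx(expected, rel=1e-5)


def test_fwhm_to_sigma_rejects_negative():
    with pytest.raises(ValueError):
        fwhm_to_sigma(-1.0)


class TestGaussianPostfilter:
    def test_zero_fwhm_is_identity(self, unit_grid):
        rng = np.random.default_rng(1)
        img = unit_grid.with_values(rng.random(unit_grid.shape))
        out = gaussian_postfilter(img, 0.0)
        assert np.array_equal(out.values, img.values)
        assert out.values is not img.values
        assert out.unit == img.unit

    def test_constant_image_preserved(self, unit_grid):
        img = unit_grid.with_values(np.full(unit_grid.shape, 3.7))
        out = gaussian_postfilter(img, 6.0)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-12)

    def test_impulse_response_matches_analytic_gaussian(self):
        n = 41
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        img = VolumetricImage(vals, spacing=(1.0, 1.0, 1.0), unit="SUV")
        fwhm = 4.7096  # sigma = 2 voxels
        out = gaussian_postfilter(img, fwhm)
        sigma = fwhm_to_sigma(fwhm)
        z = np.arange(n) - n // 2
        g = np.exp(-(z**2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        np.testing.assert_allclose(out.values, expected, atol=1e-9)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_composition_in_quadrature(self):
        rng = np.random.default_rng(7)
        img = VolumetricImage(rng.random((48, 48, 48)), spacing=(2, 2, 2), unit="SUV")
        twice = gaussian_postfilter(gaussian_postfilter(img, 6.0), 8.0)
        once = gaussian_postfilter(img, math.hypot(6.0, 8.0))
        interior = (slice(16, 32),) * 3
        np.testing.assert_allclose(
            twice.values[interior], once.values[interior], rtol=1e-6
        )

    def test_mass_conservation_for_interior_support(self):
        vals = np.zeros((48, 48, 48))
        vals[20:28, 20:28, 20:28] = 5.0  # support >= 4 fwhm from every boundary
        img = VolumetricImage(vals, spacing=(1, 1, 1), unit="kBq/ml")
        out = gaussian_postfilter(img, 4.0)
        assert abs(out.values.sum() / vals.sum() - 1) < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_max_damping(self, seed):
        rng = np.random.default_rng(seed)
        img = VolumetricImage(rng.random((16, 16, 16)), spacing=(2, 2, 2), unit="SUV")
        fwhm = float(rng.uniform(0.5, 9.0))
        out = gaussian_postfilter(img, fwhm)
        assert out.values.max() <= img.values.max() + 1e-12

    def test_rejects_negative_fwhm(self, unit_grid):
        with pytest.raises(ValueError):
            gaussian_postfilter(unit_grid, -2.0)


class TestSuvNormalize:
    def test_reference_concentration_maps_to_one(self, unit_grid):
        ctx = SubjectContext(injected_activity=250.0, body_weight=75.0)
        conc = 250.0 / 75.0  # kBq/ml equal to MBq/kg numerically
        img = unit_grid.with_values(np.full(unit_grid.shape, conc), unit="kBq/ml")
        img = VolumetricImage(img.values, img.spacing, img.origin, "kBq/ml")
        out = suv_normalize(img, ctx)
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-12)
        assert out.unit == "SUV"

    def test_worked_example(self, unit_grid):
        # 5 kBq/ml with 200 MBq in 80 kg -> 200000 kBq / 80000 ml -> SUV 2
        img = VolumetricImage(
            np.full(unit_grid.shape, 5.0), unit_grid.spacing, unit_grid.origin, "kBq/ml"
        )
        out = suv_normalize(img, SubjectContext(200.0, 80.0))
        np.testing.assert_allclose(out.values, 2.0, rtol=1e-12)

    def test_rejects_suv_input_and_bad_context(self, unit_grid):
        with pytest.raises(ValueError):
            suv_normalize(unit_grid, SubjectContext(200.0, 80.0))  # already SUV
        with pytest.raises(ValueError):
            SubjectContext(0.0, 80.0)
        with pytest.raises(ValueError):
            SubjectContext(200.0, -1.0)


class TestSphereMask:
    def test_peak_sphere_volume_close_to_analytic(self, unit_grid):
        mask = make_sphere_mask(unit_grid, (0.0, 0.0, 0.0), 12.0)
        analytic = math.pi / 6.0 * 1.2**3  # 0.9048 ml
        assert mask.total_volume_ml == pytest.approx(analytic, rel=0.01)

    def test_fully_contained_voxel_has_weight_one(self, unit_grid):
        mask = make_sphere_mask(unit_grid, (0.0, 0.0, 0.0), 12.0)
        center_idx = tuple(s // 2 for s in unit_grid.shape)
        assert mask.weights[center_idx] == 1.0

    def test_subvoxel_sphere_conserves_volume(self, coarse_grid):
        # 3 mm sphere inside one 4 mm voxel
        mask = make_sphere_mask(coarse_grid, (2.0, 2.0, 2.0), 3.0)
        analytic = math.pi / 6.0 * 0.3**3
        assert mask.total_volume_ml == pytest.approx(analytic, rel=0.15)

    def test_volume_converges_with_subsampling_density(self, coarse_grid):
        analytic = math.pi / 6.0 * 1.7**3
        errors = []
        for subsamples in (5, 11):
            mask = make_sphere_mask(coarse_grid, (1.0, -1.0, 2.0), 17.0, subsamples)
            errors.append(abs(mask.total_volume_ml - analytic))
        assert errors[1] < errors[0]
        assert errors[1] / analytic < 0.005

    def test_center_outside_grid_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            make_sphere_mask(unit_grid, (0.0, 0.0, 100.0), 12.0)

    def test_boundary_clipping_keeps_weights_valid(self, unit_grid):
        lo, _ = unit_grid.world_bounds()
        mask = make_sphere_mask(unit_grid, (lo[0] + 0.1, 0.0, 0.0), 12.0)
        assert 0 < mask.total_volume_ml < math.pi / 6.0 * 1.2**3


class TestSuvPeak:
    def test_uniform_image_returns_constant(self, unit_grid):
        img = unit_grid.with_values(np.full(unit_grid.shape, 4.2))
        tumor = make_sphere_mask(img, (0.0, 0.0, 0.0), 8.0)
        assert suv_peak(img, tumor) == pytest.approx(4.2, rel=1e-12)

    def test_single_hot_voxel_dilution(self, unit_grid):
        vals = np.zeros(unit_grid.shape)
        c = tuple(s // 2 for s in unit_grid.shape)
        vals[c] = 100.0
        img = unit_grid.with_values(vals)
        tumor = FractionalMask(
            (vals > 0).astype(float), unit_grid.voxel_volume_ml
        )
        sphere_vol = math.pi / 6.0 * 1.2**3
        expected = 100.0 * unit_grid.voxel_volume_ml / sphere_vol
        assert suv_peak(img, tumor) == pytest.approx(expected, rel=0.02)

    def test_never_exceeds_suvmax_over_sphere_supports(self, coarse_grid):
        rng = np.random.default_rng(11)
        img = coarse_grid.with_values(rng.random(coarse_grid.shape) * 10)
        tumor = make_sphere_mask(img, (0.0, 0.0, 0.0), 20.0)
        assert suv_peak(img, tumor) <= img.values.max()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_search(self, coarse_grid, seed):
        rng = np.random.default_rng(seed)
        img = coarse_grid.with_values(rng.random(coarse_grid.shape) * 8)
        tumor = np.zeros(coarse_grid.shape)
        idx = rng.integers(4, 16, size=(12, 3))
        tumor[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
        mask = FractionalMask(tumor, coarse_grid.voxel_volume_ml)
        ours = suv_peak(img, mask)
        oracle = brute_force_suv_peak(img, tumor)
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_empty_tumor_rejected(self, unit_grid):
        empty = FractionalMask(np.zeros(unit_grid.shape), unit_grid.voxel_volume_ml)
        with pytest.raises(ValueError):
            suv_peak(unit_grid, empty)
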