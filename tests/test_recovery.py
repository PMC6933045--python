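import math

import numpy as np
import pytest

from petharm.image import fwhm_to_sigma, gaussian_postfilter
from petharm.phantom import PhantomSpec, simulate_phantom
from petharm.recovery import (
    RecoveryCurve,
    SpecificationBand,
    earl_compliant,
    recovery_curve,
    select_filter,
    synthetic_band,
)

from oracles import blurred_sphere_profile


@pytest.fixture(scope="module")
def fine_spec():
    """Phantom on a 2 mm grid, fine enough that every sphere contains a
    fully-inside voxel."""
    return PhantomSpec(spacing=(2.0, 2.0, 2.0), shape=(72, 120, 160))


def test_unblurred_rc_max_is_one_for_every_sphere(fine_spec):
    img, _ = simulate_phantom(fine_spec, psf_fwhm=0.0, noise_sd_fraction=0.0)
    curve = recovery_curve(img, fine_spec)
    for d in curve.diameters:
        assert curve.rc_max[d] == 1.0


def test_partial_volume_hits_small_spheres_harder():
    spec = PhantomSpec()
    img, _ = simulate_phantom(spec, psf_fwhm=12.0, noise_sd_fraction=0.0)
    curve = recovery_curve(img, spec)
    assert curve.rc_max[10.0] < curve.rc_max[37.0]
    assert curve.rc_mean[10.0] < curve.rc_mean[37.0]


def test_rc_max_matches_closed_form_blurred_sphere():
    # single sphere centered exactly on a voxel center of a 2 mm grid
    spec = PhantomSpec(
        sphere_diameters=(22.0,),
        sphere_centers=((0.0, 0.0, 57.0),),
        spacing=(2.0, 2.0, 2.0),
        shape=(72, 120, 160),
    )
    grid = spec.grid()
    # nearest voxel center to the configured center
    idx = np.rint((np.array((0.0, 0.0, 57.0)) - grid.origin) / grid.spacing)
    center = tuple(grid.voxel_to_world(idx))
    spec = PhantomSpec(
        sphere_diameters=(22.0,), sphere_centers=(center,),
        spacing=(2.0, 2.0, 2.0), shape=(72, 120, 160),
    )
    fwhm = 7.5
    img, _ = simulate_phantom(spec, psf_fwhm=fwhm, noise_sd_fraction=0.0)
    curve = recovery_curve(img, spec)
    expected_center_value = blurred_sphere_profile(
        0.0, 11.0, spec.sphere_concentration, fwhm_to_sigma(fwhm),
        background=spec.background_concentration,
    )
    assert curve.rc_max[22.0] == pytest.approx(
        expected_center_value / spec.sphere_concentration, rel=0.01
    )


def test_rc_max_monotone_in_filter_width():
    spec = PhantomSpec()
    img, _ = simulate_phantom(spec, psf_fwhm=5.0, noise_sd_fraction=0.0)
    previous = None
    for fwhm in (0.0, 2.0, 4.0, 6.0, 8.0):
        curve = recovery_curve(gaussian_postfilter(img, fwhm), spec)
        if previous is not None:
            for d in curve.diameters:
                assert curve.rc_max[d] <= previous.rc_max[d] + 1e-12
        previous = curve


def test_filtered_curve_equals_exact_match_reference():
    spec = PhantomSpec()
    earl2, _ = simulate_phantom(spec, psf_fwhm=5.0, noise_sd_fraction=0.02, seed=9)
    earl1 = gaussian_postfilter(earl2, 7.0)  # exact-match construction
    curve_filtered = recovery_curve(gaussian_postfilter(earl2, 7.0), spec)
    curve_reference = recovery_curve(earl1, spec)
    for d in curve_filtered.diameters:
        assert curve_filtered.rc_max[d] == pytest.approx(curve_reference.rc_max[d], rel=1e-3)
        assert curve_filtered.rc_mean[d] == pytest.approx(curve_reference.rc_mean[d], rel=1e-3)


class TestCompliance:
    def _band(self):
        diam = (10.0, 37.0)
        return SpecificationBand(
            name="demo",
            rc_max_limits={d: (0.4, 0.8) for d in diam},
            rc_mean_limits={d: (0.3, 0.7) for d in diam},
        )

    def _curve(self, rc_max=0.6, rc_mean=0.5):
        return RecoveryCurve(
            rc_max={10.0: rc_max, 37.0: 0.6}, rc_mean={10.0: rc_mean, 37.0: 0.5}
        )

    def test_midpoints_pass(self):
        ok, detail = earl_compliant(self._curve(), self._band())
        assert ok and all(v for per in detail.values() for v in per.values())

    def test_single_violation_fails(self):
        ok, detail = earl_compliant(self._curve(rc_max=0.81), self._band())
        assert not ok
        assert detail[10.0]["rc_max"] is False
        assert detail[37.0]["rc_max"] is True

    def test_limits_are_inclusive(self):
        ok, _ = earl_compliant(self._curve(rc_max=0.8, rc_mean=0.3), self._band())
        assert ok

    def test_sphere_set_mismatch_rejected(self):
        curve = RecoveryCurve(rc_max={13.0: 0.5}, rc_mean={13.0: 0.5})
        with pytest.raises(ValueError, match="sphere sets"):
            earl_compliant(curve, self._band())

    def test_widening_the_band_never_flips_to_fail(self):
        rng = np.random.default_rng(0)
        band = self._band()
        for _ in range(25):
            curve = self._curve(
                rc_max=float(rng.uniform(0.2, 1.0)), rc_mean=float(rng.uniform(0.2, 1.0))
            )
            ok, _ = earl_compliant(curve, band)
            wider = SpecificationBand(
                name="w",
                rc_max_limits={d: (lo - 0.1, hi + 0.1) for d, (lo, hi) in band.rc_max_limits.items()},
                rc_mean_limits={d: (lo - 0.1, hi + 0.1) for d, (lo, hi) in band.rc_mean_limits.items()},
            )
            ok_wide, _ = earl_compliant(curve, wider)
            assert ok_wide or not ok


@pytest.fixture(scope="module")
def earl2_image():
    spec = PhantomSpec()
    img, _ = simulate_phantom(spec, psf_fwhm=5.0, noise_sd_fraction=0.0)
    return spec, img


class TestSelectFilter:

    def test_only_bridging_filter_lands_in_tight_band(self, earl2_image):
        spec, img = earl2_image
        band = synthetic_band(spec, math.hypot(5.0, 7.0), rel_width=0.02)
        result = select_filter([img], spec, band, candidates=(5.0, 6.0, 7.0, 8.0))
        assert result.histogram == {5.0: 0, 6.0: 0, 7.0: 1, 8.0: 0}
        assert result.selected == (7.0,)

    def test_degenerate_wide_band_selects_everything(self, earl2_image):
        spec, img = earl2_image
        band = synthetic_band(spec, math.hypot(5.0, 7.0), rel_width=0.9)
        result = select_filter([img], spec, band, candidates=(6.0, 7.0))
        assert result.histogram == {6.0: 1, 7.0: 1}
        assert result.selected == (6.0, 7.0)  # ties -> argmax set

    def test_empty_inputs_rejected(self, earl2_image):
        spec, img = earl2_image
        band = synthetic_band(spec, 8.6, rel_width=0.1)
        with pytest.raises(ValueError):
            select_filter([], spec, band)
        with pytest.raises(ValueError):
            select_filter([img], spec, band, candidates=())


class TestBandJson:
    def test_round_trip(self, tmp_path):
        band = synthetic_band(PhantomSpec(), 8.6, rel_width=0.1)
        path = band.to_json(tmp_path / "band.json")
        back = SpecificationBand.from_json(path)
        assert back.rc_max_limits == pytest.approx(band.rc_max_limits)
        assert back.name == band.name

    def test_missing_sphere_entry_named_in_error(self, tmp_path):
        band = SpecificationBand(
            name="partial",
            rc_max_limits={10.0: (0.3, 0.6)},
            rc_mean_limits={10.0: (0.3, 0.6)},
        )
        path = band.to_json(tmp_path / "band.json")
        with pytest.raises(ValueError, match=r"37"):
            SpecificationBand.from_json(path, required_diameters=(10.0, 37.0))
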