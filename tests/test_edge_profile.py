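"""Signed distance, step-up curves and the erf-model FWHM resolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from porequal import (
    EdgeProfile,
    GrayVolume,
    LEVEL_CONSTANT,
    fit_erf,
    resolution_fwhm,
    signed_distance,
    step_curve,
)
from porequal.edge_profile import (
    GAUSS_FWHM_FACTOR,
    LevelCrossingError,
    NoContrastError,
    _erf_model,
)

from oracles import brute_force_signed_distance, quad_blurred_ball, quad_erf, rasterize_ball


# ------------------------------------------------------------ signed distance

def test_ball_center_distance_equals_radius():
    sd = signed_distance(rasterize_ball(10, 29))
    center = (14, 14, 14)
    assert sd[center] == pytest.approx(10.0, abs=0.5)


def test_outside_distance_along_axis():
    sd = signed_distance(rasterize_ball(6, 33))
    c = 16
    assert sd[c, c, c + 11] == pytest.approx(-5.0, abs=0.5)


def test_signed_distance_matches_brute_force_exactly():
    mask = rasterize_ball(6.5, 20, center=(9.2, 10.1, 9.7))
    assert np.array_equal(signed_distance(mask), brute_force_signed_distance(mask))


@settings(derandomize=True, max_examples=15, deadline=None)
@given(st.integers(0, 10_000))
def test_signed_distance_matches_brute_force_on_random_blobs(seed):
    rng = np.random.default_rng(seed)
    mask = np.zeros((12, 12, 12), bool)
    mask[4:8, 4:8, 4:8] = True
    flips = rng.integers(1, 11, size=(rng.integers(1, 8), 3))
    for z, y, x in flips:
        mask[z, y, x] = ~mask[z, y, x]
    if not mask.any() or mask.all():
        return
    assert np.array_equal(signed_distance(mask), brute_force_signed_distance(mask))


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        signed_distance(np.zeros((6, 6, 6), bool))


# ------------------------------------------------------------ step curve

def test_constant_volume_gives_flat_profile():
    mask = rasterize_ball(8, 30)
    vol = GrayVolume(np.full((30, 30, 30), 7.0), 50.0)
    prof = step_curve(vol, mask, max_range=5)
    assert np.allclose(prof.mean_gray, 7.0)


def test_shell_distances_are_unit_spaced_integers():
    mask = rasterize_ball(8, 34)
    vol = GrayVolume(np.zeros((34, 34, 34)), 50.0)
    prof = step_curve(vol, mask, max_range=6, max_range_in=5)
    assert np.array_equal(prof.distances, np.arange(-6, 6))
    assert (prof.shell_voxel_count > 0).all()


def test_phantom_profile_matches_blurred_sphere_oracle(small_phantom):
    """Shell means across a blurred pore agree with a brute-force geometric
    binning of the quadrature ball-Gaussian profile to 1% of step height."""
    spec, vol, gt = small_phantom
    k = int(np.argmax(gt.radii))
    r = gt.radii[k]
    c = gt.centers[k]
    mask = gt.true_label_volume.values == k + 1
    prof = step_curve(vol, mask, context_mask=gt.true_label_volume.values == 0,
                      max_range=8, max_range_in=6)

    # oracle: same shells selected by explicit distances from the known
    # center, gray values recomputed by quadrature at each voxel's radius
    zz, yy, xx = np.mgrid[0:vol.shape[0], 0:vol.shape[1], 0:vol.shape[2]]
    rho = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    sd = signed_distance(mask)
    grid = np.linspace(0, rho.max() + 1, 800)
    lut = np.array([quad_blurred_ball(d, r, spec.blur_sigma) for d in grid])
    contrast = spec.gray_pore - spec.gray_scaffold
    for d_shell, measured in zip(prof.distances, prof.mean_gray):
        sel = (sd >= d_shell - 0.5) & (sd < d_shell + 0.5)
        if d_shell > 0:
            sel &= mask
        expected = spec.gray_scaffold + contrast * np.interp(
            rho[sel], grid, lut
        ).mean()
        assert measured == pytest.approx(expected, abs=0.01 * contrast)


def test_empty_shell_truncates_range_with_warning():
    mask = rasterize_ball(4, 20)
    vol = GrayVolume(np.zeros((20, 20, 20)), 50.0)
    with pytest.warns(UserWarning, match="truncated"):
        prof = step_curve(vol, mask, max_range=6, max_range_in=6)
    assert prof.distances[-1] < 6


# ------------------------------------------------------------ erf fit

def _exact_profile(A1, A2, x0, sigma, lo=-10, hi=10, voxel_size=50.0):
    d = np.arange(lo, hi + 1, dtype=float)
    return EdgeProfile(d, _erf_model(d, A1, A2, x0, sigma),
                       np.ones_like(d, dtype=int), voxel_size)


def test_fit_recovers_its_own_model_to_1e6():
    prof = _exact_profile(100.0, 200.0, 0.3, 2.0)
    fit = fit_erf(prof)
    assert fit.A1 == pytest.approx(100.0, abs=1e-6)
    assert fit.A2 == pytest.approx(200.0, abs=1e-6)
    assert fit.x0 == pytest.approx(0.3, abs=1e-6)
    assert fit.sigma_fit == pytest.approx(2.0, abs=1e-6)
    assert fit.rmse < 1e-9


def test_flat_profile_raises_no_contrast():
    prof = _exact_profile(100.0, 100.0 + 1e-12, 0.0, 2.0)
    with pytest.raises(NoContrastError):
        fit_erf(prof)


def test_fit_on_blurred_sphere_profile_recovers_sigma_within_5pct():
    """Curvature of a sphere of radius 12 biases the planar-erf width by
    less than 5% at r/sigma = 6."""
    r, sigma = 12.0, 2.0
    d = np.arange(-10, 11, dtype=float)
    vals = 100.0 + 100.0 * np.array(
        [quad_blurred_ball(r - di, r, sigma) for di in d]
    )
    prof = EdgeProfile(d, vals, np.ones_like(d, dtype=int), 50.0)
    fit = fit_erf(prof)
    assert fit.sigma_fit == pytest.approx(sigma, rel=0.05)


# ------------------------------------------------------------ FWHM

def test_level_constant_matches_independent_erf_quadrature():
    c_oracle = (1.0 - quad_erf(np.sqrt(np.log(2.0)))) / 2.0
    assert LEVEL_CONSTANT == pytest.approx(c_oracle, abs=1e-9)
    assert LEVEL_CONSTANT == pytest.approx(0.1196, abs=1e-4)


def test_exact_erf_profile_fwhm_identity():
    """On an exact erf step the level-crossing FWHM equals the Gaussian
    FWHM 2*sqrt(2 ln 2)*sigma, located independently as the half-maximum
    width of the fitted profile's derivative."""
    sigma, vox = 2.0, 50.0
    prof = _exact_profile(100.0, 200.0, 0.0, sigma, voxel_size=vox)
    fit = fit_erf(prof)
    fwhm = resolution_fwhm(prof, fit, vox)
    expected = GAUSS_FWHM_FACTOR * sigma * vox  # ~235.5 nm
    assert fwhm == pytest.approx(expected, rel=0.01)
    assert fit.fwhm_model_nm == pytest.approx(expected, rel=1e-6)
    # independent check: numerically locate the half-maximum points of the
    # derivative of the fitted model
    x = np.linspace(-10, 10, 20001)
    deriv = np.gradient(_erf_model(x, fit.A1, fit.A2, fit.x0, fit.sigma_fit), x)
    half = deriv >= 0.5 * deriv.max()
    width_nm = (x[half][-1] - x[half][0]) * vox
    assert fwhm == pytest.approx(width_nm, rel=0.01)


def test_crossing_and_model_fwhm_agree_on_exact_profiles():
    for sigma in (1.5, 2.0, 3.0):
        prof = _exact_profile(0.0, 1.0, 0.25, sigma)
        fit = fit_erf(prof)
        fwhm = resolution_fwhm(prof, fit, 50.0)
        assert fwhm == pytest.approx(fit.fwhm_model_nm, rel=0.05)


def test_perfect_step_fwhm_bounded_by_one_voxel():
    d = np.arange(-8, 9, dtype=float)
    vals = np.where(d >= 0.5, 200.0, 100.0)
    prof = EdgeProfile(d, vals, np.ones_like(d, dtype=int), 50.0)
    fit = fit_erf(prof)
    fwhm = resolution_fwhm(prof, fit, 50.0)
    assert fwhm <= 1.0 * 50.0


def test_missing_level_crossing_flagged():
    # truncated profile that never reaches the upper plateau crossing
    d = np.arange(-8, 1, dtype=float)
    vals = _erf_model(d, 100.0, 200.0, 2.5, 1.0)
    prof = EdgeProfile(d, vals, np.ones_like(d, dtype=int), 50.0)
    from porequal.edge_profile import ErfFit

    fit = ErfFit(A1=100.0, A2=200.0, x0=2.5, sigma_fit=1.0, rmse=0.0)
    with pytest.raises(LevelCrossingError):
        resolution_fwhm(prof, fit, 50.0)
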