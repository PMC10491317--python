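"""Tests of the flow-analysis chain: optical flow, speeds, correlation and
vortex length scales.

Note on tolerances: for a Gaussian-core vortex the vorticity-velocity
cross-correlation peaks in the continuum at 1.1205 times the radius of peak
tangential speed (the extended vorticity core smears the response), so
radius-recovery checks use a 15% tolerance — the estimator's intrinsic
accuracy, not a numerical artifact.
"""

import numpy as np
import pytest

from actonem.flow import (
    VelocityField,
    ell_vort,
    mean_and_rms_speed,
    optical_flow,
    optical_flow_movie,
    summarize_flow,
    velocity_autocorr_length,
    vorticity,
)
from actonem.synthetic import (
    make_correlated_field,
    make_nematic_movie,
    make_vortex_field,
    make_vortex_movie,
)


def test_velocity_field_validation():
    with pytest.raises(ValueError):
        VelocityField(np.zeros((4, 4)), np.zeros((4, 5)))
    with pytest.raises(ValueError):
        VelocityField(np.zeros((4, 4)), np.zeros((4, 4)), pixel_size=0.0)
    with pytest.raises(ValueError):
        VelocityField(np.full((4, 4), np.nan), np.zeros((4, 4)))


def test_mean_and_rms_speed_exact():
    ux = np.full((8, 8), 3.0)
    uy = np.full((8, 8), 4.0)
    mean_s, rms_s = mean_and_rms_speed(VelocityField(ux, uy))
    assert mean_s == pytest.approx(5.0)
    assert rms_s == pytest.approx(5.0)


def test_vorticity_solid_body_rotation():
    """u = omega0 x r has uniform vorticity 2*omega0."""
    n, w0 = 32, 0.1
    yy, xx = np.mgrid[0:n, 0:n].astype(float) - n / 2
    f = VelocityField(-w0 * yy, w0 * xx)
    om = vorticity(f).omega
    np.testing.assert_allclose(om[2:-2, 2:-2], 2 * w0, rtol=1e-10)


def test_vorticity_gaussian_vortex_center_sign():
    f = make_vortex_field(shape=(64, 64), n_vortices=1, core_radius=8.0, seed=1,
                          min_separation=1.0)
    om = vorticity(f).omega
    peak = np.unravel_index(np.argmax(np.abs(om)), om.shape)
    # vorticity magnitude peaks at the core center, where speed vanishes
    assert f.speed[peak] < 0.2 * f.speed.max()
    # sign at center matches the circulation sense measured from the flow
    cy, cx = peak
    sense = np.sign(f.ux[cy - 2, cx] - f.ux[cy + 2, cx])  # d(ux)/d(-y)
    assert np.sign(om[peak]) == sense


def test_vorticity_pixel_size_scaling():
    f = make_vortex_field(shape=(64, 64), n_vortices=2, seed=0)
    f2 = VelocityField(f.ux, f.uy, pixel_size=2.0)
    np.testing.assert_allclose(vorticity(f2).omega, vorticity(f).omega / 2.0)


# ---------------------------------------------------------------------------
# Velocity autocorrelation
# ---------------------------------------------------------------------------


def test_autocorr_length_recovers_exponential_L():
    """Generator has Cuu(r) = exp(-r/L) exactly; 1/e crossing must be L."""
    for L in (6.0, 10.0):
        ratios = []
        for seed in range(3):
            f = make_correlated_field(shape=(256, 256), correlation_length=L, seed=seed)
            _, ell, lower = velocity_autocorr_length(f)
            assert not lower
            ratios.append(ell / L)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_autocorr_profile_starts_at_one():
    f = make_correlated_field(shape=(128, 128), correlation_length=8.0, seed=0)
    prof, _, _ = velocity_autocorr_length(f)
    assert prof.value[0] == pytest.approx(1.0, abs=1e-9)


def test_autocorr_lower_bound_flag():
    """A nearly uniform flow never decorrelates within the frame."""
    rng = np.random.default_rng(0)
    ux = 1.0 + 1e-3 * rng.standard_normal((64, 64))
    uy = np.zeros((64, 64))
    _, ell, lower = velocity_autocorr_length(VelocityField(ux, uy))
    assert lower


def test_autocorr_rejects_zero_field():
    with pytest.raises(ValueError):
        velocity_autocorr_length(VelocityField(np.zeros((16, 16)), np.zeros((16, 16))))


# ---------------------------------------------------------------------------
# Vortex length scale
# ---------------------------------------------------------------------------


def test_ell_vort_multi_vortex_recovery():
    movie = make_vortex_movie(n_frames=10, shape=(256, 256), n_vortices=12,
                              core_radius=8.0, seed=3)
    _, ell, sd = ell_vort(movie)
    assert ell == pytest.approx(8.0, rel=0.15)
    assert np.isfinite(sd) and sd < 2.0


def test_ell_vort_single_vortex_within_bias_band():
    """Single isolated vortex: peak at the known 1.12a kernel bias."""
    f = make_vortex_field(shape=(256, 256), n_vortices=1, core_radius=8.0,
                          seed=0, min_separation=1.0)
    _, ell, _ = ell_vort(f)
    assert ell == pytest.approx(8.0, rel=0.15)


def test_ell_vort_noise_robustness():
    """20 vortices with 10% additive velocity noise still recover radius."""
    rng = np.random.default_rng(7)
    movie = []
    for s in range(6):
        f = make_vortex_field(shape=(256, 256), n_vortices=20, core_radius=8.0,
                              peak_speed=1.0, seed=100 + s, min_separation=20.0)
        f.ux = f.ux + 0.1 * rng.standard_normal(f.ux.shape)
        f.uy = f.uy + 0.1 * rng.standard_normal(f.uy.shape)
        movie.append(f)
    _, ell, _ = ell_vort(movie)
    assert ell == pytest.approx(8.0, rel=0.15)


def test_ell_vort_mirror_invariance():
    f = make_vortex_field(shape=(128, 128), n_vortices=6, core_radius=8.0, seed=3)
    _, e1, _ = ell_vort(f)
    _, e2, _ = ell_vort(VelocityField(-f.ux, -f.uy, f.pixel_size, f.dt))
    assert e2 == pytest.approx(e1, abs=1e-9)


def test_ell_vort_rotation_invariance():
    f = make_vortex_field(shape=(128, 128), n_vortices=6, core_radius=8.0, seed=3)
    _, e1, _ = ell_vort(f)
    rot = VelocityField(np.rot90(f.uy).copy(), -np.rot90(f.ux).copy())
    _, e3, _ = ell_vort(rot)
    assert e3 == pytest.approx(e1, rel=1e-6)


def test_ell_vort_speed_rescaling_invariance():
    f = make_vortex_field(shape=(128, 128), n_vortices=6, core_radius=8.0, seed=3)
    _, e1, _ = ell_vort(f)
    _, e2, _ = ell_vort(VelocityField(5.0 * f.ux, 5.0 * f.uy))
    assert e2 == pytest.approx(e1, abs=1e-9)


def test_ell_vort_pixel_size_scaling():
    f = make_vortex_field(shape=(128, 128), n_vortices=6, core_radius=8.0, seed=3)
    _, e1, _ = ell_vort(f)
    _, e2, _ = ell_vort(VelocityField(f.ux, f.uy, pixel_size=2.0))
    assert e2 == pytest.approx(2.0 * e1, rel=1e-9)


def test_ell_vort_tracks_radius_over_4x_range():
    ells = []
    for a in (4.0, 8.0, 16.0):
        movie = make_vortex_movie(n_frames=5, shape=(256, 256), n_vortices=8,
                                  core_radius=a, seed=5)
        ells.append(ell_vort(movie)[1])
    assert ells[0] < ells[1] < ells[2]


def test_ell_vort_rejects_zero_vorticity():
    with pytest.raises(ValueError):
        ell_vort(VelocityField(np.ones((32, 32)), np.zeros((32, 32))))


def test_ell_vort_subset_sd_nan_for_few_frames():
    f = make_vortex_field(shape=(64, 64), n_vortices=3, seed=0)
    _, _, sd = ell_vort([f, f])
    assert np.isnan(sd)


# ---------------------------------------------------------------------------
# Optical flow
# ---------------------------------------------------------------------------


def test_optical_flow_uniform_translation():
    rng = np.random.default_rng(0)
    from scipy import ndimage
    img = ndimage.gaussian_filter(rng.random((96, 96)), 3.0)
    shifted = np.roll(img, (0, 2), axis=(0, 1))
    f = optical_flow(img, shifted, pixel_size=1.0, dt=1.0)
    inner = np.s_[10:-10, 10:-10]
    assert np.median(f.ux[inner]) == pytest.approx(2.0, abs=0.3)
    assert np.median(np.abs(f.uy[inner])) < 0.3


def test_optical_flow_zero_variance_frames():
    with pytest.warns(UserWarning):
        f = optical_flow(np.ones((32, 32)), np.ones((32, 32)))
    assert np.all(f.ux == 0.0)


def test_optical_flow_shape_mismatch():
    with pytest.raises(ValueError):
        optical_flow(np.zeros((32, 32)), np.zeros((32, 16)))


def test_optical_flow_recovers_nematic_advection():
    frames, gt = make_nematic_movie(n_frames=4, shape=(128, 128), seed=1)
    est = optical_flow_movie(frames, pixel_size=gt.pixel_size, dt=gt.dt)[1]
    fast = gt.speed > 0.3
    rel_err = np.hypot(est.ux - gt.ux, est.uy - gt.uy)[fast] / gt.speed[fast]
    assert np.median(rel_err) < 0.2


def test_optical_flow_agrees_with_ilk():
    """Independent cross-check against scikit-image's ILK estimator."""
    from skimage.registration import optical_flow_ilk

    frames, gt = make_nematic_movie(n_frames=2, shape=(128, 128), seed=4)
    ours = optical_flow(frames[0], frames[1], pixel_size=1.0, dt=1.0)
    v, u = optical_flow_ilk(frames[0], frames[1])
    fast = gt.speed > 0.5
    # with pixel_size=1 and dt=1 both estimators report px/frame
    ours_mean = np.hypot(ours.ux, ours.uy)[fast].mean()
    ilk_mean = np.hypot(u, v)[fast].mean()
    assert ours_mean == pytest.approx(ilk_mean, rel=0.35)


def test_summarize_flow_end_to_end():
    movie = make_vortex_movie(n_frames=6, shape=(128, 128), n_vortices=6,
                              core_radius=8.0, seed=3)
    s = summarize_flow(movie, n_subsets=3)
    assert s.mean_speed > 0 and s.rms_speed >= s.mean_speed
    assert s.ell_vort == pytest.approx(8.0, rel=0.2)
    assert np.isfinite(s.ell_corr)
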