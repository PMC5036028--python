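"""Preprocessing stages against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pearloct import (
    BScanImage,
    PhantomSpec,
    SurfaceCurve,
    background_stats,
    crop_roi,
    detect_surface,
    downscale_half,
    fit_surface,
    flatten,
    generate_phantom,
    median_smooth,
    power_law,
    threshold_denoise,
)
from conftest import sliding_median


def _img(arr, **kw):
    return BScanImage(pixels=np.asarray(arr, dtype=np.float64), **kw)


# ------------------------------------------------------- background / denoise


def test_background_stats_hand_values():
    img = _img(np.vstack([np.array([[0, 0], [10, 10]]), np.full((4, 2), 99)]))
    stats = background_stats(img, n_rows=2)
    assert stats.mu == 5.0
    assert stats.sigma == pytest.approx(5.0)  # population SD of {0,0,10,10}

    flat = _img(np.full((20, 8), 5.0))
    s2 = background_stats(flat, n_rows=10)
    assert (s2.mu, s2.sigma) == (5.0, 0.0)
    assert s2.threshold == 5.0


def test_background_stats_covers_exactly_n_rows():
    rng = np.random.default_rng(0)
    arr = rng.integers(0, 255, (64, 32)).astype(float)
    stats = background_stats(_img(arr), n_rows=10)
    assert stats.mu == pytest.approx(arr[:10].mean())
    assert stats.sigma == pytest.approx(arr[:10].std())
    with pytest.raises(ValueError):
        background_stats(_img(arr), n_rows=64)


def test_threshold_denoise_mu_plus_7_sigma():
    # mu=10, sigma=2, k=7 -> threshold 24: 23 zeroed, 24 kept
    from pearloct.preprocess import BackgroundStats

    stats = BackgroundStats(mu=10.0, sigma=2.0, k=7.0)
    img = _img([[23, 24, 25], [0, 100, 23.9]])
    out = threshold_denoise(img, stats)
    np.testing.assert_array_equal(out.pixels, [[0, 24, 25], [0, 100, 0]])


def test_threshold_denoise_zero_image_unchanged():
    from pearloct.preprocess import BackgroundStats

    img = _img(np.zeros((6, 6)))
    out = threshold_denoise(img, BackgroundStats(mu=0.0, sigma=0.0))
    assert (out.pixels == 0).all()


def test_threshold_denoise_idempotent_for_fixed_stats():
    from pearloct.preprocess import BackgroundStats

    rng = np.random.default_rng(1)
    img = _img(rng.integers(0, 255, (30, 30)).astype(float))
    stats = BackgroundStats(mu=20.0, sigma=5.0)
    once = threshold_denoise(img, stats)
    twice = threshold_denoise(once, stats)
    np.testing.assert_array_equal(once.pixels, twice.pixels)


# ------------------------------------------------------------------ surface


def _band_image(height=256, width=128, top=100, value=200.0):
    arr = np.zeros((height, width))
    arr[top : top + 30, :] = value
    return _img(arr)


def test_detect_surface_on_horizontal_band():
    curve = detect_surface(_band_image(top=200, height=300))
    assert not curve.fitted
    assert np.all((curve.rows >= 198) & (curve.rows <= 202))


def test_detect_surface_interpolates_missing_columns():
    img = _band_image(top=100)
    img.pixels[:, 60:65] = 0.0  # kill the band in 5 interior columns
    curve = detect_surface(img)
    flank = curve.rows[59], curve.rows[65]
    assert curve.rows[60:65].min() >= min(flank) - 1
    assert curve.rows[60:65].max() <= max(flank) + 1


def test_detect_surface_tracks_noiseless_parabola(noiseless_defect_phantom):
    from pearloct.preprocess import BackgroundStats

    img, gt = noiseless_defect_phantom
    curve = detect_surface(threshold_denoise(img, background_stats(img)))
    assert np.abs(curve.rows - gt.surface).max() <= 2.0


def test_detect_surface_rejects_blank_image():
    with pytest.raises(ValueError):
        detect_surface(_img(np.zeros((32, 32))))


def test_fit_surface_exact_parabola():
    c = np.arange(1024, dtype=float)
    rows = 300.0 + 0.001 * (c - 512.0) ** 2
    fitted = fit_surface(SurfaceCurve(rows=rows), degree=2)
    assert fitted.fitted and fitted.poly_degree == 2
    assert np.abs(fitted.rows - rows).max() <= 1e-6


def test_fit_surface_constant_curve_stays_constant():
    fitted = fit_surface(SurfaceCurve(rows=np.full(100, 42.0)), degree=3)
    assert np.abs(fitted.rows - 42.0).max() < 1e-8


def test_fit_surface_recovers_apex_under_jitter():
    rng = np.random.default_rng(0)
    c = np.arange(1024, dtype=float)
    true_apex = 512.0
    rows = 200.0 + 2e-4 * (c - true_apex) ** 2 + rng.uniform(-1, 1, c.size)
    fitted = fit_surface(SurfaceCurve(rows=rows), degree=2)
    apex = c[np.argmin(fitted.rows)]
    assert abs(apex - true_apex) <= 1.0
    assert abs(fitted.rows.min() - 200.0) <= 1.0


def test_fit_surface_rejects_already_fitted():
    fitted = fit_surface(SurfaceCurve(rows=np.full(10, 5.0)), degree=1)
    with pytest.raises(ValueError):
        fit_surface(fitted)


# ------------------------------------------------------------------ flatten


def test_flatten_identity_for_already_flat_surface():
    img = _band_image(top=100)
    curve = SurfaceCurve(rows=np.full(img.width, 100.0), fitted=True, poly_degree=2)
    out, flat_row = flatten(img, curve)
    assert flat_row == 100
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_flatten_preserves_column_multisets():
    rng = np.random.default_rng(3)
    arr = np.zeros((120, 40))
    arr[30:, :] = rng.integers(1, 255, (90, 40))
    c = np.arange(40, dtype=float)
    curve = fit_surface(SurfaceCurve(rows=28.0 + 0.01 * (c - 20) ** 2))
    out, flat_row = flatten(_img(arr), curve)
    for col in range(40):
        before = np.sort(arr[:, col][arr[:, col] > 0])
        after = np.sort(out.pixels[:, col][out.pixels[:, col] > 0])
        np.testing.assert_array_equal(before, after)


def test_flatten_lands_surface_on_flat_row(noiseless_defect_phantom):
    img, _ = noiseless_defect_phantom
    denoised = threshold_denoise(img, background_stats(img))
    fitted = fit_surface(detect_surface(denoised))
    out, flat_row = flatten(denoised, fitted)
    redetected = detect_surface(out)
    assert np.abs(redetected.rows - flat_row).max() <= 2.0


def test_flatten_rejects_out_of_frame_shift():
    img = _band_image(height=64)
    curve = SurfaceCurve(rows=np.linspace(0, 100, img.width), fitted=True)
    with pytest.raises(ValueError):
        flatten(img, curve)


# ------------------------------------------------------------------- median


def test_median_constant_and_impulse():
    const = _img(np.full((20, 50), 7.0))
    np.testing.assert_array_equal(median_smooth(const, (10, 40)).pixels, const.pixels)
    impulse = np.full((20, 50), 7.0)
    impulse[10, 25] = 255.0
    out = median_smooth(_img(impulse), (5, 5))
    np.testing.assert_array_equal(out.pixels, np.full((20, 50), 7.0))


@pytest.mark.parametrize("window", [(3, 3), (10, 40), (4, 6), (1, 5)])
@pytest.mark.parametrize("integral", [True, False])
def test_median_matches_sliding_window_oracle(window, integral):
    """Both the uint8 fast path and the float path equal the direct
    sliding-window median on images up to 40x80."""
    rng = np.random.default_rng(hash(window) % 2**31)
    arr = rng.integers(0, 256, (40, 80)).astype(float)
    if not integral:
        arr += 0.25  # force the generic float path
    out = median_smooth(_img(arr) if integral else BScanImage(arr, bit_depth=16), window)
    expected = sliding_median(arr, window)
    np.testing.assert_array_equal(out.pixels, expected)


def test_median_step_edge_preserved():
    arr = np.zeros((30, 60))
    arr[15:, :] = 200.0
    out = median_smooth(_img(arr), (10, 40))
    expected = sliding_median(arr, (10, 40))
    np.testing.assert_array_equal(out.pixels, expected)
    # edge stays within half the window height of its true position
    transition = (np.abs(np.diff(out.pixels, axis=0)) > 0).any(axis=1)
    assert np.flatnonzero(transition).min() >= 15 - 5
    assert np.flatnonzero(transition).max() <= 15 + 5


def test_median_rejects_oversized_window():
    with pytest.raises(ValueError):
        median_smooth(_img(np.zeros((8, 8))), (10, 40))


# -------------------------------------------------------------- crop / scale


def test_crop_roi_coordinates():
    arr = np.arange(1024 * 1024, dtype=float).reshape(1024, 1024) % 255
    img = _img(arr)
    out = crop_roi(img, flat_row=100)
    assert out.pixels.shape == (600, 300)
    np.testing.assert_array_equal(out.pixels, arr[100:700, 362:662])
    assert out.pixels[0, 0] == arr[100, 512 - 150]


def test_crop_roi_pads_past_bottom():
    img = _img(np.full((512, 512), 9.0))
    with pytest.warns(UserWarning, match="zero-padded"):
        out = crop_roi(img, flat_row=100)
    assert out.pixels.shape == (600, 300)
    assert (out.pixels[:412] == 9.0).all()
    assert (out.pixels[412:] == 0.0).all()


def test_downscale_half_index_map():
    rng = np.random.default_rng(5)
    arr = rng.integers(0, 255, (600, 300)).astype(float)
    out = downscale_half(_img(arr))
    assert out.pixels.shape == (300, 150)
    # nearest-neighbour rule: out[i, j] == in[2i, 2j]
    np.testing.assert_array_equal(out.pixels, arr[::2, ::2])
    const = downscale_half(_img(np.full((64, 64), 3.0)))
    assert (const.pixels == 3.0).all()


def test_downscale_checkerboard_keeps_block_corners():
    block = np.array([[1.0, 2.0], [3.0, 4.0]])
    arr = np.tile(block, (8, 8))
    out = downscale_half(_img(arr, bit_depth=8))
    assert (out.pixels == 1.0).all()


# ---------------------------------------------------------------- power law


def test_power_law_reference_points():
    img = _img(np.array([[0.0, 0.25 * 255, 255.0]]))
    out = power_law(img, C=1.2, gamma=1.5)
    r = out.pixels / 255.0
    assert r[0, 0] == 0.0
    assert r[0, 1] == pytest.approx(1.2 * 0.25**1.5)  # 0.15
    assert r[0, 2] == 1.0  # 1.2 clipped to full scale


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=2, max_size=30, unique=True),
    st.floats(min_value=0.1, max_value=3.0),
    st.floats(min_value=0.2, max_value=3.0),
)
def test_power_law_strictly_increasing(levels, C, gamma):
    arr = np.sort(np.asarray(levels)) * 255.0
    out = power_law(BScanImage(arr[None, :]), C=C, gamma=gamma)
    unclipped = out.pixels[0] < 255.0
    vals = out.pixels[0]
    assert np.all(np.diff(vals) >= 0)
    assert np.all(np.diff(vals[unclipped]) > 0)


def test_power_law_rejects_bad_gamma():
    with pytest.raises(ValueError):
        power_law(_img(np.zeros((4, 4))), gamma=0.0)
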