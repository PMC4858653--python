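"""The per-pixel masked Gaussian filter: stencils, flood-fill restriction,
full-image filtering."""

import warnings
from collections import deque

import numpy as np
import pytest

from adaptscan import (
    AcquisitionModel,
    BinaryMask,
    DegenerateSupportError,
    filter_image,
    gaussian_stencil,
    gradient_magnitude,
    make_phantom,
    restrict_stencil,
    simulate_scan,
    threshold_top_fraction,
)
from adaptscan.adaptive_filter import _filter_image_direct


def _bfs_reachable(hia, start):
    """Independent 4-connected reachability oracle."""
    reached = np.zeros_like(hia, dtype=bool)
    if hia[start]:
        return reached
    queue = deque([start])
    reached[start] = True
    while queue:
        y, x = queue.popleft()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if (
                0 <= ny < hia.shape[0]
                and 0 <= nx < hia.shape[1]
                and not hia[ny, nx]
                and not reached[ny, nx]
            ):
                reached[ny, nx] = True
                queue.append((ny, nx))
    return reached


def _oracle_filter(initial, hia, sigma):
    """Brute-force per-pixel filter written independently for the tests."""
    c = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-c : c + 1, -c : c + 1]
    w_full = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    w_full[yy**2 + xx**2 > (3 * sigma) ** 2] = 0.0
    h, w = initial.shape
    out = initial.copy()
    for y in range(h):
        for x in range(w):
            if hia[y, x]:
                continue
            y0, y1 = max(0, y - c), min(h, y + c + 1)
            x0, x1 = max(0, x - c), min(w, x + c + 1)
            sub_w = w_full[y0 - y + c : y1 - y + c, x0 - x + c : x1 - x + c]
            reached = _bfs_reachable(hia[y0:y1, x0:x1], (y - y0, x - x0))
            weights = np.where(reached, sub_w, 0.0)
            if reached.sum() <= 1 or weights.sum() < 1e-12:
                continue
            out[y, x] = (weights * initial[y0:y1, x0:x1]).sum() / weights.sum()
    return out


class TestGaussianStencil:
    @pytest.mark.parametrize("sigma", [0.7, 1.0, 2.5, 10.0])
    def test_normalized_and_symmetric(self, sigma):
        st = gaussian_stencil(sigma)
        assert st.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(st.weights, st.weights[::-1, :])
        assert np.array_equal(st.weights, st.weights[:, ::-1])
        assert np.array_equal(st.weights, st.weights.T)

    def test_cutoff_beyond_three_sigma(self):
        st = gaussian_stencil(1.0)
        assert st.weights.shape == (7, 7)
        assert st.weights[0, 0] == 0.0  # corner at radius sqrt(18) > 3

    def test_center_weight_matches_direct_evaluation(self):
        st = gaussian_stencil(1.0)
        yy, xx = np.mgrid[-3:4, -3:4]
        r2 = yy**2 + xx**2
        w = np.exp(-r2 / 2.0)
        w[r2 > 9] = 0.0
        assert st.weights[3, 3] == pytest.approx(1.0 / w.sum(), rel=1e-12)

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_stencil(0.0)


class TestRestrictStencil:
    def test_no_hia_is_identity(self):
        st = gaussian_stencil(1.5)
        out = restrict_stencil(st, np.zeros_like(st.weights, dtype=bool))
        assert np.allclose(out.weights, st.weights, atol=1e-15)

    def test_vertical_strip_blocks_far_side(self):
        """A full-height HIA strip cuts off the far filter-region patch even
        though its pixels are not HIA themselves."""
        st = gaussian_stencil(4 / 3)  # 9x9 stencil, c = 4
        hia = np.zeros((9, 9), bool)
        hia[:, 6] = True  # strip at offset +2 from the center column
        out = restrict_stencil(st, hia)
        assert not out.weights[:, 7:].any()
        assert not out.weights[:, 6].any()
        assert out.weights[:, :6].any()
        # matches the independent BFS reachability oracle
        reached = _bfs_reachable(hia, (4, 4))
        expected = np.where(reached, st.weights, 0.0)
        expected /= expected.sum()
        assert np.allclose(out.weights, expected, atol=1e-15)

    def test_restricted_weights_sum_to_one(self, rng):
        st = gaussian_stencil(2.0)
        hia = rng.random(st.weights.shape) < 0.3
        hia[st.center] = False
        out = restrict_stencil(st, hia)
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert not out.weights[hia].any()

    def test_center_in_hia_rejected(self):
        st = gaussian_stencil(1.0)
        hia = np.zeros_like(st.weights, dtype=bool)
        hia[st.center] = True
        with pytest.raises(ValueError):
            restrict_stencil(st, hia)

    def test_enclosed_center_is_degenerate(self):
        st = gaussian_stencil(1.0)
        hia = np.ones_like(st.weights, dtype=bool)
        hia[st.center] = False
        with pytest.raises(DegenerateSupportError):
            restrict_stencil(st, hia)


class TestFilterImage:
    @pytest.mark.filterwarnings("ignore:.*no connected support")
    def test_constant_image_unchanged(self, rng):
        img = np.full((32, 32), 0.6)
        mask = BinaryMask.from_array(rng.random((32, 32)) < 0.2)
        out = filter_image(img, mask, sigma=2.0)
        assert np.allclose(out, 0.6, atol=1e-12)

    @pytest.mark.filterwarnings("ignore:.*no connected support")
    def test_hia_pixels_copied_through(self, rng):
        img = rng.random((32, 32))
        hia = rng.random((32, 32)) < 0.3
        out = filter_image(img, BinaryMask.from_array(hia), sigma=1.5)
        assert np.array_equal(out[hia], img[hia])

    @pytest.mark.parametrize("sigma", [0.8, 1.5])
    def test_fast_path_matches_direct_reference(self, rng, sigma):
        img = rng.random((16, 16))
        hia = np.zeros((16, 16), bool)
        hia[5:9, 6:10] = True  # one HIA blob
        direct, _ = _filter_image_direct(img, hia, sigma)
        fast = filter_image(img, hia, sigma, method="fast")
        assert np.allclose(fast, direct, atol=1e-10)

    def test_matches_independent_oracle(self, rng):
        img = rng.random((16, 16))
        hia = np.zeros((16, 16), bool)
        hia[5:9, 6:10] = True
        hia[0:2, 0:16] = True  # include a border-touching strip
        expected = _oracle_filter(img, hia, 1.5)
        for method in ("direct", "fast"):
            out = filter_image(img, hia, 1.5, method=method)
            assert np.allclose(out, expected, atol=1e-10)

    def test_no_cross_talk_from_hia_values(self, rng):
        """Changing HIA pixel values never changes any filter-region output."""
        img = rng.random((24, 24))
        hia = np.zeros((24, 24), bool)
        hia[8:12, 8:16] = True
        out1 = filter_image(img, hia, sigma=2.0)
        img2 = img.copy()
        img2[hia] += rng.random(hia.sum()) * 10
        out2 = filter_image(img2, hia, sigma=2.0)
        assert np.allclose(out1[~hia], out2[~hia], atol=1e-12)

    def test_locality_within_chebyshev_radius(self, rng):
        img = rng.random((40, 40))
        hia = np.zeros((40, 40), bool)
        sigma = 1.5
        c = int(np.ceil(3 * sigma))
        out1 = filter_image(img, hia, sigma)
        img2 = img.copy()
        img2[0, 0] += 5.0
        out2 = filter_image(img2, hia, sigma)
        yy, xx = np.mgrid[0:40, 0:40]
        far = np.maximum(yy, xx) > c
        assert np.allclose(out1[far], out2[far], atol=1e-9)

    def test_noise_reduction_bound_without_mask(self):
        """Plain Gaussian smoothing: residual noise below the analytic
        1 / (2 sigma sqrt(pi)) factor times a 1.5 border allowance."""
        sigma = 3.0
        truth = np.full((128, 128), 0.8)
        noisy = simulate_scan(truth, 1e-6, AcquisitionModel(seed=3))
        out = filter_image(noisy, np.zeros((128, 128), bool), sigma)
        in_std = (noisy - truth).std()
        out_std = (out - truth).std()
        assert out_std < in_std / (2 * sigma * np.sqrt(np.pi)) * 1.5

    def test_degenerate_pixel_falls_back_with_warning(self):
        img = np.arange(81, dtype=float).reshape(9, 9)
        hia = np.zeros((9, 9), bool)
        hia[3:6, 3:6] = True
        hia[4, 4] = False  # isolated filter pixel enclosed by HIA
        for method in ("direct", "fast"):
            with pytest.warns(UserWarning, match="no connected support"):
                out = filter_image(img, hia, sigma=0.5, method=method)
            assert out[4, 4] == img[4, 4]

    def test_no_mid_frequency_artifacts_at_large_sigma(self):
        """With sigma = 10 the filter-region residual spectrum is free of
        peaks near 5 px wavelength (the artifact band of moderate kernels)."""
        phantom = make_phantom("nodular", 256, 256, 8, seed=5)
        scan = simulate_scan(phantom, 300e-9, AcquisitionModel(seed=6))
        mask = threshold_top_fraction(gradient_magnitude(scan, 3.0), 0.1)
        out = filter_image(scan, mask, 10.0)
        residual = np.where(mask.values, 0.0, out - phantom.truth)
        power = np.abs(np.fft.fftshift(np.fft.fft2(residual))) ** 2
        n = residual.shape[0]
        fy = np.fft.fftshift(np.fft.fftfreq(n))
        radius = np.hypot(*np.meshgrid(fy, fy, indexing="ij"))
        ring = np.round(radius * n).astype(int)
        profile = np.bincount(ring.ravel(), power.ravel()) / np.bincount(ring.ravel())
        freqs = np.arange(profile.size) / n
        band = profile[(freqs >= 1 / 6) & (freqs <= 1 / 4)]  # 4-6 px wavelengths
        assert band.max() <= 3 * np.median(band)
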