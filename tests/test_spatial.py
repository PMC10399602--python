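"""Spatial statistics: slope, fractal dimensions, lacunarity, entropy, edges."""

import numpy as np
import pytest

from aesthstat import spatial, synthetic


class TestSpectralSlope:
    def test_white_noise_is_flat(self, rng):
        img = rng.random((256, 256))
        assert abs(spatial.spectral_slope(img)) < 0.1

    @pytest.mark.parametrize("beta", [-1.0, -1.5])
    def test_planted_exponent_recovered(self, beta):
        est = [
            spatial.spectral_slope(synthetic.make_spectral_image(256, beta, seed=s))
            for s in range(5)
        ]
        assert np.mean(est) == pytest.approx(beta, abs=0.05)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            spatial.spectral_slope(np.full((64, 64), 0.3))

    def test_mirror_invariance(self, rng):
        img = synthetic.make_spectral_image(128, -1.0, seed=3)
        a = spatial.spectral_slope(img)
        assert spatial.spectral_slope(img[::-1]) == pytest.approx(a, rel=1e-9)
        assert spatial.spectral_slope(img[:, ::-1]) == pytest.approx(a, rel=1e-9)


class TestFractalDimension1D:
    def test_straight_line_near_one(self):
        d = spatial.fractal_dimension_1d(synthetic.make_fractal_fixture("line", 256))
        assert d == pytest.approx(1.0, abs=0.1)

    def test_filled_plane_near_two(self):
        d = spatial.fractal_dimension_1d(synthetic.make_fractal_fixture("filled", 256))
        assert d == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_similarity_dimension(self):
        mask = synthetic.make_fractal_fixture("sierpinski", 256, levels=8)
        d = spatial.fractal_dimension_1d(mask)
        assert d == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            spatial.fractal_dimension_1d(np.zeros((64, 64), dtype=bool))

    def test_monotone_in_added_pixels(self, rng):
        # adding edge pixels never decreases any box count
        m1 = rng.random((128, 128)) < 0.01
        extra = rng.random((128, 128)) < 0.02
        m2 = m1 | extra

        def counts(m, s):
            mm = spatial._pad_to_multiple(m, s)
            h, w = mm.shape
            return mm.reshape(h // s, s, w // s, s).any(axis=(1, 3)).sum()

        for s in (1, 2, 4, 8, 16):
            assert counts(m2, s) >= counts(m1, s)


class TestFractalDimension2D:
    def test_constant_image_exactly_two(self):
        assert spatial.fractal_dimension_2d(np.full((128, 128), 0.4)) == pytest.approx(2.0)

    def test_planar_ramp_near_two(self):
        x = np.linspace(0, 1, 128)
        assert spatial.fractal_dimension_2d(np.outer(x, x)) == pytest.approx(2.0, abs=0.1)

    def test_fbm_surface_three_minus_hurst(self):
        ds = [
            spatial.fractal_dimension_2d(
                synthetic.make_fractal_fixture("fbm", 256, hurst=0.5, seed=s)
            )
            for s in range(5)
        ]
        assert np.mean(ds) == pytest.approx(2.5, abs=0.15)


class TestLacunarity:
    def test_filled_field_unity(self):
        curve = spatial.lacunarity_curve(np.ones((64, 64)), [1, 2, 4, 8])
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in curve.values())
        assert spatial.lacunarity(np.ones((64, 64)) * 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_box1_inverse_occupancy(self, rng):
        p = 0.3
        field = (rng.random((512, 512)) < p).astype(float)
        curve = spatial.lacunarity_curve(field, [1])
        assert curve[1] == pytest.approx(1 / p, rel=0.02)

    def test_checkerboard_box2_unity(self):
        cb = np.indices((64, 64)).sum(axis=0) % 2
        curve = spatial.lacunarity_curve(cb.astype(float), [2])
        assert curve[2] == pytest.approx(1.0, abs=1e-12)

    def test_jensen_lower_bound(self, rng):
        field = (rng.random((128, 128)) < 0.2).astype(float)
        curve = spatial.lacunarity_curve(field, [1, 2, 4, 8, 16])
        assert all(v >= 1.0 - 1e-12 for v in curve.values())

    def test_empty_field_raises(self):
        with pytest.raises(ValueError):
            spatial.lacunarity_curve(np.zeros((32, 32)), [2])


class TestEntropy:
    def test_constant_zero_bits(self):
        assert spatial.shannon_entropy(np.full((32, 32), 0.7)) == 0.0

    def test_uniform_256_levels_eight_bits(self):
        img = np.tile(np.arange(256) / 255.0, (256, 1))
        assert spatial.shannon_entropy(img) == pytest.approx(8.0, abs=1e-9)

    def test_half_half_one_bit(self):
        img = np.zeros((32, 32))
        img[:16] = 1.0
        assert spatial.shannon_entropy(img) == pytest.approx(1.0, abs=1e-12)

    def test_bounds(self, rng):
        e = spatial.shannon_entropy(rng.random((64, 64)))
        assert 0.0 <= e <= 8.0


class TestEdgeDensities:
    def test_blank_image_zero(self):
        st, ns = spatial.edge_density_straight_nonstraight(np.full((64, 64), 0.5))
        assert (st, ns) == (0.0, 0.0)

    def test_single_line_mostly_straight(self):
        img = np.zeros((128, 128))
        img[64, :] = 1.0
        img = spatial.ndimage.gaussian_filter(img, 1.0)
        st, ns = spatial.edge_density_straight_nonstraight(img)
        assert st > 0
        n_edge = st + ns
        assert ns < 0.05 * n_edge

    def test_circle_mostly_nonstraight(self):
        yy, xx = np.mgrid[:128, :128]
        img = ((yy - 64) ** 2 + (xx - 64) ** 2 < 40**2).astype(float)
        img = spatial.ndimage.gaussian_filter(img, 1.5)
        st, ns = spatial.edge_density_straight_nonstraight(img)
        assert ns > st


class TestGabor:
    def test_constant_image_near_zero(self):
        flat = spatial.gabor_edge_density(np.full((64, 64), 0.5))
        x = np.linspace(0, 2 * np.pi * 8, 64)
        grating = 0.5 + 0.5 * np.sin(np.tile(x, (64, 1)))
        assert flat < 1e-9 * spatial.gabor_edge_density(grating)

    def test_contrast_linearity(self):
        x = np.linspace(0, 2 * np.pi * 8, 64)
        g1 = 0.5 + 0.25 * np.sin(np.tile(x, (64, 1)))
        g2 = 0.5 + 0.50 * np.sin(np.tile(x, (64, 1)))
        r1 = spatial.gabor_edge_density(g1)
        r2 = spatial.gabor_edge_density(g2)
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_rotational_coverage(self):
        # a windowed grating rotated to filter-aligned orientations gets
        # equal responses (the smooth circular envelope avoids boundary
        # discontinuities that would otherwise differ between angles)
        n, size, f = 24, 128, 8
        yy, xx = np.mgrid[:size, :size] / size - 0.5
        window = np.exp(-((xx**2 + yy**2) / (2 * (1 / 6) ** 2)))
        resp = []
        for k in (0, 6, 12, 18):  # 0, 45, 90, 135 degrees
            t = np.pi * k / n
            phase = 2 * np.pi * f * (xx * np.cos(t) + yy * np.sin(t))
            resp.append(spatial.gabor_edge_density(0.5 + 0.4 * window * np.sin(phase)))
        resp = np.array(resp)
        assert resp.max() / resp.min() < 1.02


class TestEdgeOrientationEntropy:
    def _grating_edges(self, theta_deg=0.0, size=128, f=8):
        yy, xx = np.mgrid[:size, :size] / size
        t = np.radians(theta_deg)
        img = 0.5 + 0.4 * np.sin(2 * np.pi * f * (xx * np.cos(t) + yy * np.sin(t)))
        return spatial.compute_edge_map(img)

    def test_single_orientation_first_order_zero(self):
        em = self._grating_edges(0.0)
        assert spatial.edge_orientation_entropy(em, order="first") == pytest.approx(
            0.0, abs=0.3
        )

    def test_uniform_orientations_maximum(self):
        # synthetic edge map with orientations uniform over the 24 bins
        n = 24 * 50
        mask = np.zeros((80, 80), dtype=bool)
        mask.ravel()[:n] = True
        ori = np.zeros((80, 80))
        ori.ravel()[:n] = np.repeat(np.arange(24) * 7.5 + 1.0, 50)
        em = spatial.EdgeMap(magnitude=mask.astype(float), orientation=ori, edge_mask=mask)
        assert spatial.edge_orientation_entropy(em, order="first") == pytest.approx(
            np.log2(24), abs=1e-9
        )

    def test_parallel_lines_second_order_near_zero(self):
        img = np.zeros((128, 128))
        img[::16, :] = 1.0
        img = spatial.ndimage.gaussian_filter(img, 1.0)
        em = spatial.compute_edge_map(img)
        e2 = spatial.edge_orientation_entropy(em, order="second")
        assert e2 < 0.5

    def test_random_orientations_second_order_near_max(self, rng):
        mask = rng.random((128, 128)) < 0.15
        ori = rng.uniform(0, 180, (128, 128))
        em = spatial.EdgeMap(magnitude=np.ones((128, 128)), orientation=ori, edge_mask=mask)
        e2 = spatial.edge_orientation_entropy(em, order="second", max_edges=3000)
        n_diff_bins = 24 // 2 + 1
        # folding makes the 0 and 90 deg difference bins half-width, so the
        # attainable maximum is slightly below log2(n_diff_bins)
        p = np.full(n_diff_bins, 1 / 12.0)
        p[0] = p[-1] = 1 / 24.0
        max_attainable = -(p * np.log2(p)).sum()
        assert e2 > 0.95 * max_attainable

    def test_empty_mask_raises(self):
        em = spatial.EdgeMap(
            magnitude=np.zeros((8, 8)),
            orientation=np.zeros((8, 8)),
            edge_mask=np.zeros((8, 8), dtype=bool),
        )
        with pytest.raises(ValueError):
            spatial.edge_orientation_entropy(em)


class TestPhog:
    def test_constant_image(self):
        ss, an, cx = spatial.phog_features(np.full((64, 64), 0.3))
        assert np.isnan(ss) and an == 0.0 and cx == 0.0

    def test_tiled_image_maximal_self_similarity(self, rng):
        tile = rng.random((16, 16))
        img = np.tile(tile, (8, 8))
        ss, _, _ = spatial.phog_features(img)
        assert ss > 0.85

    def test_grating_more_anisotropic_than_noise(self, rng):
        x = np.linspace(0, 2 * np.pi * 8, 128)
        grating = 0.5 + 0.4 * np.sin(np.tile(x, (128, 1)))
        noise = rng.random((128, 128))
        noise = 0.5 + 0.4 * (noise - 0.5) / noise.std()
        _, an_g, _ = spatial.phog_features(grating)
        _, an_n, _ = spatial.phog_features(noise)
        assert an_g > an_n

    def test_complexity_is_mean_gradient_magnitude(self, rng):
        img = rng.random((32, 32))
        gy, gx = np.gradient(img)
        _, _, cx = spatial.phog_features(img)
        assert cx == pytest.approx(np.hypot(gx, gy).mean(), rel=1e-12)


class TestMirrorInvariance:
    @pytest.mark.parametrize(
        "fn",
        [
            spatial.shannon_entropy,
            spatial.fractal_dimension_2d,
            spatial.lacunarity,
        ],
    )
    def test_exact_mirror_invariance(self, fn, rng):
        img = rng.random((64, 64))
        a = fn(img)
        assert fn(img[::-1].copy()) == pytest.approx(a, rel=1e-9)
        assert fn(img[:, ::-1].copy()) == pytest.approx(a, rel=1e-9)
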