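import numpy as np
import pytest

from musfa import (
    BModeImage,
    PhantomSpec,
    ROIMask,
    ROITooSmallError,
    SFAConfig,
    ValidationError,
    analyze_kernels,
    analyze_roi,
    butterworth_highpass_gain,
    enumerate_kernels,
    frequency_bin_width,
    generate_phantom,
    highpass_filter,
    kernel_spectrum,
    rasterize_roi,
    spectral_parameters,
)
from musfa.sfa import KernelSpectrum


def brute_force_kernel_positions(mask, k, stride):
    rows, cols = mask.shape
    out = []
    for r in range(0, rows - k + 1):
        for c in range(0, cols - k + 1):
            if r % stride == 0 and c % stride == 0 and mask[r : r + k, c : c + k].all():
                out.append((r, c))
    return out


def make_spectrum(magnitude, spacing=0.1):
    p = magnitude.shape[0]
    axis = np.fft.fftshift(np.fft.fftfreq(p, d=spacing))
    return KernelSpectrum(magnitude=magnitude, freq_u=axis, freq_v=axis, origin_index=(p // 2, p // 2))


class TestConfig:
    def test_defaults(self):
        cfg = SFAConfig()
        assert (cfg.kernel_px, cfg.pad_px, cfg.stride_px) == (96, 128, 1)
        assert cfg.hp_cutoff == 1.0 and cfg.hp_order == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kernel_px": 0},
            {"kernel_px": 129},
            {"stride_px": 0},
            {"hp_cutoff": 0.0},
            {"hp_order": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValidationError):
            SFAConfig(**kwargs)


class TestEnumerateKernels:
    def test_exact_fit(self):
        mask = ROIMask(np.ones((96, 96), dtype=bool))
        assert enumerate_kernels(mask, SFAConfig()) == [(0, 0)]

    def test_100_grid(self):
        mask = ROIMask(np.ones((100, 100), dtype=bool))
        positions = enumerate_kernels(mask, SFAConfig())
        assert len(positions) == 25
        assert positions == [(r, c) for r in range(5) for c in range(5)]  # row-major

    def test_empty_when_too_small(self):
        mask = ROIMask(np.ones((50, 200), dtype=bool))
        assert enumerate_kernels(mask, SFAConfig()) == []

    def test_stride(self):
        mask = ROIMask(np.ones((100, 100), dtype=bool))
        positions = enumerate_kernels(mask, SFAConfig(stride_px=2))
        assert positions == [(r, c) for r in (0, 2, 4) for c in (0, 2, 4)]

    def test_random_blobs_match_oracle(self, rng):
        cfg = SFAConfig(kernel_px=8, pad_px=16)
        for _ in range(50):
            mask = rng.random((40, 40)) > 0.25
            got = enumerate_kernels(ROIMask(mask), cfg)
            assert got == brute_force_kernel_positions(mask, 8, 1)


class TestKernelSpectrum:
    def test_constant_kernel_closed_form(self):
        c = 3.0
        cfg = SFAConfig()
        img = BModeImage(np.full((96, 96), c), 0.06875, 0.06875)
        spec = kernel_spectrum(img, (0, 0), cfg)
        # Unnormalized DFT of a 96-wide constant block padded to 128 is a
        # separable Dirichlet kernel per axis.
        m = np.arange(128)
        with np.errstate(divide="ignore", invalid="ignore"):
            dirichlet = np.abs(
                np.where(
                    m == 0, 96.0, np.sin(np.pi * m * 96 / 128) / np.sin(np.pi * m / 128)
                )
            )
        expected = np.fft.fftshift(c * np.outer(dirichlet, dirichlet))
        np.testing.assert_allclose(spec.magnitude, expected, rtol=1e-9, atol=1e-6)
        assert spec.magnitude[spec.origin_index] == pytest.approx(96 * 96 * c)

    def test_all_zero_kernel(self):
        img = BModeImage(np.zeros((96, 96)), 0.1, 0.1)
        spec = kernel_spectrum(img, (0, 0), SFAConfig())
        assert spec.magnitude.max() == 0.0

    def test_cosine_peaks_at_expected_bin(self):
        cfg = SFAConfig()
        q = 16  # post-padding bin index
        j = np.arange(96)
        row = 100.0 * (1.0 + np.cos(2 * np.pi * q * j / cfg.pad_px))
        img = BModeImage(np.tile(row, (96, 1)), 0.1, 0.1)
        spec = kernel_spectrum(img, (0, 0), cfg)
        mag = spec.magnitude.copy()
        mag[spec.origin_index] = 0.0
        peaks = np.argwhere(mag == mag.max())
        centers = {tuple(p) for p in peaks}
        o = cfg.pad_px // 2
        assert centers == {(o, o - q), (o, o + q)}

    def test_frequency_axis_bin_width(self):
        img = BModeImage(np.ones((96, 96)), 0.05, 0.08)
        spec = kernel_spectrum(img, (0, 0), SFAConfig())
        assert np.diff(spec.freq_v) == pytest.approx(1 / (128 * 0.05))
        assert np.diff(spec.freq_u) == pytest.approx(1 / (128 * 0.08))
        assert spec.freq_u[64] == 0.0 and spec.freq_v[64] == 0.0

    def test_out_of_bounds_kernel(self):
        img = BModeImage(np.ones((100, 100)), 0.1, 0.1)
        with pytest.raises(ValidationError):
            kernel_spectrum(img, (10, 10), SFAConfig())

    def test_pad_placement_invariance(self):
        # magnitude spectrum is identical whether padding trails or centers
        rng = np.random.default_rng(0)
        block = rng.random((96, 96))
        trailing = np.zeros((128, 128))
        trailing[:96, :96] = block
        centered = np.zeros((128, 128))
        centered[16:112, 16:112] = block
        np.testing.assert_allclose(
            np.abs(np.fft.fft2(trailing)), np.abs(np.fft.fft2(centered)), atol=1e-8
        )


class TestHighpass:
    def test_minus_3db_at_cutoff(self):
        for order in (1, 2, 4):
            g = butterworth_highpass_gain(1.0, cutoff=1.0, order=order)
            assert 10 * np.log10(g**2) == pytest.approx(-3.0103, abs=0.01)

    def test_passband_high_frequency(self):
        cfg = SFAConfig()
        r_max = np.hypot(1 / (2 * 0.06875), 1 / (2 * 0.06875))
        assert butterworth_highpass_gain(r_max, cfg.hp_cutoff, cfg.hp_order) >= 0.99

    def test_order2_half_cutoff_closed_form(self):
        got = butterworth_highpass_gain(0.5, cutoff=1.0, order=2)
        assert got == pytest.approx(1 / np.sqrt(1 + 0.5**-4), rel=1e-12)

    def test_dc_nulled_and_monotone(self):
        r = np.linspace(0, 10, 2001)
        g = butterworth_highpass_gain(r, 1.0, 2)
        assert g[0] == 0.0
        assert np.all(np.diff(g) >= 0)

    def test_filter_applies_gain(self):
        mag = np.ones((8, 8))
        spec = make_spectrum(mag, spacing=0.5)
        out = highpass_filter(spec, SFAConfig(kernel_px=8, pad_px=8))
        expected = butterworth_highpass_gain(spec.radius_grid(), 1.0, 2)
        np.testing.assert_allclose(out.magnitude, expected)
        assert out.magnitude[out.origin_index] == 0.0


class TestSpectralParameters:
    def test_single_component(self):
        mag = np.zeros((16, 16))
        spec = make_spectrum(mag, spacing=1 / (16 * 0.5))  # bin width 0.5
        mag[8, 9] = 7.0   # (u, v) = (0.5, 0)
        mag[8, 7] = 7.0   # mirror
        spec = make_spectrum(mag, spacing=1 / (16 * 0.5))
        p = spectral_parameters(spec)
        assert p.psfr == pytest.approx(0.5)
        assert p.mmax == 7.0
        assert p.sum == 14.0
        assert p.mmax_pct == pytest.approx(50.0)

    def test_all_zero_degenerate(self):
        p = spectral_parameters(make_spectrum(np.zeros((8, 8))))
        assert p.degenerate
        assert (p.psfr, p.mmax, p.mmax_pct, p.sum) == (0.0, 0.0, 0.0, 0.0)

    def test_dc_excluded_from_peak(self):
        mag = np.zeros((8, 8))
        mag[4, 4] = 100.0  # DC
        mag[4, 6] = 5.0
        p = spectral_parameters(make_spectrum(mag))
        assert p.mmax == 5.0
        assert p.sum == 105.0  # DC still counted in the total

    def test_tie_broken_by_radius(self):
        mag = np.zeros((8, 8))
        mag[4, 5] = 3.0  # radius 1 bin
        mag[4, 7] = 3.0  # radius 3 bins
        p = spectral_parameters(make_spectrum(mag, spacing=1 / 8))
        assert p.psfr == pytest.approx(1.0)

    def test_brute_force_scan_oracle(self, rng):
        for _ in range(20):
            mag = rng.random((16, 16)) * 10
            spec = make_spectrum(mag, spacing=0.07)
            p = spectral_parameters(spec)
            best_m, total = -1.0, 0.0
            for i in range(16):
                for j in range(16):
                    total += mag[i, j]
                    if (i, j) != (8, 8) and mag[i, j] > best_m:
                        best_m = mag[i, j]
            assert p.mmax == pytest.approx(best_m, rel=1e-12)
            assert p.sum == pytest.approx(total, rel=1e-12)

    def test_mirror_symmetry_psfr(self, rng):
        # real input -> centro-symmetric magnitudes; either member of the
        # conjugate pair gives the same radius
        img = BModeImage(rng.random((96, 96)) * 50, 0.06875, 0.06875)
        spec = kernel_spectrum(img, (0, 0), SFAConfig())
        mag = spec.magnitude
        flipped = mag[::-1, ::-1]
        # centro-symmetry about DC (even-size grids: roll by one)
        np.testing.assert_allclose(np.roll(flipped, (1, 1), axis=(0, 1)), mag, atol=1e-6)


class TestAnalyzeROI:
    def test_mean_of_one(self, small_phantom, default_config):
        _, image, _ = small_phantom
        mask = np.zeros(image.shape, dtype=bool)
        mask[10:106, 12:108] = True
        res = analyze_roi(image, ROIMask(mask), default_config)
        per_kernel = analyze_kernels(image, ROIMask(mask), default_config)
        assert res.n_kernels == 1 and len(per_kernel) == 1
        assert res.psfr == per_kernel[0].psfr
        assert res.sum == per_kernel[0].sum

    def test_mmax_pct_identity_per_kernel(self, small_phantom, default_config):
        _, image, mask = small_phantom
        for q in analyze_kernels(image, mask, default_config):
            assert q.mmax_pct == pytest.approx(100 * q.mmax / q.sum, rel=1e-9)

    def test_disjoint_roi_mean_decomposition(self, default_config):
        spec = PhantomSpec(shape=(96, 200), band_freq=0.9, seed=3)
        image, _ = generate_phantom(spec, roi_margin_px=0)
        m1 = np.zeros(image.shape, dtype=bool)
        m1[:, :96] = True
        m2 = np.zeros(image.shape, dtype=bool)
        m2[:, 104:200] = True
        r1 = analyze_roi(image, ROIMask(m1), default_config)
        r2 = analyze_roi(image, ROIMask(m2), default_config)
        merged = analyze_roi(image, ROIMask(m1 | m2), default_config)
        n = r1.n_kernels + r2.n_kernels
        assert merged.n_kernels == n
        for attr in ("psfr", "mmax", "mmax_pct", "sum"):
            weighted = (
                getattr(r1, attr) * r1.n_kernels + getattr(r2, attr) * r2.n_kernels
            ) / n
            assert getattr(merged, attr) == pytest.approx(weighted, rel=1e-12)

    def test_too_small_roi(self, default_config):
        image = BModeImage(np.ones((128, 128)), 0.1, 0.1)
        mask = np.zeros(image.shape, dtype=bool)
        mask[:50, :50] = True
        with pytest.raises(ROITooSmallError, match="96x96"):
            analyze_roi(image, ROIMask(mask), default_config)

    def test_intensity_scaling_linearity(self, small_phantom, default_config):
        _, image, mask = small_phantom
        base = analyze_roi(image, mask, default_config)
        scaled_img = BModeImage(
            image.pixels * 2.5, image.spacing_axial, image.spacing_lateral
        )
        scaled = analyze_roi(scaled_img, mask, default_config)
        assert scaled.mmax == pytest.approx(2.5 * base.mmax, rel=1e-9)
        assert scaled.sum == pytest.approx(2.5 * base.sum, rel=1e-9)
        assert scaled.psfr == pytest.approx(base.psfr, rel=1e-12)
        assert scaled.mmax_pct == pytest.approx(base.mmax_pct, rel=1e-9)

    def test_stationarity_between_same_texture_rois(self, default_config):
        spec_a = PhantomSpec(shape=(140, 250), band_freq=0.8, seed=11)
        image, _ = generate_phantom(spec_a, roi_margin_px=0)
        m1 = np.zeros(image.shape, dtype=bool)
        m1[10:110, 10:115] = True
        m2 = np.zeros(image.shape, dtype=bool)
        m2[30:130, 130:240] = True
        r1 = analyze_roi(image, ROIMask(m1), default_config)
        r2 = analyze_roi(image, ROIMask(m2), default_config)
        # different texture for contrast
        other, _ = generate_phantom(PhantomSpec(shape=(140, 250), band_freq=1.4, seed=12), roi_margin_px=0)
        r3 = analyze_roi(other, ROIMask(m1), default_config)
        within = abs(r1.psfr - r2.psfr)
        between = abs(r1.psfr - r3.psfr)
        assert within < between

    def test_batched_matches_single_kernel_path(self, small_phantom, default_config):
        _, image, mask = small_phantom
        positions = enumerate_kernels(mask, default_config)[:3]
        batched = analyze_kernels(image, mask, default_config)[:3]
        for pos, got in zip(positions, batched):
            spec = highpass_filter(kernel_spectrum(image, pos, default_config), default_config)
            ref = spectral_parameters(spec)
            assert got.psfr == pytest.approx(ref.psfr, rel=1e-12)
            assert got.mmax == pytest.approx(ref.mmax, rel=1e-9)
            assert got.sum == pytest.approx(ref.sum, rel=1e-9)


def test_frequency_bin_width():
    assert frequency_bin_width(SFAConfig(), 0.06875) == pytest.approx(1 / (128 * 0.06875))
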